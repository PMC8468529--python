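"""Training and applying the lying-behavior classifiers.

Four classifiers are supported with fixed, grid-search-tuned
hyperparameters:

* random forest — 95 trees, Gini, max depth 25, min split 2, min leaf 1,
  6 features considered per split;
* decision tree — Gini, max depth 5, min split 2, min leaf 1;
* SVM — RBF kernel, C = 10, gamma = "scale";
* naive Bayes — Gaussian.

Windows are classified and the per-window labels are expanded back to the
per-second grid (majority vote where strides overlap, ties to non-lying).
Evaluation supports stratified 10-fold cross-validation and subject-wise
(leave-cows-out) splits in which test animals never contribute training
windows.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .postprocess import INVALID, LYING, NON_LYING, BinarySeries

_FORMAT_VERSION = 1

CLASSIFIERS = ("random_forest", "decision_tree", "svm", "naive_bayes")

DEFAULT_HYPERPARAMETERS = {
    "random_forest": {
        "n_estimators": 95, "criterion": "gini", "max_depth": 25,
        "min_samples_split": 2, "min_samples_leaf": 1, "max_features": 6,
        "bootstrap": True,
    },
    "decision_tree": {
        "criterion": "gini", "max_depth": 5,
        "min_samples_split": 2, "min_samples_leaf": 1,
    },
    "svm": {"kernel": "rbf", "C": 10.0, "gamma": "scale"},
    "naive_bayes": {},
}


@dataclass
class ModelSpec:
    """Full model configuration (serialized into every artifact)."""

    classifier: str = "random_forest"
    feature_set: str = "OI36"
    window_s: float = 5.0
    stride_fraction: float = 1.0
    rate_hz: float = 10.0
    seed: int = 42
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.feature_set not in FEATURE_NAMES:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.classifier])
        unknown = set(self.hyperparameters) - set(merged) if merged else set(
            self.hyperparameters)
        if unknown:
            raise ValueError(
                f"invalid hyperparameters for {self.classifier}: {sorted(unknown)}")
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


def build_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.classifier == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.classifier == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.classifier == "svm":
        return SVC(random_state=spec.seed, **hp)
    return GaussianNB(**hp)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    feature_names: tuple
    metadata: dict


def _check_features(X, spec: ModelSpec):
    names = FEATURE_NAMES[spec.feature_set]
    if isinstance(X, pd.DataFrame):
        if tuple(X.columns) != names:
            raise ValueError(
                f"feature columns do not match feature set {spec.feature_set}")
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError(
            f"expected {len(names)} features for {spec.feature_set}, "
            f"got shape {X.shape}")
    if np.isnan(X).any():
        raise ValueError("NaN feature values")
    return X


def train(features, labels, spec: ModelSpec,
          animal_ids=None) -> TrainedModel:
    """Fit the configured estimator; deterministic given ``spec.seed``."""
    X = _check_features(features, spec)
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    est = build_estimator(spec)
    t0 = time.perf_counter()
    est.fit(X, y)
    elapsed = time.perf_counter() - t0
    metadata = {
        "n_windows": int(len(X)),
        "class_counts": {str(c): int(n) for c, n in zip(classes, counts)},
        "training_animals": sorted(set(animal_ids)) if animal_ids is not None else None,
        "training_data_s": float(len(X) * spec.window_s * spec.stride_fraction),
        "fit_seconds": elapsed,
    }
    return TrainedModel(spec=spec, estimator=est,
                        feature_names=FEATURE_NAMES[spec.feature_set],
                        metadata=metadata)


def binarize_labels(labels) -> np.ndarray:
    """Map multi-class behavior labels to lying / non_lying."""
    labels = np.asarray(labels, dtype=object)
    return np.where(labels == "lying", "lying", "non_lying")


def predict_windows(model: TrainedModel, features) -> np.ndarray:
    """Per-window binary labels (``lying`` / ``non_lying``).

    Multi-class models are binarized: the lying class maps to lying,
    everything else to non-lying.
    """
    if len(features) == 0:
        return np.empty(0, dtype=object)
    X = _check_features(features, model.spec)
    raw = model.estimator.predict(X)
    return binarize_labels(raw)


def expand_to_seconds(window_labels, window_starts_s, window_s: float,
                      t0: int | None = None,
                      t1: int | None = None) -> BinarySeries:
    """Expand per-window labels onto the integer-second grid.

    Each second overlapped by a window inherits its label; where strides
    overlap, seconds take the majority label with ties going to non-lying.
    Seconds covered by no window are invalid.
    """
    window_labels = np.asarray(window_labels, dtype=object)
    starts = np.asarray(window_starts_s, dtype=float)
    if len(window_labels) != len(starts):
        raise ValueError("labels and starts disagree in length")
    if len(starts) == 0:
        if t0 is None or t1 is None:
            return BinarySeries(0, np.empty(0, dtype=np.int8))
        return BinarySeries(int(t0), np.full(int(t1) - int(t0), INVALID, np.int8))
    lo = int(np.floor(starts.min())) if t0 is None else int(t0)
    hi = (int(np.ceil((starts + window_s).max())) if t1 is None else int(t1))
    n = hi - lo
    votes_l = np.zeros(n, dtype=int)
    votes_n = np.zeros(n, dtype=int)
    for lab, s in zip(window_labels, starts):
        a = max(int(np.floor(s)), lo) - lo
        b = min(int(np.ceil(s + window_s)), hi) - lo
        if b <= a:
            continue
        if lab == "lying":
            votes_l[a:b] += 1
        else:
            votes_n[a:b] += 1
    labels = np.full(n, INVALID, dtype=np.int8)
    covered = (votes_l + votes_n) > 0
    labels[covered & (votes_l > votes_n)] = LYING
    labels[covered & (votes_l <= votes_n)] = NON_LYING
    return BinarySeries(lo, labels)


def kfold_cv(features, labels, spec: ModelSpec, k: int = 10,
             seed: int | None = None) -> dict:
    """Stratified k-fold cross-validated accuracy (mean, SD, per-fold)."""
    X = _check_features(features, spec)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(y):
        raise ValueError("k exceeds the number of windows")
    seed = spec.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        est = build_estimator(spec)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    accs = np.asarray(accs)
    return {"mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std()),
            "fold_accuracies": accs.tolist(), "k": k}


def subject_cv(features_by_animal: dict, spec: ModelSpec,
               train_ids, test_ids) -> dict:
    """Leave-cows-out evaluation: test animals are disjoint from training.

    ``features_by_animal`` maps animal id to ``(X, y)``. Returns pooled and
    per-animal accuracies plus the split metadata.
    """
    train_ids, test_ids = list(train_ids), list(test_ids)
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test animal sets overlap")
    Xtr = np.vstack([_check_features(features_by_animal[a][0], spec)
                     for a in train_ids])
    ytr = np.concatenate([np.asarray(features_by_animal[a][1])
                          for a in train_ids])
    ids = np.concatenate([np.full(len(features_by_animal[a][1]), a, object)
                          for a in train_ids])
    model = train(Xtr, ytr, spec, animal_ids=ids)
    per_animal = {}
    correct = total = 0
    for a in test_ids:
        X, y = features_by_animal[a]
        yhat = predict_windows(model, X)
        ybin = binarize_labels(y)
        per_animal[a] = float(np.mean(yhat == ybin))
        correct += int(np.sum(yhat == ybin))
        total += len(ybin)
    return {
        "pooled_accuracy": correct / total if total else None,
        "per_animal_accuracy": per_animal,
        "train_ids": sorted(train_ids), "test_ids": sorted(test_ids),
        "model": model,
    }


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model with its spec and format version."""
    joblib.dump({
        "format_version": _FORMAT_VERSION,
        "spec": asdict(model.spec),
        "feature_names": list(model.feature_names),
        "metadata": model.metadata,
        "estimator": model.estimator,
    }, path)


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != _FORMAT_VERSION:
        raise ValueError("incompatible model archive version")
    spec = ModelSpec(**blob["spec"])
    names = tuple(blob["feature_names"])
    if names != FEATURE_NAMES[spec.feature_set]:
        raise ValueError("model archive feature set does not match this version")
    return TrainedModel(spec=spec, estimator=blob["estimator"],
                        feature_names=names, metadata=blob["metadata"])
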