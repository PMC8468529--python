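"""Window feature sets: orientation-dependent (24) and orientation-independent (36).

Two sets are computed per window:

* **OD24** — max, mean, median and population standard deviation of each of
  the six raw axes (ax, ay, az, heading, roll, pitch). These change when the
  collar rotates around the neck.
* **OI36** — 18 functions applied to two derived axes, the per-sample
  Euclidean magnitude of the acceleration vector and of the Euler
  ("NDOF") vector: min, max, mean, median, standard deviation,
  interquartile range, RMS, mean crossing rate, excess kurtosis, skewness,
  spectral energy, peak frequency, frequency-domain entropy and the first
  five frequency-profile components. Because a rotation of the sensor frame
  preserves vector norms, the acceleration half of this set is exactly
  rotation-invariant.

Numerical conventions (fixed here, pinned by oracle tests):

* standard deviation uses divisor ``n``; kurtosis is Fisher (excess) and
  skewness Fisher-Pearson, both defined as 0 for a zero-variance series;
* IQR uses linear-interpolation quantiles; RMS = sqrt(mean(x**2));
* mean crossing rate counts consecutive-sample pairs whose mean-centered
  values have strictly opposite signs, divided by ``n - 1``;
* the spectrum is the real DFT of the mean-removed series (no taper, no
  padding) with one-sided power ``p_k = |X_k|**2 / n`` for
  ``k = 1..floor(n/2)`` (DC excluded); spectral energy is ``sum p_k``, peak
  frequency ``argmax p_k`` converted to Hz (ties to the lowest bin),
  entropy ``-sum q_k ln q_k`` of the normalized power (0 for an empty
  spectrum); the frequency-profile components are ``sqrt(p_k) = |X_k|/sqrt(n)``
  for ``k = 1..5``, zero-padded when the window has fewer than 5 non-DC bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RAW_AXES = ("ax", "ay", "az", "eh", "er", "ep")
OD_FUNCS = ("max", "mean", "median", "std")

OI_FUNCS = (
    "min", "max", "mean", "median", "std", "iqr", "rms", "mcr",
    "kurtosis", "skewness", "spectral_energy", "peak_freq_hz",
    "freq_entropy", "fp1", "fp2", "fp3", "fp4", "fp5",
)
DERIVED_AXES = ("acc_mag", "ndof_mag")

OD24_NAMES = tuple(f"{ax}__{fn}" for ax in RAW_AXES for fn in OD_FUNCS)
OI36_NAMES = tuple(f"{ax}__{fn}" for ax in DERIVED_AXES for fn in OI_FUNCS)

FEATURE_NAMES = {"OD24": OD24_NAMES, "OI36": OI36_NAMES}


@dataclass(frozen=True)
class FeatureVector:
    set_id: str
    names: tuple
    values: np.ndarray

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("feature vector length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


def magnitude(v: np.ndarray) -> np.ndarray:
    """Euclidean norm along the last axis."""
    return np.linalg.norm(np.asarray(v, dtype=float), axis=-1)


# -- batch kernels: M is (k, n), one series per row ------------------------

def _std(M):
    return M.std(axis=1)  # population (divisor n)


def _iqr(M):
    q1, q3 = np.percentile(M, [25, 75], axis=1)
    return q3 - q1


def _rms(M):
    return np.sqrt(np.mean(M * M, axis=1))


def _mcr(M):
    c = M - M.mean(axis=1, keepdims=True)
    s = np.sign(c)
    opposite = s[:, 1:] * s[:, :-1] < 0
    return opposite.sum(axis=1) / (M.shape[1] - 1)


def _moments(M):
    """Excess kurtosis and skewness with 0 for zero-variance rows."""
    c = M - M.mean(axis=1, keepdims=True)
    m2 = np.mean(c ** 2, axis=1)
    m3 = np.mean(c ** 3, axis=1)
    m4 = np.mean(c ** 4, axis=1)
    ok = m2 > 0
    kurt = np.zeros(len(M))
    skew = np.zeros(len(M))
    kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    return kurt, skew


def _spectrum(M, rate_hz):
    """One-sided power (DC excluded) and derived spectral features."""
    n = M.shape[1]
    X = np.fft.rfft(M - M.mean(axis=1, keepdims=True), axis=1)
    p = np.abs(X[:, 1:n // 2 + 1]) ** 2 / n       # k = 1..floor(n/2)
    energy = p.sum(axis=1)
    nbins = p.shape[1]
    if nbins:
        kstar = np.argmax(p, axis=1) + 1          # ties -> lowest k
        peak = np.where(energy > 0, kstar * rate_hz / n, 0.0)
    else:
        peak = np.zeros(len(M))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = p / energy[:, None]
        ent = np.where(energy[:, None] > 0, -np.where(q > 0, q * np.log(q), 0.0), 0.0)
    entropy = ent.sum(axis=1)
    profile = np.zeros((len(M), 5))
    take = min(5, nbins)
    profile[:, :take] = np.sqrt(p[:, :take])
    return energy, peak, entropy, profile


def oi_feature_matrix(M: np.ndarray, rate_hz: float) -> np.ndarray:
    """The 18 orientation-independent functions for each row of ``M``."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] == 0:
        raise ValueError("need a non-empty (k, n) series matrix")
    kurt, skew = _moments(M)
    energy, peak, entropy, profile = _spectrum(M, rate_hz)
    cols = [
        M.min(axis=1), M.max(axis=1), M.mean(axis=1),
        np.median(M, axis=1), _std(M), _iqr(M), _rms(M), _mcr(M),
        kurt, skew, energy, peak, entropy,
        profile[:, 0], profile[:, 1], profile[:, 2], profile[:, 3],
        profile[:, 4],
    ]
    return np.column_stack(cols)


def _window_axes(window) -> np.ndarray:
    """(n, 6) matrix of raw axes in canonical order."""
    return np.hstack([window.accel, window.euler])


def extract_od24(window) -> FeatureVector:
    """Max/mean/median/std of the six raw axes (orientation-dependent)."""
    if window.n_samples == 0:
        raise ValueError("empty window")
    A = _window_axes(window)            # (n, 6)
    vals = np.empty(24)
    vals[0::4] = A.max(axis=0)
    vals[1::4] = A.mean(axis=0)
    vals[2::4] = np.median(A, axis=0)
    vals[3::4] = A.std(axis=0)
    return FeatureVector("OD24", OD24_NAMES, vals)


def extract_oi36(window) -> FeatureVector:
    """The 18 functions on acceleration and NDOF magnitudes."""
    if window.n_samples == 0:
        raise ValueError("empty window")
    acc = magnitude(window.accel)[None, :]
    ndof = magnitude(window.euler)[None, :]
    vals = np.concatenate([
        oi_feature_matrix(acc, window.rate_hz)[0],
        oi_feature_matrix(ndof, window.rate_hz)[0],
    ])
    return FeatureVector("OI36", OI36_NAMES, vals)


def extract(window, set_id: str) -> FeatureVector:
    if set_id == "OD24":
        return extract_od24(window)
    if set_id == "OI36":
        return extract_oi36(window)
    raise ValueError(f"unknown feature set {set_id!r}")


def feature_table(windows, set_id: str) -> pd.DataFrame:
    """Feature matrix for many windows (vectorized batch path).

    Returns a DataFrame with the stable column names of ``set_id``; row
    ``i`` corresponds to ``windows[i]``. Bit-identical to per-window
    :func:`extract` (same kernels operate on stacked rows).
    """
    if set_id not in FEATURE_NAMES:
        raise ValueError(f"unknown feature set {set_id!r}")
    if not windows:
        return pd.DataFrame(columns=FEATURE_NAMES[set_id])
    rate = windows[0].rate_hz
    if set_id == "OD24":
        vals = np.stack([extract_od24(w).values for w in windows])
    else:
        acc = np.stack([magnitude(w.accel) for w in windows])
        ndof = np.stack([magnitude(w.euler) for w in windows])
        vals = np.hstack([oi_feature_matrix(acc, rate),
                          oi_feature_matrix(ndof, rate)])
    return pd.DataFrame(vals, columns=FEATURE_NAMES[set_id])


def rank_features(features: pd.DataFrame, labels, seed: int = 42,
                  n_estimators: int = 95) -> pd.Series:
    """Impurity-based importances from a random forest, descending.

    Reporting aid only — no features are dropped by default. Importances
    are normalized to sum to 1 by the forest.
    """
    from sklearn.ensemble import RandomForestClassifier

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("feature ranking needs at least two classes")
    forest = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=seed)
    forest.fit(features.to_numpy(), labels)
    imp = pd.Series(forest.feature_importances_, index=features.columns)
    return imp.sort_values(ascending=False)
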