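"""End-to-end stages shared by the command-line interface and experiments.

These helpers chain the modules: read/rasterize -> segment -> label pure
windows -> extract features -> train; and for prediction: segment ->
extract -> classify -> expand to seconds -> interbout filter. They are
deliberately thin — every scientific decision lives in the stage modules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import bout_analysis, evaluation, postprocess
from .classification import (ModelSpec, TrainedModel, expand_to_seconds,
                             predict_windows, train)
from .features import feature_table
from .postprocess import BinarySeries, interbout_filter
from .segmentation import label_windows, segment
from .sensor_io import LabelTimeline, SensorStream, rasterize_labels


@dataclass
class RunConfig:
    """Run-level configuration, serialized into every output manifest."""

    window_s: float = 5.0
    stride_fraction: float = 1.0
    rate_hz: float = 10.0
    feature_set: str = "OI36"
    classifier: str = "random_forest"
    filter_min_dur_s: int = 60
    seed: int = 42

    def model_spec(self) -> ModelSpec:
        return ModelSpec(classifier=self.classifier,
                         feature_set=self.feature_set,
                         window_s=self.window_s,
                         stride_fraction=self.stride_fraction,
                         rate_hz=self.rate_hz, seed=self.seed)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def timeline_from_intervals(intervals, t0: int, t1: int,
                            animal_id: str = "") -> LabelTimeline:
    return rasterize_labels(intervals, t0, t1, animal_id=animal_id)


def training_table(stream: SensorStream, timeline: LabelTimeline,
                   config: RunConfig, binary: bool = True):
    """Pure-window feature matrix and labels for one animal(-day)."""
    windows = segment(stream, config.window_s, config.stride_fraction)
    windows = label_windows(windows, timeline, binary=binary)
    keep = [w for w in windows if w.pure and w.label is not None]
    X = feature_table(keep, config.feature_set)
    y = np.array([w.label for w in keep], dtype=object)
    return X, y


def predict_stream(model: TrainedModel, stream: SensorStream,
                   filter_min_dur_s: int = 60):
    """Per-second raw and interbout-filtered predictions for one stream.

    Returns ``(raw, filtered)`` :class:`BinarySeries`; seconds not covered
    by any complete window (data gaps, stream edges) are invalid in both.
    """
    spec = model.spec
    windows = segment(stream, spec.window_s, spec.stride_fraction)
    t0 = int(np.floor(stream.t_ms[0] / 1000.0))
    t1 = int(np.ceil((stream.t_ms[-1] + 1000.0 / stream.nominal_rate) / 1000.0))
    if not windows:
        raw = BinarySeries(t0, np.full(t1 - t0, postprocess.INVALID, np.int8))
        return raw, raw.copy()
    X = feature_table(windows, spec.feature_set)
    labels = predict_windows(model, X)
    starts = [w.start_s for w in windows]
    raw = expand_to_seconds(labels, starts, spec.window_s, t0=t0, t1=t1)
    filtered = interbout_filter(raw, filter_min_dur_s)
    return raw, filtered


def train_animals(data_by_animal: dict, config: RunConfig,
                  binary: bool = True) -> TrainedModel:
    """Train on ``{animal: (stream, timeline)}`` pooled pure windows."""
    Xs, ys, ids = [], [], []
    for animal, (stream, timeline) in sorted(data_by_animal.items()):
        X, y = training_table(stream, timeline, config, binary=binary)
        Xs.append(X)
        ys.append(y)
        ids.extend([animal] * len(y))
    X = pd.concat(Xs, ignore_index=True)
    y = np.concatenate(ys) if ys else np.empty(0, dtype=object)
    if len(y) == 0:
        raise ValueError("no pure labeled windows available for training")
    return train(X, y, config.model_spec(), animal_ids=ids)


def evaluate_prediction(gt: BinarySeries, pred: BinarySeries) -> dict:
    """Confusion metrics plus lying-bout matching for one series pair."""
    counts = evaluation.confusion(gt, pred)
    report = evaluation.metrics(counts)
    gt_bouts = [b for b in bout_analysis.extract_bouts(gt)
                if b.label == postprocess.LYING]
    pred_bouts = [b for b in bout_analysis.extract_bouts(pred)
                  if b.label == postprocess.LYING]
    match = bout_analysis.match_bouts(gt_bouts, pred_bouts)
    deviations = bout_analysis.boundary_deviation(match.detected)
    durations = bout_analysis.compare_durations(match.detected)
    return {
        "counts": counts,
        "metrics": report,
        "metrics_percent": report.as_percent(),
        "bout_counts": match.counts,
        "boundary_deviation": {"begin": deviations["begin"],
                               "end": deviations["end"]},
        "paired_durations_s": durations,
    }
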