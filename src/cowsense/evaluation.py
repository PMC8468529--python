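"""Per-second confusion counting, the lying-metric suite, and aggregation.

Lying is the positive class. For seconds valid in both series:

* TP — ground truth lying, prediction lying
* TN — ground truth non-lying, prediction non-lying
* FP — ground truth non-lying, prediction lying
* FN — ground truth lying, prediction non-lying

and the derived ratios::

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)

All ratios are scale invariant, so counts may be seconds or hours. A ratio
with a zero denominator is reported as ``None`` (not available), never 0.
Percentages are formatted at one decimal, rounding half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .postprocess import INVALID, LYING, NON_LYING, BinarySeries


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None

    def as_percent(self) -> dict:
        return {k: None if v is None else round_percent(v)
                for k, v in self.__dict__.items()}


def round_percent(fraction: float, decimals: int = 1) -> float:
    """``fraction`` as a percentage, half rounded away from zero."""
    x = fraction * 100.0 * 10 ** decimals
    return math.copysign(math.floor(abs(x) + 0.5), x) / 10 ** decimals


def confusion(gt: BinarySeries, pred: BinarySeries) -> ConfusionCounts:
    """Per-second confusion over seconds valid in both series."""
    if gt.start_s != pred.start_s or len(gt) != len(pred):
        raise ValueError("ground truth and prediction series are misaligned")
    m = (gt.labels != INVALID) & (pred.labels != INVALID)
    g = gt.labels[m] == LYING
    p = pred.labels[m] == LYING
    return ConfusionCounts(
        tp=float(np.sum(g & p)), tn=float(np.sum(~g & ~p)),
        fp=float(np.sum(~g & p)), fn=float(np.sum(g & ~p)))


def _ratio(num, den):
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("no compared seconds")
    return MetricsReport(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn))


def reconstruct_counts(total_h: float, gt_lying_fraction: float,
                       fn_h: float, fp_h: float) -> ConfusionCounts:
    """Confusion counts (hours) from published aggregate bookkeeping.

    Given total compared hours, the ground-truth lying share, and the
    falsely-classified hours in each direction, the full confusion matrix
    follows: ``TP = share * total - FN`` and ``TN = (1 - share) * total - FP``.
    """
    if not 0 <= gt_lying_fraction <= 1:
        raise ValueError("gt_lying_fraction must be within [0, 1]")
    lying_h = gt_lying_fraction * total_h
    non_lying_h = total_h - lying_h
    if fn_h > lying_h:
        raise ValueError("FN hours exceed ground-truth lying hours")
    if fp_h > non_lying_h:
        raise ValueError("FP hours exceed ground-truth non-lying hours")
    return ConfusionCounts(tp=lying_h - fn_h, tn=non_lying_h - fp_h,
                           fp=fp_h, fn=fn_h)


def stratify(gt: BinarySeries, pred: BinarySeries,
             keys: pd.DataFrame) -> dict:
    """Metrics pooled and per (animal, day, location, farm) stratum.

    ``keys`` must have one row per second of the series with columns
    ``animal``, ``day``, ``location``, ``farm``. Returns per-stratum counts
    and metrics, pooled counts, and medians of per-(animal, day) accuracy
    overall and by location.
    """
    required = {"animal", "day", "location", "farm"}
    if gt.start_s != pred.start_s or len(gt) != len(pred):
        raise ValueError("misaligned series")
    if len(keys) != len(gt) or not required.issubset(keys.columns):
        raise ValueError("keys must cover every second with columns "
                         f"{sorted(required)}")
    m = (gt.labels != INVALID) & (pred.labels != INVALID)
    if keys.loc[m, sorted(required)].isna().any().any():
        raise ValueError("missing stratum keys on compared seconds")
    df = pd.DataFrame({
        "gt": gt.labels, "pred": pred.labels,
        "animal": keys["animal"], "day": keys["day"],
        "location": keys["location"], "farm": keys["farm"],
    })[m]
    strata = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for key, grp in df.groupby(["animal", "day", "location", "farm"]):
        g = grp["gt"].to_numpy() == LYING
        p = grp["pred"].to_numpy() == LYING
        c = ConfusionCounts(tp=float(np.sum(g & p)), tn=float(np.sum(~g & ~p)),
                            fp=float(np.sum(~g & p)), fn=float(np.sum(g & ~p)))
        strata[key] = {"counts": c, "metrics": metrics(c)}
        pooled = pooled + c

    per_ad = {}
    for key, entry in strata.items():
        ad = (key[0], key[1])
        per_ad.setdefault(ad, ConfusionCounts(0, 0, 0, 0))
        per_ad[ad] = per_ad[ad] + entry["counts"]
    ad_acc = {ad: metrics(c).accuracy for ad, c in per_ad.items()}

    by_loc = {}
    for key, entry in strata.items():
        loc = key[2]
        by_loc.setdefault(loc, {})
        ad = (key[0], key[1])
        by_loc[loc].setdefault(ad, ConfusionCounts(0, 0, 0, 0))
        by_loc[loc][ad] = by_loc[loc][ad] + entry["counts"]
    median_by_loc = {
        loc: float(np.median([metrics(c).accuracy for c in d.values()]))
        for loc, d in by_loc.items()}

    return {
        "strata": strata,
        "pooled_counts": pooled,
        "pooled_metrics": metrics(pooled),
        "median_accuracy_per_animal_day": float(np.median(list(ad_acc.values()))),
        "median_accuracy_by_location": median_by_loc,
    }


def label_agreement(timeline_a, timeline_b, detail: bool = True) -> float:
    """Percent per-second agreement between two labeled timelines.

    ``detail=True`` requires identical exclusive behavior and overlay set;
    ``detail=False`` compares only the lying / non-lying binarization.
    Computed over seconds valid in both timelines.
    """
    if timeline_a.start_s != timeline_b.start_s or len(timeline_a) != len(timeline_b):
        raise ValueError("timelines cover different time frames")
    m = timeline_a.valid & timeline_b.valid
    n = int(np.sum(m))
    if n == 0:
        raise ValueError("no jointly valid seconds")
    if detail:
        same_b = timeline_a.behavior[m] == timeline_b.behavior[m]
        idx = np.nonzero(m)[0]
        same_o = np.array([timeline_a.overlays[i] == timeline_b.overlays[i]
                           for i in idx])
        agree = np.sum(same_b & same_o)
    else:
        a = timeline_a.behavior[m] == "lying"
        b = timeline_b.behavior[m] == "lying"
        agree = np.sum(a == b)
    return 100.0 * float(agree) / n


@dataclass(frozen=True)
class DailyLyingTime:
    total_h: float
    day_h: float
    night_h: float
    missing_fraction: float
    excluded: bool      # >10% of the day missing


def daily_lying_time(pred: BinarySeries,
                     day_window: tuple[int, int] = (6 * 3600, 18 * 3600),
                     max_missing: float = 0.10) -> DailyLyingTime:
    """Lying hours over a civil day, split into day and night.

    ``pred.start_s`` is interpreted as seconds since local midnight. The
    day window defaults to 06:00-18:00. Animals with more than
    ``max_missing`` of the covered span invalid are flagged excluded.
    """
    sod = (pred.start_s + np.arange(len(pred))) % 86400
    valid = pred.labels != INVALID
    lying = pred.labels == LYING
    in_day = (sod >= day_window[0]) & (sod < day_window[1])
    missing = 1.0 - float(np.mean(valid)) if len(pred) else 1.0
    return DailyLyingTime(
        total_h=float(np.sum(lying)) / 3600.0,
        day_h=float(np.sum(lying & in_day)) / 3600.0,
        night_h=float(np.sum(lying & ~in_day)) / 3600.0,
        missing_fraction=missing,
        excluded=missing > max_missing)
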