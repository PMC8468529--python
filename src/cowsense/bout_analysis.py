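"""Bout extraction, predicted-vs-ground-truth bout matching, and boundary error.

A lying bout is a maximal continuous lying period (between a lying-down and
a standing-up event); non-lying bouts are defined symmetrically. Predicted
bouts are matched to ground-truth bouts of the same label by temporal
overlap (at least 1 s) and classified:

* **detected** — exactly one predicted bout overlaps the ground-truth bout,
  and that predicted bout overlaps no other ground-truth bout (1:1);
* **merged**  — one predicted bout spans two or more ground-truth bouts;
* **divided** — two or more predicted bouts split one ground-truth bout;
* **missed**  — a ground-truth bout with no overlapping prediction;
* **added**   — a predicted bout overlapping no ground-truth bout.

In a many-to-many overlap component the merged classification dominates
(deterministic tie-break). Boundary deviations (signed; positive = model
late) and duration comparisons use only 1:1 detected pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .postprocess import INVALID, LYING, NON_LYING, BinarySeries, runs


@dataclass(frozen=True)
class Bout:
    label: int            # LYING or NON_LYING
    start_s: int
    end_s: int
    complete: bool        # both boundaries observed, no invalid inside

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s

    def overlap_s(self, other: "Bout") -> int:
        return max(0, min(self.end_s, other.end_s)
                   - max(self.start_s, other.start_s))


@dataclass
class BoutMatchReport:
    label: int
    detected: list = field(default_factory=list)   # (gt, pred, overlap_s)
    merged: list = field(default_factory=list)     # gt bouts
    divided: list = field(default_factory=list)    # gt bouts
    missed: list = field(default_factory=list)     # gt bouts
    added: list = field(default_factory=list)      # pred bouts

    @property
    def counts(self) -> dict:
        return {
            "detected": len(self.detected), "merged": len(self.merged),
            "divided": len(self.divided), "missed": len(self.missed),
            "added": len(self.added),
        }

    @property
    def n_gt(self) -> int:
        return (len(self.detected) + len(self.merged) + len(self.divided)
                + len(self.missed))


def extract_bouts(series: BinarySeries) -> list[Bout]:
    """Maximal lying / non-lying runs as bouts.

    A bout is complete when both of its boundaries were observed: the
    seconds immediately before and after the run exist in the series and
    are valid. Runs touching the series edge or an invalid block are
    incomplete.
    """
    run_list = runs(series)
    bouts = []
    for i, (lab, start, dur) in enumerate(run_list):
        if lab == INVALID:
            continue
        left_ok = i > 0 and run_list[i - 1][0] != INVALID
        right_ok = i < len(run_list) - 1 and run_list[i + 1][0] != INVALID
        bouts.append(Bout(label=lab, start_s=start, end_s=start + dur,
                          complete=left_ok and right_ok))
    return bouts


def match_bouts(gt_bouts, pred_bouts) -> BoutMatchReport:
    """Classify same-label bouts by the overlap taxonomy (>= 1 s overlap)."""
    labels = {b.label for b in gt_bouts} | {b.label for b in pred_bouts}
    if len(labels) > 1:
        raise ValueError("match_bouts needs bouts of a single label")
    label = labels.pop() if labels else LYING
    report = BoutMatchReport(label=label)

    ov = np.zeros((len(gt_bouts), len(pred_bouts)), dtype=int)
    for i, g in enumerate(gt_bouts):
        for j, p in enumerate(pred_bouts):
            ov[i, j] = g.overlap_s(p)
    gt_deg = (ov > 0).sum(axis=1) if len(pred_bouts) else np.zeros(len(gt_bouts), int)
    pred_deg = (ov > 0).sum(axis=0) if len(gt_bouts) else np.zeros(len(pred_bouts), int)

    for j, p in enumerate(pred_bouts):
        if pred_deg[j] == 0:
            report.added.append(p)
    for i, g in enumerate(gt_bouts):
        if gt_deg[i] == 0:
            report.missed.append(g)
            continue
        partners = np.nonzero(ov[i] > 0)[0]
        if any(pred_deg[j] >= 2 for j in partners):
            # some overlapping prediction spans several GT bouts
            report.merged.append(g)
        elif len(partners) >= 2:
            report.divided.append(g)
        else:
            j = int(partners[0])
            report.detected.append((g, pred_bouts[j], int(ov[i, j])))
    return report


def boundary_deviation(detected_pairs) -> dict:
    """Signed begin/end deviations of 1:1 detected pairs (positive = late).

    Returns the deviation lists plus medians and the shares within +/-4 s
    and +/-10 min.
    """
    begins = np.array([p.start_s - g.start_s for g, p, _ in detected_pairs],
                      dtype=float)
    ends = np.array([p.end_s - g.end_s for g, p, _ in detected_pairs],
                    dtype=float)

    def _summ(d):
        if len(d) == 0:
            return {"n": 0, "median_s": None,
                    "share_within_4s": None, "share_within_10min": None}
        return {
            "n": int(len(d)),
            "median_s": float(np.median(d)),
            "share_within_4s": float(np.mean(np.abs(d) <= 4)),
            "share_within_10min": float(np.mean(np.abs(d) <= 600)),
        }

    return {"begin_s": begins.tolist(), "end_s": ends.tolist(),
            "begin": _summ(begins), "end": _summ(ends)}


def compare_durations(detected_pairs, require_complete: bool = True):
    """Paired ``(gt_duration_s, pred_duration_s)`` for uninterrupted bouts.

    Only pairs where both the ground-truth and the predicted bout were
    completely observed (no invalid second inside, both boundaries seen)
    qualify when ``require_complete``.
    """
    out = []
    for g, p, _ in detected_pairs:
        if require_complete and not (g.complete and p.complete):
            continue
        out.append((g.duration_s, p.duration_s))
    return out
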