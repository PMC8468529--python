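"""Per-second binary series and the 60-s interbout filter.

Lying behavior occurs in bouts; an interbout criterion separates brief
interruptions (prediction noise, short side behaviors) from genuine bout
boundaries. Runs of lying or non-lying shorter than the criterion (60 s by
default) are absorbed into the behavior preceding them.

The merge procedure is iterative and deterministic: within each valid
segment, the leftmost short run that has a predecessor is relabeled to the
predecessor's label and runs are re-coalesced, until no such run remains;
only then, a short *leading* run (which has no predecessor) takes the label
of the run that follows it. Repeating to fixpoint guarantees every
remaining run is at least the minimum duration, except when the whole
segment is shorter than the criterion. Invalid (unobserved) seconds act as
barriers: the filter never bridges them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LYING = 1
NON_LYING = 0
INVALID = -1

_LABEL_STR = {LYING: "lying", NON_LYING: "non_lying", INVALID: "invalid"}
_STR_LABEL = {v: k for k, v in _LABEL_STR.items()}


def code(label: str) -> int:
    return _STR_LABEL[label]


def label_name(c: int) -> str:
    return _LABEL_STR[int(c)]


@dataclass
class BinarySeries:
    """Per-second lying / non-lying / invalid labels on a contiguous grid."""

    start_s: int
    labels: np.ndarray   # int8 codes

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def end_s(self) -> int:
        return self.start_s + len(self)

    @property
    def valid(self) -> np.ndarray:
        return self.labels != INVALID

    def copy(self) -> "BinarySeries":
        return BinarySeries(self.start_s, self.labels.copy())


def from_timeline(timeline) -> BinarySeries:
    """Binary ground truth: lying -> 1; any other valid behavior -> 0.

    Transition events (lying_down / standing_up) count as non-lying — a
    lying bout runs strictly from the end of lying-down to the start of
    standing-up.
    """
    labels = np.full(len(timeline), INVALID, dtype=np.int8)
    labels[timeline.valid] = NON_LYING
    labels[(timeline.behavior == "lying") & timeline.valid] = LYING
    return BinarySeries(timeline.start_s, labels)


def runs(series: BinarySeries) -> list[tuple[int, int, int]]:
    """Maximal constant-label runs as ``(label, start_s, duration_s)``."""
    lab = series.labels
    if len(lab) == 0:
        return []
    change = np.nonzero(np.diff(lab))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(lab)]))
    return [(int(lab[a]), series.start_s + int(a), int(b - a))
            for a, b in zip(starts, ends)]


def _filter_segment(run_list, min_dur_s):
    """Fixpoint merge of (label, length) runs of one valid segment."""
    rs = [list(r) for r in run_list]

    def coalesce(i):
        # merge neighbors of run i that now share its label
        j = i
        while j > 0 and rs[j - 1][0] == rs[j][0]:
            rs[j - 1][1] += rs[j][1]
            del rs[j]
            j -= 1
        while j + 1 < len(rs) and rs[j + 1][0] == rs[j][0]:
            rs[j][1] += rs[j + 1][1]
            del rs[j + 1]

    changed = True
    while changed:
        changed = False
        # exhaust backward merges first: leftmost short run with predecessor
        i = 1
        while i < len(rs):
            if rs[i][1] < min_dur_s:
                rs[i][0] = rs[i - 1][0]
                coalesce(i)
                i = 1
                changed = True
            else:
                i += 1
        # only at backward fixpoint: a short leading run attaches forward
        if len(rs) > 1 and rs[0][1] < min_dur_s:
            rs[0][0] = rs[1][0]
            coalesce(0)
            changed = True
    return rs


def interbout_filter(series: BinarySeries, min_dur_s: int = 60) -> BinarySeries:
    """Absorb runs shorter than ``min_dur_s`` into the preceding behavior.

    Applied independently within each maximal valid segment; invalid
    seconds are never relabeled. Idempotent.
    """
    if min_dur_s <= 0:
        raise ValueError("min_dur_s must be positive")
    out = series.labels.copy()
    valid = series.labels != INVALID
    if not valid.any():
        return BinarySeries(series.start_s, out)
    # maximal valid segments
    edges = np.nonzero(np.diff(valid.astype(np.int8)))[0] + 1
    bounds = np.concatenate(([0], edges, [len(valid)]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not valid[a]:
            continue
        seg = BinarySeries(series.start_s + int(a), series.labels[a:b])
        rl = [(lab, dur) for lab, _, dur in runs(seg)]
        merged = _filter_segment(rl, min_dur_s)
        pos = a
        for lab, dur in merged:
            out[pos:pos + dur] = lab
            pos += dur
    return BinarySeries(series.start_s, out)
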