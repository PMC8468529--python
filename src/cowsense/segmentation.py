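"""Fixed-length windowing of sensor streams and training-label attachment.

Feature extraction operates on windows of ``window_s`` seconds advanced by a
stride expressed as a fraction of the window length (1.0 = non-overlapping).
Only windows that are "pure" — every second valid, a single exclusive
behavior, no overlay activity — receive a training label; mixed or
overlay-contaminated windows are still predicted on at run time but never
trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sensor_io import LabelTimeline, SensorStream

#: Exclusive behaviors that yield multi-class training labels.
TRAINING_BEHAVIORS = ("grazing", "lying", "walking", "standing")
#: Transition events; never trained on, non-lying in binary ground truth.
TRANSITIONS = ("lying_down", "standing_up")

STANDARD_STRIDES = (0.25, 0.5, 1.0)


@dataclass
class Window:
    """One contiguous, gap-free window of sensor samples."""

    start_ms: int
    size_s: float
    rate_hz: float
    accel: np.ndarray   # (w, 3)
    euler: np.ndarray   # (w, 3)
    label: str | None = None
    pure: bool = False

    @property
    def start_s(self) -> float:
        return self.start_ms / 1000.0

    @property
    def n_samples(self) -> int:
        return len(self.accel)


def window_offsets(n_samples: int, window: int, step_samples: float) -> list[int]:
    """Start offsets of full windows in a gap-free run.

    The k-th window starts ``floor(k * step_samples)`` samples in; the step
    may be fractional (stride fractions that are not a whole number of
    samples accumulate without drift). Equivalent to
    ``floor((n - w) / step) + 1`` windows when ``n >= w``.
    """
    if step_samples <= 0:
        raise ValueError("step must be positive")
    out = []
    k = 0
    while True:
        a = int(np.floor(k * step_samples + 1e-9))
        if a + window > n_samples:
            return out
        out.append(a)
        k += 1


def window_count(n_samples: int, window: int, step_samples: float) -> int:
    """Number of full windows in a gap-free run of ``n_samples`` samples."""
    return len(window_offsets(n_samples, window, step_samples))


def segment(stream: SensorStream, size_s: float = 5.0,
            stride_fraction: float = 1.0) -> list[Window]:
    """Cut ``stream`` into complete windows of ``size_s`` seconds.

    Windows are anchored at the stream start and re-anchored after every
    data gap; windows that would overlap a gap or run past the stream end
    are never emitted. The stride is ``round(size_s * rate * fraction)``
    samples.
    """
    w = size_s * stream.nominal_rate
    if abs(w - round(w)) > 1e-9 or round(w) < 1:
        raise ValueError(
            f"window of {size_s} s at {stream.nominal_rate} Hz is not a "
            "whole number of samples")
    w = int(round(w))
    if stride_fraction <= 0:
        raise ValueError("stride_fraction must be positive")
    if stride_fraction not in STANDARD_STRIDES:
        warnings.warn(f"non-standard stride fraction {stride_fraction}",
                      stacklevel=2)
    step = w * stride_fraction
    out = []
    for i0, i1 in stream.segment_bounds():
        n = i1 - i0
        for off in window_offsets(n, w, step):
            a = i0 + off
            out.append(Window(
                start_ms=int(stream.t_ms[a]), size_s=size_s,
                rate_hz=stream.nominal_rate,
                accel=stream.accel[a:a + w], euler=stream.euler[a:a + w]))
    return out


def _covered_seconds(win: Window) -> tuple[int, int]:
    """Half-open integer-second range overlapped by the window span."""
    s0 = int(np.floor(win.start_ms / 1000.0))
    end_ms = win.start_ms + int(round(win.size_s * 1000))
    s1 = int(np.ceil(end_ms / 1000.0))
    return s0, s1


def label_windows(windows, timeline: LabelTimeline,
                  binary: bool = False) -> list[Window]:
    """Attach training labels to pure windows; return the same list.

    A window is pure iff every overlapped second is valid, shares a single
    exclusive behavior, and carries no overlay activity. With
    ``binary=True`` the label is mapped to ``lying`` / ``non_lying``;
    transition events (lying_down, standing_up) never yield a training
    label.
    """
    t0 = timeline.start_s
    t1 = t0 + len(timeline)
    for win in windows:
        win.pure = False
        win.label = None
        s0, s1 = _covered_seconds(win)
        if s0 < t0 or s1 > t1:
            continue
        idx = slice(s0 - t0, s1 - t0)
        if not timeline.valid[idx].all():
            continue
        behaviors = set(timeline.behavior[idx])
        if len(behaviors) != 1:
            continue
        if any(timeline.overlays[i] for i in range(idx.start, idx.stop)):
            continue
        behavior = behaviors.pop()
        win.pure = True
        if binary:
            if behavior in TRANSITIONS:
                win.pure = False
                continue
            win.label = "lying" if behavior == "lying" else "non_lying"
        else:
            if behavior in TRAINING_BEHAVIORS:
                win.label = behavior
    return windows
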