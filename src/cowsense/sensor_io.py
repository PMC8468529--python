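"""Reading, writing and aligning collar-sensor streams and ethogram labels.

The sensor is a collar-mounted BNO055 fusion IMU sampled at 10 Hz. In NDOF
mode it reports gravity-removed linear acceleration (m/s**2) on three axes
and an absolute orientation as Euler angles (heading, roll, pitch, degrees).
Ground truth comes from video observation coded against an ethogram of
mutually exclusive behaviors (lying, lying_down, standing_up, standing,
walking, grazing, feeding, idle) plus overlay activities (chewing,
ruminating, drinking, other) that may co-occur with an exclusive behavior.

Streams keep integer-millisecond UTC timestamps; label intervals are
half-open ``[start, end)`` in seconds. Per-second comparison rasterizes the
intervals onto an integer-second grid: a second takes the behavior of the
interval covering its midpoint.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Exclusive ethogram states.
BEHAVIORS = frozenset(
    {"lying", "lying_down", "standing_up", "standing", "walking",
     "grazing", "feeding", "idle"}
)
#: Activities that may overlay an exclusive state.
OVERLAYS = frozenset({"chewing", "ruminating", "drinking", "other"})
#: Observation locations.
LOCATIONS = frozenset({"pasture", "barn"})

SENSOR_HEADER = ["t_ms", "ax", "ay", "az", "eh", "er", "ep"]
LABEL_HEADER = ["start_s", "end_s", "behavior", "overlays", "location"]


class SensorIOError(ValueError):
    """Malformed or inconsistent sensor/label input."""


@dataclass
class SensorStream:
    """Time-ordered 10 Hz (nominal) samples for one animal.

    Attributes
    ----------
    t_ms : int64 array, milliseconds since epoch (UTC), strictly increasing.
    accel : (n, 3) float array, linear acceleration per axis, m/s**2.
    euler : (n, 3) float array, (heading, roll, pitch), degrees.
    gaps : list of half-open ``(start_ms, end_ms)`` intervals with no data.
    """

    t_ms: np.ndarray
    accel: np.ndarray
    euler: np.ndarray
    animal_id: str = ""
    farm_id: str = ""
    nominal_rate: float = 10.0
    gaps: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return (self.t_ms[-1] - self.t_ms[0]) / 1000.0 + 1.0 / self.nominal_rate

    def segment_bounds(self):
        """Index bounds ``[(i0, i1), ...]`` of maximal gap-free runs."""
        if len(self) == 0:
            return []
        period = 1000.0 / self.nominal_rate
        dt = np.diff(self.t_ms)
        breaks = np.nonzero(dt > 1.2 * period)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(self)]))
        return list(zip(starts.tolist(), ends.tolist()))


@dataclass(frozen=True)
class LabelInterval:
    """One coded interval, half-open ``[start_s, end_s)`` in seconds.

    ``behavior`` is an exclusive ethogram state, or ``None`` for a row that
    carries only overlay activities (overlays may span several exclusive
    behaviors in the video coding).
    """

    start_s: float
    end_s: float
    behavior: str | None
    overlays: frozenset = frozenset()
    location: str = "pasture"

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise SensorIOError(
                f"interval start {self.start_s} must precede end {self.end_s}")
        if self.behavior is not None and self.behavior not in BEHAVIORS:
            raise SensorIOError(f"unknown behavior {self.behavior!r}")
        bad = set(self.overlays) - OVERLAYS
        if bad:
            raise SensorIOError(f"unknown overlay token(s) {sorted(bad)}")
        if self.behavior is None and not self.overlays:
            raise SensorIOError("interval with neither behavior nor overlays")
        if self.behavior == "idle" and self.overlays:
            raise SensorIOError("idle carries no overlays")
        if self.location not in LOCATIONS:
            raise SensorIOError(f"unknown location {self.location!r}")


@dataclass
class LabelTimeline:
    """Per-second ground truth on the integer-second grid.

    ``behavior[i]`` is the exclusive state covering second ``start_s + i``
    (empty string where no interval covers it), ``valid[i]`` is False for
    uncovered or idle seconds.
    """

    start_s: int
    behavior: np.ndarray        # object array of str
    overlays: list              # list of frozenset
    location: np.ndarray        # object array of str
    valid: np.ndarray           # bool
    animal_id: str = ""

    def __len__(self) -> int:
        return len(self.behavior)


def _validate_euler(eh, er, ep, where=""):
    if np.any((eh < 0) | (eh >= 360)):
        raise SensorIOError(f"euler heading out of [0, 360){where}")
    if np.any((er < -90) | (er > 90)):
        raise SensorIOError(f"euler roll out of [-90, 90]{where}")
    if np.any((ep < -180) | (ep > 180)):
        raise SensorIOError(f"euler pitch out of [-180, 180]{where}")


def read_sensor_csv(path, animal_id: str = "", farm_id: str = "",
                    nominal_rate: float = 10.0) -> SensorStream:
    """Read a sensor CSV (header ``t_ms,ax,ay,az,eh,er,ep``).

    Inter-sample spacings larger than 120% of the nominal period are
    recorded as gaps; spacings below 80% of the period, non-monotone
    timestamps, malformed rows and out-of-range Euler angles raise
    :class:`SensorIOError`.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SensorIOError(f"empty sensor file: {path}") from None
    if list(df.columns) != SENSOR_HEADER:
        raise SensorIOError(
            f"bad sensor header {list(df.columns)}; expected {SENSOR_HEADER}")
    if len(df) == 0:
        raise SensorIOError(f"sensor file has no data rows: {path}")
    for col in SENSOR_HEADER:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise SensorIOError(f"malformed value in column {col!r} at line {line}")
    t_ms = df["t_ms"].to_numpy(dtype=np.int64)
    if np.any(np.diff(t_ms) <= 0):
        raise SensorIOError("timestamps not strictly increasing")
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    euler = df[["eh", "er", "ep"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(accel)):
        raise SensorIOError("non-finite acceleration value")
    _validate_euler(euler[:, 0], euler[:, 1], euler[:, 2])

    period = 1000.0 / nominal_rate
    dt = np.diff(t_ms)
    if np.any(dt < 0.8 * period):
        raise SensorIOError("inter-sample interval below 80% of nominal period")
    gaps = []
    for i in np.nonzero(dt > 1.2 * period)[0]:
        gaps.append((int(t_ms[i] + round(period)), int(t_ms[i + 1])))
    return SensorStream(t_ms=t_ms, accel=accel, euler=euler,
                        animal_id=animal_id, farm_id=farm_id,
                        nominal_rate=nominal_rate, gaps=gaps)


def write_sensor_csv(stream: SensorStream, path) -> None:
    """Write a stream in the sensor CSV dialect (accel 3 d.p., Euler 2 d.p.)."""
    buf = io.StringIO()
    buf.write(",".join(SENSOR_HEADER) + "\n")
    for i in range(len(stream)):
        a = stream.accel[i]
        e = stream.euler[i]
        # a heading just below 360 must not round up to the excluded bound
        eh = round(e[0], 2) % 360.0
        buf.write(f"{stream.t_ms[i]},{a[0]:.3f},{a[1]:.3f},{a[2]:.3f},"
                  f"{eh:.2f},{e[1]:.2f},{e[2]:.2f}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_labels_csv(path) -> list[LabelInterval]:
    """Read label intervals (header ``start_s,end_s,behavior,overlays,location``).

    ``overlays`` is ``|``-separated; an empty ``behavior`` cell denotes an
    overlay-only interval. Intervals are returned sorted by start; exclusive
    behaviors may not overlap one another.
    """
    df = pd.read_csv(path, keep_default_na=False)
    if list(df.columns) != LABEL_HEADER:
        raise SensorIOError(
            f"bad label header {list(df.columns)}; expected {LABEL_HEADER}")
    intervals = []
    for _, row in df.iterrows():
        behavior = str(row["behavior"]).strip() or None
        ov = str(row["overlays"]).strip()
        overlays = frozenset(tok for tok in ov.split("|") if tok)
        intervals.append(LabelInterval(
            start_s=float(row["start_s"]), end_s=float(row["end_s"]),
            behavior=behavior, overlays=overlays,
            location=str(row["location"]).strip() or "pasture"))
    intervals.sort(key=lambda iv: (iv.start_s, iv.end_s))
    _check_exclusive_overlap(intervals)
    return intervals


def write_labels_csv(intervals, path) -> None:
    rows = []
    for iv in intervals:
        rows.append({
            "start_s": iv.start_s, "end_s": iv.end_s,
            "behavior": iv.behavior or "",
            "overlays": "|".join(sorted(iv.overlays)),
            "location": iv.location,
        })
    pd.DataFrame(rows, columns=LABEL_HEADER).to_csv(path, index=False)


def _check_exclusive_overlap(intervals) -> None:
    prev_end = -np.inf
    prev = None
    for iv in intervals:
        if iv.behavior is None:
            continue
        if iv.start_s < prev_end:
            raise SensorIOError(
                f"exclusive behaviors overlap: {prev} and {iv}")
        prev_end, prev = iv.end_s, iv
    return None


def rasterize_labels(intervals, t0: int, t1: int,
                     animal_id: str = "") -> LabelTimeline:
    """Rasterize intervals onto whole seconds ``[t0, t1)``.

    Each second takes the exclusive behavior of the interval covering its
    midpoint, the union of overlays active at that midpoint, and that
    interval's location. Seconds covered by no exclusive interval, or by
    ``idle``, are flagged invalid.
    """
    if not t0 < t1:
        raise SensorIOError(f"need t0 < t1, got [{t0}, {t1})")
    n = int(t1) - int(t0)
    behavior = np.full(n, "", dtype=object)
    location = np.full(n, "", dtype=object)
    overlays = [frozenset() for _ in range(n)]
    for iv in intervals:
        # seconds s whose midpoint s + 0.5 lies in [start, end)
        lo = max(int(np.ceil(iv.start_s - 0.5)), int(t0))
        hi = min(int(np.ceil(iv.end_s - 0.5)), int(t1))
        if hi <= lo:
            continue
        sl = slice(lo - int(t0), hi - int(t0))
        if iv.behavior is not None:
            behavior[sl] = iv.behavior
            location[sl] = iv.location
        if iv.overlays:
            for i in range(sl.start, sl.stop):
                overlays[i] = overlays[i] | iv.overlays
    valid = (behavior != "") & (behavior != "idle")
    return LabelTimeline(start_s=int(t0), behavior=behavior, overlays=overlays,
                         location=location, valid=valid, animal_id=animal_id)


def downsample(stream: SensorStream, target_rate: float) -> SensorStream:
    """Decimate to ``target_rate`` keeping every k-th sample per gap-free run.

    ``k = nominal_rate / target_rate`` must be a positive integer; the phase
    is re-anchored at the first sample after each gap.
    """
    ratio = stream.nominal_rate / target_rate
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise SensorIOError(
            f"target rate {target_rate} does not divide {stream.nominal_rate}")
    if k == 1:
        return replace(stream)
    keep = []
    for i0, i1 in stream.segment_bounds():
        keep.append(np.arange(i0, i1, k))
    idx = np.concatenate(keep) if keep else np.empty(0, dtype=int)
    return SensorStream(
        t_ms=stream.t_ms[idx], accel=stream.accel[idx], euler=stream.euler[idx],
        animal_id=stream.animal_id, farm_id=stream.farm_id,
        nominal_rate=target_rate, gaps=list(stream.gaps))
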