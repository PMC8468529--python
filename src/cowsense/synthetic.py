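"""Synthetic labeled cow-days: behavior sequences and matching sensor streams.

No public recording of the collar data exists, so experiments run on
simulated cow-days. The generator has two layers:

1. **Behavior sequence** — an alternating-bout semi-Markov chain over
   grazing, lying, walking and standing. Bout durations are log-normal
   (heavy right tail, positive support), parameterized by a median and a
   log-scale dispersion. Entry probabilities are proportional to
   ``time_share / mean_bout_duration`` so the long-run time shares converge
   to the configured mix (defaults: grazing 51.0%, lying 32.2%, walking
   7.6%, standing 9.2%; lying bout median 57.7 min). Every lying bout is
   flanked by 5-s lying-down and standing-up transition events. Ruminating
   episodes overlay a random sub-interval of some lying and standing bouts.

2. **Sensor stream** — the sensor reports gravity-removed linear
   acceleration, so posture lives in the Euler angles and motion in the
   acceleration. Per behavior, Euler angles follow a per-bout posture mean
   plus AR(1) jitter, and acceleration is a sinusoid on a random direction
   plus white noise. Default signatures encode the physical picture: lying
   is near-still with a rolled collar; standing has small weight-shift
   movement; walking oscillates at ~1.8 Hz (gait); grazing at ~0.8 Hz with
   a lowered head (pitch down); a ruminating overlay adds a low-amplitude
   ~1.1 Hz chewing component.

Collar-orientation shifts between farms are reproduced by rotating the
acceleration frame about the neck axis and offsetting the roll angle —
vector magnitudes, and hence the orientation-independent features, are
unchanged by construction.

All parameters beyond the class mix and the lying bout median are invented:
absolute accuracies on synthetic data reflect the configured separability,
not any real herd.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .sensor_io import LabelInterval, SensorStream, write_labels_csv, write_sensor_csv


@dataclass(frozen=True)
class BehaviorSignal:
    """Signal signature of one behavior.

    roll/pitch are posture means in degrees (heading is random per bout);
    ``jitter_sd`` is the AR(1) innovation SD of the Euler jitter (deg);
    ``amp`` and ``freq_hz`` define the acceleration oscillation (m/s**2,
    Hz) and ``noise_sd`` the white acceleration noise (m/s**2).
    """

    roll: float
    pitch: float
    jitter_sd: float
    ar1: float
    amp: float
    freq_hz: float
    noise_sd: float


DEFAULT_SIGNALS = {
    "lying":       BehaviorSignal(roll=55.0, pitch=-10.0, jitter_sd=0.3,
                                  ar1=0.95, amp=0.02, freq_hz=0.10, noise_sd=0.03),
    "standing":    BehaviorSignal(roll=0.0, pitch=-15.0, jitter_sd=0.8,
                                  ar1=0.95, amp=0.30, freq_hz=0.40, noise_sd=0.10),
    "walking":     BehaviorSignal(roll=0.0, pitch=-20.0, jitter_sd=1.5,
                                  ar1=0.90, amp=1.50, freq_hz=1.80, noise_sd=0.20),
    "grazing":     BehaviorSignal(roll=0.0, pitch=-60.0, jitter_sd=1.2,
                                  ar1=0.90, amp=0.80, freq_hz=0.80, noise_sd=0.15),
    "lying_down":  BehaviorSignal(roll=25.0, pitch=-25.0, jitter_sd=2.0,
                                  ar1=0.80, amp=0.60, freq_hz=0.50, noise_sd=0.20),
    "standing_up": BehaviorSignal(roll=25.0, pitch=-25.0, jitter_sd=2.0,
                                  ar1=0.80, amp=0.60, freq_hz=0.50, noise_sd=0.20),
}

#: ruminating overlay: extra chewing oscillation added to the acceleration
RUMINATE_AMP = 0.15
RUMINATE_FREQ_HZ = 1.1


@dataclass
class SimulationConfig:
    seed: int = 42
    duration_s: int = 86400
    rate_hz: float = 10.0
    #: long-run time shares (matches the observed training class mix)
    mix: dict = field(default_factory=lambda: {
        "grazing": 0.510, "lying": 0.322, "walking": 0.076, "standing": 0.092})
    #: per-behavior log-normal bout-duration medians, seconds
    bout_median_s: dict = field(default_factory=lambda: {
        "grazing": 1500.0, "lying": 57.7 * 60.0, "walking": 180.0,
        "standing": 480.0})
    #: log-scale dispersion of bout durations
    bout_sigma: float = 0.5
    transition_s: float = 5.0
    #: probability that a lying/standing bout carries a ruminating episode
    ruminate_prob: float = 0.5
    signals: dict = field(default_factory=lambda: dict(DEFAULT_SIGNALS))
    location: str = "pasture"

    def validate(self):
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"behavior mix sums to {total}, not 1")
        if any(v < 0 for v in self.mix.values()):
            raise ValueError("negative mix share")
        for b, sig in self.signals.items():
            if min(sig.jitter_sd, sig.noise_sd, sig.amp) < 0:
                raise ValueError(f"negative SD/amplitude for {b}")
            if sig.freq_hz >= self.rate_hz / 2:
                raise ValueError(f"{b} frequency above Nyquist")
        if not 0 <= self.ruminate_prob <= 1:
            raise ValueError("ruminate_prob must be in [0, 1]")
        return self


def _mean_duration(config, behavior):
    return (config.bout_median_s[behavior]
            * np.exp(config.bout_sigma ** 2 / 2.0))


def _entry_weights(config, behaviors) -> np.ndarray:
    """Bout-entry weights whose alternating chain hits the target mix.

    The sequence never repeats a behavior, so the next bout is drawn from
    the entry weights with the current behavior excluded and renormalized:
    ``P(b'|b) = w_b' / (1 - w_b)``. That embedded chain has stationary
    distribution proportional to ``w_b (1 - w_b)``, and the long-run *time*
    share of behavior ``b`` is its stationary visit rate times its mean
    bout duration. Hitting the configured mix therefore requires
    ``w_b (1 - w_b) ∝ mix_b / mean_duration_b``, solved here by the
    fixed-point iteration ``w ∝ r / (1 - w)``.
    """
    r = np.array([config.mix[b] / _mean_duration(config, b)
                  for b in behaviors])
    r = r / r.sum()
    if len(behaviors) <= 2:
        return r  # alternation is forced; weights only pick the start
    w = r.copy()
    for _ in range(200):
        w_new = r / np.clip(1.0 - w, 1e-9, None)
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < 1e-12:
            w = w_new
            break
        w = w_new
    return w


def simulate_behavior_sequence(config: SimulationConfig,
                               rng: np.random.Generator | None = None
                               ) -> list[LabelInterval]:
    """Sample one contiguous behavior bout sequence covering the whole day."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    behaviors = [b for b, w in config.mix.items() if w > 0]
    if not behaviors:
        raise ValueError("behavior mix is empty")
    entry = _entry_weights(config, behaviors)

    def draw_next(current):
        if len(behaviors) == 1:
            return behaviors[0]
        w = np.array([p if b != current else 0.0
                      for b, p in zip(behaviors, entry)])
        w = w / w.sum()
        return behaviors[rng.choice(len(behaviors), p=w)]

    intervals = []
    t = 0.0
    current = behaviors[rng.choice(len(behaviors), p=entry)]
    while t < config.duration_s:
        median = config.bout_median_s[current]
        dur = float(rng.lognormal(np.log(median), config.bout_sigma))
        dur = max(dur, 2.0 * config.transition_s + 1.0)
        if current == "lying":
            td = config.transition_s
            t0 = t
            pieces = [("lying_down", t0, t0 + td),
                      ("lying", t0 + td, t0 + td + dur),
                      ("standing_up", t0 + td + dur, t0 + 2 * td + dur)]
        else:
            pieces = [(current, t, t + dur)]
        for behavior, a, b in pieces:
            a, b = min(a, config.duration_s), min(b, config.duration_s)
            if b <= a:
                continue
            intervals.append(LabelInterval(
                start_s=a, end_s=b, behavior=behavior,
                location=config.location))
        t = pieces[-1][2]
        # ruminating overlays a sub-interval of eligible bouts
        if current in ("lying", "standing") and rng.random() < config.ruminate_prob:
            core = [p for p in pieces if p[0] == current][0]
            a, b = core[1], min(core[2], config.duration_s)
            if b - a > 60:
                span = (b - a) * rng.uniform(0.3, 0.8)
                off = rng.uniform(0, (b - a) - span)
                intervals.append(LabelInterval(
                    start_s=a + off, end_s=a + off + span, behavior=None,
                    overlays=frozenset({"ruminating"}),
                    location=config.location))
        current = draw_next(current)
    intervals.sort(key=lambda iv: (iv.start_s, iv.end_s))
    return intervals


def simulate_sensor_stream(intervals, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           t0_ms: int = 0) -> SensorStream:
    """Render a 10 Hz sensor stream for a contiguous behavior sequence."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    exclusive = sorted((iv for iv in intervals if iv.behavior is not None),
                       key=lambda iv: iv.start_s)
    if not exclusive:
        raise ValueError("no exclusive behavior intervals")
    for a, b in zip(exclusive, exclusive[1:]):
        if abs(a.end_s - b.start_s) > 1e-9:
            raise ValueError("behavior intervals must be contiguous")
    start = exclusive[0].start_s
    end = exclusive[-1].end_s
    dt = 1.0 / config.rate_hz
    n = int(round((end - start) / dt))
    t = start + np.arange(n) * dt
    t_ms = (t0_ms + np.round(t * 1000)).astype(np.int64)

    accel = np.zeros((n, 3))
    euler = np.zeros((n, 3))
    heading0 = rng.uniform(0, 360)

    for iv in exclusive:
        sig = config.signals[iv.behavior]
        i0 = int(np.round((iv.start_s - start) / dt))
        i1 = int(np.round((iv.end_s - start) / dt))
        m = i1 - i0
        if m <= 0:
            continue
        # posture: per-bout mean + AR(1) jitter per Euler axis
        heading0 = (heading0 + rng.normal(0, 20)) % 360
        mean = np.array([heading0, sig.roll + rng.normal(0, 3),
                         sig.pitch + rng.normal(0, 3)])
        jitter = np.zeros((m, 3))
        innov = rng.normal(0, sig.jitter_sd, size=(m, 3))
        for k in range(1, m):
            jitter[k] = sig.ar1 * jitter[k - 1] + innov[k]
        e = mean + jitter
        e[:, 0] %= 360.0
        e[:, 1] = np.clip(e[:, 1], -90, 90)
        e[:, 2] = np.clip(e[:, 2], -180, 180)
        euler[i0:i1] = e
        # motion: sinusoid on a random unit direction + white noise
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        osc = sig.amp * np.sin(2 * np.pi * sig.freq_hz * t[i0:i1] + phase)
        accel[i0:i1] = (osc[:, None] * direction
                        + rng.normal(0, sig.noise_sd, size=(m, 3)))

    # ruminating overlay adds a chewing oscillation
    for iv in intervals:
        if "ruminating" not in iv.overlays:
            continue
        i0 = max(int(np.round((iv.start_s - start) / dt)), 0)
        i1 = min(int(np.round((iv.end_s - start) / dt)), n)
        if i1 <= i0:
            continue
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        osc = RUMINATE_AMP * np.sin(
            2 * np.pi * RUMINATE_FREQ_HZ * t[i0:i1] + phase)
        accel[i0:i1] += osc[:, None] * direction

    return SensorStream(t_ms=t_ms, accel=accel, euler=euler,
                        nominal_rate=config.rate_hz)


def apply_collar_rotation(stream: SensorStream,
                          angle_deg: float) -> SensorStream:
    """Rotate the sensor frame about the neck (x) axis by ``angle_deg``.

    Models the collar sliding around the neck: the acceleration vector is
    rotated (its magnitude is exactly preserved) and the roll angle is
    offset by the same angle, wrapped back into [-90, 90).
    """
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    th = np.deg2rad(angle_deg)
    R = np.array([[1, 0, 0],
                  [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    accel = stream.accel @ R.T
    euler = stream.euler.copy()
    euler[:, 1] = ((euler[:, 1] + angle_deg + 90.0) % 180.0) - 90.0
    return replace(stream, accel=accel, euler=euler)


def simulate_cow_day(config: SimulationConfig, rotation_deg: float = 0.0):
    """One animal-day: ``(stream, intervals)`` with optional collar rotation."""
    rng = np.random.default_rng(config.seed)
    intervals = simulate_behavior_sequence(config, rng)
    stream = simulate_sensor_stream(intervals, config, rng)
    if rotation_deg:
        stream = apply_collar_rotation(stream, rotation_deg)
    return stream, intervals


def make_farm_dataset(out_dir, n_animals: int, days: int,
                      config: SimulationConfig,
                      rotation_per_farm: dict | None = None) -> dict:
    """Write per-animal-day sensor and label CSVs plus a manifest.

    ``rotation_per_farm`` maps farm id to collar rotation (degrees);
    animals are distributed round-robin across the farms. Deterministic in
    ``config.seed`` (byte-identical regeneration).
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    rotation_per_farm = rotation_per_farm or {"farm1": 0.0}
    farms = sorted(rotation_per_farm)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_animals * days)
    manifest = {"seed": config.seed, "records": []}
    k = 0
    for a in range(n_animals):
        animal = f"cow{a + 1:02d}"
        farm = farms[a % len(farms)]
        rot = float(rotation_per_farm[farm])
        for d in range(days):
            child_seed = int(children[k].generate_state(1)[0] % (2 ** 31 - 1))
            k += 1
            day_cfg = replace(config, seed=child_seed)
            stream, intervals = simulate_cow_day(day_cfg, rotation_deg=rot)
            stream.animal_id, stream.farm_id = animal, farm
            sensor_path = out_dir / f"{animal}_day{d + 1}_sensor.csv"
            label_path = out_dir / f"{animal}_day{d + 1}_labels.csv"
            write_sensor_csv(stream, sensor_path)
            write_labels_csv(intervals, label_path)
            manifest["records"].append({
                "animal": animal, "farm": farm, "day": d + 1,
                "location": config.location, "rotation_deg": rot,
                "sensor": sensor_path.name, "labels": label_path.name,
            })
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
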