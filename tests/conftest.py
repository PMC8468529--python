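import numpy as np
import pytest

from cowsense.segmentation import Window
from cowsense.sensor_io import SensorStream


def make_stream(n, rate=10.0, t0_ms=0, accel=None, euler=None, seed=0):
    """Gap-free stream of n samples with optional fixed or random signals."""
    rng = np.random.default_rng(seed)
    period = int(round(1000 / rate))
    t_ms = t0_ms + np.arange(n, dtype=np.int64) * period
    if accel is None:
        accel = rng.normal(0, 0.5, size=(n, 3))
    else:
        accel = np.broadcast_to(np.asarray(accel, float), (n, 3)).copy()
    if euler is None:
        euler = np.column_stack([
            rng.uniform(0, 359, n), rng.uniform(-80, 80, n),
            rng.uniform(-170, 170, n)])
    else:
        euler = np.broadcast_to(np.asarray(euler, float), (n, 3)).copy()
    return SensorStream(t_ms=t_ms, accel=accel, euler=euler,
                        nominal_rate=rate)


def make_window(accel, euler=None, rate=10.0):
    """Window wrapping explicit (n, 3) accel / euler arrays."""
    accel = np.asarray(accel, dtype=float)
    if accel.ndim == 1:
        accel = np.column_stack([accel, np.zeros_like(accel),
                                 np.zeros_like(accel)])
    n = len(accel)
    if euler is None:
        euler = np.zeros((n, 3))
    euler = np.asarray(euler, dtype=float)
    return Window(start_ms=0, size_s=n / rate, rate_hz=rate,
                  accel=accel, euler=euler)


def random_rotation(rng):
    """Haar-random 3x3 rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
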