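"""Feature definitions against naive reference implementations.

The oracles here are deliberately slow and literal: explicit O(n^2) DFT
sums, sorting-based quantiles, direct moment formulas. They pin every
normalization constant of the spectral features.
"""

import numpy as np
import pytest

from cowsense.features import (FEATURE_NAMES, OD24_NAMES, OI36_NAMES,
                               FeatureVector, extract_od24, extract_oi36,
                               feature_table, magnitude, oi_feature_matrix,
                               rank_features)

from conftest import make_window, random_rotation


# ---- naive oracles -------------------------------------------------------

def naive_dft_power(x):
    """One-sided power p_k = |X_k|^2 / n, k = 1..floor(n/2), explicit sum."""
    x = np.asarray(x, float)
    n = len(x)
    c = x - x.mean()
    p = []
    for k in range(1, n // 2 + 1):
        Xk = sum(c[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))
        p.append(abs(Xk) ** 2 / n)
    return np.array(p)


def naive_oi18(x, rate):
    x = np.asarray(x, float)
    n = len(x)
    mean = x.mean()
    var = np.mean((x - mean) ** 2)
    std = np.sqrt(var)
    s = np.sort(x)

    def quantile(q):
        # linear interpolation between order statistics
        h = (n - 1) * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    c = x - mean
    crossings = sum(1 for a, b in zip(c, c[1:]) if a * b < 0)
    if var > 0:
        kurt = np.mean(c ** 4) / var ** 2 - 3
        skew = np.mean(c ** 3) / var ** 1.5
    else:
        kurt = skew = 0.0
    p = naive_dft_power(x)
    energy = p.sum()
    if energy > 0:
        kstar = int(np.argmax(p)) + 1
        peak = kstar * rate / n
        q = p / energy
        entropy = -sum(qi * np.log(qi) for qi in q if qi > 0)
    else:
        peak = entropy = 0.0
    profile = [np.sqrt(p[k]) if k < len(p) else 0.0 for k in range(5)]
    return np.array([
        x.min(), x.max(), mean, quantile(0.5), std,
        quantile(0.75) - quantile(0.25), np.sqrt(np.mean(x ** 2)),
        crossings / (n - 1), kurt, skew, energy, peak, entropy, *profile])


class TestMagnitude:
    def test_pythagorean(self):
        assert magnitude([3.0, 4.0, 0.0]) == 5.0
        assert magnitude([0.0, 0.0, 0.0]) == 0.0

    def test_rotation_invariant(self, rng):
        for _ in range(10):
            v = rng.normal(size=3)
            R = random_rotation(rng)
            assert abs(magnitude(R @ v) - magnitude(v)) < 1e-12


class TestOD24:
    def test_hand_computed_series(self):
        w = make_window(np.array([1.0, 2.0, 3.0, 4.0]))
        fv = extract_od24(w)
        vals = dict(zip(fv.names, fv.values))
        assert vals["ax__max"] == 4.0
        assert vals["ax__mean"] == 2.5
        assert vals["ax__median"] == 2.5
        assert vals["ax__std"] == pytest.approx(np.sqrt(1.25), abs=1e-12)

    def test_constant_window(self):
        w = make_window(np.tile([0.0, 0.0, 1.0], (20, 1)),
                        euler=np.tile([10.0, 20.0, 30.0], (20, 1)))
        fv = extract_od24(w)
        vals = dict(zip(fv.names, fv.values))
        for ax, c in [("az", 1.0), ("eh", 10.0), ("er", 20.0), ("ep", 30.0)]:
            assert vals[f"{ax}__max"] == vals[f"{ax}__mean"] == c
            assert vals[f"{ax}__std"] == 0.0

    def test_rotation_changes_od24(self, rng):
        accel = rng.normal(size=(50, 3))
        w = make_window(accel)
        Rz90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        w_rot = make_window(accel @ Rz90.T)
        assert not np.allclose(extract_od24(w).values,
                               extract_od24(w_rot).values)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_od24(make_window(np.empty((0, 3))))


class TestOI36:
    def test_names_and_length(self):
        assert len(OI36_NAMES) == 36 and len(OD24_NAMES) == 24
        assert OI36_NAMES[0] == "acc_mag__min"
        assert OI36_NAMES[18] == "ndof_mag__min"

    def test_constant_magnitude_degenerate(self):
        w = make_window(np.tile([0.0, 0.0, 2.0], (20, 1)),
                        euler=np.tile([30.0, 40.0, 0.0], (20, 1)))
        vals = dict(zip(OI36_NAMES, extract_oi36(w).values))
        for f in ("min", "max", "mean", "median", "rms"):
            assert vals[f"acc_mag__{f}"] == pytest.approx(2.0)
        for f in ("std", "iqr", "mcr", "kurtosis", "skewness",
                  "spectral_energy", "peak_freq_hz", "freq_entropy",
                  "fp1", "fp2", "fp3", "fp4", "fp5"):
            assert vals[f"acc_mag__{f}"] == 0.0

    def test_sine_series_mean_and_peak(self):
        # m_i = 5 + sin(2*pi*2*t_i), 50 samples at 10 Hz: whole periods
        t = np.arange(50) / 10.0
        m = 5 + np.sin(2 * np.pi * 2 * t)
        w = make_window(np.column_stack([m, np.zeros(50), np.zeros(50)]))
        vals = dict(zip(OI36_NAMES, extract_oi36(w).values))
        assert vals["acc_mag__mean"] == pytest.approx(5.0, abs=1e-9)
        assert vals["acc_mag__peak_freq_hz"] == pytest.approx(2.0)

    def test_matches_naive_oracle(self, rng):
        for n in (10, 11, 50, 101):
            x = rng.normal(2.0, 1.0, size=n)
            got = oi_feature_matrix(x[None, :], 10.0)[0]
            want = naive_oi18(x, 10.0)
            np.testing.assert_allclose(got, want, atol=1e-9, rtol=1e-9)

    def test_parseval_pins_normalization(self, rng):
        # one-sided power excludes DC and does not double: for odd n the
        # energy of the mean-removed series is exactly n*var/2; for even n
        # the Nyquist bin contributes its full share once.
        for n in (51, 101):
            x = rng.normal(size=n)
            vals = oi_feature_matrix(x[None, :], 10.0)[0]
            energy = vals[OI36_NAMES.index("acc_mag__spectral_energy")]
            var = np.mean((x - x.mean()) ** 2)
            assert energy == pytest.approx(n * var / 2, rel=1e-9)
        for n in (50, 100):
            x = rng.normal(size=n)
            vals = oi_feature_matrix(x[None, :], 10.0)[0]
            energy = vals[OI36_NAMES.index("acc_mag__spectral_energy")]
            var = np.mean((x - x.mean()) ** 2)
            X = np.fft.rfft(x - x.mean())
            nyquist = abs(X[n // 2]) ** 2 / n
            assert energy == pytest.approx(n * var / 2 + nyquist / 2, rel=1e-9)

    def test_short_window_pads_profile(self):
        x = np.array([1.0, 2.0, 0.5, 1.5, 0.0])   # n=5 -> 2 non-DC bins
        vals = dict(zip(OI36_NAMES, oi_feature_matrix(
            np.tile(x, (2, 1)), 10.0)[0].tolist() + [0.0] * 18))
        assert vals["acc_mag__fp3"] == 0.0
        assert vals["acc_mag__fp4"] == 0.0
        assert vals["acc_mag__fp5"] == 0.0

    def test_accel_half_rotation_invariant(self, rng):
        accel = rng.normal(size=(50, 3)) + [0, 0, 1.0]
        w = make_window(accel)
        base = extract_oi36(w).values[:18]
        for _ in range(5):
            R = random_rotation(rng)
            w_rot = make_window(accel @ R.T)
            np.testing.assert_allclose(extract_oi36(w_rot).values[:18],
                                       base, atol=1e-9)

    def test_batch_matches_single_bitwise(self, rng):
        from conftest import make_stream
        from cowsense.segmentation import segment
        stream = make_stream(600, seed=9)
        wins = segment(stream, 5.0, 1.0)
        for set_id in ("OD24", "OI36"):
            table = feature_table(wins, set_id)
            for i, w in enumerate(wins):
                single = (extract_od24(w) if set_id == "OD24"
                          else extract_oi36(w)).values
                np.testing.assert_array_equal(table.to_numpy()[i], single)

    def test_feature_vector_rejects_nan(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureVector("OD24", OD24_NAMES, np.full(24, np.nan))


class TestRankFeatures:
    def test_label_copy_ranked_first_and_sums_to_one(self, rng):
        import pandas as pd
        y = rng.integers(0, 2, size=300)
        X = pd.DataFrame({
            "oracle": y.astype(float),
            "noise1": rng.normal(size=300),
            "noise2": rng.normal(size=300),
        })
        imp = rank_features(X, y, seed=0)
        assert imp.index[0] == "oracle"
        assert imp.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        import pandas as pd
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError, match="two classes"):
            rank_features(X, np.zeros(10))
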