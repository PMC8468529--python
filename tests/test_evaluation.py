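"""Confusion counting, the metric suite, aggregation and daily summaries."""

import numpy as np
import pandas as pd
import pytest

from cowsense.evaluation import (ConfusionCounts, DailyLyingTime, confusion,
                                 daily_lying_time, label_agreement, metrics,
                                 reconstruct_counts, round_percent, stratify)
from cowsense.postprocess import INVALID, LYING, NON_LYING, BinarySeries
from cowsense.sensor_io import LabelInterval, rasterize_labels

L, N, I = LYING, NON_LYING, INVALID


def series(*spec, start=0):
    labels = np.concatenate([np.full(n, lab, dtype=np.int8)
                             for lab, n in spec])
    return BinarySeries(start, labels)


class TestConfusion:
    def test_identical_series(self):
        s = series((L, 100), (N, 100))
        c = confusion(s, s)
        assert (c.tp, c.tn, c.fp, c.fn) == (100, 100, 0, 0)

    def test_all_lying_prediction(self):
        gt = series((L, 100), (N, 100))
        pred = series((L, 200))
        m = metrics(confusion(gt, pred))
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.accuracy == 0.5

    def test_invalid_seconds_excluded(self):
        gt = series((L, 90), (I, 10), (N, 100))
        pred = series((L, 200))
        assert confusion(gt, pred).total == 190

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            confusion(series((L, 10)), series((L, 20)))
        with pytest.raises(ValueError, match="misaligned"):
            confusion(series((L, 10)), series((L, 10), start=5))


class TestMetrics:
    def test_perfect(self):
        m = metrics(ConfusionCounts(50, 50, 0, 0))
        assert all(v == 1.0 for v in m.__dict__.values())

    def test_zero_denominator_not_available(self):
        m = metrics(ConfusionCounts(0, 10, 0, 0))
        assert m.sensitivity is None
        assert m.ppv is None
        assert m.specificity == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no compared"):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_scale_invariance_hours_vs_seconds(self):
        sec = metrics(ConfusionCounts(3600, 7200, 1800, 900))
        hrs = metrics(ConfusionCounts(1.0, 2.0, 0.5, 0.25))
        for k in sec.__dict__:
            assert getattr(sec, k) == pytest.approx(getattr(hrs, k))

    def test_accuracy_identity(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 1000, size=4)
            c = ConfusionCounts(float(tp), float(tn), float(fp), float(fn))
            if c.total == 0:
                continue
            m = metrics(c)
            assert m.accuracy == pytest.approx(
                (c.total - c.fp - c.fn) / c.total)

    def test_swap_duality(self, rng):
        for _ in range(20):
            a = rng.choice([L, N], size=300).astype(np.int8)
            b = rng.choice([L, N], size=300).astype(np.int8)
            m1 = metrics(confusion(BinarySeries(0, a), BinarySeries(0, b)))
            m2 = metrics(confusion(BinarySeries(0, b), BinarySeries(0, a)))
            assert m1.sensitivity == pytest.approx(m2.ppv)
            assert m1.specificity == pytest.approx(m2.npv)
            assert m1.accuracy == pytest.approx(m2.accuracy)

    def test_rounding_half_away_from_zero(self):
        assert round_percent(0.87345) == 87.3
        assert round_percent(0.87350) == 87.4
        assert round_percent(-0.005) == -0.5


class TestReconstructCounts:
    def test_published_aggregate_bookkeeping(self):
        c = reconstruct_counts(476.2, 0.461, fn_h=9.7, fp_h=51.0)
        assert c.tp == pytest.approx(209.83, abs=0.005)
        assert c.tn == pytest.approx(205.67, abs=0.005)

    def test_balanced_no_error(self):
        c = reconstruct_counts(100, 0.5, 0, 0)
        assert (c.tp, c.tn) == (50, 50)

    def test_fn_bound(self):
        with pytest.raises(ValueError, match="FN"):
            reconstruct_counts(100, 0.1, fn_h=20, fp_h=0)

    def test_fp_bound(self):
        with pytest.raises(ValueError, match="FP"):
            reconstruct_counts(100, 0.9, fn_h=0, fp_h=20)


class TestStratify:
    def _keys(self, n, animal="a1", day=1, location="pasture", farm="f1"):
        return pd.DataFrame({"animal": [animal] * n, "day": [day] * n,
                             "location": [location] * n, "farm": [farm] * n})

    def test_pooled_equals_stratum_sums(self):
        gt = series((L, 100), (N, 100), (L, 100), (N, 100))
        pred = series((L, 200), (N, 200))
        keys = pd.concat([self._keys(200, "a1"), self._keys(200, "a2")],
                         ignore_index=True)
        out = stratify(gt, pred, keys)
        summed = sum((e["counts"].total for e in out["strata"].values()))
        assert summed == out["pooled_counts"].total == 400

    def test_median_of_mixed_strata(self):
        # one perfect animal-day, one at 50% accuracy, equal time
        gt = series((L, 50), (N, 50), (L, 50), (N, 50))
        pred = series((L, 50), (N, 50), (L, 100))
        keys = pd.concat([self._keys(100, "a1"), self._keys(100, "a2")],
                         ignore_index=True)
        out = stratify(gt, pred, keys)
        assert out["median_accuracy_per_animal_day"] == pytest.approx(0.75)

    def test_single_stratum_median_is_pooled(self):
        gt = series((L, 80), (N, 20))
        pred = series((L, 100))
        out = stratify(gt, pred, self._keys(100))
        assert out["median_accuracy_per_animal_day"] == pytest.approx(
            out["pooled_metrics"].accuracy)

    def test_missing_keys_rejected(self):
        gt = series((L, 10))
        pred = series((L, 10))
        keys = self._keys(10)
        keys.loc[3, "animal"] = None
        with pytest.raises(ValueError, match="missing"):
            stratify(gt, pred, keys)

    def test_short_keys_rejected(self):
        gt = series((L, 10))
        with pytest.raises(ValueError, match="cover"):
            stratify(gt, gt, self._keys(5))


class TestLabelAgreement:
    def _tl(self, intervals, t1=100):
        return rasterize_labels(intervals, 0, t1)

    def test_identical(self):
        tl = self._tl([LabelInterval(0, 100, "lying")])
        assert label_agreement(tl, tl, detail=True) == 100.0

    def test_partial(self):
        a = self._tl([LabelInterval(0, 100, "standing")])
        b = self._tl([LabelInterval(0, 95, "standing"),
                      LabelInterval(95, 100, "walking")])
        assert label_agreement(a, b, detail=True) == 95.0

    def test_binary_collapses_non_lying(self):
        a = self._tl([LabelInterval(0, 100, "standing")])
        b = self._tl([LabelInterval(0, 100, "grazing")])
        assert label_agreement(a, b, detail=True) == 0.0
        assert label_agreement(a, b, detail=False) == 100.0

    def test_overlay_difference_counts_in_detail(self):
        a = self._tl([LabelInterval(0, 100, "standing",
                                    frozenset({"ruminating"}))])
        b = self._tl([LabelInterval(0, 100, "standing")])
        assert label_agreement(a, b, detail=True) == 0.0
        assert label_agreement(a, b, detail=False) == 100.0

    def test_disjoint_frames_rejected(self):
        a = self._tl([LabelInterval(0, 10, "lying")], t1=10)
        b = rasterize_labels([LabelInterval(50, 60, "lying")], 50, 60)
        with pytest.raises(ValueError, match="time frame"):
            label_agreement(a, b)


class TestDailyLyingTime:
    def test_day_night_split(self):
        labels = np.full(86400, N, dtype=np.int8)
        labels[6 * 3600:12 * 3600] = L      # 06:00-12:00
        labels[20 * 3600:24 * 3600] = L     # 20:00-24:00
        out = daily_lying_time(BinarySeries(0, labels))
        assert out.total_h == pytest.approx(10.0)
        assert out.day_h == pytest.approx(6.0)
        assert out.night_h == pytest.approx(4.0)
        assert not out.excluded

    def test_all_lying(self):
        out = daily_lying_time(series((L, 86400)))
        assert (out.total_h, out.day_h, out.night_h) == (24.0, 12.0, 12.0)

    def test_excessive_missing_flagged(self):
        labels = np.full(86400, L, dtype=np.int8)
        labels[: int(0.15 * 86400)] = I
        out = daily_lying_time(BinarySeries(0, labels))
        assert out.missing_fraction == pytest.approx(0.15, abs=1e-3)
        assert out.excluded
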