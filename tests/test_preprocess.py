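import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgval import (
    ConditionWindow,
    PreprocessError,
    clean_segment,
    correct,
    karlsson_flags,
    range_filter_flags,
    segment,
    tune_threshold,
)


class TestRangeFilter:
    def test_bounds_applied(self):
        flags = range_filter_flags(np.array([250.0, 800.0, 800.0]))
        assert list(flags) == [True, False, False]

    def test_all_in_range(self):
        assert not range_filter_flags(np.array([300.0, 1000.0, 2000.0])).any()

    def test_boundary_values_kept(self):
        # "shorter than 300 / longer than 2000" is strict
        flags = range_filter_flags(np.array([300.0, 2000.0, 299.999, 2000.001]))
        assert list(flags) == [False, False, True, True]


class TestKarlssonFlags:
    def test_hand_evaluated_flag(self):
        # neighbour mean 800; |1100-800|=300 > 0.25*800=200
        flags = karlsson_flags(np.array([800.0, 1100.0, 800.0]), 0.25)
        assert list(flags) == [False, True, False]

    def test_hand_evaluated_no_flag(self):
        # |990-800|=190 <= 200
        assert not karlsson_flags(np.array([800.0, 990.0, 800.0]), 0.25).any()

    def test_constant_series_never_flagged(self):
        assert not karlsson_flags(np.full(50, 900.0), 0.01).any()

    def test_first_and_last_never_flagged(self):
        flags = karlsson_flags(np.array([5000.0, 800.0, 810.0, 790.0, 5000.0]), 0.25)
        assert not flags[0] and not flags[-1]

    def test_short_series_all_false(self):
        assert not karlsson_flags(np.array([800.0, 5000.0]), 0.25).any()

    @settings(max_examples=30, deadline=None)
    @given(
        ibis=st.lists(st.floats(min_value=310, max_value=1900), min_size=3, max_size=60),
        c1=st.floats(min_value=0.05, max_value=0.9),
        c2=st.floats(min_value=0.05, max_value=0.9),
    )
    def test_monotone_in_threshold(self, ibis, c1, c2):
        """Raising the coefficient never increases the flag count."""
        lo, hi = sorted([c1, c2])
        arr = np.asarray(ibis)
        assert karlsson_flags(arr, hi).sum() <= karlsson_flags(arr, lo).sum()

    def test_huge_threshold_flags_nothing(self, rng):
        arr = rng.uniform(400, 1800, 100)
        assert not karlsson_flags(arr, 1e9).any()


class TestCorrect:
    def test_middle_value_interpolated(self, make_series):
        s = make_series([800, 1100, 800])
        res = correct(s, np.array([False, True, False]))
        np.testing.assert_allclose(res.series.ibis, [800, 800, 800])
        assert res.n_artifacts == 1
        assert list(res.series.interpolated_mask) == [False, True, False]
        np.testing.assert_array_equal(res.series.onsets, s.onsets)

    def test_no_flags_is_identity(self, make_series):
        s = make_series([800, 900, 850])
        res = correct(s, np.zeros(3, bool))
        np.testing.assert_array_equal(res.series.ibis, s.ibis)
        assert res.n_artifacts == 0

    def test_run_of_flags_equally_spaced(self, make_series):
        s = make_series([600, 50, 50, 900])
        res = correct(s, np.array([False, True, True, False]))
        np.testing.assert_allclose(res.series.ibis, [600, 700, 800, 900])

    def test_flagged_extremes_take_nearest_unflagged(self, make_series):
        s = make_series([100, 800, 900, 100])
        res = correct(s, np.array([True, False, False, True]))
        np.testing.assert_allclose(res.series.ibis, [800, 800, 900, 900])

    def test_all_flagged_raises(self, make_series):
        s = make_series([100, 100])
        with pytest.raises(PreprocessError, match="anchor"):
            correct(s, np.array([True, True]))


class TestCleanSegment:
    def test_clean_input_is_identity(self, make_series):
        s = make_series([800, 820, 810, 805, 815])
        res = clean_segment(s, 0.25)
        assert res.n_artifacts == 0
        np.testing.assert_array_equal(res.series.ibis, s.ibis)
        assert res.threshold_used == 0.25

    def test_union_of_both_rules_counted(self, make_series):
        # one range violation (250) and one Karlsson outlier (1100 in 800s)
        s = make_series([800, 250, 800, 800, 1100, 800, 800])
        res = clean_segment(s, 0.25)
        assert res.n_artifacts == 2
        assert res.series.interpolated_mask.sum() == 2

    def test_length_conserved(self, rng, make_series):
        ibis = rng.uniform(200, 2500, 80)
        s = make_series(ibis)
        res = clean_segment(s, 0.25)
        assert len(res.series) == len(s)

    def test_idempotent(self, rng, make_series):
        ibis = rng.normal(900, 40, 120).clip(600, 1400)
        ibis[10] = 250
        ibis[50] = 2500
        s = make_series(ibis)
        once = clean_segment(s, 0.3)
        twice = clean_segment(once.series.replace(interpolated_mask=np.zeros(len(s), bool)), 0.3)
        assert twice.n_artifacts == 0
        np.testing.assert_allclose(twice.series.ibis, once.series.ibis)

    def test_empty_segment_passes_through(self, make_series):
        from ppgval import IbiSeries

        res = clean_segment(IbiSeries("d", "p", [], []), 0.25)
        assert res.n_artifacts == 0 and len(res.series) == 0


class TestTuneThreshold:
    def _segmented(self, make_series, ibis):
        s = make_series(ibis)
        return segment(s, [ConditionWindow("all", 0, int(s.onsets[-1]) + 1)])

    def test_clean_criterion_keeps_start(self, make_series):
        rec = self._segmented(make_series, [800, 810, 805, 795, 800])
        assert tune_threshold(rec) == 0.25

    def test_escalates_to_cover_max_deviation_ratio(self, make_series):
        # construct max neighbour-deviation ratio of 0.32 by brute force:
        # neighbours 800, 800 -> mean 800; value 800*1.32 = 1056
        ibis = [800.0, 1056.0, 800.0, 810.0, 790.0]
        arr = np.array(ibis)
        ratios = np.abs(arr[1:-1] - (arr[:-2] + arr[2:]) / 2) / ((arr[:-2] + arr[2:]) / 2)
        assert ratios.max() == pytest.approx(0.32)
        rec = self._segmented(make_series, ibis)
        assert tune_threshold(rec) == pytest.approx(0.35)

    def test_uncorrectable_gap_errors_at_cap(self, make_series):
        # 1900 between 450s: ratio |1900-450|/450 > 3; range filter keeps all
        rec = self._segmented(make_series, [450.0, 1900.0, 450.0, 460.0])
        with pytest.raises(PreprocessError, match="cap"):
            tune_threshold(rec)

    def test_result_clears_all_segments(self, rng, make_series):
        ibis = np.clip(rng.normal(900, 60, 300), 400, 1800)
        s = make_series(ibis)
        rec = segment(
            s,
            [
                ConditionWindow("a", 0, 100_000),
                ConditionWindow("b", 100_000, 1_000_000),
            ],
        )
        c = tune_threshold(rec)
        from ppgval.preprocess import karlsson_flags as kf, range_filter_flags as rf
        from ppgval.preprocess import correct as corr

        for seg in rec.segments.values():
            if not len(seg):
                continue
            cleaned = corr(seg, rf(seg.ibis)).series.ibis
            assert not kf(cleaned, c).any()
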