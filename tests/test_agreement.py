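import math

import numpy as np
import pytest
from scipy import stats

from ppgval import (
    PpgvalError,
    adjust_p,
    agreement_stats,
    band_label,
    bland_altman,
    ln_transform,
    maape,
    regress,
)

MAAPE_MAX = 100 * math.pi / 2


class TestMaape:
    def test_perfect_agreement_zero(self, rng):
        c = rng.uniform(40, 120, 30)
        assert maape(c, c) == 0.0

    def test_doubling_gives_arctan_one(self):
        # |2c - c| / c = 1 -> arctan(1) = pi/4 -> 25*pi percent
        assert maape([80.0], [40.0]) == pytest.approx(100 * math.pi / 4)

    def test_bounded_by_asymptote(self, rng):
        d = rng.uniform(0.01, 1e6, 100)
        c = rng.uniform(0.01, 100, 100)
        assert 0 <= maape(d, c) <= MAAPE_MAX

    def test_scale_invariance(self, rng):
        d = rng.uniform(20, 60, 50)
        c = rng.uniform(20, 60, 50)
        assert maape(3.7 * d, 3.7 * c) == pytest.approx(maape(d, c), abs=1e-12)

    def test_brute_force_oracle(self, rng):
        d = rng.uniform(30, 90, 40)
        c = rng.uniform(30, 90, 40)
        brute = 100.0 * sum(
            math.atan(abs(dv - cv) / abs(cv)) for dv, cv in zip(d, c)
        ) / len(d)
        assert maape(d, c) == pytest.approx(brute, abs=1e-9)

    def test_zero_criterion_rejected(self):
        with pytest.raises(PpgvalError, match="0"):
            maape([1.0], [0.0])


class TestRegress:
    def test_identity_line(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        res = regress(c, c)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)

    def test_exact_affine_line(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        res = regress(2 * c + 1, c)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        c = rng.uniform(50, 100, 100)
        d = 1.3 * c - 5 + rng.normal(0, 4, 100)
        res = regress(d, c)
        x = np.column_stack([np.ones(100), c])
        beta = np.linalg.solve(x.T @ x, x.T @ d)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(PpgvalError, match="variance"):
            regress([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestBandLabel:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.95, "very high"),
            (0.90, "very high"),  # boundary assigned upward
            (0.70, "high"),
            (0.69, "moderate"),
            (0.50, "moderate"),
            (0.30, "low"),
            (0.29, "negligible"),
            (-0.95, "very high"),  # banding on |r|
        ],
    )
    def test_bands(self, r, expected):
        assert band_label(r) == expected


class TestBlandAltman:
    def test_identical_pairs(self):
        c = np.array([10.0, 20.0, 30.0])
        ba = bland_altman(c, c)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        c = np.array([10.0, 20.0, 30.0])
        ba = bland_altman(c + 2, c)
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_sign_convention(self, rng):
        """Differences are device minus criterion; negating the offset negates bias."""
        c = rng.uniform(40, 80, 50)
        assert bland_altman(c + 3, c).bias == pytest.approx(-bland_altman(c - 3, c).bias)

    def test_simulated_normal_diffs_recover_closed_form(self):
        rng = np.random.default_rng(2024)
        n = 200
        c = rng.uniform(50, 100, n)
        d = c + rng.normal(1.0, 2.0, n)
        ba = bland_altman(d, c)
        se_bias = 2.0 / math.sqrt(n)  # Monte-Carlo SE of the mean
        se_loa = 2.0 * math.sqrt(3.0 / n)  # large-sample SE of a LoA
        assert abs(ba.bias - 1.0) < 3 * se_bias
        assert abs(ba.loa_low - (1.0 - 1.96 * 2.0)) < 3 * se_loa
        assert abs(ba.loa_high - (1.0 + 1.96 * 2.0)) < 3 * se_loa

    def test_ci_construction(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(40, 90, 30)
        d = c + rng.normal(0.5, 1.5, 30)
        ba = bland_altman(d, c)
        half = stats.t.ppf(0.975, 29) * ba.sd_diff / math.sqrt(30)
        assert ba.ci_bias[0] == pytest.approx(ba.bias - half)
        half_loa = 1.959963984540054 * ba.sd_diff * math.sqrt(3 / 30)
        assert ba.ci_loa_low[1] == pytest.approx(ba.loa_low + half_loa)
        assert ba.loa_low <= ba.bias <= ba.loa_high

    def test_too_few_pairs_rejected(self):
        with pytest.raises(PpgvalError):
            bland_altman([1.0], [1.0])


class TestLnTransform:
    def test_values(self):
        out = ln_transform([1.0, math.e])
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0)

    def test_round_trip(self, rng):
        v = rng.uniform(0.1, 100, 50)
        np.testing.assert_allclose(np.exp(ln_transform(v)), v)

    def test_nonpositive_named(self):
        with pytest.raises(PpgvalError, match="index 1"):
            ln_transform([2.0, -1.0], context="p3/sitting")


class TestAdjustP:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.001, 32, 0.032), (0.5, 32, 1.0), (0.123, 1, 0.123)]
    )
    def test_bonferroni(self, p, m, expected):
        assert adjust_p(p, m) == pytest.approx(expected)


class TestAgreementStats:
    def test_pairwise_complete_and_n(self, rng):
        c = rng.uniform(40, 80, 20)
        d = c + rng.normal(0, 2, 20)
        full = agreement_stats(d, c)
        d2 = d.copy()
        d2[5] = np.nan  # incomplete pair dropped
        partial = agreement_stats(d2, c)
        assert full.n == 20 and partial.n == 19

    def test_log_transform_applies_to_regression_not_maape(self, rng):
        c = rng.uniform(20, 60, 25)
        d = c * rng.lognormal(0.1, 0.2, 25)
        raw = agreement_stats(d, c, log_transform=False)
        logged = agreement_stats(d, c, log_transform=True)
        assert raw.maape == pytest.approx(logged.maape)
        assert raw.bias != pytest.approx(logged.bias)
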