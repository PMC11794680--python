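import numpy as np
import pytest

from ppgval import (
    ConditionWindow,
    ConfigError,
    SynthConfig,
    corrupt,
    simulate_accel,
    simulate_criterion,
)
from ppgval.features import rmssd


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ConfigError):
            SynthConfig(miss_rate=1.5)

    def test_truth_must_stay_in_physiological_range(self):
        with pytest.raises(ConfigError, match="300"):
            SynthConfig(mean_ibi_ms=400, rsa_amp_ms=80, noise_sd_ms=10)


class TestSimulateCriterion:
    def test_degenerate_generator_constant(self):
        s, truth = simulate_criterion(SynthConfig(rsa_amp_ms=0, noise_sd_ms=0))
        assert np.all(s.ibis == s.ibis[0])
        assert truth["rmssd"] == 0.0

    def test_determinism(self):
        a, _ = simulate_criterion(SynthConfig(seed=42))
        b, _ = simulate_criterion(SynthConfig(seed=42))
        np.testing.assert_array_equal(a.onsets, b.onsets)

    def test_beat_count_matches_duration_over_mean(self):
        s, _ = simulate_criterion(
            SynthConfig(mean_ibi_ms=900, duration_s=300, rsa_amp_ms=0, noise_sd_ms=0)
        )
        assert abs(len(s) - 300000 / 900) <= 2

    def test_truth_rmssd_matches_features_module(self):
        """Ground truth and the feature path agree to 1e-9 (independent code)."""
        s, truth = simulate_criterion(SynthConfig(seed=5, noise_sd_ms=20))
        assert truth["rmssd"] == pytest.approx(rmssd(s.ibis), abs=1e-9)

    def test_truth_hr_is_exact_mean_construction(self):
        s, truth = simulate_criterion(SynthConfig(seed=6))
        assert truth["hr"] == pytest.approx(60000.0 / np.mean(s.ibis), abs=1e-9)


class TestCorrupt:
    def test_no_corruption_is_identity(self):
        s, _ = simulate_criterion(SynthConfig(seed=1))
        d = corrupt(s, SynthConfig(seed=1))
        np.testing.assert_array_equal(d.onsets, s.onsets)
        np.testing.assert_allclose(d.ibis, s.ibis)

    def test_clock_offset_pure_shift(self):
        s, _ = simulate_criterion(SynthConfig(seed=1))
        d = corrupt(s, SynthConfig(seed=1, clock_offset_ms=5000))
        np.testing.assert_array_equal(d.onsets, s.onsets + 5000)

    def test_miss_rate_halves_detection(self):
        s, _ = simulate_criterion(SynthConfig(seed=2, duration_s=1800))
        d = corrupt(s, SynthConfig(seed=2, miss_rate=0.5))
        # surviving beats ~ Binomial(n, 0.5); intervals ~ beats - 1
        n = len(s) + 1
        rate = len(d) / len(s)
        sd = np.sqrt(0.25 / n)
        assert abs(rate - 0.5) < 4 * sd + 2 / n

    def test_miss_rate_monotone_in_detection(self):
        s, _ = simulate_criterion(SynthConfig(seed=3, duration_s=1200))
        rates = []
        for mr in (0.0, 0.2, 0.4, 0.6):
            counts = [
                len(corrupt(s, SynthConfig(seed=seed, miss_rate=mr)))
                for seed in range(5)
            ]
            rates.append(np.mean(counts))
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_extra_rate_adds_beats(self):
        s, _ = simulate_criterion(SynthConfig(seed=4))
        d = corrupt(s, SynthConfig(seed=4, extra_rate=0.3))
        assert len(d) > len(s)

    def test_dropout_window_empties_region(self):
        s, _ = simulate_criterion(SynthConfig(seed=5))
        win = (60_000.0, 120_000.0)
        d = corrupt(s, SynthConfig(seed=5, dropout_windows=(win,)))
        inside = (d.onsets >= win[0]) & (d.onsets < win[1])
        # only the interval bridging the gap may have its closing beat after it
        assert inside.sum() == 0

    def test_determinism(self):
        s, _ = simulate_criterion(SynthConfig(seed=6))
        cfg = SynthConfig(seed=6, miss_rate=0.1, extra_rate=0.05, jitter_sd_ms=10)
        a = corrupt(s, cfg)
        b = corrupt(s, cfg)
        np.testing.assert_array_equal(a.onsets, b.onsets)


class TestSimulateAccel:
    WINDOWS = [
        ConditionWindow("sitting", 0, 120_000),
        ConditionWindow("walking", 120_000, 240_000),
    ]

    def test_determinism(self):
        cfg = SynthConfig(seed=8)
        a = simulate_accel(self.WINDOWS, {"sitting": 0.01, "walking": 0.16}, 32, cfg)
        b = simulate_accel(self.WINDOWS, {"sitting": 0.01, "walking": 0.16}, 32, cfg)
        np.testing.assert_array_equal(a.x, b.x)

    def test_gravity_present_on_z(self):
        raw = simulate_accel(self.WINDOWS, {}, 32, SynthConfig(seed=9))
        z_g = raw.z * raw.physical_range / raw.digital_range
        assert np.mean(z_g) == pytest.approx(1.0, abs=0.01)
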