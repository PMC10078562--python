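import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturo.core import DataError, DegenerateInputError, EmbeddingSpec
from posturo.config import SimulationConfig
from posturo.nonlinear import (
    average_mutual_information,
    delay_embed,
    false_nearest_neighbors,
    mean_period,
    rosenstein_lye,
    trial_lye,
)
from posturo.simulate import simulate_cop_trial


class TestAverageMutualInformation:
    def test_sine_first_minimum_at_quarter_period(self, period100_sine):
        res = average_mutual_information(period100_sine, max_lag=60)
        assert abs(res.first_minimum - 25) <= 1
        assert not res.fallback_used

    def test_iid_noise_is_uninformative_and_falls_back(self):
        noise = np.random.default_rng(0).uniform(size=100_000)
        res = average_mutual_information(noise, max_lag=10, n_bins=64)
        assert np.all(res.ami[1:] <= 0.05)
        assert res.fallback_used

    def test_lag_zero_is_the_maximum(self, lorenz_series):
        res = average_mutual_information(lorenz_series[:20_000], max_lag=40)
        assert res.ami[0] == pytest.approx(res.ami.max())
        assert np.argmax(res.ami) == 0

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            average_mutual_information(np.ones(1000), max_lag=10)


class TestFalseNearestNeighbors:
    def test_lorenz_embeds_in_three_dimensions(self, lorenz_series):
        ami = average_mutual_information(lorenz_series, max_lag=50)
        res = false_nearest_neighbors(lorenz_series, ami.first_minimum, max_dim=6)
        assert res.chosen_dimension == 3
        assert not res.saturated

    def test_clean_sine_embeds_in_two_dimensions(self, period100_sine):
        res = false_nearest_neighbors(period100_sine, 25, max_dim=5)
        assert res.chosen_dimension == 2
        assert not res.saturated

    def test_iid_noise_saturates_at_max_dim(self):
        noise = np.random.default_rng(0).normal(size=4000)
        res = false_nearest_neighbors(noise, 1, max_dim=8)
        assert res.saturated
        assert res.chosen_dimension == 8


class TestDelayEmbed:
    def test_direct_indexing_example(self):
        series = np.arange(1.0, 11.0)
        pts = delay_embed(series, EmbeddingSpec(delay=2, dimension=3))
        assert pts.shape == (6, 3)
        assert tuple(pts[0]) == (1.0, 3.0, 5.0)

    def test_dimension_one_is_identity(self):
        series = np.random.default_rng(1).normal(size=50)
        pts = delay_embed(series, EmbeddingSpec(delay=3, dimension=1))
        assert np.array_equal(pts[:, 0], series)

    @given(n=st.integers(10, 300), T=st.integers(1, 10), d=st.integers(1, 5))
    @settings(max_examples=50, deadline=None)
    def test_point_count_formula(self, n, T, d):
        m = n - (d - 1) * T
        series = np.arange(float(n))
        if m < 1:
            with pytest.raises(DataError):
                delay_embed(series, EmbeddingSpec(T, d))
        else:
            assert len(delay_embed(series, EmbeddingSpec(T, d))) == m


class TestMeanPeriod:
    def test_pure_tone_gives_its_period(self):
        t = np.arange(0, 40, 1 / 50)
        assert mean_period(np.sin(2 * np.pi * t), 50.0) == pytest.approx(1.0, rel=1e-6)

    def test_equal_power_mixture_gives_mean_frequency(self):
        t = np.arange(0, 64, 1 / 50)  # integer cycles of both tones
        mix = np.sin(2 * np.pi * t) + np.sin(2 * np.pi * 2 * t)
        assert mean_period(mix, 50.0) == pytest.approx(1 / 1.5, rel=1e-6)

    def test_white_noise_mean_frequency_near_quarter_rate(self):
        noise = np.random.default_rng(2).normal(size=50_000)
        assert mean_period(noise, 50.0) == pytest.approx(4 / 50.0, rel=0.05)


class TestRosensteinLye:
    def test_logistic_map_slope_is_ln2(self, logistic_series):
        curve = rosenstein_lye(
            logistic_series, EmbeddingSpec(1, 2), sampling_rate=1.0,
            track_time=8.0, fit_window=(0.0, 4.0),
        )
        assert curve.slope == pytest.approx(np.log(2.0), rel=0.05)

    def test_lorenz_slope_matches_benettin_oracle(self, lorenz_series, lorenz_benettin_lye):
        ami = average_mutual_information(lorenz_series, max_lag=50)
        curve = rosenstein_lye(
            lorenz_series, EmbeddingSpec(ami.first_minimum, 3), sampling_rate=100.0,
            track_time=3.0, fit_window=(0.5, 2.5),
        )
        assert curve.slope == pytest.approx(lorenz_benettin_lye, rel=0.15)

    def test_damped_noisy_oscillator_shows_no_exponential_divergence(self, lorenz_benettin_lye):
        # strongly damped stochastic oscillator: x'' + 2zw x' + w^2 x = noise
        rng = np.random.default_rng(7)
        w0, zeta, dt = 2 * np.pi * 1.0, 0.9, 0.01
        x = v = 0.0
        out = np.empty(30_000)
        for i in range(len(out)):
            v += (-2 * zeta * w0 * v - w0**2 * x) * dt + 0.5 * np.sqrt(dt) * rng.normal()
            x += v * dt
            out[i] = x
        # smooth the forcing noise out so divergence reflects the dynamics
        from scipy.signal import butter, filtfilt

        b, a = butter(4, 3.0, fs=100)
        out = filtfilt(b, a, out)
        curve = rosenstein_lye(
            out, EmbeddingSpec(10, 3), sampling_rate=100.0,
            track_time=3.0, fit_window=(0.5, 2.5),
        )
        assert curve.slope <= 0.05 * lorenz_benettin_lye

    def test_amplitude_scaling_shifts_curve_but_not_slope(self, logistic_series):
        spec = EmbeddingSpec(1, 2)
        kw = dict(sampling_rate=1.0, track_time=6.0, fit_window=(0.0, 4.0))
        c1 = rosenstein_lye(logistic_series, spec, **kw)
        c2 = rosenstein_lye(1000.0 * logistic_series, spec, **kw)
        assert c2.slope == pytest.approx(c1.slope, rel=1e-6)
        shift = c2.mean_log_divergence - c1.mean_log_divergence
        assert np.allclose(shift, np.log(1000.0), atol=1e-9)

    def test_divergence_curve_increases_over_fit_window_for_chaos(self, lorenz_series):
        curve = rosenstein_lye(
            lorenz_series, EmbeddingSpec(16, 3), sampling_rate=100.0,
            track_time=3.0, fit_window=(0.5, 2.5),
        )
        in_win = (curve.times >= 0.5) & (curve.times <= 2.5)
        y = curve.mean_log_divergence[in_win]
        # monotone onset up to smoothing noise: fit both halves
        assert y[-1] > y[0]
        assert np.mean(np.diff(y) > 0) > 0.8

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            rosenstein_lye(np.random.default_rng(0).normal(size=120),
                           EmbeddingSpec(5, 6), 50.0)


class TestTrialLye:
    def test_deterministic_on_identical_trial(self):
        cfg = SimulationConfig()
        trial = simulate_cop_trial(cfg, 0, "AIR", "T5", 0)
        s1, c1 = trial_lye(trial, "AP")
        s2, c2 = trial_lye(trial, "AP")
        assert s1 == s2
        assert np.array_equal(c1.mean_log_divergence, c2.mean_log_divergence)
        assert c1.slope == c2.slope
        assert s1.dimension == 6  # study default embedding dimension

    def test_delays_are_tens_of_samples_in_study_regime(self):
        cfg = SimulationConfig()
        delays = []
        for i in range(8):
            trial = simulate_cop_trial(cfg, i, "AIR", "T5", 0)
            spec, _ = trial_lye(trial, "AP")
            delays.append(spec.delay)
        assert 10 <= np.mean(delays) <= 120  # descriptive regime check
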