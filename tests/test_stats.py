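"""Response statistics against closed-form and Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from anfsim.fiber import SpikeTrain
from anfsim.stats import (apsth, fano_factor, fit_fe, fit_strength_duration,
                          fit_summation_tau, isi_histogram, latency_stats,
                          psth, vector_strength)


def train(times, seed=0):
    times = np.asarray(times, float)
    return SpikeTrain(spike_times=times, sources=np.zeros(times.size, int),
                      trial_seed=seed)


class TestFitFE:
    def test_probit_parameter_recovery(self):
        """Bernoulli draws from an integrated Gaussian (θ=100, σ=5) are
        recovered by the ML probit fit within 1 % / 10 %."""
        rng = np.random.default_rng(2)
        theta, sigma, n = 100.0, 5.0, 1000
        levels = np.linspace(88, 112, 7)
        counts = rng.binomial(n, norm.cdf((levels - theta) / sigma))
        fit = fit_fe(levels, counts, n)
        assert fit.theta == pytest.approx(theta, rel=0.01)
        assert fit.sigma == pytest.approx(sigma, rel=0.10)
        assert fit.rs == fit.sigma / fit.theta

    def test_symmetric_probabilities_give_midpoint_threshold(self):
        levels = np.array([90.0, 100.0, 110.0])
        counts = np.array([100, 500, 900])
        fit = fit_fe(levels, counts, 1000)
        assert fit.theta == pytest.approx(100.0, rel=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        levels = np.linspace(88, 112, 7)
        counts = rng.binomial(500, norm.cdf((levels - 100.0) / 5.0))
        f1 = fit_fe(levels, counts, 500)
        c = 7.3
        f2 = fit_fe(levels * c, counts, 500)
        assert f2.theta == pytest.approx(c * f1.theta, rel=1e-6)
        assert f2.sigma == pytest.approx(c * f1.sigma, rel=1e-6)
        assert f2.rs == pytest.approx(f1.rs, rel=1e-9)

    def test_degenerate_outcomes_signalled(self):
        levels = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="widen"):
            fit_fe(levels, np.zeros(3), 100)
        with pytest.raises(ValueError, match="widen"):
            fit_fe(levels, np.full(3, 100.0), 100)


class TestVectorStrength:
    def test_perfect_phase_locking(self):
        spikes = np.arange(1, 200) * 4000.0
        assert vector_strength(spikes, 4000.0, discard_before=0.0) == pytest.approx(1.0)

    def test_antiphase_pair_cancels(self):
        assert vector_strength([0.0, 500.0], 1000.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_period_pair(self):
        vs = vector_strength([0.0, 250.0], 1000.0, 0.0)
        assert vs == pytest.approx(np.sqrt(2) / 2, rel=1e-9)

    def test_discard_window_applied(self):
        # early spikes at a different phase are excluded
        spikes = np.array([1000.0, 2000.0, 60_000.0, 64_000.0])
        assert vector_strength(spikes, 4000.0) == pytest.approx(1.0)

    def test_no_retained_spikes_signalled(self):
        with pytest.raises(ValueError, match="discard"):
            vector_strength([100.0], 1000.0, discard_before=50_000.0)

    def test_bounds_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = rng.uniform(0, 3e5, rng.integers(1, 40))
            assert 0.0 <= vector_strength(t, 200.0, 0.0) <= 1.0


class TestFanoFactor:
    def test_identical_counts_zero(self):
        assert fano_factor([3, 3, 3, 3]) == 0.0

    def test_poisson_counts_near_one(self):
        n = 10_000
        counts = np.random.default_rng(11).poisson(7.0, n)
        se = np.sqrt(2.0 / n)  # SE of var/mean for Poisson
        assert fano_factor(counts) == pytest.approx(1.0, abs=3 * se)

    def test_binomial_thinning_matches_enumeration(self):
        """Thinning a fixed count N with prob p gives FF = 1 - p; verified
        against exact enumeration of the binomial pmf."""
        from math import comb
        N, p = 6, 0.3
        pmf = np.array([comb(N, k) * p**k * (1 - p)**(N - k) for k in range(N + 1)])
        ks = np.arange(N + 1)
        mean = (pmf * ks).sum()
        var = (pmf * ks**2).sum() - mean**2
        assert var / mean == pytest.approx(1 - p, rel=1e-12)
        counts = np.random.default_rng(12).binomial(N, p, 200_000)
        assert fano_factor(counts) == pytest.approx(1 - p, abs=0.01)

    def test_zero_mean_signalled(self):
        with pytest.raises(ValueError):
            fano_factor([0, 0, 0])


class TestLatency:
    def test_zero_jitter_for_identical_latencies(self):
        trains = [train([300.0]), train([300.0]), train([300.0])]
        mean, jitter = latency_stats(trains)
        assert mean == 300.0 and jitter == 0.0

    def test_first_spike_used(self):
        trains = [train([200.0, 900.0]), train([400.0])]
        mean, _ = latency_stats(trains)
        assert mean == 300.0

    def test_no_spikes_signalled(self):
        with pytest.raises(ValueError):
            latency_stats([train([])])


class TestHistograms:
    def test_isi_entrained_250pps(self):
        trains = [train(np.arange(40) * 4000.0)]
        bins, counts = isi_histogram(trains)
        assert counts[4] == 39 and counts.sum() == 39

    def test_isi_single_spike_empty(self):
        bins, counts = isi_histogram([train([1000.0])])
        assert counts.sum() == 0

    def test_apsth_uniform_is_flat(self):
        t = np.arange(0.5, 300_000, 500.0)  # exactly 2 spikes/ms everywhere
        centers, rates = apsth([train(t)])
        np.testing.assert_allclose(rates, 2000.0, rtol=1e-6)

    def test_apsth_onset_only(self):
        centers, rates = apsth([train([1000.0, 2000.0, 3000.0])])
        assert rates[0] > 0 and np.all(rates[1:] == 0)

    def test_psth_and_apsth_same_total_count(self):
        rng = np.random.default_rng(13)
        trains = [train(np.sort(rng.uniform(0, 300_000, 50))) for _ in range(8)]
        _, p_rates = psth(trains)
        _, a_rates = apsth(trains)
        total_psth = p_rates.sum() * 1e-3 * len(trains)
        windows = ((0, 4), (4, 12), (12, 24), (24, 48), (48, 100), (100, 200),
                   (200, 300))
        total_apsth = sum(r * (b - a) * 1e-3 * len(trains)
                          for r, (a, b) in zip(a_rates, windows))
        assert total_psth == pytest.approx(total_apsth, rel=1e-9)
        assert total_psth == pytest.approx(50 * 8, rel=1e-9)


class TestSummationFit:
    def test_self_consistency_recovery(self):
        delays = np.linspace(100, 300, 9)
        t_inf, a, tau = 500.0, 300.0, 200.0
        thr = t_inf - a * np.exp(-delays / tau)
        tau_hat, asym = fit_summation_tau(delays, thr)
        assert tau_hat == pytest.approx(tau, rel=0.05)
        assert asym == pytest.approx(t_inf, rel=0.05)

    def test_constant_thresholds_signalled(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_summation_tau([100, 200, 300, 400], [50.0, 50.0, 50.0, 50.0])

    def test_too_few_points_signalled(self):
        with pytest.raises(ValueError):
            fit_summation_tau([100, 200, 300], [1.0, 2.0, 3.0])


class TestStrengthDuration:
    def test_exact_recovery_on_noiseless_weiss_data(self):
        rheobase, chronaxie = 11.0, 779.0
        durations = np.array([25.0, 50.0, 100.0, 200.0, 500.0])
        thresholds = rheobase * (1 + chronaxie / durations)
        rb, cx = fit_strength_duration(durations, thresholds)
        assert rb == pytest.approx(rheobase, rel=1e-9)
        assert cx == pytest.approx(chronaxie, rel=1e-9)

    def test_constant_thresholds_give_zero_chronaxie(self):
        rb, cx = fit_strength_duration([25, 50, 100, 200], [40.0, 40.0, 40.0, 40.0])
        assert cx == pytest.approx(0.0, abs=1e-9)
        assert rb == pytest.approx(40.0)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(15)
        rheobase, chronaxie = 11.0, 779.0
        durations = np.array([25.0, 50.0, 100.0, 200.0, 500.0])
        clean = rheobase * (1 + chronaxie / durations)
        rbs, cxs = [], []
        for _ in range(100):
            noisy = clean * rng.normal(1.0, 0.02, clean.size)
            rb, cx = fit_strength_duration(durations, noisy)
            rbs.append(rb)
            cxs.append(cx)
        assert np.mean(rbs) == pytest.approx(rheobase, rel=0.05)
        assert np.mean(cxs) == pytest.approx(chronaxie, rel=0.05)
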