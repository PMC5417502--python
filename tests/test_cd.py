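"""Avalanche-superposition generator: lifetime law, shapes, superposition."""

import numpy as np
import pytest
import scipy.stats

from critband.cd import (
    CDParams,
    active_counts,
    avalanche_profile,
    colored_noise,
    make_avalanche,
    sample_lifetimes,
    simulate_cd,
    truncated_powerlaw_cdf,
    truncated_powerlaw_mean,
)
from critband._spectral import periodogram_slope


class TestLifetimes:
    def test_degenerate_support(self, rng):
        assert np.all(sample_lifetimes(2.5, 1, 5, rng) == 1.0)

    def test_mean_matches_truncated_closed_form(self, rng):
        # E[L] = ((a-1)/(a-2)) (1 - L_c^(2-a)) / (1 - L_c^(1-a)) ~ 2 for a=3
        L = sample_lifetimes(3.0, 1e5, 1_000_000, rng)
        expected = truncated_powerlaw_mean(3.0, 1e5)
        assert expected == pytest.approx(2.0, abs=1e-3)
        assert L.mean() == pytest.approx(expected, rel=0.01)

    def test_ks_against_analytic_cdf(self, rng):
        L = sample_lifetimes(2.5, 1e4, 1_000_000, rng)
        res = scipy.stats.kstest(L, lambda v: truncated_powerlaw_cdf(v, 2.5, 1e4))
        assert res.statistic < 0.005

    def test_support_bounds(self, rng):
        L = sample_lifetimes(1.2, 50.0, 10_000, rng)
        assert L.min() >= 1.0 and L.max() <= 50.0

    def test_alpha_at_most_one_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            sample_lifetimes(1.0, 100, 10, rng)


class TestColoredNoise:
    def test_white_noise_is_flat_and_uncorrelated(self, rng):
        x = colored_noise(2**14, 0.0, rng)
        assert abs(periodogram_slope(x)) < 0.1
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.03

    def test_spectral_slope_minus_two(self):
        slopes = [
            periodogram_slope(colored_noise(2**14, 2.0, np.random.default_rng(i)))
            for i in range(20)
        ]
        assert np.mean(slopes) == pytest.approx(-2.0, abs=0.15)

    def test_standardization(self, rng):
        x = colored_noise(4096, 1.0, rng)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)

    def test_single_sample(self, rng):
        assert colored_noise(1, 2.0, rng) == pytest.approx(0.0)


class TestAvalancheShape:
    def test_parabola_normalized_mean_one(self):
        a = avalanche_profile(101)
        assert a.mean() == pytest.approx(1.0, abs=1e-12)
        # peak at the middle sample equals max(b)/mean(b): the parabola maximum
        # divided by the discrete normalization constant
        t = (np.arange(1, 102) - 0.5) / 101
        b = -4 * (t - 0.5) ** 2 + 1
        assert np.argmax(a) == 50
        assert a[50] == pytest.approx(b.max() / b.mean(), abs=1e-12)
        assert a[0] == pytest.approx(a[-1])  # symmetric endpoints

    def test_length_one_is_unit_sample(self, rng):
        a = make_avalanche(1, CDParams(alpha=2.5, beta=1.0, noise_on=False), rng)
        assert a.shape == (1,) and a[0] == pytest.approx(1.0)

    def test_noisy_avalanche_mean_one_on_average(self):
        p = CDParams(alpha=2.5, beta=1.0, noise_on=True)
        means = [
            make_avalanche(4096, p, np.random.default_rng(i)).mean() for i in range(50)
        ]
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_noise_free_shape_is_deterministic(self, rng):
        a1 = make_avalanche(257, CDParams(alpha=2.5, beta=0.0, noise_on=False), rng)
        a2 = make_avalanche(257, CDParams(alpha=2.5, beta=0.0, noise_on=False), rng)
        np.testing.assert_array_equal(a1, a2)


class TestSimulate:
    def test_unit_cutoff_gives_constant_q(self):
        p = CDParams(alpha=2.5, beta=0.0, L_c=1, q=3, T=100, burn_in=10, noise_on=False)
        sig = simulate_cd(p)
        np.testing.assert_allclose(sig.samples, 3.0)
        assert len(sig) == 90

    def test_mean_level_equals_q_for_unit_cutoff(self):
        # each avalanche contributes exactly one unit sample per step
        p = CDParams(alpha=3.0, beta=0.0, L_c=1, q=7, T=200, burn_in=1, noise_on=False)
        assert simulate_cd(p).samples.mean() == pytest.approx(7.0)

    def test_linearity_of_superposition_mean(self):
        # mean(X | q1+q2) equals mean(X | q1) + mean(X | q2) for independent runs
        base = dict(alpha=2.5, beta=0.5, L_c=500, T=6000, burn_in=500, noise_on=False)
        m12 = np.mean(
            [simulate_cd(CDParams(q=5, seed=s, **base)).samples.mean() for s in range(8)]
        )
        m1 = np.mean(
            [simulate_cd(CDParams(q=2, seed=s + 100, **base)).samples.mean() for s in range(8)]
        )
        m2 = np.mean(
            [simulate_cd(CDParams(q=3, seed=s + 200, **base)).samples.mean() for s in range(8)]
        )
        # E[X] = q E[h]; compare against 3 standard errors of the replicate spread
        assert m12 == pytest.approx(m1 + m2, rel=0.05)

    def test_invalid_T_burnin(self):
        with pytest.raises(ValueError):
            CDParams(alpha=2.5, beta=1.0, L_c=100, T=100, burn_in=100)

    def test_mu2_raw_hurst_matches_formula_in_scaling_regime(self):
        # H_raw = beta - alpha/2 + 2 = 1.75 for (2.5, 1); measured on the
        # noise-free profile superposition with windows well inside the cutoff,
        # where the derivation of the raw exponent applies
        from critband import dfa

        hs = []
        for s in range(10):
            sig = simulate_cd(
                CDParams(alpha=2.5, beta=1.0, L_c=100_000, q=5, T=300_000,
                         seed=s, noise_on=False)
            )
            hs.append(dfa(sig.samples, n_min=100, n_max=10_000, num=12).hurst_)
        assert np.mean(hs) == pytest.approx(1.75, abs=0.15)

    def test_mu1_marginal_is_gaussian(self):
        # CLT regime: alpha=1.5 has ~L_c^(2-alpha) simultaneously active
        # avalanches; the marginal is pooled over independent runs because a
        # single run is strongly long-range correlated
        samples = []
        for s in range(20):
            p = CDParams(alpha=1.5, beta=1.0, L_c=10_000, q=5, T=14_000, seed=s)
            samples.append(simulate_cd(p).samples)
        k = scipy.stats.kurtosis(np.concatenate(samples))
        assert abs(k) < 0.3


class TestActiveCounts:
    def test_unit_cutoff_counts(self):
        p = CDParams(alpha=2.5, beta=0.0, L_c=1, q=3, T=50, burn_in=1)
        assert np.all(active_counts(p) == 3)

    def test_mean_count_matches_renewal_theory(self):
        # stationary mean active count = q E[ceil(L)], with E[L] ~ 2 for alpha=3;
        # oracle: E[ceil(L)] summed from the analytic truncated CDF
        p = CDParams(alpha=3.0, beta=0.0, L_c=10_000, q=1, T=40_000, burn_in=1000)
        m = active_counts(p).mean()
        k = np.arange(1, 10_001)
        cdf = truncated_powerlaw_cdf(k.astype(float), 3.0, 10_000)
        e_ceil = np.sum(1.0 - cdf[:-1]) + 1.0  # E[ceil(L)] = 1 + sum P(L > k)
        assert truncated_powerlaw_mean(3.0, 10_000) == pytest.approx(2.0, abs=0.01)
        assert m == pytest.approx(e_ceil, abs=0.2)

    def test_cutoff_scaling_of_active_counts(self):
        # mean active count scales as L_c^(2-alpha) for alpha < 2
        means = {}
        for L_c in (1000, 10_000):
            vals = [
                active_counts(
                    CDParams(alpha=1.5, beta=0.0, L_c=L_c, q=1, T=L_c + 4000,
                             burn_in=L_c, seed=s)
                ).mean()
                for s in range(10)
            ]
            means[L_c] = np.mean(vals)
        ratio = means[10_000] / means[1000]
        assert ratio == pytest.approx(10 ** 0.5, rel=0.25)
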