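"""DFA / DCCA / rho_DCCA against closed forms, naive references and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from critband import (
    DetrendedCrossCorrelation,
    DetrendedFluctuation,
    WindowPlan,
    dcca,
    dfa,
    rho_dcca,
    tail_gradient,
)
from critband._spectral import spectral_noise


def naive_f2(x, y, n, degree=1):
    """Double-loop reference for the detrended (cross-)fluctuation F^2(n)."""
    px = np.cumsum(x - np.mean(x))
    py = np.cumsum(y - np.mean(y))
    k = len(px) // n
    t = np.arange(n, dtype=float)
    total = 0.0
    for j in range(k):
        wx, wy = px[j * n : (j + 1) * n], py[j * n : (j + 1) * n]
        rx = wx - np.polyval(np.polyfit(t, wx, degree), t)
        ry = wy - np.polyval(np.polyfit(t, wy, degree), t)
        total += rx @ ry
    return total / (k * n)


def synth_long_memory(n, hurst, seed):
    """Stationary noise with Hurst exponent H via spectral exponent 2H - 1."""
    return spectral_noise(n, 2 * hurst - 1, np.random.default_rng(seed))


class TestDFA:
    def test_constant_series_has_zero_fluctuations(self):
        est = dfa(np.full(4096, 3.7), n_min=16, n_max=512, num=8)
        np.testing.assert_allclose(est.fluctuations_, 0.0, atol=1e-10)

    @pytest.mark.parametrize("hurst", [0.5, 0.8])
    def test_hurst_recovery_on_synthetic_noise(self, hurst):
        ests = [
            dfa(synth_long_memory(2**16, hurst, seed), n_min=16, n_max=4096, num=20).hurst_
            for seed in range(20)
        ]
        assert np.mean(ests) == pytest.approx(hurst, abs=0.05)

    def test_matches_naive_reference(self, rng):
        x = rng.standard_normal(64)
        est = dfa(x, window_sizes=[8, 16])
        for i, n in enumerate((8, 16)):
            assert est.fluctuations_[i] ** 2 == pytest.approx(
                naive_f2(x, x, n), abs=1e-12
            )

    def test_window_size_validation(self, rng):
        with pytest.raises(ValueError, match="detrend degree"):
            dfa(rng.standard_normal(100), window_sizes=[2, 8])
        with pytest.raises(ValueError, match="exceeds series length"):
            dfa(rng.standard_normal(100), window_sizes=[8, 200])

    def test_non_finite_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            dfa(x, window_sizes=[8, 16])

    def test_scale_and_shift_invariance(self, rng):
        x = rng.standard_normal(2048)
        a = dfa(x, n_min=16, n_max=256, num=8)
        b = dfa(5.0 * x, n_min=16, n_max=256, num=8)
        c = dfa(x + 100.0, n_min=16, n_max=256, num=8)
        assert b.hurst_ == pytest.approx(a.hurst_, abs=1e-12)
        np.testing.assert_allclose(b.fluctuations_, 5.0 * a.fluctuations_, rtol=1e-10)
        np.testing.assert_allclose(c.fluctuations_, a.fluctuations_, atol=1e-8)

    def test_sklearn_param_protocol(self):
        est = DetrendedFluctuation(n_min=32)
        assert est.get_params()["n_min"] == 32
        est.set_params(n_max=512)
        assert est.n_max == 512


class TestDCCA:
    def test_self_dcca_equals_dfa_bitwise(self, rng):
        x = rng.standard_normal(4000)
        f2 = dcca(x, x, window_sizes=[16, 64, 256])
        est = dfa(x, window_sizes=[16, 64, 256])
        np.testing.assert_array_equal(f2, est.fluctuations_sq_)

    def test_antisymmetric_pair(self, rng):
        x = rng.standard_normal(4000)
        f2 = dcca(x, -x, window_sizes=[16, 64, 256])
        est = dfa(x, window_sizes=[16, 64, 256])
        np.testing.assert_allclose(f2, -est.fluctuations_**2, rtol=1e-12)

    def test_independent_series_average_to_zero(self):
        sizes = [16, 64]
        vals = np.array(
            [
                dcca(
                    np.random.default_rng(2 * s).standard_normal(2000),
                    np.random.default_rng(2 * s + 1).standard_normal(2000),
                    window_sizes=sizes,
                )
                for s in range(100)
            ]
        )
        for i in range(len(sizes)):
            mean, se = vals[:, i].mean(), vals[:, i].std(ddof=1) / 10
            assert abs(mean) < 3 * se + 1e-12

    def test_matches_naive_cross_reference(self, rng):
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        f2 = dcca(x, y, window_sizes=[8, 16])
        for i, n in enumerate((8, 16)):
            assert f2[i] == pytest.approx(naive_f2(x, y, n), abs=1e-12)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            dcca(rng.standard_normal(100), rng.standard_normal(99), window_sizes=[8])


class TestRho:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(4000)
        est = rho_dcca(x, x, window_sizes=[16, 64, 256])
        np.testing.assert_allclose(est.rho_, 1.0, atol=1e-12)

    def test_anti_correlation_is_minus_one(self, rng):
        x = rng.standard_normal(4000)
        est = rho_dcca(x, -x, window_sizes=[16, 64, 256])
        np.testing.assert_allclose(est.rho_, -1.0, atol=1e-12)

    def test_matches_pearson_for_stationary_pairs(self):
        # y = 0.6 x + e: rho_DCCA estimates the same quantity as Pearson
        rs = []
        for s in range(10):
            g = np.random.default_rng(s)
            x = g.standard_normal(20_000)
            y = 0.6 * x + g.standard_normal(20_000)
            est = rho_dcca(x, y, window_sizes=[32, 64, 128])
            rs.append(est.rho_[1] - np.corrcoef(x, y)[0, 1])
        assert np.mean(np.abs(rs)) < 0.05

    def test_trend_robustness(self, rng):
        # a common linear trend barely moves rho once the detrending degree
        # covers it (series trend of degree d-1 is removed by DFA/DCCA-d)
        x = rng.standard_normal(8000)
        y = 0.5 * x + rng.standard_normal(8000)
        trend = np.linspace(0, 50, 8000)
        r0 = rho_dcca(x, y, window_sizes=[32, 128, 512], degree=2).rho_
        r1 = rho_dcca(x + trend, y + trend, window_sizes=[32, 128, 512], degree=2).rho_
        assert np.max(np.abs(r1 - r0)) < 0.02

    def test_constant_window_reported_missing(self):
        x = np.zeros(200)
        y = np.arange(200.0)
        est = rho_dcca(x, y, window_sizes=[8, 16])
        assert np.all(np.isnan(est.rho_))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rho_bounded_by_one(self, seed):
        g = np.random.default_rng(seed)
        x = np.cumsum(g.standard_normal(600)) if seed % 2 else g.standard_normal(600)
        y = g.standard_normal(600) + (0.5 * x if seed % 3 else 0.0)
        est = rho_dcca(x, y, window_sizes=[8, 32, 128])
        ok = np.isfinite(est.rho_)
        assert np.all(np.abs(est.rho_[ok]) <= 1.0 + 1e-9)


class TestTailGradient:
    def test_constant_rho_gives_zero(self):
        assert tail_gradient(np.arange(10, 30), np.full(20, 0.4)) == pytest.approx(0.0)

    def test_exact_linear_in_log_n(self):
        n = np.unique(np.geomspace(10, 10_000, 20).astype(int))
        rho = 0.1 + 0.07 * np.log(n)
        assert tail_gradient(n, rho, k=11) == pytest.approx(0.07, abs=1e-12)

    def test_too_few_usable_points(self):
        with pytest.raises(ValueError, match="usable"):
            tail_gradient(np.array([10, 20, 30]), np.array([np.nan, np.nan, 0.5]))


class TestWindowPlan:
    def test_logspaced_dedup_and_monotone(self):
        plan = WindowPlan.logspaced(8, 64, num=40)
        assert np.all(np.diff(plan.sizes) > 0)
        assert plan.sizes[0] == 8 and plan.sizes[-1] == 64

    def test_fit_mask_range(self):
        plan = WindowPlan(sizes=np.array([8, 16, 32, 64]), fit_range=(16, 32))
        np.testing.assert_array_equal(plan.fit_mask(), [False, True, True, False])
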