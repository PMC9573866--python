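"""Aerobic-scope envelopes: binning, percentile fits, gap maximisation."""

import numpy as np
import pytest

from otolife import (
    bin_by_temperature,
    estimate_scope_envelope,
    fit_lower_envelope,
    fit_upper_envelope,
    optimal_temperature,
)
from otolife.scope import TempBin


def _bins_from_values(centers, p_values, n_per_bin=5):
    """Bins whose p95 and p5 both equal the given value (constant members)."""
    return [
        TempBin(lower=c - 0.5, width=1.0, temps=np.full(n_per_bin, c),
                moto=np.full(n_per_bin, v))
        for c, v in zip(centers, p_values)
    ]


class TestBinning:
    def test_sparse_bin_dropped(self):
        temps = np.concatenate([np.full(5, 13.5), np.full(5, 14.2), [15.2, 15.9], np.full(5, 16.5)])
        moto = np.linspace(0.1, 0.5, temps.size)
        bins = bin_by_temperature(temps, moto)
        assert [b.lower for b in bins] == [13.0, 14.0, 16.0]  # n=2 bin at 15 dropped

    def test_degenerate_percentiles(self):
        temps = np.concatenate([np.full(5, 14.5), np.full(4, 15.5), np.full(4, 16.5)])
        moto = np.concatenate([np.full(5, 0.3), np.linspace(0.1, 0.2, 4), np.linspace(0.1, 0.2, 4)])
        bins = bin_by_temperature(temps, moto)
        assert bins[0].p95 == bins[0].p5 == 0.3

    def test_percentiles_match_order_statistic_oracle(self):
        rng = np.random.default_rng(0)
        moto = rng.uniform(0, 1, 50)
        temps = np.concatenate([np.full(50, 14.3), np.full(4, 15.5), np.full(4, 16.5)])
        allm = np.concatenate([moto, np.zeros(8)])
        bins = bin_by_temperature(temps, allm, min_n=4)
        # brute-force sorted linear interpolation
        s = np.sort(moto)
        h = 0.95 * (s.size - 1)
        lo = int(np.floor(h))
        expected = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert bins[0].p95 == pytest.approx(expected, abs=1e-12)

    def test_bin_by_temperature_needs_three_bins(self):
        with pytest.raises(ValueError, match="unfittable"):
            bin_by_temperature(np.full(10, 14.5), np.linspace(0, 1, 10))

    def test_bins_anchored_at_integers(self):
        bins = bin_by_temperature(
            np.concatenate([np.full(4, 13.99), np.full(4, 14.01), np.full(4, 15.5)]),
            np.zeros(12),
        )
        assert [b.lower for b in bins] == [13.0, 14.0, 15.0]
        assert [b.center for b in bins] == [13.5, 14.5, 15.5]


class TestUpperEnvelope:
    def test_exact_quadratic_recovered(self):
        centers = np.arange(12.5, 19.5)
        values = -0.01 * centers**2 + 0.3 * centers - 1.7
        coefs = fit_upper_envelope(_bins_from_values(centers, values))
        assert coefs == pytest.approx((-0.01, 0.3, -1.7), abs=1e-9)

    def test_three_bins_interpolate(self):
        centers = [13.5, 14.5, 15.5]
        values = [0.2, 0.5, 0.3]
        coefs = fit_upper_envelope(_bins_from_values(centers, values))
        fitted = np.polyval(coefs, centers)
        assert np.allclose(fitted, values, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        centers = np.arange(11.5, 21.5)
        values = 0.4 - 0.01 * (centers - 16) ** 2 + rng.normal(0, 0.02, centers.size)
        coefs = fit_upper_envelope(_bins_from_values(centers, values))
        X = np.vander(centers, 3)
        oracle = np.linalg.solve(X.T @ X, X.T @ values)
        assert np.allclose(coefs, oracle, atol=1e-8)

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            fit_upper_envelope(_bins_from_values([13.5, 14.5], [0.1, 0.2]))


class TestLowerEnvelope:
    def test_exact_exponential_recovered(self):
        centers = np.arange(10.5, 20.5)
        values = np.exp(0.1 + 0.05 * centers)
        eta0, eta1 = fit_lower_envelope(_bins_from_values(centers, values))
        assert eta0 == pytest.approx(0.1, abs=1e-6)
        assert eta1 == pytest.approx(0.05, abs=1e-6)

    def test_two_bins_interpolate_exactly(self):
        centers = [14.5, 16.5]
        values = [0.10, 0.16]
        eta0, eta1 = fit_lower_envelope(_bins_from_values(centers, values))
        fitted = np.exp(eta0 + eta1 * np.asarray(centers))
        assert np.allclose(fitted, values, atol=1e-8)

    def test_matches_grid_search_likelihood_oracle(self):
        rng = np.random.default_rng(3)
        centers = np.arange(11.5, 21.5)
        values = np.exp(-2.5 + 0.04 * centers) + rng.normal(0, 0.005, centers.size)
        eta0, eta1 = fit_lower_envelope(_bins_from_values(centers, values))
        # brute-force Gaussian likelihood scan around the fitted optimum
        e0_grid = np.linspace(eta0 - 0.2, eta0 + 0.2, 81)
        e1_grid = np.linspace(eta1 - 0.01, eta1 + 0.01, 81)
        sse = np.array([
            [np.sum((values - np.exp(a + b * centers)) ** 2) for b in e1_grid]
            for a in e0_grid
        ])
        i, j = np.unravel_index(sse.argmin(), sse.shape)
        assert eta0 == pytest.approx(e0_grid[i], abs=(e0_grid[1] - e0_grid[0]) * 1.5)
        assert eta1 == pytest.approx(e1_grid[j], abs=(e1_grid[1] - e1_grid[0]) * 1.5)

    def test_nonpositive_percentile_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_lower_envelope(_bins_from_values([13.5, 14.5, 15.5], [0.1, -0.01, 0.2]))


class TestOptimalTemperature:
    def test_analytic_argmax(self):
        upper = (-0.002, 2 * 0.002 * 16, 0.5 - 0.002 * 256)  # 0.5 - 0.002 (T-16)^2
        lower = (np.log(0.1), 0.0)  # constant 0.1
        t_opt, grid, gap, flag = optimal_temperature(upper, lower, (10.0, 20.0))
        assert t_opt == pytest.approx(16.0)
        assert not flag

    def test_monotone_gap_boundary(self):
        upper = (0.0, 0.02, 0.1)  # increasing line
        lower = (np.log(0.05), 0.0)
        t_opt, *_ = optimal_temperature(upper, lower, (10.0, 20.0))
        assert t_opt == pytest.approx(20.0)

    def test_tie_breaks_to_lowest_temperature(self):
        upper = (0.0, 0.0, 0.5)  # flat
        lower = (np.log(0.1), 0.0)  # flat -> gap constant
        t_opt, *_ = optimal_temperature(upper, lower, (10.0, 20.0))
        assert t_opt == pytest.approx(10.0)

    def test_nonpositive_gap_flagged(self):
        upper = (0.0, 0.0, 0.05)
        lower = (np.log(0.1), 0.0)
        with pytest.warns(UserWarning, match="nowhere positive"):
            t_opt, _, _, flag = optimal_temperature(upper, lower, (10.0, 20.0))
        assert flag

    def test_scaling_moto_preserves_argmax(self):
        """Multiplying M_oto by c > 0 rescales both envelopes, not the argmax."""
        rng = np.random.default_rng(6)
        temps = rng.uniform(11, 21, 4000)
        moto = np.exp(-2.8 + 0.03 * temps) + rng.uniform(0, 1, 4000) * (
            0.5 - 0.011 * (temps - 15.5) ** 2 - np.exp(-2.8 + 0.03 * temps)
        )
        base = estimate_scope_envelope(temps, moto)
        scaled = estimate_scope_envelope(temps, 3.0 * moto)
        assert scaled.optimal_temperature_c == pytest.approx(base.optimal_temperature_c, abs=1e-9)
        assert np.allclose(scaled.gap_curve, 3.0 * base.gap_curve, rtol=1e-6, atol=1e-9)

    def test_optimum_inside_occupied_range(self, default_ca_cohort):
        from otolife import estimate_moto, invert_fixed_sw
        from otolife.metabolism import IsotopeContext
        from otolife.thermometry import acid_fractionation_adjust

        params, profiles, _ = default_ca_cohort
        ctx = IsotopeContext.for_region("CA")
        temps, moto = [], []
        for p in profiles:
            for iv in p.milled_intervals:
                d = acid_fractionation_adjust(iv.d18o, iv.instrument)
                temps.append(float(invert_fixed_sw(d, params.seawater_d18o)))
                moto.append(float(estimate_moto(iv.d13c, ctx.dic_midpoint, ctx.diet_midpoint)))
        env = estimate_scope_envelope(temps, moto)
        centers = [b.center for b in env.bins]
        assert min(centers) <= env.optimal_temperature_c <= max(centers)
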