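"""Ricker residuals, correlations, model selection, FDR control."""

import itertools

import numpy as np
import pytest

from otolife import (
    StockRecruitSeries,
    bh_adjust,
    correlate_survival_with_anomaly,
    fit_ricker,
    gen_stock_recruit,
    lnrr,
    pearson_with_p,
    quadratic_term_selection,
)


def _series(ssb, log_rs):
    ssb = np.asarray(ssb, float)
    return StockRecruitSeries(
        years=np.arange(2000, 2000 + ssb.size),
        ssb=ssb,
        recruits=ssb * np.exp(np.asarray(log_rs, float)),
    )


class TestRicker:
    def test_exact_ricker_recovery(self):
        s = np.linspace(0.5, 3.0, 10)
        series = _series(s, 1.2 - 0.4 * s)
        a, b = fit_ricker(series)
        assert a == pytest.approx(1.2, abs=1e-10)
        assert b == pytest.approx(-0.4, abs=1e-10)
        assert np.allclose(lnrr(series), 0.0, atol=1e-12)

    def test_hand_ols_three_points(self):
        series = _series([1.0, 2.0, 3.0], [1.0, 0.5, 0.3])
        a, b = fit_ricker(series)
        assert a == pytest.approx(1.3)
        assert b == pytest.approx(-0.35)
        assert np.allclose(lnrr(series), [0.05, -0.10, 0.05], atol=1e-12)

    def test_constant_ssb_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            fit_ricker(_series([2.0, 2.0, 2.0], [0.1, 0.2, 0.3]))

    def test_residuals_always_sum_to_zero(self):
        rng = np.random.default_rng(8)
        series = _series(rng.uniform(0.5, 4, 50), rng.normal(0, 1, 50))
        values = lnrr(series)
        assert abs(values.sum()) < 1e-9 * values.size

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            StockRecruitSeries(np.arange(3), np.array([1.0, -1.0, 2.0]), np.ones(3))

    def test_parameter_recovery_within_three_se(self):
        """The OLS fit recovers the generative (a, b) on a noisy series."""
        series, _ = gen_stock_recruit(a=0.8, b=-0.6, temp_effect=0.0, sigma=0.3,
                                      n_years=100, seed=12)
        a, b = fit_ricker(series)
        s = series.ssb
        resid = lnrr(series)
        sigma2 = resid @ resid / (s.size - 2)
        sxx = np.sum((s - s.mean()) ** 2)
        se_b = np.sqrt(sigma2 / sxx)
        se_a = np.sqrt(sigma2 * (1 / s.size + s.mean() ** 2 / sxx))
        assert abs(a - 0.8) < 3 * se_a
        assert abs(b + 0.6) < 3 * se_b


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonal_zero_correlation(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=(2, 10))
        r, p = pearson_with_p(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = xc @ yc / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_direct, abs=1e-12)
        from scipy import stats

        t = r_direct * np.sqrt(8 / (1 - r_direct**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _bh_bruteforce(pvals, alpha=0.05):
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestBenjaminiHochberg:
    def test_hand_case(self):
        reject, _ = bh_adjust([0.01, 0.02, 0.04, 0.5])
        assert reject.tolist() == [True, True, False, False]

    def test_all_ones_rejects_none(self):
        reject, p_adj = bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.allclose(p_adj, 1.0)

    def test_single_small_p_rejected(self):
        reject, _ = bh_adjust([0.01])
        assert reject.tolist() == [True]

    def test_matches_bruteforce_on_subsets(self):
        """Step-up agrees with an exhaustive oracle on subsets of 6 p-values."""
        rng = np.random.default_rng(13)
        pool = rng.uniform(0, 1, 6)
        for size in range(1, 7):
            for subset in itertools.combinations(pool, size):
                reject, _ = bh_adjust(list(subset))
                assert reject.tolist() == _bh_bruteforce(np.array(subset)).tolist()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestQuadraticTermSelection:
    def test_exact_linear_breaks_tie_to_linear(self):
        t = np.linspace(10, 20, 12)
        choice = quadratic_term_selection(3.0 * t + 1.0, t)
        assert choice.chosen == "linear"

    def test_exact_dome_chooses_quadratic(self):
        t = np.linspace(10, 22, 15)
        y = -((t - 16.0) ** 2) + 40.0
        choice = quadratic_term_selection(y, t)
        assert choice.chosen == "quadratic"
        assert choice.coefficients["temp2"] < 0

    def test_matches_direct_aic_oracle(self):
        rng = np.random.default_rng(14)
        t = rng.uniform(10, 22, 40)
        y = -0.8 * (t - 16.0) ** 2 + 50 + rng.normal(0, 2, 40)
        choice = quadratic_term_selection(y, t)
        n = t.size
        for model, X in {
            "null": np.ones((n, 1)),
            "linear": np.column_stack([np.ones(n), t]),
            "quadratic": np.column_stack([np.ones(n), t, t**2]),
        }.items():
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            rss = float(np.sum((y - X @ beta) ** 2))
            assert choice.aic[model] == pytest.approx(
                n * np.log(rss / n) + 2 * (X.shape[1] + 1), abs=1e-9
            )
        assert choice.chosen == min(choice.aic, key=choice.aic.get)

    def test_choice_invariant_to_affine_temperature_rescaling(self):
        rng = np.random.default_rng(15)
        t = rng.uniform(10, 22, 30)
        y = -0.5 * (t - 15.0) ** 2 + 30 + rng.normal(0, 1, 30)
        c1 = quadratic_term_selection(y, t)
        c2 = quadratic_term_selection(y, 1.8 * t + 32.0)
        assert c1.chosen == c2.chosen

    def test_degenerate_design(self):
        with pytest.raises(ValueError):
            quadratic_term_selection(np.arange(6.0), np.full(6, 15.0))


class TestSurvivalAnomalyCorrelation:
    def test_noise_free_no_signal_degenerate(self):
        series, x = gen_stock_recruit(a=0.5, b=-0.5, temp_effect=0.0, sigma=0.0,
                                      n_years=30, seed=1)
        with pytest.raises(ValueError, match="variance"):
            correlate_survival_with_anomaly(series, series.years, x)

    def test_noise_free_signal_perfect_correlation(self):
        series, x = gen_stock_recruit(a=0.5, b=-0.5, temp_effect=0.5, sigma=0.0,
                                      n_years=30, seed=2)
        r, _ = correlate_survival_with_anomaly(series, series.years, x)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_matches_generative_closed_form(self):
        """r ≈ β·SD(x)/sqrt(β²·SD(x)² + σ²) with standardized anomalies."""
        series, x = gen_stock_recruit(a=0.5, b=-0.5, temp_effect=0.5, sigma=0.3,
                                      n_years=200, seed=3)
        r, p = correlate_survival_with_anomaly(series, series.years, x)
        expected = 0.5 / np.hypot(0.5, 0.3)
        assert r == pytest.approx(expected, abs=0.1)
        assert p < 1e-6

    def test_requires_overlap(self):
        series, x = gen_stock_recruit(a=0.5, b=-0.5, temp_effect=0.5, sigma=0.1,
                                      n_years=10, seed=4)
        with pytest.raises(ValueError, match="overlap"):
            correlate_survival_with_anomaly(series, series.years + 100, x)
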