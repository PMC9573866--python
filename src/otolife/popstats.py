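"""Population-level statistics: survival index and temperature-growth tests.

The early-life survival index is the log recruitment residual (LNRR)
from a Ricker stock-recruitment model,

    LNRR_t = ln(R_t / S_t) − (a + b·S_t),

where (a, b) are OLS coefficients of ln(R_t/S_t) on spawning stock
biomass S_t.  LNRR measures year-class survival after removing the
density-dependent expectation, and is correlated here against habitat
temperature anomalies.

Temperature-growth relationships use Pearson correlation with exact
t-based two-sided p-values, AIC-based selection between null, linear and
quadratic-in-temperature models (to capture dome-shaped responses), and
Benjamini-Hochberg false-discovery-rate control across test families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StockRecruitSeries",
    "RegressionChoice",
    "fit_ricker",
    "lnrr",
    "pearson_with_p",
    "bh_adjust",
    "quadratic_term_selection",
    "correlate_survival_with_anomaly",
]


@dataclass
class StockRecruitSeries:
    """Yearly spawning stock biomass and recruitment, with Ricker fit state."""

    years: np.ndarray
    ssb: np.ndarray  # S_t, spawning stock biomass
    recruits: np.ndarray  # R_t
    a: float | None = None
    b: float | None = None
    lnrr_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        self.ssb = np.asarray(self.ssb, dtype=float)
        self.recruits = np.asarray(self.recruits, dtype=float)
        if not (self.years.size == self.ssb.size == self.recruits.size):
            raise ValueError("years, ssb and recruits must align")
        if np.any(self.ssb <= 0) or np.any(self.recruits <= 0):
            raise ValueError("SSB and recruitment must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "ssb": self.ssb, "recruits": self.recruits})
        if self.lnrr_values is not None:
            df["lnrr"] = self.lnrr_values
        return df


def fit_ricker(series: StockRecruitSeries) -> tuple[float, float]:
    """OLS fit of ln(R_t/S_t) on S_t, returning the Ricker (a, b)."""
    if series.years.size < 3:
        raise ValueError("need >= 3 years")
    s = series.ssb
    y = np.log(series.recruits / s)
    if np.ptp(s) == 0:
        raise ValueError("SSB has zero variance; Ricker slope undefined")
    b, a = np.polyfit(s, y, 1)
    series.a, series.b = float(a), float(b)
    return float(a), float(b)


def lnrr(series: StockRecruitSeries, a: float | None = None, b: float | None = None) -> np.ndarray:
    """Log recruitment residuals per year.

    Uses the series' fitted (a, b), fitting first if absent; explicit
    coefficients override.  With the internal OLS fit the residuals sum
    to zero (normal equations).
    """
    if a is None or b is None:
        if series.a is None or series.b is None:
            fit_ricker(series)
        a, b = series.a, series.b
    values = np.log(series.recruits / series.ssb) - (a + b * series.ssb)
    series.lnrr_values = values
    return values


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with the exact two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)`` aligned with the input order:
    hypotheses 1..k* in the sorted order are rejected where k* is the
    largest k with p(k) <= k·alpha/m; adjusted p-values by the monotone
    step-up cumulative minimum.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


@dataclass
class RegressionChoice:
    """AIC-based choice among null / linear / quadratic temperature models."""

    aic: dict[str, float]
    chosen: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n: int


def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Gaussian OLS AIC with profiled variance: n·ln(RSS/n) + 2·(k+1)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    aic = n * np.log(rss / n) + 2 * (k + 1) if rss > 0 else -np.inf
    # two-sided t p-values for coefficients
    dof = n - k
    if dof > 0 and rss > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    elif rss == 0 and dof > 0:
        pvals = np.zeros(k)  # exact fit
    else:
        pvals = np.full(k, np.nan)
    return aic, beta, pvals


def quadratic_term_selection(lengths, temps) -> RegressionChoice:
    """Select null vs linear vs quadratic temperature model by AIC.

    Fits length ~ 1, length ~ T and length ~ T + T² by OLS and keeps the
    minimal-AIC model; an AIC tie breaks toward the model with fewer
    parameters.  The quadratic captures dome-shaped temperature-growth
    responses.
    """
    y = np.asarray(lengths, dtype=float)
    t = np.asarray(temps, dtype=float)
    if y.size != t.size or y.size < 5:
        raise ValueError("need aligned samples with n >= 5")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all temperatures equal")
    n = y.size
    ones = np.ones(n)
    designs = {
        "null": np.column_stack([ones]),
        "linear": np.column_stack([ones, t]),
        "quadratic": np.column_stack([ones, t, t**2]),
    }
    names = {
        "null": ["intercept"],
        "linear": ["intercept", "temp"],
        "quadratic": ["intercept", "temp", "temp2"],
    }
    aics: dict[str, float] = {}
    fits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for model, X in designs.items():
        aic, beta, pvals = _ols_aic(X, y)
        aics[model] = float(aic)
        fits[model] = (beta, pvals)
    # minimise AIC; near-ties (<=1e-9) go to the smaller model, in the
    # null < linear < quadratic order of increasing complexity
    order = ["null", "linear", "quadratic"]
    best = min(order, key=lambda m: (round(aics[m] / 1e-9) * 1e-9, order.index(m)))
    beta, pvals = fits[best]
    return RegressionChoice(
        aic=aics,
        chosen=best,
        coefficients=dict(zip(names[best], beta.tolist())),
        p_values=dict(zip(names[best], pvals.tolist())),
        n=n,
    )


def correlate_survival_with_anomaly(
    series: StockRecruitSeries,
    anomaly_years,
    anomaly_values,
) -> tuple[float, float]:
    """Pearson r (with p) between LNRR and a yearly anomaly series.

    Aligns the stock-recruit series and the anomaly on common years,
    computes LNRR internally from the series' own Ricker fit, and
    delegates to :func:`pearson_with_p`.
    """
    anomaly_years = np.asarray(anomaly_years)
    anomaly_values = np.asarray(anomaly_values, dtype=float)
    residuals = lnrr(series)
    scale = max(float(np.std(np.log(series.recruits / series.ssb))), 1.0)
    if float(np.std(residuals)) <= 1e-9 * scale:
        raise ValueError("LNRR has (numerically) zero variance; correlation undefined")
    common, idx_s, idx_a = np.intersect1d(series.years, anomaly_years, return_indices=True)
    if common.size < 3:
        raise ValueError(f"only {common.size} overlapping years (need >= 3)")
    return pearson_with_p(residuals[idx_s], anomaly_values[idx_a])
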