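"""Aerobic-scope envelope and metabolically optimal temperature.

The spread of the metabolic proxy M_oto across temperature carries a
physiological signal: the highest field metabolic rates are constrained
by the maximum metabolic rate (parabolic in temperature) and the lowest
sit near the standard metabolic rate (exponential in temperature).  The
gap between the two is an analogue of aerobic scope, and the temperature
maximising it is the metabolically optimal temperature.

Procedure: pool (temperature, M_oto) pairs, group into 1 °C bins
(dropping bins with fewer than four members), take the 95th and 5th
percentile of M_oto per bin, fit a quadratic to the 95th percentiles and
a Gaussian GLM with log link to the 5th percentiles, and locate the
argmax of the fitted gap on a 0.1 °C grid over the occupied range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TempBin",
    "ScopeEnvelope",
    "bin_by_temperature",
    "fit_upper_envelope",
    "fit_lower_envelope",
    "optimal_temperature",
    "estimate_scope_envelope",
]


@dataclass
class TempBin:
    """One occupied 1 °C temperature bin of (T, M_oto) pairs."""

    lower: float  # bin is [lower, lower + width)
    width: float
    temps: np.ndarray
    moto: np.ndarray

    @property
    def center(self) -> float:
        return self.lower + 0.5 * self.width

    @property
    def n(self) -> int:
        return self.moto.size

    @property
    def p95(self) -> float:
        return float(np.percentile(self.moto, 95))

    @property
    def p5(self) -> float:
        return float(np.percentile(self.moto, 5))


@dataclass
class ScopeEnvelope:
    """Fitted upper/lower M_oto envelopes and the derived optimum."""

    upper_coefficients: tuple[float, float, float]  # quadratic in T (a, b, c)
    lower_coefficients: tuple[float, float]  # (eta0, eta1): mean = exp(eta0 + eta1·T)
    temperature_grid: np.ndarray  # 0.1 °C grid over the occupied-bin range
    gap_curve: np.ndarray
    optimal_temperature_c: float
    bins: list[TempBin] = field(default_factory=list)
    nonpositive_gap: bool = False  # warning flag: gap <= 0 everywhere

    def upper(self, t):
        a, b, c = self.upper_coefficients
        return a * np.asarray(t) ** 2 + b * np.asarray(t) + c

    def lower(self, t):
        e0, e1 = self.lower_coefficients
        return np.exp(e0 + e1 * np.asarray(t))


def bin_by_temperature(
    temps,
    moto,
    width: float = 1.0,
    min_n: int = 4,
) -> list[TempBin]:
    """Group (T, M_oto) pairs into temperature bins, dropping sparse bins.

    Bins are half-open intervals [k·width, (k+1)·width) anchored at
    integer multiples of the width; bins with fewer than ``min_n``
    members are excluded to avoid under-sampled percentiles.  Raises if
    fewer than three bins survive (the envelopes would be unfittable).
    """
    t = np.asarray(temps, dtype=float)
    m = np.asarray(moto, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("temps and moto must be equal-length 1-D sequences")
    keys = np.floor(t / width).astype(int)
    bins = []
    for k in np.unique(keys):
        sel = keys == k
        if sel.sum() < min_n:
            continue
        bins.append(TempBin(lower=k * width, width=width, temps=t[sel], moto=m[sel]))
    if len(bins) < 3:
        raise ValueError(
            f"only {len(bins)} bins with >= {min_n} members; envelope unfittable (need >= 3)"
        )
    return bins


def fit_upper_envelope(bins: list[TempBin], degree: int = 2) -> tuple[float, ...]:
    """Least-squares polynomial (default quadratic) of per-bin 95th percentiles.

    Returns coefficients highest power first, padded to the requested
    degree.
    """
    if len(bins) < degree + 1:
        raise ValueError(f"need >= {degree + 1} bins for a degree-{degree} fit, got {len(bins)}")
    x = np.array([b.center for b in bins])
    y = np.array([b.p95 for b in bins])
    return tuple(float(c) for c in np.polyfit(x, y, degree))


def fit_lower_envelope(bins: list[TempBin], max_iter: int = 100, tol: float = 1e-8) -> tuple[float, float]:
    """Gaussian GLM with log link for the per-bin 5th percentiles.

    Fits mean = exp(η0 + η1·T) to the p5 values by iteratively
    reweighted least squares; requires all p5 values positive (the log
    link has no natural home for non-positive means — inspect the data
    rather than shifting it silently).
    """
    if len(bins) < 2:
        raise ValueError("need >= 2 bins for the lower envelope")
    x = np.array([b.center for b in bins])
    y = np.array([b.p5 for b in bins])
    if np.any(y <= 0):
        bad = x[y <= 0].tolist()
        raise ValueError(
            f"non-positive 5th-percentile M_oto at bin centers {bad}; "
            "inspect the data before fitting a log-link envelope"
        )
    X = np.column_stack([np.ones_like(x), x])
    beta = np.polyfit(x, np.log(y), 1)[::-1]  # log-linear start
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        # working response and weights for the log link (dμ/dη = μ)
        z = eta + (y - mu) / mu
        w = mu**2
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, WX.T @ z)
        step = float(np.max(np.abs(new - beta)))
        beta = new
        if step < tol:
            return float(beta[0]), float(beta[1])
    raise RuntimeError(f"lower-envelope IRLS did not converge in {max_iter} iterations")


def optimal_temperature(
    upper_coefficients: tuple[float, ...],
    lower_coefficients: tuple[float, float],
    temp_range: tuple[float, float],
    grid_step: float = 0.1,
) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Argmax of the envelope gap on a regular temperature grid.

    Returns ``(t_opt, grid, gap_curve, nonpositive_flag)``.  The gap is
    evaluated only within ``temp_range`` (the occupied-bin range); ties
    break toward the lowest temperature; a gap nowhere positive sets the
    warning flag instead of raising.
    """
    lo, hi = temp_range
    if hi < lo:
        raise ValueError("temp_range reversed")
    n = int(round((hi - lo) / grid_step)) + 1
    grid = lo + grid_step * np.arange(n)
    upper = np.polyval(upper_coefficients, grid)
    e0, e1 = lower_coefficients
    gap = upper - np.exp(e0 + e1 * grid)
    idx = int(np.argmax(gap))  # np.argmax returns the first (lowest-T) maximiser
    flag = bool(np.all(gap <= 0))
    if flag:
        warnings.warn("envelope gap is nowhere positive over the occupied range", stacklevel=2)
    return float(grid[idx]), grid, gap, flag


def estimate_scope_envelope(
    temps,
    moto,
    bin_width: float = 1.0,
    min_n: int = 4,
    grid_step: float = 0.1,
) -> ScopeEnvelope:
    """Full envelope estimate: bin, fit both envelopes, maximise the gap."""
    bins = bin_by_temperature(temps, moto, width=bin_width, min_n=min_n)
    upper = fit_upper_envelope(bins)
    lower = fit_lower_envelope(bins)
    centers = [b.center for b in bins]
    t_opt, grid, gap, flag = optimal_temperature(upper, lower, (min(centers), max(centers)), grid_step)
    return ScopeEnvelope(
        upper_coefficients=upper,
        lower_coefficients=lower,
        temperature_grid=grid,
        gap_curve=gap,
        optimal_temperature_c=t_opt,
        bins=bins,
        nonpositive_gap=flag,
    )
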