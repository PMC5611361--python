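"""Standardized major axis (SMA) line fitting and slope hypothesis tests.

The bivariate power law y = gamma * x^beta is linearized to
Y = alpha + beta * X on log10 scale; SMA estimates beta as
sign(r) * sd(Y)/sd(X), which treats the axes symmetrically.  Isometry is the
hypothesis beta = 1 (or -1 for inverse relationships).

The slope test exploits the identity that beta equals b0 exactly when the
residual axis (Y - b0*X) and the fitted axis (Y + b0*X) are uncorrelated, so
testing slope = b0 reduces to a correlation t-test between those two scores.
The common-slope test minimizes the summed log-likelihood-ratio statistic
-sum(n_i * ln(1 - r_i(b)^2)) over candidate slopes b and refers the minimum
to a chi-square with (k - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SMAFit",
    "log10_prepare",
    "sma_fit",
    "sma_slope_test",
    "common_slope_test",
    "fit_pairs",
]


@dataclass(frozen=True)
class SMAFit:
    """SMA estimates for one log-log trait pair."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    ci_low: float
    ci_high: float
    p_slope_vs_b0: float
    b0: float
    degenerate: bool = False  # |r| = 1: zero-width CI, test undefined

    def __post_init__(self):
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("slope outside its own confidence interval")


def log10_prepare(
    table: pd.DataFrame, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Elementwise log10 of selected trait columns.

    Raises a descriptive error naming species (index) and trait for any
    non-positive value; NA values pass through for pairwise deletion
    downstream.
    """
    cols = list(traits) if traits is not None else list(table.columns)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"traits not in table: {missing}")
    sub = table[cols].astype(float)
    bad = (sub <= 0) & sub.notna()
    if bad.any().any():
        rows, colids = np.nonzero(bad.values)
        where = [f"{sub.index[r]}/{cols[c]}" for r, c in zip(rows, colids)]
        raise ValueError(
            f"non-positive values cannot be log10-transformed: {where[:10]}"
        )
    return np.log10(sub)


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def sma_fit(x, y, b0: float = 1.0) -> SMAFit:
    """Fit an SMA line and test the slope against ``b0``.

    slope = sign(cov) * sd(y)/sd(x); the 95% CI follows the standard SMA
    construction slope * (sqrt(B + 1) +/- sqrt(B)) with
    B = F(0.95; 1, n-2) * (1 - r^2) / (n - 2).
    """
    x, y = _clean_pair(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y: SMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    r2 = r * r

    degenerate = bool(np.isclose(r2, 1.0, atol=1e-12))
    if degenerate:
        ci_low = ci_high = slope
        p = 1.0 if np.isclose(slope, b0) else 0.0
    else:
        B = stats.f.ppf(0.95, 1, n - 2) * (1.0 - r2) / (n - 2)
        lo, hi = slope * (np.sqrt(B + 1.0) - np.sqrt(B)), slope * (
            np.sqrt(B + 1.0) + np.sqrt(B)
        )
        ci_low, ci_high = (lo, hi) if lo <= hi else (hi, lo)
        p = sma_slope_test(x, y, b0)
    return SMAFit(
        n=n,
        slope=float(slope),
        intercept=intercept,
        r_squared=float(r2),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_slope_vs_b0=float(p),
        b0=float(b0),
        degenerate=degenerate,
    )


def _residual_fitted_correlation(x, y, b0: float) -> float:
    res = y - b0 * x
    fit = y + b0 * x
    sr, sf = np.std(res, ddof=1), np.std(fit, ddof=1)
    if sr == 0 or sf == 0:
        return 0.0
    return float(np.corrcoef(res, fit)[0, 1])


def sma_slope_test(x, y, b0: float) -> float:
    """Two-sided p-value for H0: SMA slope == b0."""
    if b0 == 0:
        raise ValueError("b0 must be nonzero")
    x, y = _clean_pair(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    r_res = _residual_fitted_correlation(x, y, b0)
    if abs(r_res) >= 1.0:
        return 0.0
    t = r_res * np.sqrt((n - 2) / (1.0 - r_res * r_res))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def common_slope_test(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> tuple[float, float]:
    """Estimate a common SMA slope across groups and test slope heterogeneity.

    Returns (b_common, p_heterogeneity).  All groups must share the sign of
    their x-y correlation; the common slope is searched on that sign within
    a bracket spanning the per-group SMA slopes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cleaned = []
    slopes = []
    signs = set()
    for gx, gy in groups:
        x, y = _clean_pair(gx, gy)
        if x.size < 3:
            raise ValueError("every group needs at least 3 complete pairs")
        fit = sma_fit(x, y)
        cleaned.append((x, y))
        slopes.append(fit.slope)
        signs.add(np.sign(fit.slope))
    if len(signs) > 1:
        raise ValueError(
            "groups have mixed correlation signs; analyze positive and "
            "negative relationships separately"
        )
    sign = signs.pop()

    def lr(b: float) -> float:
        total = 0.0
        for x, y in cleaned:
            r = _residual_fitted_correlation(x, y, b)
            r2 = min(r * r, 1.0 - 1e-15)
            total += -x.size * np.log1p(-r2)
        return total

    mags = np.abs(slopes)
    lo, hi = mags.min() / 3.0, mags.max() * 3.0
    if sign > 0:
        res = optimize.minimize_scalar(lr, bounds=(lo, hi), method="bounded")
    else:
        res = optimize.minimize_scalar(
            lambda b: lr(-b), bounds=(lo, hi), method="bounded"
        )
    b_common = float(sign * abs(res.x))
    stat = lr(b_common)
    df = len(cleaned) - 1
    p = float(stats.chi2.sf(stat, df))
    return b_common, p


def fit_pairs(
    log_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    b0_map: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """SMA fits for a list of (y, x) trait-code pairs of a log10 table.

    Returns a tidy frame shaped like a published slope table:
    Y, X, n, R2, slope, ci_low, ci_high, P (slope vs b0, default +1, or the
    value supplied per pair in ``b0_map``).
    """
    b0_map = b0_map or {}
    rows = []
    for yname, xname in pairs:
        b0 = b0_map.get((yname, xname), 1.0)
        sub = log_table[[xname, yname]].dropna()
        fit = sma_fit(sub[xname].values, sub[yname].values, b0=b0)
        rows.append(
            {
                "Y": yname,
                "X": xname,
                "n": fit.n,
                "R2": fit.r_squared,
                "slope": fit.slope,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "b0": b0,
                "P": fit.p_slope_vs_b0,
            }
        )
    return pd.DataFrame(rows)
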