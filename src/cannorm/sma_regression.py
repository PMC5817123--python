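"""Standardized major axis (SMA) line fitting and identity tests.

The SMA slope is sign(cov(x, y)) * SD(y) / SD(x); the line passes through the
bivariate mean.  Between-group identity tests follow the standard SMA testing
framework: a likelihood-ratio test for a common slope (the common slope is
estimated iteratively by minimizing the statistic) and, conditional on the
common slope, a Wald test for equal elevations (intercepts).  True major axis
(MA) fitting is also provided.

Pearson correlation tests use the closed-form t = r sqrt(n-2) / sqrt(1-r^2)
with df = n - 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SMAFit",
    "SMAComparison",
    "CorrelationResult",
    "sma_fit",
    "ma_fit",
    "pearson_test",
    "sma_common_slope_test",
    "sma_elevation_test",
]


@dataclass
class SMAFit:
    slope: float
    intercept: float
    n: int
    r: float
    group: str = ""


@dataclass
class SMAComparison:
    statistic: float
    df: int
    p_value: float
    kind: str  # "common_slope" (likelihood ratio) or "elevation" (Wald)
    common_slope: float | None = None


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p_value: float


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def sma_fit(x, y, group: str = "") -> SMAFit:
    """Standardized major axis fit: slope = sign(cov) * SD(y)/SD(x)."""
    x, y = _check_xy(x, y)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    cov = np.cov(x, y, ddof=1)[0, 1]
    r = cov / (sx * sy)
    slope = float(np.sign(cov) if cov != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAFit(slope=float(slope), intercept=intercept, n=len(x), r=float(r), group=group)


def ma_fit(x, y, group: str = "") -> SMAFit:
    """True major axis fit: the dominant eigenvector of the 2x2 covariance matrix."""
    x, y = _check_xy(x, y)
    cov = np.cov(x, y, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("major axis is vertical: slope undefined")
    slope = float(v[1] / v[0])
    intercept = float(np.mean(y) - slope * np.mean(x))
    r = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    return SMAFit(slope=slope, intercept=intercept, n=len(x), r=r, group=group)


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with its two-sided t-test (df = n - 2)."""
    x, y = _check_xy(x, y)
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, t=float(t), df=df, p_value=float(p))


# ---------------------------------------------------------------------------
# Between-group identity tests


def _group_stats(groups):
    out = []
    for gx, gy in groups:
        gx, gy = _check_xy(gx, gy)
        n = len(gx)
        out.append(
            dict(
                n=n,
                xbar=gx.mean(),
                ybar=gy.mean(),
                sxx=np.var(gx, ddof=1),
                syy=np.var(gy, ddof=1),
                sxy=np.cov(gx, gy, ddof=1)[0, 1],
            )
        )
    return out


def _slope_lr_statistic(b: float, gs) -> float:
    """-sum n_i ln(1 - corr^2(residual, fitted-axis)) at common SMA slope b.

    For SMA, residual and fitted-axis scores in group i are y - b x and
    y + b x; under a shared slope their correlation is zero in every group.
    """
    total = 0.0
    for g in gs:
        var_r = g["syy"] - 2 * b * g["sxy"] + b**2 * g["sxx"]
        var_f = g["syy"] + 2 * b * g["sxy"] + b**2 * g["sxx"]
        cov_rf = g["syy"] - b**2 * g["sxx"]
        r2 = cov_rf**2 / (var_r * var_f)
        r2 = min(r2, 1.0 - 1e-15)
        total += -g["n"] * np.log1p(-r2)
    return total


def _common_slope(gs, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Common SMA slope minimizing the likelihood-ratio statistic."""
    slopes = [np.sign(g["sxy"]) * np.sqrt(g["syy"] / g["sxx"]) for g in gs]
    lo = min(abs(s) for s in slopes) * 0.2
    hi = max(abs(s) for s in slopes) * 5.0
    sign = np.sign(np.sum([g["sxy"] for g in gs])) or 1.0
    res = optimize.minimize_scalar(
        lambda b: _slope_lr_statistic(sign * b, gs),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    return float(sign * res.x)


def sma_common_slope_test(groups) -> SMAComparison:
    """Likelihood-ratio test that all groups share one SMA slope.

    ``groups`` is a sequence of (x, y) pairs.  The statistic is compared to a
    chi-square with (#groups - 1) degrees of freedom.  It is exactly 0 when
    all groups contain identical data.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gs = _group_stats(groups)
    b = _common_slope(gs)
    stat = float(_slope_lr_statistic(b, gs))
    df = len(groups) - 1
    return SMAComparison(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        kind="common_slope",
        common_slope=b,
    )


def sma_elevation_test(groups, common_slope: float | None = None) -> SMAComparison:
    """Wald test of equal elevations given a common SMA slope.

    Elevation of group i is a_i = ybar_i - b xbar_i.  Its variance combines the
    residual variance of y - b x and the uncertainty of the common slope
    propagated through xbar_i.  The weighted dispersion of elevations around
    their precision-weighted mean is chi-square with (#groups - 1) df.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gs = _group_stats(groups)
    b = common_slope if common_slope is not None else _common_slope(gs)

    # per-group variance of the slope estimate (large-sample SMA form),
    # pooled into the common-slope variance
    var_b_inv = 0.0
    for g in gs:
        r2 = g["sxy"] ** 2 / (g["sxx"] * g["syy"])
        r2 = min(r2, 1.0 - 1e-15)
        var_bi = b**2 * (1.0 - r2) / (r2 * max(g["n"] - 2, 1)) if r2 > 0 else np.inf
        if np.isfinite(var_bi) and var_bi > 0:
            var_b_inv += 1.0 / var_bi
    var_b = 1.0 / var_b_inv if var_b_inv > 0 else 0.0

    # elevations share the common slope, so cov(a_i, a_j) = xbar_i xbar_j var(b)
    k = len(gs)
    elevations = np.array([g["ybar"] - b * g["xbar"] for g in gs])
    xbars = np.array([g["xbar"] for g in gs])
    resid = np.array([(g["syy"] - 2 * b * g["sxy"] + b**2 * g["sxx"]) / g["n"] for g in gs])
    cov_a = np.diag(resid) + var_b * np.outer(xbars, xbars)
    contrast = np.hstack([np.ones((k - 1, 1)), -np.eye(k - 1)])  # a_1 - a_i
    diffs = contrast @ elevations
    stat = float(diffs @ np.linalg.solve(contrast @ cov_a @ contrast.T, diffs))
    df = len(groups) - 1
    return SMAComparison(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        kind="elevation",
        common_slope=b,
    )
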