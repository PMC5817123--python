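"""AIC model selection for cannibal growth responses.

Two analysis stages are covered:

* Nonlinear curve selection for cannibal size/shape score means against the
  per-population victim count x2: an asymptotic form a + b(1 - exp(-c x2))
  versus a non-asymptotic power form a + b x2^c.
* Six competing exploitation/interference linear models for the largest
  cannibal in each population, built from the census counts x1 (cannibals)
  and x2 (victims):

  1. egalitarian exploitation,      X1 = x2 / x1
  2. semi-exclusive exploitation,   X2 = x2 - x1        (each rival eats 1)
  3. fully exclusive exploitation,  X3 = x2             (rivals eat ~0)
  4. interference,                  x1
  5. interference + exploitation,   x1 + x2
  6. + interaction,                 x1 + x2 + x1*x2

All models are compared by AIC with the full Gaussian log-likelihood
constant: AIC = n ln(2 pi RSS / n) + n + 2 (k + 1), where k counts
mean-structure coefficients (the residual variance contributes the +1).
Delta-AIC and Akaike weights are invariant to that constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ModelFitResult",
    "ModelComparisonTable",
    "gaussian_aic",
    "akaike_weights",
    "fit_nonlinear",
    "compare_nonlinear",
    "build_exploitation_design",
    "fit_linear_model",
    "compare_models",
    "select_largest_cannibal_models",
    "EXPLOITATION_MODEL_NAMES",
]

EXPLOITATION_MODEL_NAMES = {
    1: "X1 = x2/x1 (egalitarian exploitation)",
    2: "X2 = x2 - x1 (semi-exclusive exploitation)",
    3: "X3 = x2 (exclusive exploitation)",
    4: "x1 (interference)",
    5: "x1 + x2 (interference + exploitation)",
    6: "x1 + x2 + x1*x2 (interference x exploitation)",
}


@dataclass
class ModelFitResult:
    model: str
    coefficients: np.ndarray
    k: int  # mean-structure parameter count as reported in comparison tables
    rss: float
    n: int
    aic: float
    delta_aic: float = np.nan
    w_aic: float = np.nan


@dataclass
class ModelComparisonTable:
    fits: list[ModelFitResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(model=f.model, k=f.k, AIC=f.aic, dAIC=f.delta_aic, wAIC=f.w_aic, RSS=f.rss)
                for f in self.fits
            ]
        )

    @property
    def best(self) -> ModelFitResult:
        return min(self.fits, key=lambda f: (f.aic, f.rss, f.k))


def gaussian_aic(rss: float, n: int, k: int, scale: float = 1.0) -> float:
    """AIC of a Gaussian least-squares fit with k mean parameters.

    ``scale`` sets a numerical floor on RSS (n * (1e-9 * scale)^2): residuals
    at roundoff level are treated as exact fits so that model ranking among
    interpolating models falls back to the parameter-count penalty instead of
    the accidental ordering of floating-point residues.
    """
    floor = n * (1e-9 * max(scale, 1e-12)) ** 2
    rss = max(rss, floor)
    return float(n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1))


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _annotate(fits: list[ModelFitResult]) -> ModelComparisonTable:
    w = akaike_weights([f.aic for f in fits])
    best = min(f.aic for f in fits)
    for f, wi in zip(fits, w):
        f.delta_aic = f.aic - best
        f.w_aic = float(wi)
    return ModelComparisonTable(fits=fits)


# ---------------------------------------------------------------------------
# Nonlinear growth curves


def _curve(form: str):
    if form == "asymptotic":
        return lambda p, x: p[0] + p[1] * (1.0 - np.exp(-p[2] * x))
    if form == "power":
        # 0^c defined as 0 for c > 0
        return lambda p, x: p[0] + p[1] * np.where(x > 0, x, 1.0) ** p[2] * (x > 0)
    raise ValueError(f"unknown form {form!r}")


def fit_nonlinear(x2, response, form: str) -> ModelFitResult:
    """Least-squares fit of an asymptotic or power curve by multi-start
    bounded optimization over the rate/exponent parameter c."""
    x = np.asarray(x2, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need matched x2/response with at least 4 points")
    if np.any(x < 0):
        raise ValueError("x2 must be non-negative")
    f = _curve(form)

    def resid(p):
        return f(p, x) - y

    slope0 = np.polyfit(x, y, 1)[0]
    best = None
    for c0 in np.linspace(0.01, 5.0, 25):
        p0 = np.array([y[np.argmin(x)], np.sign(slope0) * (np.ptp(y) or 1.0), c0])
        try:
            sol = least_squares(
                resid, p0,
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 50.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"nonlinear fit ({form}) failed from all starts")
    rss = float(2.0 * best.cost)
    n = len(x)
    k = 3
    return ModelFitResult(
        model=form, coefficients=best.x, k=k, rss=rss, n=n,
        aic=gaussian_aic(rss, n, k, scale=float(np.abs(y).max())),
    )


def compare_nonlinear(x2, response) -> ModelComparisonTable:
    """Fit the asymptotic and power curves and compare them by AIC."""
    fits = [fit_nonlinear(x2, response, form) for form in ("asymptotic", "power")]
    return _annotate(fits)


# ---------------------------------------------------------------------------
# Exploitation / interference linear models


def build_exploitation_design(x1, x2, model_id: int) -> np.ndarray:
    """Covariate columns (without intercept) for exploitation/interference model 1-6."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must align")
    if model_id == 1:
        if np.any(x1 <= 0):
            raise ValueError("Model 1 requires x1 > 0 in every population")
        return (x2 / x1)[:, None]
    if model_id == 2:
        return (x2 - x1)[:, None]
    if model_id == 3:
        return x2[:, None]
    if model_id == 4:
        return x1[:, None]
    if model_id == 5:
        return np.column_stack([x1, x2])
    if model_id == 6:
        return np.column_stack([x1, x2, x1 * x2])
    raise ValueError(f"unknown model id {model_id}")


def fit_linear_model(design: np.ndarray, response, model: str = "") -> ModelFitResult:
    """OLS fit of response on [1, design]; k counts intercept + slopes."""
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(response, dtype=float)
    n = len(y)
    xmat = np.column_stack([np.ones(n), x])
    k = xmat.shape[1]
    if n <= k:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(xmat) < k:
        raise ValueError("rank-deficient design")
    coef, _, _, _ = np.linalg.lstsq(xmat, y, rcond=None)
    rss = float(((y - xmat @ coef) ** 2).sum())
    return ModelFitResult(
        model=model, coefficients=coef, k=k, rss=rss, n=n,
        aic=gaussian_aic(rss, n, k, scale=float(np.abs(y).max())),
    )


def compare_models(fits) -> ModelComparisonTable:
    """Attach delta-AIC and Akaike weights to a collection of fits."""
    return _annotate(list(fits))


def select_largest_cannibal_models(x1, x2, response) -> ModelComparisonTable:
    """Fit exploitation/interference Models 1-6 to one response value per tank
    (a largest-cannibal size or shape score) and compare them by AIC."""
    x1 = np.asarray(x1, dtype=float)
    if len(x1) < 6:
        raise ValueError("need at least 6 tanks")
    fits = []
    for mid in range(1, 7):
        try:
            design = build_exploitation_design(x1, x2, mid)
            fit = fit_linear_model(design, response, model=EXPLOITATION_MODEL_NAMES[mid])
        except ValueError as exc:
            # e.g. constant cannibal counts make a design rank-deficient;
            # that model is not identifiable for this census and is dropped
            warnings.warn(f"model {mid} skipped: {exc}")
            continue
        fits.append(fit)
    if len(fits) < 2:
        raise ValueError("fewer than 2 identifiable models; nothing to compare")
    return _annotate(fits)
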