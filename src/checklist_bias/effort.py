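"""Shifted power-function effort model y = coef * x**exp - 1.

The curve links survey duration x (minutes) to the relative bias y of a
checklist's richness against its site reference.  The "- 1" shift anchors
the curve so y = 0 means parity with the reference: completeness, the
percentage of the reference richness captured, is 100 * (1 + y) =
100 * coef * x**exp.

Fitting is plain nonlinear least squares (Levenberg-Marquardt with the
analytic Jacobian); parameter standard errors come from
residual_se**2 * (J'J)^-1 at the optimum, t statistics are estimate/SE and
p values are two-sided from the t distribution on n - 2 degrees of
freedom.  Uncertainty bands for the fitted curve are built three ways:
Monte-Carlo parameter simulation (the primary output) and first-/
second-order Taylor (delta-method) propagation for parity with error-
propagation software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerFitResult",
    "CurveBand",
    "fit_power",
    "predict_bias",
    "completeness_percent",
    "mc_confidence_band",
    "taylor_confidence_band",
    "crossing_duration",
]


@dataclass(frozen=True)
class PowerFitResult:
    """Least-squares fit of y = coef * x**exp - 1 with uncertainty."""

    coef: float
    exp: float
    se_coef: float
    se_exp: float
    t_coef: float
    t_exp: float
    p_coef: float
    p_exp: float
    residual_se: float
    dof: int
    covariance: np.ndarray
    converged: bool
    n_points: int

    @classmethod
    def from_params(cls, coef: float, exp: float) -> "PowerFitResult":
        """Wrap known parameters (e.g. published estimates) with no uncertainty."""
        return cls(
            coef=float(coef),
            exp=float(exp),
            se_coef=math.nan,
            se_exp=math.nan,
            t_coef=math.nan,
            t_exp=math.nan,
            p_coef=math.nan,
            p_exp=math.nan,
            residual_se=math.nan,
            dof=0,
            covariance=np.zeros((2, 2)),
            converged=True,
            n_points=0,
        )


@dataclass(frozen=True)
class CurveBand:
    """Pointwise 95% confidence band for the fitted curve on a duration grid."""

    x: np.ndarray
    fitted: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_sims: int
    seed: Optional[int]
    method: str = "monte_carlo"


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    coef, exp = params
    return coef * np.power(x, exp) - 1.0


def _jacobian(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    coef, exp = params
    xe = np.power(x, exp)
    return np.column_stack([xe, coef * xe * np.log(x)])


def _initial_guess(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log(y+1) = log(coef) + exp*log(x) is exact for noiseless data
    mask = (y + 1.0) > 0
    if mask.sum() >= 3:
        lx, ly = np.log(x[mask]), np.log(y[mask] + 1.0)
        slope, intercept = np.polyfit(lx, ly, 1)
        coef0 = math.exp(intercept)
        if np.isfinite(coef0) and coef0 > 0:
            return np.array([coef0, slope])
    return np.array([0.2, 0.3])


def fit_power(
    x_durations,
    y_biases,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PowerFitResult:
    """Fit y = coef * x**exp - 1 to (duration, bias) points by least squares.

    Requires at least 3 points and strictly positive durations.  Failure to
    converge is flagged on the result, never silently dropped.
    """
    x = np.asarray(x_durations, dtype=float)
    y = np.asarray(y_biases, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points to fit 2 parameters, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("durations must be strictly positive")

    p0 = _initial_guess(x, y)
    res = optimize.least_squares(
        lambda p: _model(p, x) - y,
        p0,
        jac=lambda p: _jacobian(p, x),
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 2,
    )
    coef, exp = res.x
    n = x.size
    dof = n - 2
    rss = float(np.sum(res.fun**2))
    residual_se = math.sqrt(rss / dof) if dof > 0 else math.nan

    jac = _jacobian(res.x, x)
    jtj = jac.T @ jac
    try:
        cov = residual_se**2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = res.x / se
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), dof) if dof > 0 else np.array([np.nan, np.nan])

    return PowerFitResult(
        coef=float(coef),
        exp=float(exp),
        se_coef=float(se[0]),
        se_exp=float(se[1]),
        t_coef=float(t_vals[0]),
        t_exp=float(t_vals[1]),
        p_coef=float(p_vals[0]),
        p_exp=float(p_vals[1]),
        residual_se=residual_se,
        dof=dof,
        covariance=cov,
        converged=bool(res.success),
        n_points=n,
    )


def predict_bias(fit: PowerFitResult, x: float) -> float:
    """Bias predicted by the fitted curve at duration x: coef*x**exp - 1."""
    if np.any(np.asarray(x) <= 0):
        raise ValueError("duration must be strictly positive")
    return fit.coef * np.power(x, fit.exp) - 1.0


def completeness_percent(fit: PowerFitResult, x: float) -> float:
    """Completeness at duration x as a percentage: 100*(1 + bias) = 100*coef*x**exp."""
    return 100.0 * (1.0 + predict_bias(fit, x))


def _positive_semidefinite(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if np.all(vals >= 0):
        return cov
    warnings.warn("covariance not positive semidefinite; clipping negative eigenvalues at 0")
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def mc_confidence_band(
    fit: PowerFitResult,
    x_grid,
    n_sims: int = 10_000,
    seed: Optional[int] = None,
) -> CurveBand:
    """95% pointwise band by simulating parameters from the fit covariance.

    Draws ``n_sims`` (coef, exp) pairs from the bivariate normal centred on
    the estimates, evaluates the curve on the grid and takes the 2.5/97.5
    percentiles.  A zero covariance collapses the band onto the fit.
    """
    if not fit.converged:
        raise ValueError("cannot build a confidence band from a non-converged fit")
    cov = np.asarray(fit.covariance, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("fit covariance is not finite")
    cov = _positive_semidefinite(cov)
    x = np.asarray(x_grid, dtype=float)
    rng = np.random.default_rng(seed)
    params = rng.multivariate_normal([fit.coef, fit.exp], cov, size=n_sims, method="svd")
    curves = params[:, [0]] * np.power(x[None, :], params[:, [1]]) - 1.0
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return CurveBand(
        x=x,
        fitted=_model(np.array([fit.coef, fit.exp]), x),
        lower95=lo,
        upper95=hi,
        n_sims=n_sims,
        seed=seed,
        method="monte_carlo",
    )


def taylor_confidence_band(fit: PowerFitResult, x_grid, order: int = 1) -> CurveBand:
    """Delta-method 95% band (first- or second-order Taylor propagation).

    First order: var(y) = g' C g with gradient g = (x**exp,
    coef*x**exp*log x).  Second order adds the Hessian correction
    tr((H C)^2)/2 to the variance and tr(H C)/2 to the mean.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    cov = _positive_semidefinite(np.asarray(fit.covariance, dtype=float))
    x = np.asarray(x_grid, dtype=float)
    fitted = _model(np.array([fit.coef, fit.exp]), x)
    grads = _jacobian(np.array([fit.coef, fit.exp]), x)
    var = np.einsum("ij,jk,ik->i", grads, cov, grads)
    mean = fitted.copy()
    if order == 2:
        logx = np.log(x)
        xe = np.power(x, fit.exp)
        corr = np.empty_like(x)
        var2 = np.empty_like(x)
        for i in range(x.size):
            h = np.array(
                [
                    [0.0, xe[i] * logx[i]],
                    [xe[i] * logx[i], fit.coef * xe[i] * logx[i] ** 2],
                ]
            )
            hc = h @ cov
            corr[i] = 0.5 * np.trace(hc)
            var2[i] = 0.5 * np.trace(hc @ hc)
        mean = fitted + corr
        var = var + var2
    half = 1.959963984540054 * np.sqrt(var)
    return CurveBand(
        x=x,
        fitted=fitted,
        lower95=mean - half,
        upper95=mean + half,
        n_sims=0,
        seed=None,
        method=f"taylor_order{order}",
    )


def crossing_duration(
    fit: PowerFitResult, target_bias: float = 0.0, x_max: float = 200.0
) -> Optional[float]:
    """Duration at which the fitted curve reaches ``target_bias``, or None.

    Solved analytically: coef*x**exp - 1 = target gives
    x = ((1 + target)/coef)**(1/exp).  Returns None when the curve cannot
    reach the target by accumulating effort (exp <= 0: the curve does not
    increase with duration), when the ratio is non-positive, or when the
    solution exceeds ``x_max``.
    """
    ratio = (1.0 + target_bias) / fit.coef if fit.coef != 0 else math.nan
    if not math.isfinite(ratio) or ratio <= 0:
        return None
    if fit.exp <= 0:
        return None
    try:
        x = ratio ** (1.0 / fit.exp)
    except (OverflowError, ZeroDivisionError):
        return None
    if not math.isfinite(x) or x <= 0 or x > x_max:
        return None
    return float(x)
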