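"""Segmented regression for a single ITS series: OLS, Prais-Winsten, REML.

The model is Y_t = beta0 + beta1*t + beta2*D_t + beta3*(t - T_I)*D_t + e_t
with D_t = 1 for t >= T_I and AR(1) errors e_t = rho*e_{t-1} + w_t. OLS
ignores the autocorrelation; Prais-Winsten (PW) iteratively whitens the
data with the residual-estimated rho (keeping the first observation scaled
by sqrt(1-rho^2)); REML maximises the restricted likelihood of the model
with correlation matrix R_ij = rho^|i-j|.

:func:`fit_with_fallback` applies the preference hierarchy used in
practice: REML when it converges with rho in (-1, 1), then PW, then OLS.
Whatever produced the estimates, the OLS residual RMSE of the same series
is carried along for downstream standardisation.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .types import ITSFit, TimeSeriesStudy

__all__ = [
    "build_design",
    "fit_ols",
    "fit_pw",
    "fit_reml_ar1",
    "fit_with_fallback",
    "lag1_autocorrelation",
]

_N_PARAMS = 4
#: |rho| at or beyond this is treated as "estimate of autocorrelation not
#: inside (-1, 1)" and triggers the fallback hierarchy.
_RHO_BOUND = 0.99
_NOISELESS_TOL = 1e-10


def build_design(study: TimeSeriesStudy) -> np.ndarray:
    """Design matrix with columns [1, t, D_t, (t - T_I)*D_t]."""
    t = study.times.astype(float)
    d = (study.times >= study.interruption_index).astype(float)
    return np.column_stack([np.ones_like(t), t, d, (t - study.interruption_index) * d])


def lag1_autocorrelation(residuals: np.ndarray) -> float:
    """rho_hat = sum_{t>=2} e_t e_{t-1} / sum_t e_t^2.

    Returns 0 (with a warning) for all-zero residuals.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(np.dot(e, e))
    if denom == 0.0:
        warnings.warn("all-zero residuals; lag-1 autocorrelation set to 0", stacklevel=2)
        return 0.0
    return float(np.dot(e[1:], e[:-1]) / denom)


def fit_ols(study: TimeSeriesStudy) -> ITSFit:
    """Ordinary least squares with conventional (T-4)-denominator SEs."""
    x = build_design(study)
    res = sm.OLS(study.values, x).fit()
    rmse = float(np.sqrt(res.scale))  # scale = RSS / (T - 4)
    return ITSFit(
        study_id=study.study_id,
        beta_hat=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        rho_hat=None,
        rmse_ols=rmse,
        estimator_used="OLS",
        converged=True,
        n_points=study.n_points,
        interval_unit=study.interval_unit,
    )


def _pw_transform(x: np.ndarray, y: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Prais-Winsten whitening: row 1 scaled by sqrt(1-rho^2), rows t>=2 quasi-differenced."""
    xs = x - rho * np.vstack([x[:1], x[:-1]])
    ys = y - rho * np.concatenate([y[:1], y[:-1]])
    c = np.sqrt(1.0 - rho**2)
    xs[0] = c * x[0]
    ys[0] = c * y[0]
    return xs, ys


def _gls_at_rho(x: np.ndarray, y: np.ndarray, rho: float):
    """Transformed least squares at a fixed rho; returns (beta, rss_t, xtx)."""
    xs, ys = _pw_transform(x, y, rho)
    xtx = xs.T @ xs
    beta = np.linalg.solve(xtx, xs.T @ ys)
    resid = ys - xs @ beta
    return beta, float(resid @ resid), xtx, xs, ys


def fit_pw(study: TimeSeriesStudy, tol: float = 1e-6, max_iter: int = 100) -> ITSFit:
    """Iterated Prais-Winsten estimation.

    Each pass estimates lag-1 autocorrelation from the original-scale
    residuals, whitens, and refits, until rho stabilises within ``tol``.
    Non-convergence (max_iter hit, or |rho| >= 1 at any iterate) is flagged
    rather than raised so the fallback hierarchy can act on it.
    """
    x = build_design(study)
    y = study.values
    ols = sm.OLS(y, x).fit()
    rmse = float(np.sqrt(ols.scale))
    if rmse <= _NOISELESS_TOL:  # exact fit: PW is the identity transform
        return ITSFit(
            study_id=study.study_id,
            beta_hat=np.asarray(ols.params, dtype=float),
            se=np.zeros(_N_PARAMS),
            rho_hat=0.0,
            rmse_ols=rmse,
            estimator_used="PW",
            converged=True,
            n_points=study.n_points,
            interval_unit=study.interval_unit,
        )
    beta = np.asarray(ols.params, dtype=float)
    rho = lag1_autocorrelation(y - x @ beta)
    converged = False
    for _ in range(max_iter):
        if abs(rho) >= 1.0:
            break
        beta, _, _, xs, ys = _gls_at_rho(x, y, rho)
        rho_new = lag1_autocorrelation(y - x @ beta)
        if abs(rho_new - rho) < tol:
            rho = rho_new
            converged = abs(rho) < 1.0
            break
        rho = rho_new
    rho_fit = float(np.clip(rho, -0.999999, 0.999999))
    res = sm.OLS(*reversed(_pw_transform(x, y, rho_fit))).fit()
    return ITSFit(
        study_id=study.study_id,
        beta_hat=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        rho_hat=float(rho),
        rmse_ols=rmse,
        estimator_used="PW",
        converged=converged,
        n_points=study.n_points,
        interval_unit=study.interval_unit,
    )


def reml_neg2_loglik(rho: float, x: np.ndarray, y: np.ndarray) -> float:
    """-2 x profiled restricted log-likelihood of the AR(1) model (up to a constant).

    With P the Prais-Winsten whitening matrix, P R P' = (1-rho^2) I, so all
    R^{-1} quadratic forms reduce to transformed least squares. Profiling
    the variance leaves
    (T-p)*log(RSS_t) - log(1-rho^2) + log|X_t' X_t|.
    """
    t, p = x.shape
    _, rss_t, xtx, _, _ = _gls_at_rho(x, y, rho)
    if rss_t <= 0.0:
        return np.inf
    sign, logdet = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf
    return (t - p) * np.log(rss_t) - np.log1p(-rho**2) + logdet


def fit_reml_ar1(study: TimeSeriesStudy) -> ITSFit:
    """REML estimation of the segmented model with AR(1) errors.

    rho is profiled on (-0.999, 0.999) by a coarse grid followed by bounded
    scalar minimisation around the best grid point (guarding against local
    optima); the variance has a closed-form profile. beta_hat is the GLS
    estimate at rho_hat with SEs from (X' V^{-1} X)^{-1} using the
    REML (T-4 denominator) variance. A maximiser pinned at the rho boundary
    is flagged as non-converged, mirroring the "autocorrelation outside
    (-1, 1)" failure mode.
    """
    x = build_design(study)
    y = study.values
    ols = sm.OLS(y, x).fit()
    rmse = float(np.sqrt(ols.scale))
    if rmse <= _NOISELESS_TOL:
        return ITSFit(
            study_id=study.study_id,
            beta_hat=np.asarray(ols.params, dtype=float),
            se=np.zeros(_N_PARAMS),
            rho_hat=0.0,
            rmse_ols=rmse,
            estimator_used="REML",
            converged=True,
            n_points=study.n_points,
            interval_unit=study.interval_unit,
        )
    grid = np.linspace(-0.95, 0.95, 39)
    vals = np.array([reml_neg2_loglik(r, x, y) for r in grid])
    ok = np.isfinite(vals)
    converged = True
    if not ok.any():
        converged = False
        rho_hat = 0.0
    else:
        i = int(np.argmin(np.where(ok, vals, np.inf)))
        lo = grid[max(i - 1, 0)] if i > 0 else -0.999
        hi = grid[min(i + 1, grid.size - 1)] if i < grid.size - 1 else 0.999
        lo, hi = max(lo, -0.999), min(hi, 0.999)
        opt = minimize_scalar(
            reml_neg2_loglik,
            bounds=(lo, hi),
            args=(x, y),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho_hat = float(opt.x) if opt.success else float(grid[i])
        if not opt.success or not np.isfinite(opt.fun):
            converged = False
        if abs(rho_hat) >= _RHO_BOUND:
            converged = False
    beta, rss_t, xtx, _, _ = _gls_at_rho(x, y, float(np.clip(rho_hat, -0.9995, 0.9995)))
    sigma2_w = rss_t / (study.n_points - _N_PARAMS)
    cov = sigma2_w * np.linalg.inv(xtx)
    return ITSFit(
        study_id=study.study_id,
        beta_hat=np.asarray(beta, dtype=float),
        se=np.sqrt(np.diag(cov)),
        rho_hat=float(rho_hat),
        rmse_ols=rmse,
        estimator_used="REML",
        converged=converged,
        n_points=study.n_points,
        interval_unit=study.interval_unit,
    )


def fit_with_fallback(study: TimeSeriesStudy) -> ITSFit:
    """REML, else PW, else OLS — the preference hierarchy for the AR(1) arm.

    Never raises on a valid study: OLS always succeeds. The returned fit's
    ``estimator_used`` records which method actually produced the
    estimates.
    """
    try:
        fit = fit_reml_ar1(study)
        if fit.converged and (fit.rho_hat is None or abs(fit.rho_hat) < 1.0):
            return fit
    except Exception:
        pass
    try:
        fit = fit_pw(study)
        if fit.converged:
            return fit
    except Exception:
        pass
    return fit_ols(study)
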