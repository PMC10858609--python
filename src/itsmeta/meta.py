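"""Fixed- and random-effects meta-analysis of standardised ITS effects.

Implements inverse-variance pooling with five method combinations: a
fixed-effect model, and random-effects models crossing two between-study
variance estimators (DerSimonian-Laird moment estimator; REML) with two
confidence interval methods (Wald-type normal; Hartung-Knapp/Sidik-Jonkman
with its weighted-residual SE adjustment and t_{K-1} quantiles). The HKSJ
adjustment is used untruncated, which is what allows HKSJ intervals to be
narrower than Wald-type ones when there are few studies and the estimated
between-study variance is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .types import MetaResult, ValidationError

__all__ = [
    "MetaInput",
    "pooled_estimate",
    "tau2_dl",
    "tau2_reml",
    "ci_wald",
    "ci_hksj",
    "run_all_methods",
]


@dataclass(frozen=True)
class MetaInput:
    """Per-study effect estimates and within-study variances for one pooling."""

    meta_id: str
    metric: str
    estimates: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "variances", var)
        if est.ndim != 1 or est.shape != var.shape:
            raise ValidationError("estimates and variances must be equal-length 1-d arrays")
        if est.size < 2:
            raise ValidationError("a meta-analysis needs at least two studies")
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            raise ValidationError("all within-study variances must be positive and finite")

    @property
    def k(self) -> int:
        return int(self.estimates.size)


def pooled_estimate(estimates: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean sum(W*b)/sum(W) and its variance 1/sum(W)."""
    w = np.asarray(weights, dtype=float)
    b = np.asarray(estimates, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    sw = float(w.sum())
    return float((w * b).sum() / sw), 1.0 / sw


def tau2_dl(inp: MetaInput) -> float:
    """DerSimonian-Laird moment estimator from Cochran's Q, truncated at 0."""
    w = 1.0 / inp.variances
    est, _ = pooled_estimate(inp.estimates, w)
    q = float(np.sum(w * (inp.estimates - est) ** 2))
    sw = float(w.sum())
    denom = sw - float(np.sum(w**2)) / sw
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (inp.k - 1)) / denom)


def reml_neg_loglik(tau2: float, estimates: np.ndarray, variances: np.ndarray) -> float:
    """Negative restricted log-likelihood of the normal-normal random-effects model."""
    w = 1.0 / (variances + tau2)
    mu = float(np.sum(w * estimates) / np.sum(w))
    return 0.5 * (
        float(np.sum(np.log(variances + tau2)))
        + float(np.log(np.sum(w)))
        + float(np.sum(w * (estimates - mu) ** 2))
    )


def tau2_reml(inp: MetaInput, tol: float = 1e-8, max_iter: int = 100) -> float:
    """REML estimator of the between-study variance.

    Maximises the restricted log-likelihood over tau2 >= 0 with a bounded
    scalar optimiser on [0, 10*DL + 1]. On optimiser failure, falls back to
    the DL value with a warning.
    """
    dl = tau2_dl(inp)
    upper = 10.0 * dl + 1.0
    opt = minimize_scalar(
        reml_neg_loglik,
        bounds=(0.0, upper),
        args=(inp.estimates, inp.variances),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not opt.success or not np.isfinite(opt.fun):
        warnings.warn(
            f"{inp.meta_id}: REML between-study variance failed to converge; using DL",
            stacklevel=2,
        )
        return dl
    tau2 = float(opt.x)
    # the bounded optimiser cannot sit exactly on the boundary; snap to 0
    # when the objective is non-increasing there
    if tau2 < 10 * tol and reml_neg_loglik(0.0, inp.estimates, inp.variances) <= opt.fun:
        return 0.0
    return max(0.0, tau2)


def ci_wald(estimate: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Normal-quantile CI and two-sided p-value for estimate/se."""
    if se < 0:
        raise ValidationError("se must be nonnegative")
    if se == 0:
        return estimate, estimate, (1.0 if estimate == 0 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    p = 2 * stats.norm.sf(abs(estimate) / se)
    return estimate - z * se, estimate + z * se, float(p)


def ci_hksj(
    inp: MetaInput, tau2_hat: float, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Hartung-Knapp/Sidik-Jonkman CI: adjusted SE with t_{K-1} quantiles.

    se_HKSJ^2 = sum W_k (b_k - b*)^2 / ((K-1) sum W_k) with random-effects
    weights W_k = 1/(v_k + tau2). No truncation is applied, so the interval
    can be narrower than the Wald-type one. All effects equal gives a
    degenerate zero-width interval (flagged by the caller).
    Returns (low, high, p, se_hksj).
    """
    w = 1.0 / (inp.variances + tau2_hat)
    est, _ = pooled_estimate(inp.estimates, w)
    k = inp.k
    se2 = float(np.sum(w * (inp.estimates - est) ** 2)) / ((k - 1) * float(np.sum(w)))
    se = float(np.sqrt(se2))
    tq = stats.t.ppf(0.5 + level / 2, df=k - 1)
    if se == 0:
        return est, est, (1.0 if est == 0 else 0.0), 0.0
    p = 2 * stats.t.sf(abs(est) / se, df=k - 1)
    return est - tq * se, est + tq * se, float(p), se


def run_all_methods(inp: MetaInput, level: float = 0.95) -> list[MetaResult]:
    """Pool one meta-analysis under all five method combinations.

    Returns, in order: fixed; (DL, WT); (DL, HKSJ); (REML, WT);
    (REML, HKSJ). The two results sharing a tau2 estimator share the same
    tau2_hat, weights and point estimate — only the interval differs.
    """
    results: list[MetaResult] = []

    w_fe = 1.0 / inp.variances
    est, var = pooled_estimate(inp.estimates, w_fe)
    se = float(np.sqrt(var))
    lo, hi, p = ci_wald(est, se, level)
    results.append(
        MetaResult(
            meta_id=inp.meta_id, metric=inp.metric, model="fixed", tau2_method="none",
            ci_method="WT", estimate=est, se=se, ci_low=lo, ci_high=hi, p_value=p,
            tau2_hat=None, k=inp.k,
        )
    )

    for tau2_method, tau2 in (("DL", tau2_dl(inp)), ("REML", tau2_reml(inp))):
        w_re = 1.0 / (inp.variances + tau2)
        est, var = pooled_estimate(inp.estimates, w_re)
        se = float(np.sqrt(var))
        lo, hi, p = ci_wald(est, se, level)
        results.append(
            MetaResult(
                meta_id=inp.meta_id, metric=inp.metric, model="random",
                tau2_method=tau2_method, ci_method="WT", estimate=est, se=se,
                ci_low=lo, ci_high=hi, p_value=p, tau2_hat=tau2, k=inp.k,
            )
        )
        lo, hi, p, se_h = ci_hksj(inp, tau2, level)
        results.append(
            MetaResult(
                meta_id=inp.meta_id, metric=inp.metric, model="random",
                tau2_method=tau2_method, ci_method="HKSJ", estimate=est, se=se_h,
                ci_low=lo, ci_high=hi, p_value=p, tau2_hat=tau2, k=inp.k,
                degenerate=(se_h == 0.0),
            )
        )
    # keep canonical order: fixed, DL+WT, DL+HKSJ, REML+WT, REML+HKSJ
    return results
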