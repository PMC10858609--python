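"""Standardisation of interruption effects for cross-study pooling.

Raw level- and slope-changes are on the outcome's own scale, so before
meta-analysis each estimate (and its SE) is divided by the root mean
square error of the *OLS* fit of the same series — whichever estimator
produced the estimate — giving effects in residual-SD units. Slope-changes
are then rescaled to per-month units, and pooled estimates are finally
sign-aligned so a positive value is always beneficial.
"""

from __future__ import annotations

from .types import INTERVAL_UNITS, ITSFit, MetaResult, StandardizedEffect, ValidationError

__all__ = ["standardize_effect", "slope_to_per_month", "apply_direction", "per_month_factor"]

DAYS_PER_MONTH = 365.25 / 12  # 30.4375


def standardize_effect(fit: ITSFit, metric: str) -> StandardizedEffect:
    """Divide the chosen effect and its SE by the series' OLS RMSE.

    metric: "level_change" (beta2) or "slope_change" (beta3, still in
    per-time-interval units; see :func:`slope_to_per_month`).
    """
    if fit.rmse_ols <= 0:
        raise ValidationError(
            f"{fit.study_id}: OLS RMSE is zero (perfect fit); the series cannot be "
            "standardised and should be excluded"
        )
    idx = {"level_change": 2, "slope_change": 3}
    if metric not in idx:
        raise ValidationError(f"unknown metric {metric!r}")
    j = idx[metric]
    return StandardizedEffect(
        study_id=fit.study_id,
        metric=metric,
        estimate=float(fit.beta_hat[j]) / fit.rmse_ols,
        se=float(fit.se[j]) / fit.rmse_ols,
        estimator_used=fit.estimator_used,
    )


def per_month_factor(interval_unit: str, days_per_month: float = DAYS_PER_MONTH) -> float:
    """Multiplier converting a per-interval slope to a per-month slope.

    A slope per year is divided by 12; a slope per day is multiplied by the
    number of days in a month (30.4375 under the 365.25/12 convention);
    generally factor = days_per_month / days_per_interval.
    """
    if interval_unit not in INTERVAL_UNITS:
        raise ValidationError(f"unknown interval_unit {interval_unit!r}")
    return days_per_month / INTERVAL_UNITS[interval_unit]


def slope_to_per_month(
    effect: StandardizedEffect, interval_unit: str, days_per_month: float = DAYS_PER_MONTH
) -> StandardizedEffect:
    """Rescale a slope-change effect (and SE) to per-month units."""
    if effect.metric != "slope_change":
        raise ValidationError(f"expected a slope_change effect, got {effect.metric!r}")
    f = per_month_factor(interval_unit, days_per_month)
    return StandardizedEffect(
        study_id=effect.study_id,
        metric="slope_change_per_month",
        estimate=effect.estimate * f,
        se=effect.se * f,
        estimator_used=effect.estimator_used,
    )


def apply_direction(result, beneficial_direction: str):
    """Sign-align an estimate so positive means beneficial (an involution).

    Accepts a pooled :class:`MetaResult` (the usual case: the flip is
    applied at the meta-analysis level) or a study-level
    :class:`StandardizedEffect`. When a decrease is beneficial the estimate
    is negated and CI limits swap and negate; SEs, p-values and tau2 are
    untouched.
    """
    if beneficial_direction not in ("increase", "decrease"):
        raise ValidationError(f"beneficial_direction must be 'increase' or 'decrease', got {beneficial_direction!r}")
    if beneficial_direction == "increase":
        return result
    if isinstance(result, StandardizedEffect):
        return StandardizedEffect(
            study_id=result.study_id,
            metric=result.metric,
            estimate=-result.estimate,
            se=result.se,
            estimator_used=result.estimator_used,
        )
    return MetaResult(
        meta_id=result.meta_id,
        metric=result.metric,
        model=result.model,
        tau2_method=result.tau2_method,
        ci_method=result.ci_method,
        estimate=-result.estimate,
        se=result.se,
        ci_low=-result.ci_high,
        ci_high=-result.ci_low,
        p_value=result.p_value,
        tau2_hat=result.tau2_hat,
        k=result.k,
        degenerate=result.degenerate,
    )
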