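"""Core containers for interrupted time series (ITS) meta-analysis.

An ITS study is a single outcome series measured at regular intervals with
one interruption (a policy change, exposure, ...). The segmented linear
model estimates a pre-interruption intercept and slope (beta0, beta1) and
two interruption effects: an immediate level-change (beta2) and a
slope-change (beta3), with AR(1) errors. Studies are pooled per
meta-analysis after standardisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Recognised aggregation intervals and their length in days. One month is
#: taken as 365.25/12 = 30.4375 days; the 4-week interval is 28 days.
INTERVAL_UNITS = {
    "day": 1.0,
    "4-week": 28.0,
    "month": 30.4375,
    "year": 365.25,
}

MIN_POINTS_PER_SEGMENT = 3


class ValidationError(ValueError):
    """Raised when input data violate a structural requirement."""


@dataclass(frozen=True)
class SeriesParams:
    """Generating parameters for one synthetic ITS series.

    Time runs t = 1..n_points in unit steps; the interruption occurs at
    t = interruption_index, which belongs to the post segment. The error
    process is stationary AR(1): e_t = rho*e_{t-1} + w_t with
    w_t ~ N(0, sigma_w^2), so the marginal error SD is
    sigma_w/sqrt(1-rho^2).
    """

    n_points: int
    interruption_index: int
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    rho: float = 0.0
    sigma_w: float = 1.0
    interval_unit: str = "month"
    seed: int = 0

    def __post_init__(self) -> None:
        t, ti = self.n_points, self.interruption_index
        if t < 2 * MIN_POINTS_PER_SEGMENT:
            raise ValidationError(f"series needs >= {2 * MIN_POINTS_PER_SEGMENT} points, got {t}")
        n_pre = ti - 1
        n_post = t - ti + 1
        if n_pre < MIN_POINTS_PER_SEGMENT or n_post < MIN_POINTS_PER_SEGMENT:
            raise ValidationError(
                f"need >= {MIN_POINTS_PER_SEGMENT} points per segment; "
                f"interruption at {ti} gives {n_pre} pre / {n_post} post"
            )
        if not abs(self.rho) < 1:
            raise ValidationError(f"AR(1) coefficient must satisfy |rho| < 1, got {self.rho}")
        if self.sigma_w < 0:
            raise ValidationError("sigma_w must be nonnegative")
        if self.interval_unit not in INTERVAL_UNITS:
            raise ValidationError(
                f"unknown interval_unit {self.interval_unit!r}; expected one of {sorted(INTERVAL_UNITS)}"
            )


@dataclass(frozen=True)
class TimeSeriesStudy:
    """One validated ITS series ready for segmented regression.

    ``times`` are consecutive integers 1..T; ``interruption_index`` is the
    first time index of the post-interruption segment.
    """

    study_id: str
    times: np.ndarray
    values: np.ndarray
    interruption_index: int
    interval_unit: str = "month"
    outcome_type: str = "continuous"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValidationError(f"{self.study_id}: times and values must be equal-length 1-d arrays")
        if times.size < 2 * MIN_POINTS_PER_SEGMENT:
            raise ValidationError(f"{self.study_id}: series too short (T={times.size})")
        d = np.diff(times)
        if not np.all(d == 1):
            bad = int(np.argmax(d != 1))
            raise ValidationError(
                f"{self.study_id}: times must be consecutive integers; gap between "
                f"t={times[bad]} and t={times[bad + 1]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"{self.study_id}: non-finite outcome values")
        n_pre = int(np.sum(times < self.interruption_index))
        n_post = int(np.sum(times >= self.interruption_index))
        if n_pre < MIN_POINTS_PER_SEGMENT or n_post < MIN_POINTS_PER_SEGMENT:
            raise ValidationError(
                f"{self.study_id}: need >= {MIN_POINTS_PER_SEGMENT} points on each side "
                f"of the interruption (got {n_pre} pre / {n_post} post)"
            )
        if self.interval_unit not in INTERVAL_UNITS:
            raise ValidationError(f"{self.study_id}: unknown interval_unit {self.interval_unit!r}")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ITSFit:
    """Estimates from fitting the segmented model to one series.

    ``rmse_ols`` is always the residual root-mean-square error of the OLS
    fit of the same series (T-4 denominator), whichever estimator produced
    ``beta_hat`` — it is the standardisation scale used downstream.
    ``se`` and ``rmse_ols`` are zero only in the degenerate noiseless case;
    standardisation refuses that case explicitly.
    """

    study_id: str
    beta_hat: np.ndarray
    se: np.ndarray
    rho_hat: Optional[float]
    rmse_ols: float
    estimator_used: str  # "REML" | "PW" | "OLS"
    converged: bool
    n_points: int
    interval_unit: str = "month"

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta_hat, dtype=float)
        se = np.asarray(self.se, dtype=float)
        object.__setattr__(self, "beta_hat", beta)
        object.__setattr__(self, "se", se)
        if beta.shape != (4,) or se.shape != (4,):
            raise ValidationError("beta_hat and se must be 4-vectors")
        if np.any(se < 0) or self.rmse_ols < 0:
            raise ValidationError("standard errors and rmse_ols must be nonnegative")
        if self.estimator_used not in ("REML", "PW", "OLS"):
            raise ValidationError(f"unknown estimator {self.estimator_used!r}")

    @property
    def level_change(self) -> float:
        return float(self.beta_hat[2])

    @property
    def slope_change(self) -> float:
        return float(self.beta_hat[3])


@dataclass(frozen=True)
class StandardizedEffect:
    """A scale-free interruption effect ready for pooling.

    metric is "level_change" or "slope_change_per_month"; estimate and se
    share the same standardisation factor so se/estimate is preserved.
    """

    study_id: str
    metric: str
    estimate: float
    se: float
    estimator_used: str

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.study_id}: standardised se must be positive")
        if not math.isfinite(self.estimate):
            raise ValidationError(f"{self.study_id}: non-finite standardised estimate")


@dataclass(frozen=True)
class MetaResult:
    """Pooled result for one (meta-analysis, metric, method combination)."""

    meta_id: str
    metric: str
    model: str  # "fixed" | "random"
    tau2_method: str  # "none" | "DL" | "REML"
    ci_method: str  # "WT" | "HKSJ"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2_hat: Optional[float]
    k: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValidationError("ci_low must not exceed ci_high")
        if self.tau2_hat is not None and self.tau2_hat < -0.0:
            raise ValidationError("tau2_hat must be nonnegative")

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    @property
    def meta_method(self) -> str:
        """Short label: 'fixed', 'DL+WT', 'DL+HKSJ', 'REML+WT', 'REML+HKSJ'."""
        if self.model == "fixed":
            return "fixed"
        return f"{self.tau2_method}+{self.ci_method}"


@dataclass(frozen=True)
class MethodCombination:
    """One cell of the 2 x 5 grid: ITS estimator arm x meta-analysis method."""

    its_method: str  # "OLS" | "REML" (REML = REML->PW->OLS fallback chain)
    meta_method: str  # "fixed" | "DL+WT" | "DL+HKSJ" | "REML+WT" | "REML+HKSJ"

    def __str__(self) -> str:
        return f"{self.its_method} ITS / {self.meta_method} MA"


META_METHOD_ORDER = ("fixed", "DL+WT", "DL+HKSJ", "REML+WT", "REML+HKSJ")
ITS_METHOD_ORDER = ("OLS", "REML")

#: Canonical ordering of the ten method combinations: the OLS block before
#: the REML-chain block, meta-analysis methods in META_METHOD_ORDER within
#: each block. Pairwise differences are oriented later-minus-earlier.
ALL_COMBINATIONS = tuple(
    MethodCombination(its, mm) for its in ITS_METHOD_ORDER for mm in META_METHOD_ORDER
)


@dataclass
class PairwiseComparison:
    """Agreement statistics between two method combinations across meta-analyses."""

    combo_a: MethodCombination
    combo_b: MethodCombination
    metric: str
    n: int
    mean_diff: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan
    mean_se_ratio: float = np.nan
    se_ratio_low: float = np.nan
    se_ratio_high: float = np.nan
    tau2_median_diff: float = np.nan
    tau2_q1: float = np.nan
    tau2_q3: float = np.nan
    pct_agree: float = np.nan
    kappa: float = np.nan
    kappa_label: str = ""


@dataclass(frozen=True)
class MetaParams:
    """Generating parameters for one synthetic meta-analysis collection.

    True per-study effects are drawn as mean +/- N(0, tau2) independently
    for the level- and slope-change (the between-study correlation of the
    two effects is not modelled; see docs/methods.md).
    """

    n_studies: int
    mean_level_effect: float
    mean_slope_effect: float
    tau2_level: float
    tau2_slope: float
    series_template: "SeriesTemplate"
    beneficial_direction: str = "increase"
    meta_id: str = "meta_1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValidationError("a meta-analysis needs at least two ITS studies")
        if self.tau2_level < 0 or self.tau2_slope < 0:
            raise ValidationError("between-study variances must be nonnegative")
        if self.beneficial_direction not in ("increase", "decrease"):
            raise ValidationError("beneficial_direction must be 'increase' or 'decrease'")


@dataclass(frozen=True)
class SeriesTemplate:
    """Distributional template for drawing SeriesParams within a collection.

    Defaults emulate the spread observed in published ITS meta-analyses:
    series length with median ~52 points (range 7-195), lag-1
    autocorrelation with median ~0.22, interruptions located mid-series,
    and mostly monthly aggregation. Set a ``*_fixed`` field to pin a value.
    """

    n_points_fixed: Optional[int] = None
    n_points_log_median: float = 52.0
    n_points_log_sigma: float = 0.6
    n_points_range: tuple[int, int] = (7, 195)
    rho_fixed: Optional[float] = None
    rho_mean: float = 0.22
    rho_sd: float = 0.28
    rho_range: tuple[float, float] = (-0.5, 0.92)
    sigma_w: float = 1.0
    beta0: float = 10.0
    beta1: float = 0.05
    interruption_frac: tuple[float, float] = (0.3, 0.7)
    interval_unit: Optional[str] = None  # None -> draw from the corpus mix
    #: Observed mix of aggregation intervals across meta-analyses.
    interval_unit_probs: tuple[tuple[str, float], ...] = (
        ("month", 11 / 17),
        ("year", 4 / 17),
        ("4-week", 1 / 17),
        ("day", 1 / 17),
    )


@dataclass(frozen=True)
class RepositoryTemplate:
    """Template for a whole synthetic repository of meta-analyses.

    The number of studies per meta-analysis K is drawn log-normally with
    median ~11 and clipped to [3, 62]; per-meta mean effects are drawn
    around a modest beneficial effect on the standardised scale.
    """

    k_fixed: Optional[int] = None
    k_log_median: float = 11.0
    k_log_sigma: float = 0.7
    k_range: tuple[int, int] = (3, 62)
    mean_level_effect_mean: float = 0.5
    mean_level_effect_sd: float = 0.25
    mean_slope_effect_mean: float = 0.03
    mean_slope_effect_sd: float = 0.03
    tau2_level: float = 0.05
    tau2_slope: float = 0.0025
    series: SeriesTemplate = field(default_factory=SeriesTemplate)
    p_decrease: float = 0.5
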