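"""Synthetic ITS data with the statistical structure assumed downstream.

Three layers: one AR(1) segmented series (:func:`generate_series`), a
meta-analysis collection whose true interruption effects are drawn from a
normal distribution with between-study variance tau^2
(:func:`generate_meta_dataset`), and a whole repository of such
collections (:func:`generate_repository`) that round-trips through the
tabular reader in :mod:`itsmeta.io`.

A single repository seed spawns per-meta and per-study child seeds through
``numpy.random.SeedSequence``, so any subset regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .types import (
    MetaParams,
    RepositoryTemplate,
    SeriesParams,
    SeriesTemplate,
    TimeSeriesStudy,
    ValidationError,
)

__all__ = [
    "generate_series",
    "generate_meta_dataset",
    "generate_repository",
    "MetaDataset",
    "SyntheticRepository",
]


def _ar1_errors(rng: np.random.Generator, n: int, rho: float, sigma_w: float) -> np.ndarray:
    """Stationary AR(1) noise: e_1 ~ N(0, sigma_w^2/(1-rho^2)), then recurse."""
    if sigma_w == 0.0:
        return np.zeros(n)
    w = rng.normal(0.0, sigma_w, size=n)
    e = np.empty(n)
    e[0] = w[0] / np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + w[t]
    return e


def segmented_mean(params: SeriesParams, times: np.ndarray) -> np.ndarray:
    """Noise-free segmented trend beta0 + beta1*t + beta2*D + beta3*(t-T_I)*D."""
    d = (times >= params.interruption_index).astype(float)
    return (
        params.beta0
        + params.beta1 * times
        + params.beta2 * d
        + params.beta3 * (times - params.interruption_index) * d
    )


def generate_series(params: SeriesParams) -> TimeSeriesStudy:
    """Draw one ITS series under the segmented AR(1) model.

    Deterministic given ``params.seed``. The noiseless case (sigma_w=0)
    returns the exact piecewise line.
    """
    rng = np.random.default_rng(params.seed)
    times = np.arange(1, params.n_points + 1)
    values = segmented_mean(params, times) + _ar1_errors(
        rng, params.n_points, params.rho, params.sigma_w
    )
    return TimeSeriesStudy(
        study_id=f"series_{params.seed}",
        times=times,
        values=values,
        interruption_index=params.interruption_index,
        interval_unit=params.interval_unit,
    )


def draw_series_params(
    template: SeriesTemplate,
    rng: np.random.Generator,
    beta2: float,
    beta3: float,
    seed: int,
) -> SeriesParams:
    """Draw series shape (length, interruption, rho, unit) from a template."""
    if template.n_points_fixed is not None:
        t = int(template.n_points_fixed)
    else:
        t = int(round(np.exp(rng.normal(np.log(template.n_points_log_median), template.n_points_log_sigma))))
        t = int(np.clip(t, *template.n_points_range))
    t = max(t, 6)
    if template.rho_fixed is not None:
        rho = float(template.rho_fixed)
    else:
        rho = float(np.clip(rng.normal(template.rho_mean, template.rho_sd), *template.rho_range))
    lo = max(4, int(np.ceil(template.interruption_frac[0] * t)))
    hi = min(t - 2, int(np.floor(template.interruption_frac[1] * t)))
    if hi < lo:  # short series: fall back to the widest admissible window
        lo, hi = 4, t - 2
    ti = int(rng.integers(lo, hi + 1))
    if template.interval_unit is not None:
        unit = template.interval_unit
    else:
        units, probs = zip(*template.interval_unit_probs)
        unit = str(rng.choice(units, p=np.asarray(probs) / np.sum(probs)))
    return SeriesParams(
        n_points=t,
        interruption_index=ti,
        beta0=template.beta0,
        beta1=template.beta1,
        beta2=beta2,
        beta3=beta3,
        rho=rho,
        sigma_w=template.sigma_w,
        interval_unit=unit,
        seed=seed,
    )


@dataclass
class MetaDataset:
    """One synthetic meta-analysis: studies plus their latent truths."""

    meta_id: str
    beneficial_direction: str
    studies: list[TimeSeriesStudy]
    series_params: list[SeriesParams]
    true_level_effects: np.ndarray
    true_slope_effects: np.ndarray
    params: MetaParams

    def __iter__(self) -> Iterator[TimeSeriesStudy]:
        return iter(self.studies)


def generate_meta_dataset(params: MetaParams) -> MetaDataset:
    """Draw a collection of K studies with heterogeneous true effects.

    Per-study effects are mean + delta_k with delta_k ~ N(0, tau2), drawn
    independently for the level- and slope-change. tau2 = 0 makes every
    study share the same true effects.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    level = params.mean_level_effect + rng.normal(0.0, np.sqrt(params.tau2_level), params.n_studies)
    slope = params.mean_slope_effect + rng.normal(0.0, np.sqrt(params.tau2_slope), params.n_studies)
    child_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=params.n_studies)]
    studies: list[TimeSeriesStudy] = []
    all_params: list[SeriesParams] = []
    for k in range(params.n_studies):
        sp = draw_series_params(
            params.series_template, rng, beta2=float(level[k]), beta3=float(slope[k]), seed=child_seeds[k]
        )
        study = generate_series(sp)
        study = TimeSeriesStudy(
            study_id=f"{params.meta_id}_study_{k + 1}",
            times=study.times,
            values=study.values,
            interruption_index=study.interruption_index,
            interval_unit=study.interval_unit,
        )
        studies.append(study)
        all_params.append(sp)
    return MetaDataset(
        meta_id=params.meta_id,
        beneficial_direction=params.beneficial_direction,
        studies=studies,
        series_params=all_params,
        true_level_effects=level,
        true_slope_effects=slope,
        params=params,
    )


@dataclass
class SyntheticRepository:
    """A bundle of synthetic meta-analyses mirroring the reader's layout."""

    metas: list[MetaDataset]
    seed: int
    template: RepositoryTemplate = field(default_factory=RepositoryTemplate)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per observed time point."""
        rows = []
        for meta in self.metas:
            for study, sp in zip(meta.studies, meta.series_params):
                seg = np.where(study.times >= study.interruption_index, 2, 1)
                for t, v, s in zip(study.times, study.values, seg):
                    rows.append(
                        {
                            "meta_id": meta.meta_id,
                            "study_id": study.study_id,
                            "time": int(t),
                            "interval_unit": study.interval_unit,
                            "interruption_time": int(study.interruption_index),
                            "segment": int(s),
                            "value": float(v),
                            "outcome_type": study.outcome_type,
                            "beneficial_direction": meta.beneficial_direction,
                            "is_control": 0,
                        }
                    )
        return pd.DataFrame(rows)

    def truths(self) -> dict:
        """Latent generating truths keyed by meta_id, for recovery tests."""
        out: dict = {"seed": self.seed, "metas": {}}
        for meta in self.metas:
            out["metas"][meta.meta_id] = {
                "beneficial_direction": meta.beneficial_direction,
                "mean_level_effect": meta.params.mean_level_effect,
                "mean_slope_effect": meta.params.mean_slope_effect,
                "tau2_level": meta.params.tau2_level,
                "tau2_slope": meta.params.tau2_slope,
                "n_studies": meta.params.n_studies,
                "studies": {
                    s.study_id: {
                        "level_effect": float(l),
                        "slope_effect": float(m),
                        "rho": sp.rho,
                        "sigma_w": sp.sigma_w,
                        "n_points": sp.n_points,
                        "interruption_index": sp.interruption_index,
                        "interval_unit": sp.interval_unit,
                    }
                    for s, sp, l, m in zip(
                        meta.studies, meta.series_params, meta.true_level_effects, meta.true_slope_effects
                    )
                },
            }
        return out

    def write(self, csv_path, truths_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if truths_path is not None:
            import json

            with open(truths_path, "w") as fh:
                json.dump(self.truths(), fh, indent=1)


def generate_repository(
    n_meta: int,
    template: RepositoryTemplate | None = None,
    seed: int = 0,
) -> SyntheticRepository:
    """Generate a repository of ``n_meta`` meta-analyses.

    K per meta-analysis, per-meta mean effects, beneficial directions and
    all series are drawn from the template; the repository seed spawns a
    deterministic child seed per meta-analysis.
    """
    if n_meta < 1:
        raise ValidationError("n_meta must be >= 1")
    template = template or RepositoryTemplate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    metas: list[MetaDataset] = []
    for m in range(n_meta):
        if template.k_fixed is not None:
            k = int(template.k_fixed)
        else:
            k = int(round(np.exp(rng.normal(np.log(template.k_log_median), template.k_log_sigma))))
            k = int(np.clip(k, *template.k_range))
        k = max(k, 2)
        mp = MetaParams(
            n_studies=k,
            mean_level_effect=float(rng.normal(template.mean_level_effect_mean, template.mean_level_effect_sd)),
            mean_slope_effect=float(rng.normal(template.mean_slope_effect_mean, template.mean_slope_effect_sd)),
            tau2_level=template.tau2_level,
            tau2_slope=template.tau2_slope,
            series_template=template.series,
            beneficial_direction="decrease" if rng.random() < template.p_decrease else "increase",
            meta_id=f"meta_{m + 1:02d}",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        metas.append(generate_meta_dataset(mp))
    return SyntheticRepository(metas=metas, seed=seed, template=template)
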