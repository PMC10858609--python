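"""End-to-end orchestration: data -> fits -> standardised effects -> pooling -> agreement.

Two ITS-analysis arms are run for every study: plain OLS, and the
preference chain REML -> PW -> OLS (labelled "REML"; each fit records the
estimator that actually produced it). Standardised level-changes and
per-month slope-changes are pooled per meta-analysis under the five
meta-analysis methods, pooled estimates are sign-aligned so positive is
beneficial, and the comparison suite is run over the resulting
10-combination grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .compare import ComparisonSuite, run_comparison_suite
from .io import FilterResult, RepositoryData, apply_inclusion_filters, read_repository, write_manifest
from .itsfit import fit_ols, fit_with_fallback
from .meta import MetaInput, run_all_methods
from .standardize import apply_direction, slope_to_per_month, standardize_effect
from .synth import generate_repository
from .types import META_METHOD_ORDER, RepositoryTemplate, TimeSeriesStudy, ValidationError

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "fit_studies", "meta_analyse"]

METRICS = ("level_change", "slope_change_per_month")


@dataclass
class PipelineConfig:
    """Declarative run configuration.

    Either ``input_csv`` points at a repository file, or a synthetic
    repository of ``synth_n_meta`` meta-analyses is generated from
    ``synth_template`` with ``seed``.
    """

    input_csv: Optional[str] = None
    synth_n_meta: int = 17
    synth_template: RepositoryTemplate = field(default_factory=RepositoryTemplate)
    seed: int = 0
    zero_threshold: float = 0.40
    min_points_per_segment: int = 3
    meta_methods: tuple[str, ...] = META_METHOD_ORDER
    outdir: Optional[str] = None
    column_map: Optional[dict] = None


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    effects: pd.DataFrame
    meta_results: pd.DataFrame
    suite: Optional[ComparisonSuite]
    filter_result: FilterResult
    convergence: dict
    manifest: dict
    #: latent generating truths (synthetic inputs only), for recovery checks
    truths: Optional[dict] = None


def fit_studies(included: dict[str, list[TimeSeriesStudy]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 1: fit both ITS arms and standardise the effects.

    Returns (fits table, effects table). The fits table has one row per
    study x arm; the effects table one row per study x arm x metric with
    standardised estimate and SE.
    """
    fit_rows, eff_rows = [], []
    for meta_id, studies in included.items():
        for study in studies:
            arms = {"OLS": fit_ols(study), "REML": fit_with_fallback(study)}
            for arm, fit in arms.items():
                fit_rows.append(
                    {
                        "meta_id": meta_id,
                        "study_id": study.study_id,
                        "its_method": arm,
                        "estimator_used": fit.estimator_used,
                        "converged": fit.converged,
                        "beta0": fit.beta_hat[0],
                        "beta1": fit.beta_hat[1],
                        "beta2": fit.beta_hat[2],
                        "beta3": fit.beta_hat[3],
                        "se_beta2": fit.se[2],
                        "se_beta3": fit.se[3],
                        "rho_hat": fit.rho_hat if fit.rho_hat is not None else np.nan,
                        "rmse_ols": fit.rmse_ols,
                        "n_points": fit.n_points,
                        "interval_unit": fit.interval_unit,
                    }
                )
                level = standardize_effect(fit, "level_change")
                slope = slope_to_per_month(standardize_effect(fit, "slope_change"), study.interval_unit)
                for eff in (level, slope):
                    eff_rows.append(
                        {
                            "meta_id": meta_id,
                            "study_id": study.study_id,
                            "its_method": arm,
                            "estimator_used": eff.estimator_used,
                            "metric": eff.metric,
                            "estimate": eff.estimate,
                            "se": eff.se,
                        }
                    )
    return pd.DataFrame(fit_rows), pd.DataFrame(eff_rows)


def meta_analyse(
    effects: pd.DataFrame,
    directions: dict[str, str],
    meta_methods: tuple[str, ...] = META_METHOD_ORDER,
) -> pd.DataFrame:
    """Stage 2: pool standardised effects per meta-analysis x metric x arm.

    Pooled estimates (and CIs) are sign-aligned via the meta-analysis'
    beneficial direction. Returns the long results table consumed by the
    comparison suite.
    """
    rows = []
    for (meta_id, metric, arm), g in effects.groupby(["meta_id", "metric", "its_method"], sort=True):
        inp = MetaInput(
            meta_id=meta_id,
            metric=metric,
            estimates=g["estimate"].to_numpy(),
            variances=g["se"].to_numpy() ** 2,
        )
        for res in run_all_methods(inp):
            if res.meta_method not in meta_methods:
                continue
            res = apply_direction(res, directions.get(meta_id, "increase"))
            rows.append(
                {
                    "meta_id": meta_id,
                    "metric": metric,
                    "its_method": arm,
                    "meta_method": res.meta_method,
                    "model": res.model,
                    "tau2_method": res.tau2_method,
                    "ci_method": res.ci_method,
                    "estimate": res.estimate,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "ci_width": res.ci_width,
                    "p_value": res.p_value,
                    "tau2_hat": res.tau2_hat if res.tau2_hat is not None else np.nan,
                    "k": res.k,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole two-stage workflow plus the agreement battery.

    Deterministic given ``config.seed``. When ``config.outdir`` is set,
    all tables, the exclusion log and a run manifest are written there.
    """
    if config.input_csv is not None:
        data = read_repository(config.input_csv, column_map=config.column_map)
        truths = None
    else:
        repo = generate_repository(config.synth_n_meta, config.synth_template, seed=config.seed)
        frame = repo.to_frame()
        data = _repository_from_frame(frame)
        truths = repo.truths()

    filt = apply_inclusion_filters(
        data,
        zero_threshold=config.zero_threshold,
        min_points_per_segment=config.min_points_per_segment,
    )
    if not filt.included:
        raise ValidationError("no meta-analyses survived the inclusion filters")

    fits, effects = fit_studies(filt.included)
    results = meta_analyse(effects, filt.directions, config.meta_methods)
    suite = run_comparison_suite(results, meta_methods=config.meta_methods) if len(config.meta_methods) else None

    chain = fits[fits["its_method"] == "REML"]
    convergence = {
        "n_series": int(chain.shape[0]),
        "reml": int((chain["estimator_used"] == "REML").sum()),
        "pw": int((chain["estimator_used"] == "PW").sum()),
        "ols": int((chain["estimator_used"] == "OLS").sum()),
    }
    manifest = {
        "itsmeta_version": __version__,
        "seed": config.seed,
        "input": config.input_csv or f"synthetic(n_meta={config.synth_n_meta})",
        "zero_threshold": config.zero_threshold,
        "min_points_per_segment": config.min_points_per_segment,
        "meta_methods": list(config.meta_methods),
        "n_meta_included": len(filt.included),
        "n_studies_included": filt.n_included,
        "n_excluded": len(filt.exclusions),
        "convergence": convergence,
    }
    if truths is not None:
        manifest["synthetic_truths"] = True

    result = PipelineResult(
        fits=fits,
        effects=effects,
        meta_results=results,
        suite=suite,
        filter_result=filt,
        convergence=convergence,
        manifest=manifest,
        truths=truths,
    )
    if config.outdir is not None:
        _write_outputs(Path(config.outdir), result, truths)
    return result


def _repository_from_frame(frame: pd.DataFrame) -> RepositoryData:
    """Build RepositoryData from an in-memory long-format table (synthetic path)."""
    from .io import RepositoryStudy

    studies = []
    for (meta_id, study_id), g in frame.groupby(["meta_id", "study_id"], sort=True):
        g = g.sort_values("time")
        studies.append(
            RepositoryStudy(
                meta_id=str(meta_id),
                study_id=str(study_id),
                times=g["time"].to_numpy(dtype=int),
                values=g["value"].to_numpy(dtype=float),
                segments=g["segment"].to_numpy(dtype=int),
                interruption_time=int(g["interruption_time"].iloc[0]),
                interval_unit=str(g["interval_unit"].iloc[0]),
                outcome_type=str(g["outcome_type"].iloc[0]),
                beneficial_direction=str(g["beneficial_direction"].iloc[0]),
                is_control=bool(g["is_control"].iloc[0]),
            )
        )
    return RepositoryData(studies=studies, source="synthetic")


def _write_outputs(outdir: Path, result: PipelineResult, truths: Optional[dict]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(outdir / "fits.csv", index=False)
    result.effects.to_csv(outdir / "effects.csv", index=False)
    result.meta_results.to_csv(outdir / "meta_results.csv", index=False)
    if result.suite is not None:
        result.suite.estimates.to_csv(outdir / "compare_estimates.csv", index=False)
        result.suite.se_ratios.to_csv(outdir / "compare_se_ratios.csv", index=False)
        result.suite.significance.to_csv(outdir / "compare_significance.csv", index=False)
        result.suite.tau2.to_csv(outdir / "compare_tau2.csv", index=False)
        result.suite.ci_widths.to_csv(outdir / "compare_ci_widths.csv", index=False)
        result.suite.bland_altman.to_csv(outdir / "bland_altman_points.csv", index=False)
    exclusions = pd.DataFrame(
        [
            {"meta_id": e.meta_id, "study_id": e.study_id, "rule": e.rule, "detail": e.detail}
            for e in result.filter_result.exclusions
        ]
    )
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    write_manifest(outdir / "manifest.json", result.manifest)
    if truths is not None:
        write_manifest(outdir / "truths.json", truths)
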