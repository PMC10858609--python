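"""Between-method agreement battery (Bland-Altman style).

Given the long results table (one row per meta-analysis x metric x method
combination), computes for every pair of method combinations: mean
difference of pooled estimates with 95% limits of agreement,
multiplicative SE ratios from log-transformed SEs, scaled relative CI
widths, median/IQR of between-study variance differences, and agreement in
statistical significance at p = 0.05 (percent agreement and Cohen's
kappa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ALL_COMBINATIONS,
    ITS_METHOD_ORDER,
    MethodCombination,
    PairwiseComparison,
    ValidationError,
)

__all__ = [
    "mean_diff_loa",
    "log_se_ratio_loa",
    "scaled_ci_widths",
    "tau2_diff_summary",
    "significance_agreement",
    "kappa_adjective",
    "run_comparison_suite",
    "ComparisonSuite",
]


def mean_diff_loa(values_a, values_b) -> tuple[float, float, float]:
    """Mean difference a-b and 95% limits of agreement (mean +/- 1.96*SD, SD with n-1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be equal-length 1-d arrays")
    if a.size < 2:
        raise ValidationError("need at least 2 pairs")
    d = a - b
    m = float(d.mean())
    s = float(d.std(ddof=1))
    return m, m - 1.96 * s, m + 1.96 * s


def log_se_ratio_loa(se_a, se_b) -> tuple[float, float, float]:
    """Multiplicative SE ratio a/b and limits, from log-scale differences.

    SEs are log-transformed first (removing the variability-magnitude
    relationship), limits computed as for mean_diff_loa, then
    exponentiated back to ratios.
    """
    a = np.asarray(se_a, dtype=float)
    b = np.asarray(se_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("standard errors must be positive")
    m, lo, hi = mean_diff_loa(np.log(a), np.log(b))
    return float(np.exp(m)), float(np.exp(lo)), float(np.exp(hi))


def scaled_ci_widths(
    widths_ref, widths_cmp, estimates_ref, estimates_cmp, meta_ids=None
) -> pd.DataFrame:
    """Per-meta relative CI widths, scaled so the reference spans -0.5..0.5.

    Each comparison interval is centred on |est_cmp - est_ref| / width_ref
    with half-width (width_cmp / width_ref) / 2; an interval inside
    (-0.5, 0.5) therefore means the comparison CI is narrower than the
    reference. Rows are ranked by scaled width, ties broken by meta_id.
    Zero-width references are excluded and flagged.
    """
    wr = np.asarray(widths_ref, dtype=float)
    wc = np.asarray(widths_cmp, dtype=float)
    er = np.asarray(estimates_ref, dtype=float)
    ec = np.asarray(estimates_cmp, dtype=float)
    if meta_ids is None:
        meta_ids = [str(i) for i in range(wr.size)]
    if np.any(wc < 0) or np.any(wr < 0):
        raise ValidationError("CI widths must be nonnegative")
    rows = []
    for mid, w0, w1, e0, e1 in zip(meta_ids, wr, wc, er, ec):
        if w0 == 0:
            rows.append({"meta_id": mid, "scaled_width": np.nan, "center": np.nan,
                         "low": np.nan, "high": np.nan, "excluded_zero_ref": True})
            continue
        ratio = w1 / w0
        center = abs(e1 - e0) / w0
        rows.append({"meta_id": mid, "scaled_width": ratio, "center": center,
                     "low": center - ratio / 2, "high": center + ratio / 2,
                     "excluded_zero_ref": False})
    df = pd.DataFrame(rows)
    ok = df[~df["excluded_zero_ref"]].sort_values(
        ["scaled_width", "meta_id"], kind="mergesort"
    )
    df["rank"] = np.nan
    df.loc[ok.index, "rank"] = np.arange(1, len(ok) + 1)
    return df


def tau2_diff_summary(tau2_a, tau2_b) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation rule) of paired tau2 differences."""
    d = np.asarray(tau2_a, dtype=float) - np.asarray(tau2_b, dtype=float)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return float(med), float(q1), float(q3)


def kappa_adjective(kappa: float) -> str:
    if not np.isfinite(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    for hi, label in ((0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
                      (0.80, "substantial"), (1.0, "almost perfect")):
        if kappa <= hi + 1e-12:
            return label
    return "almost perfect"


def significance_agreement(p_a, p_b, threshold: float = 0.05) -> tuple[float, float, str]:
    """Agreement on the significant / non-significant dichotomy.

    Returns (percent agreement, Cohen's kappa, adjective). With degenerate
    marginals (every meta-analysis in the same cell for both methods)
    kappa is undefined and reported as NaN with 100% agreement.
    """
    a = np.asarray(p_a, dtype=float) < threshold
    b = np.asarray(p_b, dtype=float) < threshold
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("paired p-value vectors required")
    n = a.size
    n11 = int(np.sum(a & b))
    n00 = int(np.sum(~a & ~b))
    po = (n11 + n00) / n
    pe = ((np.sum(a) * np.sum(b)) + (np.sum(~a) * np.sum(~b))) / n**2
    pct = 100.0 * po
    if pe >= 1.0:
        return pct, float("nan"), "undefined"
    kappa = (po - pe) / (1 - pe)
    return pct, float(kappa), kappa_adjective(kappa)


#: Between-study variance is only defined for random-effects rows; tau2
#: comparisons run over the 4 combos of ITS arm x tau2 estimator.
TAU2_COMBINATIONS = tuple(
    MethodCombination(its, est) for its in ITS_METHOD_ORDER for est in ("DL", "REML")
)


@dataclass
class ComparisonSuite:
    """All pairwise agreement results plus Bland-Altman scatter data."""

    estimates: pd.DataFrame
    se_ratios: pd.DataFrame
    significance: pd.DataFrame
    tau2: pd.DataFrame
    ci_widths: pd.DataFrame
    bland_altman: pd.DataFrame
    comparisons: list[PairwiseComparison] = field(default_factory=list)


def _pivot(results: pd.DataFrame, metric: str, column: str) -> pd.DataFrame:
    sub = results[results["metric"] == metric]
    piv = sub.pivot_table(index="meta_id", columns=["its_method", "meta_method"],
                          values=column, aggfunc="first")
    return piv


def run_comparison_suite(results: pd.DataFrame, meta_methods=None) -> ComparisonSuite:
    """Run the full battery over the long results table.

    Expects columns: meta_id, metric, its_method, meta_method, estimate,
    se, p_value, ci_width, tau2_hat. Differences are oriented
    later-listed-combination minus earlier-listed in the canonical
    ordering (OLS block then REML-chain block; fixed, DL+WT, DL+HKSJ,
    REML+WT, REML+HKSJ within block). ``meta_methods`` restricts the grid
    to a subset of meta-analysis methods (default: all five).
    """
    required = {"meta_id", "metric", "its_method", "meta_method", "estimate",
                "se", "p_value", "ci_width", "tau2_hat"}
    missing = required - set(results.columns)
    if missing:
        raise ValidationError(f"results table missing columns: {sorted(missing)}")
    if meta_methods is None:
        combos = ALL_COMBINATIONS
    else:
        combos = tuple(c for c in ALL_COMBINATIONS if c.meta_method in set(meta_methods))
        if not combos:
            raise ValidationError(f"no known meta-analysis methods in {meta_methods!r}")
    tau2_estimators = sorted(
        {c.meta_method.split("+")[0] for c in combos if c.meta_method != "fixed"}
    )
    tau2_combos = tuple(
        MethodCombination(its, est) for its in ITS_METHOD_ORDER for est in ("DL", "REML")
        if est in tau2_estimators
    )

    est_rows, se_rows, sig_rows, tau_rows, ci_rows, ba_rows = [], [], [], [], [], []
    comparisons: list[PairwiseComparison] = []

    for metric in sorted(results["metric"].unique()):
        piv_est = _pivot(results, metric, "estimate")
        piv_se = _pivot(results, metric, "se")
        piv_p = _pivot(results, metric, "p_value")
        piv_w = _pivot(results, metric, "ci_width")
        for combo in combos:
            key = (combo.its_method, combo.meta_method)
            if key not in piv_est.columns:
                raise ValidationError(f"results table is missing combination {combo}")
            if piv_est[key].isna().any():
                bad = piv_est.index[piv_est[key].isna()][0]
                raise ValidationError(f"missing result for {combo} in meta {bad!r}")
        n = len(piv_est)

        for i, ca in enumerate(combos):
            for cb in combos[i + 1 :]:
                ka, kb = (ca.its_method, ca.meta_method), (cb.its_method, cb.meta_method)
                # orientation: later-listed minus earlier-listed
                md, lo, hi = mean_diff_loa(piv_est[kb], piv_est[ka])
                mr, rlo, rhi = log_se_ratio_loa(piv_se[kb], piv_se[ka])
                pct, kap, lab = significance_agreement(piv_p[ka], piv_p[kb])
                cmpn = PairwiseComparison(
                    combo_a=ca, combo_b=cb, metric=metric, n=n,
                    mean_diff=md, loa_low=lo, loa_high=hi,
                    mean_se_ratio=mr, se_ratio_low=rlo, se_ratio_high=rhi,
                    pct_agree=pct, kappa=kap, kappa_label=lab,
                )
                comparisons.append(cmpn)
                base = {"metric": metric, "combo_a": str(ca), "combo_b": str(cb), "n": n}
                est_rows.append({**base, "mean_diff": md, "loa_low": lo, "loa_high": hi})
                se_rows.append({**base, "mean_ratio": mr, "ratio_low": rlo, "ratio_high": rhi})
                sig_rows.append({**base, "pct_agree": pct, "kappa": kap, "label": lab})
                scaled = scaled_ci_widths(piv_w[ka], piv_w[kb], piv_est[ka], piv_est[kb],
                                          meta_ids=piv_est.index)
                scaled.insert(0, "combo_b", str(cb))
                scaled.insert(0, "combo_a", str(ca))
                scaled.insert(0, "metric", metric)
                ci_rows.append(scaled)
                d = (piv_est[kb] - piv_est[ka]).to_numpy()
                avg = ((piv_est[kb] + piv_est[ka]) / 2).to_numpy()
                ba_rows.append(pd.DataFrame({
                    "metric": metric, "combo_a": str(ca), "combo_b": str(cb),
                    "meta_id": piv_est.index, "average": avg, "difference": d,
                }))

        # tau2: restricted to ITS arm x estimator (identical for WT / HKSJ rows)
        if not tau2_combos:
            continue
        if "model" not in results.columns or "tau2_method" not in results.columns:
            raise ValidationError("results table needs model/tau2_method columns for tau2 comparisons")
        sub = results[(results["metric"] == metric) & (results["model"] == "random")]
        if sub.empty:
            raise ValidationError("results table lacks random-effects rows for tau2 comparisons")
        piv_t = sub.pivot_table(index="meta_id", columns=["its_method", "tau2_method"],
                                values="tau2_hat", aggfunc="first")
        for i, ca in enumerate(tau2_combos):
            for cb in tau2_combos[i + 1 :]:
                ka, kb = (ca.its_method, ca.meta_method), (cb.its_method, cb.meta_method)
                med, q1, q3 = tau2_diff_summary(piv_t[kb], piv_t[ka])
                tau_rows.append({"metric": metric, "combo_a": f"{ca.its_method} ITS / {ca.meta_method}",
                                 "combo_b": f"{cb.its_method} ITS / {cb.meta_method}",
                                 "n": len(piv_t), "median_diff": med, "q1": q1, "q3": q3})

    return ComparisonSuite(
        estimates=pd.DataFrame(est_rows),
        se_ratios=pd.DataFrame(se_rows),
        significance=pd.DataFrame(sig_rows),
        tau2=pd.DataFrame(tau_rows),
        ci_widths=pd.concat(ci_rows, ignore_index=True) if ci_rows else pd.DataFrame(),
        bland_altman=pd.concat(ba_rows, ignore_index=True) if ba_rows else pd.DataFrame(),
        comparisons=comparisons,
    )
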