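#!/usr/bin/env python
"""Stages 3-4: between-method agreement battery and Bland-Altman figures.

Computes, for every pair of the ten ITS x meta-analysis method
combinations: mean differences with 95% limits of agreement,
multiplicative SE ratios, scaled relative CI widths, median/IQR of tau2
differences, and significance agreement (percent + kappa). Emits tidy CSVs
and a Bland-Altman scatter grid for the level-change.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from itsmeta import run_comparison_suite

OUT = Path(__file__).resolve().parents[1] / "results"


def bland_altman_grid(points: pd.DataFrame, path: Path) -> None:
    pairs = points[["combo_a", "combo_b"]].drop_duplicates().values[:12]
    fig, axes = plt.subplots(3, 4, figsize=(16, 10), sharey=False)
    for ax, (ca, cb) in zip(axes.ravel(), pairs):
        sub = points[(points.combo_a == ca) & (points.combo_b == cb)]
        ax.scatter(sub["average"], sub["difference"], s=12, alpha=0.7)
        m = sub["difference"].mean()
        s = sub["difference"].std(ddof=1)
        for y, ls in ((m, "-"), (m - 1.96 * s, "--"), (m + 1.96 * s, "--")):
            ax.axhline(y, color="tab:orange", ls=ls, lw=1)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(f"{cb}\nvs {ca}", fontsize=7)
    fig.suptitle("Difference vs average of pooled level-change estimates")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def main() -> None:
    results = pd.read_csv(OUT / "meta_results.csv")
    suite = run_comparison_suite(results)
    suite.estimates.to_csv(OUT / "compare_estimates.csv", index=False)
    suite.se_ratios.to_csv(OUT / "compare_se_ratios.csv", index=False)
    suite.significance.to_csv(OUT / "compare_significance.csv", index=False)
    suite.tau2.to_csv(OUT / "compare_tau2.csv", index=False)
    suite.ci_widths.to_csv(OUT / "compare_ci_widths.csv", index=False)
    suite.bland_altman.to_csv(OUT / "bland_altman_points.csv", index=False)

    est = suite.estimates[suite.estimates.metric == "level_change"]
    se = suite.se_ratios[suite.se_ratios.metric == "level_change"]
    sig = suite.significance[suite.significance.metric == "level_change"]
    print(f"{len(est)} pairwise cells per metric")
    print(f"level-change mean differences: largest |mean| "
          f"{est['mean_diff'].abs().max():.3f}")
    fixed_vs_re = se[se.combo_a.str.contains("fixed") & ~se.combo_b.str.contains("fixed")]
    print(f"RE vs fixed SE ratio (level): mean of means "
          f"{fixed_vs_re['mean_ratio'].mean():.2f} (RE standard errors are larger)")
    print(f"significance agreement (level): median {sig['pct_agree'].median():.1f}% "
          f"(kappa median {sig['kappa'].median():.2f})")

    figdir = OUT / "figures"
    figdir.mkdir(exist_ok=True)
    pts = suite.bland_altman[suite.bland_altman.metric == "level_change"]
    bland_altman_grid(pts, figdir / "bland_altman_level.png")
    print(f"wrote comparison tables and {figdir/'bland_altman_level.png'}")


if __name__ == "__main__":
    main()
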