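#!/usr/bin/env python
"""Stage 2: pool the standardised effects under five meta-analysis methods.

For each meta-analysis, metric (level-change, slope-change per month) and
ITS arm, runs fixed-effect pooling plus the four random-effects
combinations (DL/REML between-study variance x WT/HKSJ intervals), with
pooled estimates sign-aligned so positive is beneficial. Writes the long
results table consumed by the comparison suite.
"""

from pathlib import Path

import pandas as pd

from itsmeta import apply_inclusion_filters, read_repository
from itsmeta.pipeline import meta_analyse

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = read_repository(OUT / "repository.csv")
    filt = apply_inclusion_filters(data)
    effects = pd.read_csv(OUT / "effects.csv")
    results = meta_analyse(effects, filt.directions)
    results.to_csv(OUT / "meta_results.csv", index=False)

    n_meta = results["meta_id"].nunique()
    print(f"pooled {n_meta} meta-analyses x 2 metrics x 10 method combinations "
          f"= {len(results)} rows -> {OUT/'meta_results.csv'}")
    level = results[(results.metric == "level_change") & (results.meta_method == "REML+WT")
                    & (results.its_method == "REML")]
    print(f"REML ITS / REML+WT level-change: median pooled estimate "
          f"{level['estimate'].median():.2f}, median tau2 {level['tau2_hat'].median():.3f}")
    sig = results[results.metric == "level_change"].groupby("meta_method")["p_value"] \
        .apply(lambda p: (p < 0.05).mean() * 100)
    print("percent of level-change results significant at p<0.05, by MA method:")
    for mm, pct in sig.items():
        print(f"  {mm:10s} {pct:5.1f}%")


if __name__ == "__main__":
    main()
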