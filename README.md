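# itsmeta

Meta-analysis of interrupted time series (ITS) studies, and a framework for
asking whether the *choice of statistical method* changes the answer.

An ITS study measures an outcome at regular intervals before and after an
interruption (a policy change, an exposure); the pre-interruption trend acts
as the counterfactual. When a systematic review collects several such
studies, a two-stage meta-analysis is standard: fit a segmented regression
per series, then pool the interruption effects. Both stages admit multiple
estimators, and reviews rarely report which was used — this package
implements the common choices side by side and quantifies how much they
agree.

## The model

Stage 1 fits, per series,

    Y_t = β₀ + β₁·t + β₂·D_t + β₃·(t − T_I)·D_t + ε_t,     D_t = 1(t ≥ T_I)

with AR(1) errors ε_t = ρ·ε_{t−1} + w_t. β₂ is the immediate level-change
and β₃ the slope-change. Three estimators are provided — OLS, iterated
Prais–Winsten, and REML with an AR(1) correlation matrix — applied via the
preference chain REML → PW → OLS (a stage falls through when the optimiser
fails or |ρ̂| ≥ 1). Effects and their standard errors are standardised by
the OLS root-mean-square error of the same series, slope-changes rescaled
to per-month units, and pooled estimates sign-aligned so positive means
beneficial.

Stage 2 pools the standardised effects per meta-analysis with
inverse-variance weights under five methods: fixed-effect, and
random-effects crossing two between-study variance (τ²) estimators
(DerSimonian–Laird; REML) with two confidence-interval methods (Wald-type
normal; Hartung–Knapp/Sidik–Jonkman with t_{K−1} quantiles, untruncated).

The comparison suite then computes, for every pair of the ten
ITS-method × meta-analysis-method combinations, Bland–Altman mean
differences with 95% limits of agreement, multiplicative SE ratios (from
log-transformed SEs), scaled relative CI widths, median/IQR of τ²
differences, and agreement in statistical significance at p = 0.05
(percent agreement and Cohen's κ).

A synthetic-data module generates single series, meta-analysis collections
with true effects drawn from N(β*, τ²), and whole repositories emulating a
published ITS corpus (17 meta-analyses; K median ~11, range 3–62; series
length median ~52, range 7–195; lag-1 autocorrelation median ~0.22), so the
entire pipeline is testable without external data.

## Worked example

```sh
$ python analysis/01_simulate_repository.py
wrote 179 series across 17 meta-analyses -> results/repository.csv
  studies per meta-analysis: median 8 (range 3-22)
  series length: median 56 (range 13-195)
  generating autocorrelation: median 0.18

$ python analysis/02_fit_series.py
eligibility: 179 series included, 0 excluded, 0 truncated
fallback chain over 179 series: REML 174, PW 5, OLS 0
median REML autocorrelation estimate: 0.18

$ python analysis/03_meta_analyse.py
pooled 17 meta-analyses x 2 metrics x 10 method combinations = 340 rows
percent of level-change results significant at p<0.05, by MA method:
  DL+HKSJ     35.3%
  DL+WT       52.9%
  REML+HKSJ   38.2%
  REML+WT     50.0%
  fixed       55.9%

$ python analysis/04_compare_methods.py
45 pairwise cells per metric
level-change mean differences: largest |mean| 0.027
RE vs fixed SE ratio (level): mean of means 1.32 (RE standard errors are larger)
significance agreement (level): median 82.4% (kappa median 0.64)
```

Reading the output: most series converge under REML and the handful that do
not fall back to Prais–Winsten; random-effects standard errors are ~30%
larger than fixed-effect ones because the between-study variance is usually
estimated above zero; and the HKSJ interval's t-quantiles make fewer
results significant than Wald-type intervals (35–38% vs 50–56%), exactly
the kind of method sensitivity the agreement battery is built to expose.
Pairs of method combinations typically agree on significance for ~82% of
meta-analyses (κ ≈ 0.64, "substantial").

The same workflow is available as a CLI (`itsmeta simulate|fit|meta|compare|run`)
and as a single call:

```python
from itsmeta import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(synth_n_meta=17, seed=1))
result.suite.estimates          # 45 pairwise limits-of-agreement cells per metric
```

Real data are read from a long-format CSV (one row per time point) with
columns `meta_id, study_id, time, interval_unit, interruption_time,
segment, value, outcome_type, beneficial_direction[, is_control]`; a
`column_map` argument adapts other layouts. Eligibility filters (≥3 points
per segment, ≤40% zero values — strict inequality, first interruption only,
controls removed) are applied with a full exclusion log.

## Layout

- `src/itsmeta/` — the library: `synth`, `itsfit`, `standardize`, `meta`,
  `compare`, `io`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — unit, property and end-to-end statistical tests
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
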