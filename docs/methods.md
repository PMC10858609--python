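# Methods

## Stage 1: segmented regression per series

Each ITS series is modelled as

    Y_t = β₀ + β₁ t + β₂ D_t + β₃ (t − T_I) D_t + ε_t,   D_t = 1(t ≥ T_I),

for t = 1..T in unit steps of the series' aggregation interval, with AR(1)
errors ε_t = ρ ε_{t−1} + w_t, w_t ~ N(0, σ_w²). The series must carry at
least three points on each side of the interruption, so the four-column
design is always full rank. Outcomes of any type (counts, rates,
proportions) are treated as continuous; no link function or count
likelihood is fitted.

Three estimators:

- **OLS** — ordinary least squares with conventional standard errors;
  residual variance uses the T−4 denominator. Its residual RMSE,
  `rmse_ols = sqrt(RSS/(T−4))`, is the standardisation scale for *all*
  estimators of the same series.
- **Prais–Winsten (PW)** — iterated feasible GLS. Lag-1 autocorrelation is
  estimated from original-scale residuals as
  ρ̂ = Σ_{t≥2} e_t e_{t−1} / Σ_t e_t² (the estimator is fixed here because
  several variants exist; this one makes the iteration reproducible
  bit-for-bit). The data are whitened — first row scaled by √(1−ρ̂²), later
  rows quasi-differenced — and refitted until |ρ̂_i − ρ̂_{i−1}| < 1e−6
  (max 100 iterations). Non-convergence, or any iterate with |ρ̂| ≥ 1, is
  flagged, not raised.
- **REML with AR(1) errors** — the restricted likelihood of the model with
  correlation matrix R_ij = ρ^|i−j| is profiled over ρ: because the
  Prais–Winsten transform P satisfies P R Pᵀ = (1−ρ²) I, all R⁻¹ quadratic
  forms reduce to transformed least squares and −2·profile-loglik is
  (T−4)·log RSS_t − log(1−ρ²) + log|X̃ᵀX̃| up to a constant. A 39-point
  grid on (−0.95, 0.95) followed by bounded scalar minimisation guards
  against local optima. β̂ is the GLS estimate at ρ̂ with covariance
  σ̂²(XᵀV⁻¹X)⁻¹ using the REML (T−4 denominator) variance. A maximiser
  pinned at the ρ boundary (|ρ̂| ≥ 0.99) is declared non-converged.

The analysis arm labelled "REML" applies the preference chain
REML → PW → OLS; OLS always succeeds, so the chain never fails. Each fit
records which estimator actually produced it. No small-sample
degrees-of-freedom correction (e.g. Satterthwaite) is applied to the
stage-1 standard errors; users comparing against software that applies one
should expect slightly narrower SEs here for short series.

Noiseless series (zero residual RMSE) are a degenerate case: the fits
return exact coefficients with zero SEs, and standardisation refuses them
with an instruction to exclude the series.

## Standardisation

Level- and slope-change estimates (and SEs) are divided by `rmse_ols`,
giving effects in residual-SD units comparable across outcomes. Slope
changes are converted to per-month units with factor
(days per month)/(days per interval), using 1 month = 365.25/12 = 30.4375
days: per-year slopes are divided by 12, per-day slopes multiplied by
30.4375, per-4-week slopes by 30.4375/28. The month-length convention is a
declared choice (configurable via `days_per_month`); only the year→month
factor is canonical. Finally, pooled estimates for meta-analyses where a
*decrease* is beneficial are multiplied by −1 (CI limits swap and negate;
SEs, p-values and τ² untouched), so positive always means beneficial. The
flip is applied at the meta-analysis level, after pooling.

## Stage 2: meta-analysis

With standardised effects β̂_k and within-study variances v_k = se_k²,
pooling is the weighted mean Σ W β̂ / Σ W with variance 1/Σ W.

- Fixed-effect: W_k = 1/v_k, normal-quantile CI (the reference distribution
  for the fixed-effect interval is a declared choice; normal is standard).
- Random-effects: W_k = 1/(v_k + τ̂²), with τ̂² from either the
  DerSimonian–Laird moment estimator
  τ̂² = max(0, (Q − (K−1)) / (ΣW − ΣW²/ΣW)) (fixed-effect weights), or
  REML, maximising the restricted log-likelihood
  −½[Σ log(v_k+τ²) + log ΣW + Σ W(β̂_k−μ̂)²] over τ² ∈ [0, 10·τ̂²_DL + 1]
  with a bounded scalar optimiser (xatol 1e−8, ≤100 iterations; DL fallback
  with a warning on failure).
- Intervals: Wald-type (WT) normal quantiles on se = √(1/ΣW), or HKSJ with
  se²_HKSJ = Σ W(β̂_k−μ̂)² / ((K−1) ΣW) and t_{K−1} quantiles. The HKSJ
  adjustment is deliberately **untruncated** (no q ≥ 1 floor): that is what
  allows HKSJ intervals to be narrower than WT when there are few studies
  and τ̂² = 0, a behaviour the comparison suite checks for. With K small
  and the DL estimator, narrower-HKSJ cases can in principle also arise at
  larger K (t ≈ z there), which is why the width-ordering test is run in
  the few-studies regime where the clean dichotomy holds.
- All p-values are two-sided; the level is fixed at 95%.

Identical effects give a degenerate zero-width HKSJ interval; the result is
flagged rather than patched.

## Comparison suite

Differences are oriented later-minus-earlier in the canonical combination
order (OLS block before the REML chain; fixed, DL+WT, DL+HKSJ, REML+WT,
REML+HKSJ within a block); the opposite orientation follows by
antisymmetry. Limits of agreement are mean ± 1.96·SD of the paired
differences with the n−1 SD denominator (a declared choice). SE ratios are
computed on the log scale and back-transformed. Scaled CI widths divide
the comparison width by the reference width, centring each interval on
|Δestimate|/width_ref, so an interval inside (−0.5, 0.5) means a narrower
comparison CI. τ² comparisons run over the four ITS-arm × τ²-estimator
combinations; quartiles use linear interpolation (type-7). Cohen's κ on
the p < 0.05 dichotomy is reported with the conventional adjectives
(0.41–0.6 moderate, 0.61–0.8 substantial, 0.81–1.0 almost perfect); with
degenerate marginals (all meta-analyses in one cell for both methods) κ is
undefined and reported as NaN alongside 100% agreement, rather than
imputed.

## Synthetic data

The generator mirrors the structure the analysis assumes, at three levels:

1. **Series**: exact segmented mean plus stationary AR(1) noise
   (ε₁ drawn with marginal SD σ_w/√(1−ρ²), so the variance is homogeneous
   along the series — the standard stationarity assumption, rather than
   ε₁ = w₁).
2. **Meta-analysis**: per-study true effects β*_m + δ_k, δ_k ~ N(0, τ²_m),
   drawn independently for level and slope. The between-study correlation
   of the two effect types is not modelled (no published value to emulate);
   the draws are independent by default.
3. **Repository**: K per meta-analysis log-normal with median 11 clipped to
   [3, 62]; series length log-normal with median 52 clipped to [7, 195];
   ρ normal (mean 0.22, SD 0.28) clipped to (−0.5, 0.92); interruption
   uniform in the middle 30–70% of the series; aggregation intervals drawn
   ~65% month / 24% year / 6% 4-week / 6% day; per-meta mean effects
   N(0.5, 0.25²) for level and N(0.03, 0.03²) per interval for slope;
   τ²_level = 0.05, τ²_slope = 0.0025; beneficial direction a fair coin.
   These defaults emulate the spread of a published corpus of 17 ITS
   meta-analyses (282 series).

One repository seed spawns per-meta and per-study child seeds via
`SeedSequence`, so any subset regenerates identically. Sampling noise
enters only through the series-level AR(1) errors: there is no
participant-level layer, no seasonality, no count/rate generative model,
and only a single interruption — so passing tests demonstrate correctness
of the estimators under the assumed model, not robustness to real-data
features the model omits (model misfit, confounding, non-normal errors).

## Eligibility filters

Applied in order per series: control series dropped; multi-interruption
series truncated to the points before the second interruption (segments 1
and 2); series with strictly more than 40% exactly-zero values excluded
(exactly 40% is retained); series with fewer than three points on either
side of the interruption excluded; meta-analyses left with fewer than two
studies dropped. The sensitivity mode tightens the zero rule to a strict
30% threshold. Every exclusion is logged with its rule; counts always
balance (included + excluded = input).

## Problem sizes used in the test-suite experiments

- CI coverage: K = 10, τ² = 0.05, known within-study variances
  v_k ∈ [0.05, 0.3] (the regime of standardised level-changes from
  medium-length series), 2000 replicates.
- Parameter recovery: 200 replicate repositories of 2 meta-analyses,
  K = 11, T = 500, ρ = 0, σ_w = 1, mid-series interruptions. Long
  uncorrelated series make the standardised scale coincide with the
  generating scale and keep within-study variance (~0.03) below
  τ² = 0.05, so the truncation-at-zero bias of τ̂² stays well inside the
  Monte-Carlo tolerance; with short series that bias is a property of the
  estimators, not of the implementation.
- PW whitening and REML-ρ̂ consistency are checked as replicate means
  (100 and 500 series), since the single-series statistics carry
  irreducible O(1/√T) sampling noise.
- The method-indifferent (null) regime: ρ = 0, T = 120, τ² = 0, K = 12,
  17 meta-analyses — there the ITS estimator choice must not matter, and
  the suite's between-ITS cells are required to be null.

## Known limitations

- Only lag-1 autocorrelation; no higher-order or seasonal error structure.
- All outcomes treated as continuous; no confounder adjustment.
- No prediction intervals for the random-effects models.
- No small-sample df correction for stage-1 REML standard errors.
- Agreement statistics are descriptive; no inference (CIs) on κ or the
  limits of agreement themselves.
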