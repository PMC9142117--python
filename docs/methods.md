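# Methods

This note documents the statistical procedures, the synthetic-data design,
and the numerical and design choices made where more than one defensible
option existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Study design being emulated

The pipeline reproduces the structure of an ecological (area-level) analysis
of emergency-department use by uninsured adults. The unit of analysis is the
ZIP Code Tabulation Area (ZCTA). Inputs are (a) an area covariate table —
annual populations aged 18–64 for two study years plus survey-derived
percentage covariates — and (b) an episode-level ED encounter table. The
stages are:

1. **Inclusion filtering.** Keep encounters billed to an uninsured payer
   (self-pay or indigent/charitable organization) by adults aged 18–64 with
   a valid area label.
2. **Condition selection and rates.** Tabulate minor-diagnostic-category
   labels, keep the top *k* (default 15), and compute the two-year visit
   rate per 1000: `1000 · visits / (pop_year1 + pop_year2)`.
3. **LTU index.** Model the area uninsured share from five deprivation
   covariates, score every area in (0, 1), rank into quintiles Q1–Q5.
4. **Association.** Per condition, OLS of the rate on quintile indicators
   Q2–Q5 (Q1 reference) plus covariates, HC1 sandwich inference.
5. **Counterfactual.** Predict every area's rate with quintile indicators
   reset to Q1, covariates fixed; aggregate to mean rates and visit counts.

## 2. The LTU propensity model

The source analysis calls the index model "a logistic regression" without
stating its binary outcome; at the area level no binary outcome exists. Two
readings are implemented, selected by `spec=`:

- **`fractional` (default):** fractional-response logistic regression. The
  outcome is the uninsured share (0–1); the mean is `logit⁻¹(x'β)`; fitting
  is binomial quasi-likelihood via IRLS (statsmodels GLM), capped at 100
  iterations with deviance tolerance 1e-8. This is the default because the
  uninsured rate is the only index variable that can plausibly play the
  outcome role, and fractional logit is the standard model for a proportion
  outcome.
- **`median-binary`:** a conventional logistic fit of the indicator
  "uninsured share above the sample median".

Predictors are the remaining five index covariates: % Hispanic, % with less
than high-school education, % unemployed (16+), % non-family households,
% below 200% of the federal poverty level. The "minority" construct is
ambiguous in the source material (Hispanic share vs Black share vs both);
the generator emits all race/ethnicity fields and the predictor tuple is an
argument of `fit_propensity`, so either reading is one call away. Constant
or collinear predictors raise a degeneracy error naming the column rather
than silently dropping it.

**Quintile rule.** Areas are sorted by (score, zcta_id) ascending and split
into five groups whose sizes differ by at most one, any remainder allocated
to the *lowest* quintiles first (392 areas → 79, 79, 78, 78, 78). The
published group sizes (80, 78, 79, 77, 78) follow no stated deterministic
rule, so a documented reproducible rule is used instead. The id tie-break
makes the assignment invariant to input order; a warning is emitted when
tied scores straddle a group boundary.

## 3. Regression and inference

Per condition the design is: intercept, Q2–Q5 indicators, and eight
covariates (% white, % Black, % < high school, poverty share, unemployment,
% delayed care due to cost, % no usual source of care, % obese). The
tooth-disease condition adds the county dentist ratio per 1000 and % with no
dental visit. Rows are sorted by area id; zero-visit cells enter with rate 0
(dense panel), so every condition is fit on the full set of areas.

"Robust variance" is implemented as **HC1**,
`(n/(n−k)) (X'X)⁻¹ X' diag(e²) X (X'X)⁻¹`, the common default of
survey-oriented statistical software; HC0 and HC3 are available via
`cov_type=`. Note HC1 equals the HC0 sandwich scaled by `n/(n−k)` always,
and collapses exactly to the classical OLS variance when all residuals share
one magnitude — both relations are asserted in the tests. p values and 95%
CIs use the t distribution on n−k degrees of freedom. R², adjusted R² and
the overall F are classical sums-of-squares quantities. Two-sided p values;
no multiple-testing correction is applied, matching the emulated analysis.

One percentage scale (0–100) is used for all covariates by default, with a
`fraction` option; the source tables mix scales across covariates, so no
attempt is made to match their covariate coefficient magnitudes numerically.
The poverty measure is stored as `pct_below_200fpl` (below 200% of the
poverty line, the index definition) even though the descriptive tables label
it "below poverty level"; one column serves both roles.

## 4. Counterfactual simulation

The source text replaces quintiles "Q2–Q4" in one sentence and "all ZCTAs"
(i.e. Q2–Q5) in the results table; only the Q2–Q5 reading is arithmetically
consistent with the reported totals, so **q2q5 is the default** and `q2q4`
is a flag. Predictions are floored at 0 (rates are nonnegative).

- **Status-quo mean rate:** unweighted mean of observed area rates, CI
  `mean ± t₀.₉₇₅,ₙ₋₁ · SD/√n` — unweighted to match the unweighted
  regression.
- **Simulated mean rate:** unweighted mean of counterfactual predictions;
  its CI is a delta-method interval from the fit's robust covariance,
  `SE = √(a'Va)` with `a` the column means of the counterfactual design and
  t critical value on n−k degrees of freedom. The source does not state how
  its simulated CI was formed; the delta method is this package's choice.
- **Visit counts:** `round(Σ_z rate_z · pop2yr_z / 1000)`, each area
  weighted by its own two-year population, rounded half away from zero once
  on the grand total. Observed rates therefore convert back to the exact
  filtered visit totals (the float error before rounding is ~1e-13 of a
  visit for realistic counts, far below the half-unit threshold).
- **Significance flag:** true iff the two 95% intervals are disjoint —
  a conservative screen, as interval overlap does not equal a formal test.

The change columns are derived in a separate `finalize_report` step from the
mean/count columns, so the arithmetic can be verified on externally supplied
values.

## 5. The synthetic-data generator

**What it emulates.** A state-like region of 392 areas (default) whose
covariates follow published quintile-stratified means and SDs, and an
encounter stream in which qualifying uninsured-adult visits are the count
expansion of a per-area Poisson law. Generation is latent-quintile-first:
the latent quintile is drawn (near-equal partition, remainder to the lowest
quintiles), covariates are drawn `N(mean_q, sd_q)` clamped to [0, 100]
(ratio fields to [0, ∞)), and for each condition the expected rate is

    η_zc = intercept_c + effect_c[q(z)] + slopes'x_z + N(0, residual_sd),

truncated at 0, with counts `Poisson(η · pop2yr/1000)`. Annual populations
are uniform integers in `population_range` (default 500–14,000, giving
area populations of the order observed in a southeastern US state).

**Calibration defaults.** Ten covariates use published stratified
means/SDs; the uninsured, Hispanic and non-family rows have no published
stratified values and use plausible monotone gradients (e.g. uninsured
14→28% across quintiles, SD ≈ 4). Condition intercepts are the published
Q1 mean rates; the Q2–Q5 offsets are the published regression effects; the
covariate slopes default to 0 (the published covariate coefficients mix
scales and cannot be planted coherently); `residual_sd` defaults to 2.0
per 1000 — roughly the median within-quintile rate SD net of count noise —
so that observed rate SDs land in the published 2–7 range for mid-size
areas. For the contusions condition, which lacks a published Q1 mean, the
intercept is set to its simulated mean rate (7.4), consistent with its
near-zero quintile effects.

**Noise records.** `round(K·f/(1−f))` additional records (f =
`noise_fraction`, default 0.739 — the published flow kept 1,062,418 of
4,076,200 visits) are appended, each violating exactly one inclusion
criterion: an insured payer, an age outside 18–64, or the `invalid` area
sentinel. Three independent RNG streams (covariates, counts, noise) are
spawned from the single seed, so adding noise never perturbs the covariate
or count draws; `draw_rate_panel` shares the count stream and therefore
produces exactly the panel that record expansion plus filtering would.

**What it does not emulate — and what passing tests show.** Covariates are
independent Gaussians given the quintile (real deprivation covariates are
mutually correlated and skewed); rates have no spatial autocorrelation;
there are no ICD codes, charges, patient identities or repeat visitors;
"valid area" is simple membership in the covariate table. Passing tests
therefore demonstrate that the *estimators and plumbing* are correct under
the planted model — unbiased coefficient recovery, nominal robust-CI
coverage, exact filter accounting — not that the substantive published
effect sizes are recoverable from real data.

**Attenuation is expected, not a defect.** Effects are planted on *latent*
quintiles, but the pipeline regresses on quintiles re-estimated from noisy
covariates. Under the default calibration roughly half the areas land in
exactly their latent quintile (Rand index ≈ 0.76), so pipeline coefficient
estimates are attenuated relative to truth — classical errors-in-exposure
behavior. The acceptance script reports the abdominal-pain Q3 coefficient
under both the pipeline quintiles and the latent oracle quintiles to make
the attenuation visible; the Monte-Carlo calibration test uses the latent
quintiles, where coverage is nominal.

## 6. Numerical choices and degenerate inputs

- Exclusion attribution order is fixed (payer → age → area), one bucket per
  record, plus an "unparseable" bucket for unknown payer codes, null or
  negative ages, and null area labels; the tally identity
  `input = kept + Σ exclusions` is property-tested.
- Condition ranking ties break by label ascending; quintile score ties by
  area id.
- Rank deficiency is detected via `numpy.linalg.matrix_rank` before fitting
  and reported with QR-based candidate columns; an all-zero column is an
  error, never a silent drop.
- Perfect fits (zero residuals) report robust SEs of 0, R² = 1 and an
  infinite F statistic rather than dividing by zero.
- Problem sizes in the test suite: unit fixtures use 40–150 areas with
  annual populations of 500–9,000; the Monte-Carlo calibration uses 500
  replicates at the full 392 areas via the count-level fast path. The whole
  suite runs in well under a minute.

## 7. Known limitations

- The fractional-logit outcome is itself a survey *estimate* of the
  uninsured share; its sampling error is ignored, as in the emulated
  analysis.
- The delta-method CI for the simulated mean ignores the uncertainty of the
  quintile classification itself (conditioning on the assignment), and no
  bootstrap is offered.
- Episode-level analysis counts visits, not patients; frequent ED users are
  counted once per visit.
- The generator's defaults aim at structural realism (gradients, scales,
  filter shares), not at reproducing any particular published coefficient
  table, which mixed covariate scales irreproducibly.
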