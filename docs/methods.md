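# Methods

This note documents the statistical model behind `promiss`, the synthetic
cohort it is validated against, the numerical choices, and what the tests do
and do not establish.

## 1. Missingness magnitude and strata

The core statistic is the normalized missing count per protein per stratum,
`alpha = missing_count / n_samples`, computed as an exact ratio. Strata are
the levels of one of two axes: collection time point (baseline, 3 m, 6 m)
or disease-activity group (HD = high, 2HD = secondary high — low at 3 months
but worsening by 6 — LD = low). Denominators are always the per-stratum
sample counts, which is why samples present in exactly one of matrix or
metadata are a hard error: silently dropping them would corrupt alpha. A
stratum with no samples yields *no* alpha row (undefined), never 0 — a zero
would fabricate evidence of complete observation.

Values in the matrix may be on any monotone scale; nothing in the profiling
stages transforms them. Only the LOD assessment takes logs, and it does so
itself (natural log; the base only rescales and cannot change a Pearson
correlation). Zero is a legitimate observed measurement and is never
conflated with missingness; on disk, missing cells are the empty string or
`NA` by default (configurable token set).

## 2. Observation threshold

The default filter retains proteins observed in at least `ceil(0.10 · N)` of
the N samples. With N = 149 this is ≥ 15 observations. Descriptions of this rule in
practice mix a ">10 % of samples" phrasing with a ">15 observations"
parenthetical, which conflict at N = 149 (10 % of 149 = 14.9); the
ceiling-of-the-fraction reading is the default, and the strict
count variant is available via `ThresholdSpec("min_observed_count", 16)`.
Threshold comparisons use a 1e−9 guard so an exact multiple (e.g. 0.5 × 10)
is not pushed over the ceiling by float representation error.

## 3. Cross-stratum correlation and confidence intervals

Per-protein alpha vectors from two strata are compared with the sample
Pearson correlation; the 95 % interval is the Fisher-z interval
`tanh(atanh(r) ± z_{0.975}/√(n−3))`. `atanh` is capped at ±20 so r = ±1
degenerates to a (±1, ±1) interval instead of overflowing. Correlations on
vectors with variance below 1e−12, or with n < 4, are *undefined* and raise
(they are never reported as 0). The implementation is validated against
scipy's `pearsonr` confidence interval (same transform) and against a set
of reference (r, n) → CI pairs reproduced to two decimals.

Correlations are computed on alpha by default; a `missing_count` mode exists
for sensitivity checks (raw counts conflate stratum size with missingness,
so alpha is the primary scale).

## 4. Residual-band outlier detection

Outliers between a stratum pair (a, b) are defined against the OLS fit of
alpha_b on alpha_a over all proteins: a protein is flagged when
`|alpha_b − fitted| > k · SD(residuals)`. This replaces a visual
"band parallel to the regression line" with a reproducible rule; k = 2.5 is
a default chosen so the null flag rate approximates the two-sided normal
tail mass (~1.2 %), not a published value, and an absolute alpha half-width
is available instead. Design choices:

* plain OLS of y on x, not orthogonal regression — it matches a plotted
  regression line; an orthogonal option is future work;
* `direction` reports which stratum carries excess missingness (positive
  residual → stratum b);
* a degenerate fit (no variance in x) warns and fits a horizontal line; a
  1e−10 tolerance on the band keeps exactly-collinear data unflagged;
* binomial noise in alpha is heteroscedastic (largest near alpha = 0.5), so
  mid-range proteins are slightly over-flagged relative to the pooled SD;
  this is the main driver of the screen's imperfect recall (below).

The candidate screen keeps proteins flagged in at least one disease-group
comparison and in no time-point comparison: group-dependent but time-stable
missingness.

## 5. LOD assessment

Left-censoring at the instrument's limit of detection would make missingness
a function of abundance. The assessment correlates each protein's mean
natural-log abundance over its *observed* cells with its missing count
(Fisher-z CI as above), overall or within one stratum. Proteins with no
observed cells in scope are excluded and listed. A complete matrix has zero
variance in missing counts and reports an explicitly undefined correlation.

## 6. Batch adjustments

Four batch-aware rescalings of the per-stratum missingness are provided,
with B = the number of batches containing at least one sample of the
stratum: (1) alpha / total samples in those batches; (2) alpha / (mean
stratum samples per contributing batch × B) — the product equals the stratum
sample count; (3) raw missing count over the same denominator, which
recovers alpha itself; (4) alpha / B. The printed formulas these implement
are ambiguous ("frequency × count of batches"); this is one concrete,
documented reading that keeps the four schemes distinct as formulas. All
four are stratum-constant positive rescalings of alpha, so OLS residual
ranks and band flags are structurally invariant — `batch_sensitivity`
reports the Jaccard overlap of flag sets (1.0 up to band-edge effects) and,
alongside, each group's batch span, which is where genuine group–batch
confounding (e.g. one group confined to two batches) is visible.

## 7. ML confirmation

The outcome is 6-month disease activity encoded low = 0 vs high = 1, with
2HD counted as high (its activity worsens by 6 months). Features are the
quantification values of one time point (default baseline) with missing
cells set to zero — used *only* here, and deliberately: zero-imputation
converts group-dependent missingness into group-dependent means, which is
how an informative-missingness protein becomes learnable by a
complete-data classifier. Pipeline ordering guarantees profiles are
computed before any imputation.

Selection: univariate |Pearson r| ≥ 0.3 against the outcome (point-biserial
on the 0/1 encoding; zero-variance features are excluded with a warning),
then greedy redundancy pruning of pairs with |r| > 0.75 — the member of the
worst pair with the larger mean absolute correlation to the other survivors
is dropped, ties broken by lexicographically larger name, making the result
order-independent. Recursive feature elimination then ranks features under
a Random Forest (500 trees by default; repeated stratified 5 × 5-fold CV):
within each training fold the least-important quarter is dropped
iteratively, a fresh forest is scored on the held-out fold at each candidate
subset size (powers-of-two grid), and the size with the best mean accuracy
(smaller on ties) is refit on all data for the final importance-ordered
subset. Everything is deterministic given the seed in `FeatureSelectionSpec`. The resampling
plan and forest size are deliberate defaults, not canonical values.

## 8. Synthetic cohort generator

The generator emulates the study conditions so every downstream stage has
ground truth: 12 HD / 20 2HD / 32 LD participants; whole samples retained
per time point to totals 58/47/44 (proportional allocation across groups by
largest remainder, then seeded sampling within group); each participant's
samples run in a single batch, with batch pools giving HD a span of 2
batches, 2HD 8 and LD 10 out of 12.

Missingness probability per cell is additive-clamped across mechanisms:

```
p = clamp(propensity_i + lod_i + delta_t, 0, 1)        background proteins
p = rate_g                                             planted informative proteins
p = u_i ~ U(0.92, 0.995)                               rarely-detected block
```

* `propensity_i` — a time-stable per-protein level drawn from a Beta
  distribution with SD 0.26. This broad, right-skewed spread (substantial
  mass near 0, i.e. near-complete proteins) is what makes alpha correlate
  strongly across time points; a single shared missingness rate would leave
  the cross-time correlation noise-dominated, contradicting the reproducible
  missingness the analysis relies on.
* `lod_i = lod_strength · expit(−(mu_i − c)/s)` — a logistic left-censoring
  term in the protein's mean log abundance, centred one abundance-SD below
  the mean (c) with width s = 0.5 SD. The default strength 0.40 targets an
  abundance–missingness correlation of ≈ −0.37 on the post-filter matrix;
  strength 0 removes the abundance link entirely, and the correlation is
  monotone in the strength.
* `delta_t` — per-time-point offsets solved by bisection so the mean
  probability over background proteins equals the configured rates
  0.39/0.31/0.30. Two passes: after a first solve, proteins whose expected
  missingness exceeds ~0.9 (which the observation filter would remove) are
  dropped and the offsets re-solved, so the configured rates describe the
  *analysis* population, as the reported percentages do.
* planted proteins use the configured per-group rates (defaults LD 0.76,
  HD 0.32, 2HD 0.30) exactly and constant in time — group-dependent,
  time-stable missingness, the pattern the screen is built to find. Eight
  are planted by default (~1.5 % of analysis proteins).
* the rarely-detected block (742 − 565 = 177 proteins, drawn 2 log-units
  lower in abundance) emulates the inflated low-observation mode that the
  observation filter removes.

Observed cells carry log-normal abundances (per-protein mean drawn from
N(14, 1.5²) in log units, within-protein SD 0.5 — arbitrary intensity
units; log-normal is
a modelling choice, not an empirical fit). The truth object stores the full protein × sample
probability matrix, so every downstream recovery test has an exact oracle.
A single `numpy` Generator seeded from the config drives all draws; the
pipeline derives the simulator and ML seeds from its one top-level seed.

What the generator does **not** model: peptide-level structure and roll-up,
retention-time/m-z effects, duplicate-injection CV filtering, correlated
missingness between proteins (cells are independent Bernoulli given p),
batch-driven dropout, and abundance differences between outcome groups
(only missingness separates groups). Passing tests therefore show that the
pipeline recovers group-dependent missingness under these idealized
conditions — not that it would overcome correlated or batch-confounded
missingness in real data.

Realized emulation under the defaults (20 seeds): ~515–540 of 742 proteins
pass the filter (the target population is ~565; the Beta propensity tail
pushes some background proteins under the observation cut), per-time-point
missingness within ±0.01 of target, cross-time correlations ≈ 0.90–0.93
and cross-group correlations strictly below them in every seed, abundance–
missingness correlation ≈ −0.37. Cross-time correlations sit slightly below
the ~0.95 seen in real data because the filter truncates the propensity
spread; the qualitative ordering, which the analysis depends on, is
preserved.

## 9. Problem sizes in tests and the acceptance script

Recovery metrics average 20 seeded default cohorts (cheap stages). The
threshold-ordering check and confirmation-stage tests use a reduced
resampling plan (1 × 5-fold, 60–80 trees) and, where iteration over many
seeds is needed, a scaled-down cohort (120–300 proteins); these sizes are
the package's validation defaults and are configurable upward. The
acceptance script reports means over 20 cohorts for structural metrics and
3 cohorts for the ML accuracies.

## 10. Known limitations

* The residual band assumes homoscedastic residuals; a variance-stabilizing
  (e.g. arcsine-square-root) transform of alpha before fitting would reduce
  the mid-range over-flagging and is a natural extension.
* Scheme-level batch adjustments cannot, by construction, change outlier
  flags; detecting batch-driven dropout requires protein-level batch
  information (e.g. which batches carry a protein's missing cells).
* The ML stage's univariate filter uses Pearson on the 0/1 outcome; a rank
  correlation variant is not implemented.
* Candidate proteins are discoveries for validation, not validated
  biomarkers; with 2.5-SD bands, roughly 1–2 % of background
  protein-comparisons are flagged by chance.
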