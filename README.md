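# promiss — missingness as a biomarker in DIA/SWATH proteomics

`promiss` treats the *pattern of missing values* in a data-independent-acquisition
(SWATH-MS) protein quantification matrix as a measurement in its own right.
In longitudinal cohort studies, a protein that is reproducibly **missing** in
one outcome group and reproducibly **present** in another is informative
("biologically missing", a subclass of missing-not-at-random), yet standard
workflows impute or discard it. This package provides a tested pipeline for
discovering such proteins, aimed at proteomics/biomarker researchers who have
a protein × sample relative-quantification matrix (e.g. MSstats output) plus
per-sample metadata (participant, time point, outcome group, batch).

## The statistic and the screen

For protein *i* in stratum *s* (a collection time point — baseline / 3 m /
6 m — or a disease-activity group — HD / 2HD / LD), the magnitude of
missingness is the normalized missing count

```
alpha_i(s) = (# missing values of protein i in s) / (# samples in s)
```

The pipeline then:

1. **Filters** proteins observed in fewer than 10 % of all samples
   (`observed ≥ ceil(0.10 · N)`; threshold configurable).
2. **Correlates** the per-protein α vectors between strata (Pearson *r* with
   a Fisher-z 95 % CI, `tanh(atanh r ± z₀.₉₇₅/√(n−3))`). Strong cross-time
   correlation (technique reproducibility) licenses reading cross-group
   deviations as biology.
3. **Flags outliers** per stratum pair: OLS of α_b on α_a over all proteins,
   flag `|residual| > k · SD(residuals)` (default k = 2.5) — an algorithmic
   version of the "band parallel to the regression line" read off a scatter
   plot.
4. **Screens across axes**: candidate biomarkers are proteins flagged in ≥ 1
   disease-group comparison and 0 time-point comparisons (group-dependent,
   time-stable missingness).
5. **Supporting checks**: a limit-of-detection assessment (corr between mean
   log abundance over observed cells and missing count — weakly negative
   means missingness is not mere left-censoring) and four batch-aware
   rescalings of α with a Jaccard report of flag stability.
6. **ML confirmation**: zero-impute missing cells, drop features with
   |r| < 0.3 against the low/high 6-month outcome and pairs with mutual
   |r| > 0.75, then repeated cross-validated recursive feature elimination
   under a Random Forest.

A seeded synthetic cohort generator (`promiss.simulate`) reproduces the
study conditions — 64 participants (12 HD / 20 2HD / 32 LD), 58/47/44
samples over three time points, 742 proteins with a rarely-detected block,
~39/31/30 % missingness, a weak abundance–missingness correlation ≈ −0.37,
12 batches with group–batch imbalance, and planted group-dependent proteins —
and returns the exact per-cell missingness probabilities as ground truth.

## Worked example

```python
from promiss import (SimulationConfig, simulate, apply_threshold, profile,
                     correlate_axis, lod_assessment, BandSpec, cross_axis_screen)
from promiss.correlation import all_outlier_reports

matrix, meta, truth = simulate(SimulationConfig(seed=0))
filtered, removed = apply_threshold(matrix)
print(f"{matrix.n_proteins} proteins -> {filtered.n_proteins} after the 10%-observations filter")

prof_t = profile(filtered, meta, "timepoint")
prof_g = profile(filtered, meta, "group")
for c in correlate_axis(prof_t, "timepoint") + correlate_axis(prof_g, "group"):
    print(f"{c.stratum_a:>8} vs {c.stratum_b:<8} r={c.r:.2f}  CI=({c.ci_low:.2f}, {c.ci_high:.2f})")

lod = lod_assessment(filtered)
print(f"LOD check: r={lod.r:.2f}  CI=({lod.ci_low:.2f}, {lod.ci_high:.2f})")

rep_g = all_outlier_reports(prof_g, "group", BandSpec(k=2.5))
rep_t = all_outlier_reports(prof_t, "timepoint", BandSpec(k=2.5))
cand = cross_axis_screen(rep_g, rep_t, prof_g)
planted = set(truth.informative_protein_ids)
print(f"candidates: {len(cand)}; planted informative proteins recovered: "
      f"{sum(p in planted for p in cand.protein_id)}/8")
```

prints

```
742 proteins -> 514 after the 10%-observations filter
baseline vs 3m       r=0.93  CI=(0.92, 0.94)
baseline vs 6m       r=0.91  CI=(0.90, 0.93)
      3m vs 6m       r=0.92  CI=(0.91, 0.94)
      HD vs 2HD      r=0.89  CI=(0.87, 0.90)
      HD vs LD       r=0.87  CI=(0.84, 0.89)
     2HD vs LD       r=0.90  CI=(0.89, 0.92)
LOD check: r=-0.44  CI=(-0.50, -0.36)
candidates: 17; planted informative proteins recovered: 8/8
```

Read this as: per-protein missingness is highly reproducible across time
points, slightly less consistent across disease-activity groups (the planted
group-dependent proteins pull those correlations down), missingness is only
weakly explained by abundance, and the cross-axis screen recovers every
planted informative protein among 17 candidates. A planted candidate shows
the signature pattern, e.g. α(HD) = 0.07, α(2HD) = 0.38, α(LD) = 0.80 —
present in high disease activity, missing in low.

The same analysis runs from the shell:

```sh
promiss simulate --seed 0 --out-dir data/
promiss correlate --matrix data/matrix.tsv --metadata data/metadata.csv --out corr.tsv
promiss run-all --config config.yaml        # full bundle + manifest + summary
```

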