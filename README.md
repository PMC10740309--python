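# dimorph

Robust estimation of sex **differences and similarities** in regional
gray-matter volumes, before and after head-size correction.

Group comparisons of regional brain volumes are dominated by a nuisance
variable: total intracranial volume (TIV) differs between men and women by
almost two standard deviations, and every regional volume scales with it.
`dimorph` implements a complete, reusable version of the analysis strategy
used in large-sample structural studies of the 18-region SENT_CORE
sentence-processing network: every analysis is run twice, on *raw* volumes
and on *power-corrected-proportion* (PCP) adjusted volumes

> VOL_adj = VOL / TIV^b,  b = slope of log(VOL) ~ log(TIV) in the pooled sample,

with both variants standardized to robust z-scores
`0.6745 (x − median) / MAD`.  Because restricted cohort data cannot be
redistributed, the package ships a synthetic-cohort generator whose
ground truth (allometric exponents, TIV sex gap, per-ROI sex offsets on the
adjusted scale) is known exactly, so every estimator can be validated by
parameter recovery, null calibration and closed-form limits.

## What it computes

**Univariate battery** (per ROI, on robust z-scores):

- heteroscedastic rank test of a global shift (Cliff dominance machinery;
  Brunner–Munzel optional), with the Harrell–Davis (HD) median shift;
- η overlap index: area under the pointwise minimum of the two group KDEs,
  with a percentile-bootstrap CI;
- HD decile shift function d̂₁…d̂₉ with percentile-bootstrap CIs and
  Hochberg control over the nine deciles;
- probability of superiority, Cliff's delta `P(A>B) − P(A<B)` with the
  consistent-variance bounded CI, and an empirically counted Cohen's U3;
- spread and shape: Wald-type HD inter-quartile-ratio test and
  percentile-bootstrap skewness/kurtosis differences;
- Benjamini–Hochberg FDR across the 18 ROIs within each test family, plus
  the Spearman table relating each ROI's effect size to the proportion of
  variance TIV explains in it.

**Multivariate batteries** (network as a whole):

- L2-penalized logistic regression (penalty chosen by corrected AIC over a
  grid, Harrell-style bootstrap optimism correction of Nagelkerke R²,
  C-index and Somers' Dxy) whose fitted probabilities — *Pclass scores* —
  are analyzed with the same univariate battery, plus accuracy at the 0.5
  cutoff, all-pairwise-difference summaries with POMP reading, calibration
  curves and nomogram tables;
- a projection-type multivariate Wilcoxon–Mann–Whitney analysis: subjects
  are projected on the line joining the two groups' HD-median centers;
  PS/delta (split-half inference), an ANOVA-style R² and the density-based
  Q classification effect size are computed on the projected distances;
- HC4 bootstrap-t correlations between Pclass scores, projected distances
  and TIV; cross-model coefficient-ordering comparisons (|Spearman rho|)
  and the intersection analysis of significant predictors, with and
  without TIV as an extra predictor.

## Worked example

```python
from dimorph import build_datasets, cliff_delta_inference, fit_penalized_lr
from dimorph.synthetic import generate_cohort, study_spec

cohort = generate_cohort(study_spec(n_per_sex=300, seed=7))
raw, pcp = build_datasets(cohort)

print(f"PCP exponent for T2_3: b = {pcp.b_hat['T2_3']:.3f}")
print(f"TIV R^2, raw vs adjusted: {raw.tiv_r2['T2_3']:.3f} -> {pcp.tiv_r2['T2_3']:.4f}")
for ds in (raw, pcp):
    d = cliff_delta_inference(ds.group("F", "T2_3"), ds.group("M", "T2_3")).delta
    print(f"{ds.kind:>4} T2_3 Cliff's delta (F vs M): {d.value:+.2f} "
          f"[{d.ci_low:+.2f}, {d.ci_high:+.2f}]  ({d.label})")

model = fit_penalized_lr(pcp.zscores, pcp.sex, reference_sex="F")
print(f"PCP model: penalty={model.penalty:g}, "
      f"C={model.apparent['c_index']:.2f}, R2={model.apparent['nagelkerke_r2']:.2f}")
```

prints

```
PCP exponent for T2_3: b = 0.428
TIV R^2, raw vs adjusted: 0.104 -> 0.0000
 raw T2_3 Cliff's delta (F vs M): -0.11 [-0.20, -0.02]  (negligible)
 pcp T2_3 Cliff's delta (F vs M): +0.16 [+0.07, +0.25]  (small)
PCP model: penalty=128, C=0.64, R2=0.06
```

Reading: on raw volumes the T2_3 region trends male-larger (the TIV gap
dominates), while after PCP adjustment the seeded female-larger offset
emerges as a "small" positive delta whose CI excludes zero; TIV explains
none of the adjusted variance, and the whole-network classifier retains
only modest discrimination (C = 0.64) once head size is removed.

## Command line

```bash
dimorph simulate --out cohort.csv --seed 3 --n-per-sex 300
dimorph validate-input --input cohort.csv
dimorph run --input cohort.csv --outdir results/ --seed 3 --reduced [--plots]
```

`run` writes tidy CSV tables (adjustment exponents, per-family univariate
tables, TIV-dependence table, model coefficients and indexes, score
batteries, pairwise summaries, nomograms, projection comparison,
structure/intersection reports, per-subject scores) plus a `manifest.json`
with the configuration, seed and per-file checksums; identical input,
configuration and seed reproduce every number exactly.

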