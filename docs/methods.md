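# Methods

This note documents the statistical model behind `dimorph`, the defaults
and their rationale, the numerical choices that matter, and what the
synthetic cohorts do and do not establish about real data.

## Generative model of the synthetic cohorts

For subject *i* and region *j*:

```
log TIV_i  ~ Normal(mu_sex(i), sigma_T)
log VOL_ij = log a_j + b_j log TIV_i + delta_j 1[sex_i = F] + eps_ij
eps_ij     = s_j (lam f_i + sqrt(1 - lam^2) e_ij),   f_i, e_ij ~ N(0, 1)
```

Log-normal TIV with multiplicative log-normal regional noise is the
simplest model in which the power-corrected-proportions (PCP) adjustment
is exactly correct, so ground truth is unambiguous: `b_j` is the
allometric exponent the adjustment should recover, and `delta_j` is a sex
offset that survives any proportional TIV correction.

Defaults (one fixed choice, per parameter, with units):

| parameter | default | rationale |
|---|---|---|
| `n_per_sex` | 300 | balanced cohort of 600, the scale at which all desk experiments run |
| TIV location F / M | log 1380 / log 1550 ml | typical young-adult means; with `sigma_T` below this is a ~1.9 SD TIV gap |
| `tiv_log_sd` | 0.06 | ~6 % coefficient of variation of TIV |
| `b_j` | 18 values evenly spaced on 0.50–0.95 | hypoallometric scaling, heterogeneous across regions so TIV-dependence analyses have spread |
| `a_j` | set so mean volumes at TIV = 1465 ml span 2–11 ml | plausible cortical parcel sizes |
| `noise_sd` (`s_j`) | 0.10 | ~10 % residual coefficient of variation |
| `delta_j` | 0 (null); study condition: +0.06 in T2_3 and f2_2 | see below |
| `common_factor_loading` (`lam`) | 0 | residuals independent by default; a single shared factor is available to induce cross-ROI dependence for multivariate checks |

**Why 0.06 for the study-condition offset.** The pooled log–log slope
used by PCP absorbs part of any sex offset, because the sex indicator is
correlated with log TIV; with these defaults the attenuation factor is
about one half.  A generative offset of 0.06 log units therefore yields
an *observed* post-adjustment shift of ≈ 0.28 robust-z units — a "small"
effect of the size the analysis is designed to detect — while leaving the
raw-scale pattern male-larger in essentially all regions.  This coupling
is a real property of pooled-slope adjustments, not an artifact.

Randomness: one integer seed drives a single generator; the stream is
consumed in a fixed order (TIV, shared factor, then regional residuals in
label order), so tables are byte-identical across runs and platforms.

## TIV adjustment and standardization

`b` is fitted per ROI by OLS of log volume on log TIV over the pooled
sample (both sexes), exactly as the PCP definition requires; no
sex-stratified option is applied by default.  Adjusted volumes are
`VOL / TIV^b`.  Both variants are transformed to robust z-scores
`0.6745 (x − median) / MAD` with the *unscaled* MAD (median of absolute
deviations); the 0.6745 factor makes the result numerically comparable to
conventional z-scores.  A zero MAD raises an error naming the region.
The per-ROI proportion of variance explained by TIV (R²) is computed by
simple linear regression on the volume scale; a log-scale variant is
available behind a flag (the choice is immaterial for the qualitative
raw-vs-adjusted contrast, which is what the R² table is for).

## Univariate estimators

- **Harrell–Davis quantiles.** Beta-weighted L-estimator; weights are
  increments of the Beta((n+1)q, (n+1)(1−q)) CDF over ((i−1)/n, i/n].
  Bootstrap resamples reuse sorted-matrix multiplication with the fixed
  weight vector, which makes decile bootstraps cheap.
- **Decile shift function.** d̂_q = HD_q(A) − HD_q(B) for q = 0.1…0.9,
  percentile-bootstrap CIs from independent within-group resampling, and
  Hochberg's step-up procedure across the nine deciles.  On robust
  z-scores the differences read on the Cohen-d scale (benchmarks
  0.2/0.5/0.8, upper bounds inclusive).
- **Dominance.** PS counts ties as ½ (so delta = 2·PS − 1 exactly); the
  delta CI uses the consistent variance estimator and the asymmetric
  transformation that respects [−1, 1]; delta benchmarks 0.147/0.33/0.474.
  The global rank test defaults to this same machinery (the two named
  procedures share it); Brunner–Munzel is a config alternative.
- **Overlap.** Gaussian-kernel KDE per group with the 0.9·min(SD,
  IQR/1.34)·n^(−1/5) bandwidth, common 512-point grid spanning the pooled
  range ± 3 bandwidths, trapezoid integration of the pointwise minimum.
  The percentile bootstrap holds the bandwidths at their full-sample
  values and re-bins resamples on the fixed grid (a kernel-matrix ×
  histogram product): bootstrap samples have near-identical spread, and
  this makes the 1000-repetition CI ~50× cheaper.
- **U3.** Percent of group A strictly above the HD median of group B,
  percentile-bootstrap CI with both groups resampled.  Strict inequality
  is immaterial for continuous data but fixed.
- **Spread and shape.** IQRs from HD quartiles; Wald test on the log IQR
  ratio with bootstrap standard errors.  Skewness (plug-in g1) and
  kurtosis (plug-in, *non-excess*: Gaussian → 3) differences use the
  percentile bootstrap with p = 2·min(P*(diff < 0), P*(diff > 0)).
  Measured at n = 100/group on mildly log-normal data, this sign-crossing
  p is slightly liberal for skewness (true level ≈ 0.065 at α = 0.05) —
  a known property of percentile bootstraps for third moments, documented
  rather than patched, since the symmetrized alternative measures worse.
- **Multiplicity.** One BH-FDR correction per test family across the 18
  ROIs; deciles are controlled within ROI by Hochberg.  A direction
  (F>M / M>F) is assigned only when the FDR-adjusted global or delta test
  is significant.
- **TIV-dependence table.** Spearman rho of per-ROI TIV R² against the
  nine signed decile differences, delta, U3 and overlap (12 rows, one
  FDR correction).  Deltas are F-oriented throughout the package, so a
  raw-data "bigger R², bigger male advantage" pattern appears as strongly
  *negative* rho for the difference measures.

## Penalized logistic models and Pclass scores

The classifier is a ridge-penalized logistic regression fitted by
Newton–Raphson with step halving (penalty λ·Σβ²/2, intercept unpenalized).
λ is selected over the grid {0, 2⁻⁴ … 2⁸} by corrected AIC, with
effective degrees of freedom trace(I(β̂)(I(β̂) + λP)⁻¹).  Wald statistics
use the sandwich covariance (I + λP)⁻¹ I (I + λP)⁻¹ and are approximate
for penalized fits; coefficient significance is FDR-corrected across
predictors.  Discrimination: Nagelkerke R² from the unpenalized
likelihoods, C-index as the rank statistic of scores versus labels, and
Dxy = 2(C − ½).  Optimism correction follows the Harrell bootstrap
(default 200 refits at the selected λ; failed refits skipped, > 20 %
failures is an error).  Calibration is an equal-frequency reliability
curve.

The reference sex (class coded 1) follows the direction of the observed
univariate effects — the median Cliff's delta over the FDR-significant
ROIs, falling back to the all-ROI median when nothing is significant —
so that higher Pclass always means "more gray matter" on that dataset's
scale.  Restricting to significant ROIs keeps the choice stable when most
regions carry no signal; ties fall to F with a logged warning.

Pclass scores are analyzed with the same battery as any ROI, plus
accuracy at the 0.5 cutoff reported as per-sex rates and their balanced
mean, per-sex CDF deciles, and the distribution of all
reference-minus-other pairwise differences (HD deciles; percent of pairs
favoring the reference with ties excluded from numerator and denominator;
subject-level percentile-bootstrap CI, 500 repetitions by default; for
Pclass a difference of x is also a POMP of 100·x percent).  Nomograms
assign each predictor 100·|β_j|·range_j / max_k(|β_k|·range_k) points over
its observed span, oriented so more points push toward the reference
class; the total-points-to-probability map inverts the recovered linear
predictor exactly.

## Projection analysis

Observations are projected onto the line joining the two groups'
marginal HD-median centers (coordinate-wise median or mean optional);
distances are (x − c_A)·u with u = (c_B − c_A)/‖c_B − c_A‖.  Two
properties deserve emphasis:

1. **Orientation.** With u defined A→B, group B sits higher on the axis
   *by construction*; the direction of the difference is carried by the
   axis, not by the dominance sign.  The pipeline therefore flips the
   axis, when its coordinate sum is negative, so that larger projected
   distance always means more total gray matter ("gm" orientation) and
   the sign of PS/delta on distances is direction-explicit.
2. **Inference.** Because the direction is estimated from the same data,
   full-sample projected distances separate the groups even under the
   null (at n = 100/sex with 18 regions the spurious separation is ≈ 0.75
   robust-z units; a naive Cliff CI covered the null 9 % of the time in
   simulation).  `projection_ps_inference` therefore estimates centers and
   direction on a seeded random half of each group and computes the Cliff
   inference on the held-out halves only, which restores exchangeability
   (measured null coverage 94.8 %).  Full-sample distances remain the
   descriptive per-subject scores — the right comparator for in-sample
   Pclass scores, which are optimistic in exactly the same sense.

Effect sizes on distances: Cliff PS/delta; ANOVA R² (between-group over
total sum of squares); and Q, computed by assigning each observation to
the group with the higher Gaussian-KDE density (Silverman bandwidth,
equal priors) and averaging the two within-group correct rates.  Depth- or
scatter-based refinements of the projection are deliberately not
reproduced; the plain center-line projection satisfies every property the
analysis relies on.

**HC4 bootstrap-t correlations.** Both variables are standardized once on
the full sample (so the OLS slope equals Pearson's r); pair resamples
reuse that scaling.  HC4 weights e²/(1 − h)^δ with δ = min(4, n·h/p)
guard against heteroscedasticity; the CI is bootstrap-t (599 resamples by
default) and the p-value is the smallest level at which it excludes zero.
Re-standardizing within each resample degrades coverage (0.895 vs 0.937
measured under variance-proportional-to-x² noise at n = 100) and is
avoided.

## Pipeline, seeds and problem sizes

Every stage derives its generator from the master seed via SHA-256 of
`"{seed}:{stage}"`, and per-(operation, ROI) streams are derived with
CRC32-keyed SeedSequences, so any stage or ROI can be recomputed in
isolation and full reruns are byte-identical.  The report bundle is tidy
CSV plus a JSON manifest (configuration, seed, versions, per-file
checksums).

Desk-scale defaults used throughout the examples, tests and the
acceptance script: 600 subjects (300 per sex); reduced bootstrap preset
500/250/250/250 repetitions for deciles/overlap/U3/moments, 200 pairwise
and 399 correlation resamples, 50 validation refits.  A full two-dataset
run at this size takes well under a minute on one CPU; the full-repetition
defaults (4000/1000/2000/2000, 200 validation refits) scale linearly.

## What the synthetic cohorts do not show

The generator reproduces the *statistical structure* the method assumes —
allometric scaling, a TIV sex gap, localized adjusted-scale offsets,
multiplicative noise, optional single-factor dependence.  It does not
emulate age or education covariates, family/twin structure, scanner or
site effects, segmentation error, non-power-law TIV relationships, or
regionally correlated offset patterns.  Passing tests therefore establish
correctness and calibration of the estimators under the stated model, and
qualitative reproduction of the raw-versus-adjusted contrast; they do not
certify behavior under model violations.  Two further caveats: the
pooled-slope attenuation described above means PCP partially absorbs true
group offsets (an inherent property of the adjustment), and with only two
non-null adjusted-scale regions the raw/PCP coefficient-ordering
concordance is information-limited — its measured |rho| (~0.65–0.8) is
well above the n = 18 permutation null but below what graded region-wide
offsets would produce.
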