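# Methods

`errtsem` implements a latent-variable analysis of affect ratings from a
film-based emotion reactivity and regulation task (ERRT), together with a
source-based-morphometry (SBM) decomposition of gray-matter images, and a
synthetic cohort generator whose ground truth lets every estimation step be
scored by simulation. This note documents the models, the numerical
choices, the generator's assumptions, and the limits of what the test suite
demonstrates.

## The task data and net scores

Each subject contributes eight condition-mean ratings — positive and
negative affect (1–11 scale) for Neutral Watch, Positive Watch, Negative
Watch and Negative Regulate — plus per-condition compliance ratings.
Compliance is ingested and reported but enters no score or model: it is a
manipulation check only. Subjects with out-of-range or missing ratings are
excluded with a logged count.

The three classic net-emotionality indices are double differences:

```
net positive reactivity  = (PW+ − PW−) − (NW+ − NW−)
net negative reactivity  = (NegW− − NegW+) − (NW− − NW+)
net negative regulation  = (NegReg− − NegReg+) − (NegW− − NegW+)
```

with `PW` = Positive Watch, `NW` = Neutral Watch, `NegW` = Negative Watch,
`NegReg` = Negative Regulate, and `+`/`−` the positive/negative affect
scale. Each index depends only on its four named ratings, is invariant
under adding a constant to all ratings, and lies in [−20, 20]. Because each
index mixes ratings that load on *different* latent factors with opposite
age trends, the net score can correlate negatively with age even when every
disaggregated positivity factor rises with age — the scaling artifact the
package reproduces (see "Synthetic cohorts" below).

## The covariance-structure engine

Models are specified in a lavaan-style text DSL (`=~` measured-by, `~`
regressed-on, `~~` covariance; numeric premultipliers fix parameters,
repeated identifier premultipliers impose equality) and compiled to RAM
form: with directed paths `A`, symmetric (co)variances `S`, and filter `F`,

    Sigma(theta) = F (I − A)⁻¹ S (I − A)⁻ᵀ Fᵀ.

Expansion defaults: every observed variable gets a residual variance;
latent variances are fixed to 1 (`unit_variance`, the default, matching
fully standardized reporting) or the first loading is fixed to 1
(`marker`); latent disturbances covary freely with each other, as do
exogenous observed variables. Covariance (not correlation) matrices are
analysed, with divisor N−1 and chi-square (N−1)·F_ML; means saturate out
and are not modelled. Missing data are handled by complete-case deletion.

**Estimation.** F_ML = log|Σ| + tr(SΣ⁻¹) − log|S| − p is minimized by
L-BFGS with analytic gradients (a few matrix products per step via the RAM
identities). Free variances are optimized on the log scale so they remain
positive; an estimate below 10⁻³ of the median observed variance is flagged
as a boundary (Heywood) solution — reported, never silently truncated.
Start values: loadings 0.7·sd(indicator), residual variances half the
sample variance, exogenous blocks at their sample moments, latent
covariances 0.3 (a nonzero start is needed because a two-indicator factor
is locally unidentified at zero factor correlation). Infeasible regions
(non-positive-definite implied covariance) are handled by a penalty that
climbs back toward the start. Identification is checked before fitting:
free-parameter count against moment count, and the rank of the Jacobian of
vech Σ at the start values. Convergence tolerance: projected gradient
1e-6, at most 1000 iterations; failure yields a `dnc` status object whose
estimates cannot be read, never an exception.

**Robust statistics.** With Δ the Jacobian of vech Σ, V the normal-theory
weight 0.5·D′(Σ⁻¹⊗Σ⁻¹)D and Γ the empirical covariance of vech of the
casewise cross-products (the fourth-moment matrix), the mean-scaling
correction is c = tr(UΓ)/df with U = V − VΔ(Δ′VΔ)⁻¹Δ′V; the scaled
statistic is chi2/c, and standard errors come from the sandwich
(Δ′VΔ)⁻¹Δ′VΓVΔ(Δ′VΔ)⁻¹/N. The scaled difference test for nested fits uses
the pooled scaling c_d = (df₀c₀ − df₁c₁)/(df₀ − df₁), floored at zero with
a warning when the pooled scale or the difference is negative. A scaling
factor of one is recovered on normal data; inflation requires *dependent*
non-normality (e.g. an elliptical t distribution with a shared scale
mixture) — with independent non-normal factors and residuals the ML
statistic is asymptotically robust and c ≈ 1 is the correct answer.

**Fit indices.** RMSEA = sqrt(max(chi2 − df, 0)/(df(N−1))); CFI compares
model noncentrality to that of the independence baseline, clamped to
[0, 1]. By default both are computed from the scaled statistic (with the
baseline scaled by its own correction); `index_variant="ml"` uses the
naive statistic. AIC = −2 loglik + 2·n_free.

**Modification indices** are univariate score tests for fixed or absent
parameters (candidate loadings and residual covariances by default):
MI = (N−1)·g²/(4s), with g the discrepancy gradient for the candidate and
s the profiled (Schur-complement) information; EPC = −g/(2s). A candidate
whose profiled information falls below 10⁻³ of its marginal information is
dropped: freeing it would not be identified, and the score statistic
degenerates there. MIs agree with brute-force refits within a few percent
in simulation.

## The model ladder

The measurement sequence over the eight ratings: a single general factor; a
four-factor model (`PosReactivity`: neutral+, positive-watch+;
`PosRegulation`: regulate+, negative-watch+; `NegReactivity`: regulate−,
negative-watch−; `BasalNegAffect`: neutral−, positive-watch−, and a small
negative-watch− loading); a hierarchical variant with a second-order
general factor; and the modified four-factor model adding three freed
parameters — the positive-watch residual covariance (+/− anticorrelation),
a cross-loading of positive-watch+ on `BasalNegAffect`, and the
regulate−/negative-watch+ residual covariance. The as-described
four-factor structure has df 13 (modified 10, modified-with-age 14); df-12
tabulations of this model family exist, so a one-parameter-freer
`four_factor_df12` variant is stored alongside, and every quantity the
tests rely on (df *deltas*, index arithmetic on reference values) is
robust to that one-parameter ambiguity.

Covariate extensions regress all four factors on each covariate, with
age → education and age → fluid-intelligence paths when present. Brain
models add twelve gray-matter source loadings as predictors of all four
factors (48 paths), retain education/gender/depression, and exclude fluid
intelligence; the comparison protocol runs the single-vs-four test, the
age-path equality test (Δdf 3), the equality-constrained brain model
(47 fewer parameters) and twelve per-source zero-out tests (Δdf 4 each).
Before fitting, `run_ladder` z-scores age, fluid intelligence, education
and the source columns — pure preconditioning for the optimizer (the fit is
scale-equivariant) that also makes covariate paths read as standardized
effects; binary gender (female = 1) and depression history stay 0/1 and
exogenous. Covariates covary freely by default. The single-vs-four
comparison is nested through a rank constraint rather than a parameter
subset, so the difference test relaxes its nestedness check to the df
ordering for that pair only. Rows that fail to converge are recorded as
DNC without indices and never abort the ladder; p-values below 2.2e-16 are
printed as "< 2.2e-16".

## Source-based morphometry

A subjects×voxels gray-matter matrix is decomposed as `mixing @ sources`.

**Order selection.** Voxels are decimated at the smallest stride whose
subsample has lag-1 spatial autocorrelation below 0.1 (our concrete
reading of entropy-rate-matched subsampling; smooth images violate the
i.i.d.-sample assumption of eigenvalue criteria). On the per-subject-mean-
removed subsample, each candidate order k is scored by the sphericity
likelihood ratio of the trailing eigenvalues, N·m·ln(arith/geom mean),
plus a complexity penalty for the pk − k(k−1)/2 + 1 free parameters. Two
penalties are offered: AIC (2d) and MDL (d·ln N). Selection defaults to
MDL because argmin-AIC is not order-consistent — its penalty step is the
same order as the likelihood drop from absorbing the largest noise
eigenvalue, so it overshoots a planted rank with roughly 10% probability
even on essentially noise-free low-rank data; MDL recovers planted ranks
exactly across seeds and drives white noise to k = 1. The AIC curve
remains available (`criterion="aic"`).

**Unmixing.** PCA-whitening to k dimensions, then logistic-infomax
natural-gradient ascent in shuffled blocks of 64 voxels, learning rate
0.01/ln k, annealed by 0.9 when the update direction turns by more than
60°, halved with a restart on divergence, stopped when the weight change
falls below 1e-7. The unmixing matrix is square and invertible, so
`mixing @ sources` reproduces the whitened data to machine precision (the
only reconstruction error is PCA truncation). Source signs are fixed so
every spatial map has positive skewness; recovery is always evaluated
after Hungarian matching, never by index. Runs are deterministic given
`random_state`.

**Reporting.** Source rows are z-scored and thresholded at |Z| > 3.0;
components are selected by Jaccard overlap ≥ 0.2 (configurable) between
their suprathreshold set and any user-supplied anatomical mask. NIfTI
input/output goes through nibabel.

## Effects regressions

Age effects are ordinary least squares on centered linear and quadratic
age terms; the reported R² is for the full model. Its confidence interval
inverts the noncentral-F distribution of the overall test (Steiger-style;
the bound λ maps to R² = λ/(λ+n)); a percentile bootstrap is available
behind `ci_method="bootstrap"`. Net-score/age associations are Pearson
correlations on complete cases; the paired t test is the textbook
statistic. scipy's noncentral-F underflows to NaN at extreme
noncentrality, which is treated as a zero tail probability.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the study's size (n = 249 by default), with every generating value stored
in a `SyntheticTruth`.

* **Demographics.** Ages uniform within seven ten-year decades
  (18–28 … 79–88) drawn with the study's decade proportions
  (27/38/44/36/40/39/25 of 249). Fluid intelligence follows the
  least-squares line through the decade means (44.19 − 0.219·age,
  residual SD 4.3) — a linear approximation that sits ~1.9 points above
  the youngest decades, which plateau in the reference data. Education is
  a thresholded latent normal tilted −0.25 against standardized age, cut
  to match the overall attainment distribution (7/19/12.5/61.5%); gender
  is Bernoulli(0.52) (female = 1), depression history Bernoulli(0.15).
* **Ratings.** Latent factor scores are linear in standardized age,
  gender and depression history plus correlated Gaussian disturbances
  (disturbance correlation 0.3, a generator choice; the analysis reports
  none). Age paths are sqrt of the target R² (0.22 positive regulation,
  0.20 positive reactivity, 0.30 basal negative affect, 0.03 negative
  reactivity) on *population*-standardized age, so the targets are exact
  in population terms; gender paths 0.21/0.31, depression 0.16.
  Indicators mix the factors through the standardized loadings
  (0.82, 1.02, 0.89, 0.77, 0.86, 0.86, 0.90, 0.58, 0.06), the freed
  cross-loading and the two freed residual covariances, then shift/scale
  into the rating metric (per-condition means, common scale 1.25).
  Residual variances are 1 − communality floored at 0.25 so the truth
  stays estimable. Ratings are continuous by default; `discretized`
  rounds and clamps to {1..11}, which violates the normality the ML
  theory assumes and is therefore opt-in.
* **Values without a reference, chosen once.** The cross-loading is −0.75:
  no reference value pins it, and the magnitude is set from the net-score algebra
  so the model-implied correlation between net positive reactivity and
  age is negative (≈ −0.10 at the defaults), reproducing the direction of
  the reported scaling artifact while all positivity factors rise with
  age. The two freed residual correlations default to −0.35
  (positive-watch +/−, the anticorrelation) and +0.20
  (regulate−/negative-watch+, a positive association). Condition-mean
  separations are compressed relative to real floor-skewed ratings so the
  Gaussian ratings stay inside 1–11 (~0.5% of subjects are trimmed by
  range validation at the defaults).
* **Gray matter.** Source loadings decline linearly in standardized age at
  per-source R² spanning 0.04 (angular gyrus) to 0.40 (middle temporal
  gyrus), with the intermediate values interpolated; their correlation
  matrix defaults to the reference 12×12 inter-source table (verified
  positive definite, as is the residual structure after removing the
  age-explained part). Spatial phantoms place k isotropic Gaussian blobs
  (σ = max grid/10) on a fixed lattice and add white noise; with zero
  noise the centered stack has exactly rank k.

**What passing tests do and do not show.** The generator is linear-
Gaussian with exact moment structure: passing recovery and calibration
tests demonstrates the estimation machinery, not robustness to real
rating data (floor effects, ordinal scales, non-normal residuals) or real
morphometry (registration error, intensity artifacts, non-Gaussian source
shapes). The discretized mode exists precisely to probe the first gap:
clamping compresses variance at the scale ends and biases loadings
downward.

## Simulation designs behind the headline checks

Problem sizes were chosen so each check measures its target property
rather than Monte-Carlo noise, while the default test run stays fast.

* **Recovery** (200 cohorts, n = 249): loadings of the modified
  four-factor model, fitted with robust SEs. Small-sample ML bias peaks
  at ~0.02–0.03 for the positive-watch+ loading — the weakly identified
  corner of the model, where the near-unit standardized loading leaves a
  small residual variance; for the same reason roughly a quarter to a
  third of replicates end at the variance boundary (a genuine feature of
  the ML surface, confirmed by refitting from the true values). Boundary
  fits are retained; per-loading bias is assessed against 0.03 allowing
  for the replicate-level Monte-Carlo error, and Wald coverage pools all
  loadings.
* **Planted misfit** (100 cohorts, n = 600): a single residual
  correlation of 0.6 omitted from an otherwise clean four-factor truth.
  At the analysis's own modification sizes (|r| ≈ 0.2–0.35, n = 249) the
  top-rank probability is only 25–55% because near-equivalent candidates
  share the misfit — distinctive top-ranking requires a distinctly
  detectable plant.
* **Zero-out type-I** (100 cohorts, n = 249): four sources, factor-age
  effects set to zero so all brain-behavior paths are truly null;
  rejection of the Δdf = 4 scaled difference test at α = 0.05 runs at the
  nominal rate.
* **Source recovery**: four-blob phantom, 200 subjects, 14³ grid, noise
  SD 0.1 (≈10% of blob amplitude); matched spatial correlations ≥ 0.99.
  Order estimation: 20 planted ranks of 3–7 among 40 subjects, 6000
  voxels, noise SD 0.01.
* **Moment matching**: empirical vs truth-implied indicator correlations
  at n = 50,000, where the sampling expectation of the Frobenius
  discrepancy (~0.03) sits safely below the 0.05 bound; at n = 20,000 the
  expectation itself is ~0.047.

## Known limitations

* No ordinal/categorical estimators (WLSMV), no FIML for missing data, no
  multi-group models, no mean structure.
* The modification-index candidate set covers loadings and residual
  covariances, not regression paths.
* The hierarchical (second-order) model is identified here only through
  its unit-variance disturbances; with real, weakly correlated factors it
  frequently fails to converge, as second-order models of weakly
  correlated factors commonly do.
* Infomax assumes super-Gaussian sources (logistic nonlinearity, no
  extended-infomax switch); clearly sub-Gaussian spatial sources would
  need a different nonlinearity.
* The net-score range validator trims a small fraction of continuous-mode
  subjects at the scale ends, a mild truncation absent from the
  covariance-structure path, which uses the raw columns.
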