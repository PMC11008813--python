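# Methods

`vertexspan` re-implements, as a tested reusable pipeline, a vertex-wise
lifespan analysis of birth-weight (BW) effects on cortical structure:
mass-univariate longitudinal mixed models on spherical surface meshes,
cluster-extent correction with a permutation null, spin-test spatial
consistency analysis, split-half and across-sample replicability,
monozygotic (MZ) twin discordance contrasts, and effect-size /
aging-equivalence reporting.  A synthetic cohort generator with known ground
truth makes every stage testable without access to restricted cohort data.
This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic validation does and does not show.

## The vertex-wise mixed model

At every vertex v the measure (area, thickness, or volume) is modeled as

    y_iv = x_i' beta(v) + u_{s(i)}(v) + e_iv,
    u_s(v) ~ N(0, sigma_u^2(v)),   e_iv ~ N(0, sigma_e^2(v)),

with a subject random intercept and homoscedastic residuals.  The fixed
effects are the contrast of interest plus baseline age, sex, scanner site
(dummy-coded) and time since baseline; ethnicity is added for the
developmental-cohort preset, and education, intracranial volume and
gestational length are optional sensitivity covariates.  Continuous
predictors are standardized within cohort, so beta reads as natural measure
units per 1 SD of the predictor.  Three contrast families are fitted in
turn: the BW main effect; BW x time (change), with both main effects as
covariates; and baseline age x time x BW, with all two-way interactions as
covariates.  The twin model replaces BW with the standardized within-pair
BW discordance and adds the pair-mean BW as a covariate, isolating
non-genetic (intrauterine) variance in genetically identical twins.

Vertices are fitted independently.  This deliberately forgoes the spatial
pooling of variance parameters that spatiotemporal mixed-effects packages
perform; the accepted validation surface is parameter recovery and
statistical calibration on synthetic data, not bit-level agreement with any
particular legacy implementation.

### Estimation

Because the design and grouping are shared across vertices and only the
response differs, the within-subject covariance is parameterized by the
intraclass correlation rho = sigma_u^2 / (sigma_u^2 + sigma_e^2).  The
per-group correlation matrix (1-rho)I + rho J has closed-form inverse,
determinant and square root, so the total variance profiles out analytically
and the profile ML log-likelihood at any candidate rho for *all* vertices
costs a handful of matrix products on precomputed sufficient statistics.
The optimizer is a shared 33-point grid on rho in [0, 0.995] followed by a
vectorized golden-section refinement with a per-vertex bracket (default
tolerance 1e-6; 1e-3 inside permutation loops, where rho precision is
immaterial).  Boundary estimates at rho = 0 collapse to ordinary least
squares exactly, and a design with one observation per subject short-circuits
to OLS (the likelihood is flat in rho there).  Inference is Wald:
t = beta/SE with residual degrees of freedom n - rank(X) and the variance
scale RSS/(n - p) in the whitened metric.  The engine is cross-checked in
the test suite against a dense grid-search GLS oracle (agreement to 1e-5)
and against an independent mixed-model implementation.

## Cluster-extent correction

Supra-threshold vertices (-log10 p > 2.0, i.e. p < 0.01 two-sided) form
signed connected components within each hemisphere's mesh adjacency.  Each
cluster's vertex count is referred to the permutation distribution of the
per-hemisphere maximum cluster size, with significance declared at
p < 0.025 per hemisphere (0.05 split over two hemispheres);
p = (1 + #{null max >= size}) / (1 + n_null).

The permutation scheme permutes the contrast variable's subject-level
residuals (after regressing it on the subject-level covariates) across
whole subjects, keeping each subject's longitudinal rows intact.  Two
implementation choices matter:

* **One working correlation.**  The observed statistic map inside the
  cluster stage and all permutation maps are computed by ordinary least
  squares after whitening at a single working intraclass correlation (the
  median of the per-vertex ML estimates).  This makes observed and null
  statistics exchangeable by construction and reduces each permutation to
  one matrix-vector product, which is what makes 200-null-sample cluster
  correction inside 50-split replicability loops tractable on one CPU.  The
  reported effect maps remain full per-vertex ML fits.
* **Signal-free null pool.**  The null responses are the *full-model*
  residuals (observed contrast effect removed) rather than
  reduced-model residuals.  With reduced-model residuals, a strong true
  effect is treated as exchangeable noise and inflates null cluster sizes
  whenever the permuted contrast correlates with the observed one by
  chance, destroying power exactly where the effect is strongest.  Removing
  the fitted contrast component eliminates this contamination; under the
  null the two pools coincide up to one degree of freedom.  Familywise
  error calibration is verified empirically (200 null runs in the
  acceptance suite; observed rate well under the 0.05 nominal level).

## Spin tests and map comparisons

Spatial correspondence of two vertex maps is the Pearson correlation across
concatenated hemispheres, referred to a spin null: for each permutation a
uniform (Haar) rotation of the sphere is drawn, applied to the left
hemisphere and mirrored into the right with M = diag(-1, 1, 1) (the
mirroring axis follows the spin-test literature), and each vertex inherits
the value of the nearest rotated source vertex by great-circle distance
(exact nearest neighbor; ties break to the lowest index for determinism).
The first map of a pair is spun by convention; two-tailed
p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm); families of comparisons are
Benjamini-Hochberg FDR-adjusted.  One spin bank is generated per run and
shared across all comparisons — a choice, recorded here, since regenerating
per pair is equally defensible.  Note that a hemisphere's mean value is
invariant under spinning, so maps differing only in hemispheric offsets are
(correctly) never declared spatially aligned by this test.

Cohort-level beta maps combine by per-vertex inverse-variance fixed-effect
meta-analysis (beta_meta = sum(w beta)/sum(w), w = 1/SE^2, normal
inference), producing the map that is compared with the twin-discordance
map.

## QC outlier screen

Before model fitting, each cohort is screened with a smooth-age-trend model:
at every vertex, value ~ natural cubic spline in age at scan (5 basis
functions, unpenalized — the basis dimension is configurable) + subject
random intercept.  An observation is excluded when its absolute
*conditional* residual (subject BLUP subtracted; a configurable choice)
exceeds 4 times the per-vertex residual SE — the square root of the
estimated residual variance component — at strictly more than the threshold
count of vertices.  The reference rule is 6000 of 163,842 vertices; on
smaller meshes the count is reinterpreted as the same fraction (~3.66%),
rounded.  Under clean Gaussian data the rule almost never fires (the
acceptance suite demands at most one false exclusion in 50 simulations),
while a whole-row offset of 10 residual SDs is always caught: the BLUP
absorbs only part of a single corrupted row's offset when the subject has
other clean scans.

## Replicability

Within-sample: the full analysis (vertex model + cluster correction) is
repeated on random half-samples split at the *subject* level — all of a
subject's scans travel together, co-twins stay in the same half, and splits
are stratified by cohort and site (a documented choice; unstratified
splitting is statistically equivalent at these sizes).  Exploratory
replicability is, per vertex, the fraction of splits in which it survived
correction; confirmatory replicability is, per split, the fraction of
train-significant vertices that are also significant (uncorrected p < 0.05,
same sign) in the held-out half.  Splits with no corrected-significant
train vertices are excluded from the confirmatory summary, never counted as
zeros.  Under the null with the sign constraint the confirmatory fraction
concentrates near 0.025 (half of alpha), a built-in self-check.
Across-sample replicability applies the same train/test logic to two whole
cohorts, in both directions; a direction with no significant train vertices
is labeled not assessable.

Desk-scale defaults are 50 splits on a 1284-vertex (subdivision-3) mesh
pair with a reduced inner cluster null of 200 permutations; the
reference-scale settings (500 splits, 2562 vertices per hemisphere) are
configuration presets.

## Effect-size translation

The BW effect on the total (vertex-summed) measure is refitted with the
same mixed model, giving: effect per 1 SD of BW in natural units (the
cohort's grams-per-SD scaling, typically ~600 g, is carried from the
standardization record); percent of the cohort's mean total measure at
baseline; and the aging equivalence — the effect divided by the absolute
annual change of the total measure, estimated from the time coefficient
(natural units, unstandardized time) among subjects whose *baseline* age
falls in a stated window (default 50-60 y; an age-at-scan window is offered
as a flag).  The worked reference example: 6708 mm^3 per SD against
895 mm^3/y gives 7.495 -> reported 7.5 years; 8466 against 1402 gives
6.04 -> reported 6 years.  Reported equivalences round to one decimal below
10 years, except that a value above 5 within 0.1 of an integer reads as the
integer — the convention that reproduces both reference renderings — and
raw values always accompany the rounded ones.

## The synthetic cohort generator

The generator *is* the study-condition definition, not a tuning knob.  Its
defaults:

| parameter | default | rationale |
|---|---|---|
| lifespan cohort | n=635, ages 4.1-81.9, 2-5 visits, ~2 y gaps | accelerated longitudinal design with up to ~8 y follow-up |
| developmental cohort | n=3324, ages 8.9-11.1, 2 visits ~2 y apart, 8 sites, ethnicity covariate | narrow-age multi-site design |
| older-adult cohort | n=1759, ages 47-80.3, 2 visits 2.3 (0.1) y apart | two-wave aging design |
| birth weight | Normal(3.4, 0.6) kg truncated to (0.5, 6.5); 3.5 (0.6) in the lifespan preset | reference descriptives; ~600 g per SD |
| effect maps | smoothed white noise (20 neighbor-averaging iterations, self-weight 0.5), standardized so the across-vertex SD equals the amplitude | smooth topographies with controlled effect scale |
| amplitudes | age 1.0, sex 0.5, BW 1.0, time -0.3, BW x time 0 (all x sigma_e) | moderate, recoverable effects; zero change effect mirrors the level-vs-change contrast |
| noise | sigma_u = sigma_e = 1 (ICC 0.5), site offsets SD 0.5 | typical repeated-morphometry reliability |
| twins | 193 MZ pairs (386 twins), ~80/17/3% developmental/adult/older mix, discordance SD 300 g, 20% single-time-point twins | mixed-age twin subsample with partly cross-sectional data |
| corruption | fraction 0, offset k >= 8 sigma_e when enabled | QC-stage stress scenario |

BW is simulated in kg and standardized within cohort before entering
effects; the generative model is exactly the fitted model (linear,
random intercept only), with an optional quadratic-age term for the spline
sensitivity path and an optional BW-dependent-dropout flag whose parameters
are user-supplied.  Localized effects are spherical caps around the pole
(constant amplitude inside a geodesic radius), used for twin-discordance
and cluster power scenarios.  All randomness flows from explicit seeds;
regeneration is bit-identical.

**What the generator does not emulate:** realistic folding geometry and
physical mm scales (smoothing is specified in iterations; an FWHM-to-
iterations conversion is provided for imported meshes with real edge
lengths), spatially correlated measurement noise (only the true effect maps
are smooth; noise is independent across vertices), non-Gaussian residuals,
and informative dropout.  Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
real-data violations of it.  In particular, spin-test calibration is shown
for isotropic random fields; real cortical maps have anisotropic,
region-dependent smoothness for which spin tests are known to be only
approximately exact.

## Numerical choices and degenerate inputs

* Intraclass correlation capped at 0.995; RSS floored at 1e-300; p-values
  floored at 1e-300 before -log10.
* Rank-deficient designs raise immediately (the design is shared across
  vertices, so per-vertex degeneracy can only come from the data); vertices
  with non-finite data are flagged degenerate, excluded from clustering,
  and carried as NaN in maps.
* An all-equal-age QC design falls back to an intercept-only trend and is
  flagged.
* Nearest-neighbor spin ties break to the lowest vertex index; permutation
  and rotation streams are spawned per permutation index from a seed
  sequence, so any single permutation can be regenerated independently.
* The 10% repeated-BW discrepancy rule uses (max - min)/mean — the
  denominator is not pinned down by the reference wording and is
  configurable; BW-window bounds (2.5-5.0 kg) are inclusive.
* Education precedence: own education if present, else the mean of parental
  education.
* The pooled twin subsample standardizes covariates across the whole twin
  sample (`within=None`) because per-cohort contingents can be single pairs.

## Desk-scale problem sizes

The shipped tests and the acceptance script run on subdivision-3 icospheres
(642 vertices per hemisphere, 1284 total) with cohorts of 80-600 subjects,
200-permutation cluster nulls, 1000-rotation spin banks, 50 replicability
splits and 200-run calibration loops.  These sizes were chosen once as the
smallest at which the calibration quantities (type-I error, familywise
error, spin uniformity) are estimated with useful precision; the
full-resolution settings remain available through configuration.

## Known limitations

Independent per-vertex fits ignore spatial covariance, so cluster p-values
rely entirely on the permutation null rather than smoothness estimates.
Random slopes, Satterthwaite degrees of freedom, threshold-free cluster
enhancement and variogram-matched surrogate nulls are out of scope.  The
double-scan (same-day two-scanner) design is treated as ordinary repeated
observations with distinct site codes, without a within-time-point
correlation structure.
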