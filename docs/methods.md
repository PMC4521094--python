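# Methods

This note documents the models, numerical choices and limitations behind
`amypet`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data model

### Phantom volumes

A phantom is a 3-D voxel grid partitioned into labeled regions (boxes, or
slabs along the first axis when no box is given). Each region carries a
true uptake ratio relative to the reference region; the noise-free voxel
value is `ratio × reference_value`. Additive Gaussian noise (SD in uptake
units) is applied voxel-wise, then an optional isotropic Gaussian blur
whose FWHM is specified in millimetres and converted per axis to voxel
sigma (`FWHM / (2√(2 ln 2)) / voxel_size`). The blur emulates
resolution-driven spill-over — in particular white-matter activity
bleeding into adjacent grey matter, the mechanism that motivates
whole-cerebellum (rather than cerebellar-GM) referencing for tracers with
high non-specific white-matter uptake. The label grid is never affected
by noise or blur. The default atlas phantom has 24 grey-matter labels
(12 bilateral ROIs × left/right), cerebellar GM (the PIB reference),
cerebellar WM (union with cerebellar GM = whole cerebellum) and cerebral
WM. No raw PET dynamics, scanner effects or MRI are simulated.

### Cohort tables

Subjects are drawn per stratum (diagnosis HC/MCI/AD × age group
younger 55–75 y / older 76–93 y). The composite neocortical ratio
(CCTXR) of a stratum follows a one- or two-component Gaussian mixture;
the shipped defaults are the mixture parameters reported for a large
Florbetapir cohort:

| stratum      | n   | components (mean ± SD, weight)              |
|--------------|-----|---------------------------------------------|
| HC younger   | 123 | 1.23 ± 0.08 (110/123), 1.52 ± 0.08 (13/123) |
| HC older     | 123 | 1.26 ± 0.16                                 |
| MCI younger  | 171 | 1.36 ± 0.19                                 |
| MCI older    | 171 | 1.35 ± 0.20                                 |
| AD younger   | 69  | 1.48 ± 0.17                                 |
| AD older     | 69  | 1.08 ± 0.13 (15/69), 1.48 ± 0.13 (54/69)    |

Latent component membership is recorded (`true_component`) for recovery
scoring only; no analysis stage reads it. Negative draws are redrawn
(truncation at zero) and counted in the log; at the default calibration
they essentially never occur.

**ApoE4.** Carrier status is drawn per latent component (younger HC:
26 % low / 69 % high; older AD: 7 % low / 74 % high — the published
subgroup rates; unimodal strata use their group-level rates). This
reproduces the carrier enrichment of the high-amyloid subpopulation while
keeping the marginal CCTXR distribution exactly the configured mixture —
an additive carrier shift would distort the calibrated mixture, and the
generator's calibration property (KS distance of 10,000 draws to the
configured mixture CDF < 0.02) is part of the design. An additive
`apoe4_shift` knob exists for sensitivity experiments, default 0.

**Regional SUVRs.** Each ROI value is a linear transform of the subject's
CCTXR, `SUVR_roi = a + b·CCTXR + ε`, with `(a, b)` frozen from a
least-squares fit to published group-level regional means across the four
HC/AD × age cells, and residual SD set so that within-stratum ROI spread
is of the published order (floored at 0.03). Residuals share a common
factor across ROIs within a subject (`roi_correlation`, default 0.5, the
fraction of residual variance that is shared). The source material
constrains only group-level regional means, not intra-subject regional
correlation, so the correlation is an exposed free parameter, not a
claim. Consequences worth knowing: the generated per-ROI columns do not
average back exactly to the drawn CCTXR (the composite identity holds
for volume-derived tables, not for generated cohort tables), and
realistic features such as site effects, longitudinal drift and
non-Gaussian heavy tails are absent — passing tests validate the
pipeline's arithmetic and statistical behaviour, not robustness to those
real-data features.

Demographics (MMSE, education, sex ratio, carrier rates, ages uniform
within the group bounds) follow the published stratum tables. The age
bounds use 76–93 y for the older group (the source is internally
inconsistent, also printing 76–83 y once; 76–93 appears in the abstract
and the main demographic table).

## Quantification

The reference value is the median or mean over all voxels carrying any
reference label; SUVR images divide every voxel by it (documented
non-idempotence). Bilateral ROI means are voxel-union means, so
hemispheres weight by voxel count. The CCTXR weights are exposed; the
default used by the pipeline weights the frontal/parietal/temporal ROIs
by voxel count because the original "weighted average" weights are not
published — volume weighting is the choice that reproduces the direct
voxel-level composite mean, and it is documented as a choice, not a claim
about the original pipeline. Candidate reference regions are benchmarked
by the coefficient of variation of healthy-control CCTXR (denominator
stability) and Cohen's d between HC and AD (preserved contrast).

## Cut-offs and harmonization

The ROC threshold grid is the set of midpoints between adjacent distinct
pooled scores plus ∓∞ sentinels; positivity is strictly `score >
threshold`. AUC is the Mann–Whitney statistic with ties counted ½
(equal to the trapezoid area). The 95 % CI uses DeLong's covariance
estimate (the publication's CI method is unstated; a bootstrap percentile
CI is available behind `ci_method="bootstrap"`). The optimal cut-off
minimizes the Euclidean distance to (0, 1); distance ties prefer higher
sensitivity, then the lower threshold (distances are compared after
rounding at 1e-12 to make exact ties well-defined in floating point).

Cross-tracer harmonization fits tracer-B on tracer-A *ROI-mean* values by
OLS (n = number of ROIs, not subjects) and pushes a cut-off through the
line; display values round half-even to two decimals while stored values
keep full precision. No attempt is made to reproduce the absolute
real-data cut-offs (1.42 PIB / 1.34 Florbetapir) — those depend on the
original scan cohorts; the worked example 1.42 → 1.32 through
y = 1.13x − 0.28 is exact arithmetic.

## Mixture analysis

Normality: one-sample KS statistic against a normal with estimated mean
and SD; because the parameters are estimated from the sample, the p-value
comes from a seeded Lilliefors-style Monte-Carlo null (default 10,000
standard-normal replicates of the same size, each re-standardized by its
own estimates; `(exceed + 1)/(n_mc + 1)` convention).

EM: univariate K ∈ {1, 2} Gaussian mixtures. K = 1 is closed form
(mean, ML 1/n standard deviation). K = 2 runs EM from 20 restarts —
median split and quartile seeds (deterministic), then random pairs of
observations — converging when the log-likelihood gain drops below 1e-8
or at 500 iterations; component variances are floored at
1e-4 × sample variance so a component cannot collapse onto a single
point; components are canonicalized to ascending mean order, which also
makes the fit invariant to input permutation. Model order is chosen by
BIC (−2ℓ + p log n with p = 2 for K = 1, 5 for K = 2); the original
analysis tool's "more likely" criterion is unpublished, so BIC is a
documented stand-in; ties go to the smaller model. Hard assignment takes
the larger responsibility, ties to the high component. K > 2 and
non-Gaussian components are out of scope.

## Cohort statistics

* Two-way ANOVA: Type III sums of squares with sum-to-zero contrasts via
  statsmodels OLS + `anova_lm` (mirrors the SPSS default; verified in the
  tests against R `car::Anova` on an unbalanced fixture and against
  Type I on balanced designs, where they coincide). An empty cell makes
  the interaction inestimable; main effects then come from the additive
  model with a warning.
* Chi-squared: Pearson without continuity correction by default (Yates
  behind a flag).
* Spearman: midrank ties; for n ≤ 12 untied pairs the two-sided p is
  exact, from the permutation distribution of S = Σd² computed by
  dynamic programming over rank subsets (4.8 × 10⁸ permutations counted
  exactly at n = 12); larger or tied samples use the t approximation.
* Matching: greedy 1:1 nearest-neighbour without replacement, reference
  order randomized by seed, exact on the categorical variables and
  minimal pool-SD-scaled Euclidean distance on the continuous ones;
  balance reported as standardized mean differences. The original study
  says only "randomly matched"; greedy seeded matching is the documented
  interpretation.
* Cohen's d uses the pooled n−1-weighted SD; κ uses marginal-product
  expected agreement (degenerate marginals → NaN with a warning).

## Pipeline

One top-level seed spawns per-stage seeds through
`numpy.random.SeedSequence`, so stages are independently reproducible;
the manifest records the scenario name, seeds, package version and
SHA-256 of every output file, and a rerun with the same configuration is
byte-identical. Report rounding is half-even and applied only at display
time. The pipeline's per-stratum normality screen uses 2,000 Monte-Carlo
replicates (the standalone function defaults to 10,000) to keep a full
scenario run interactive.

## Problem sizes used in validation

Stochastic checks run at the published stratum sizes (n = 69–171) with
100 simulation seeds for parameter-recovery and model-selection rates,
200 seeds for tail-probability calibration, 2,000 replicates for the
ANOVA type-I calibration, and 10,000 draws for distribution-calibration
KS checks. These sizes make the Monte-Carlo error small relative to every
asserted tolerance while keeping the full suite and the acceptance script
each within a few minutes on one CPU.

## Known limitations

* The generator emulates marginal distributions and first-order
  covariate effects, not spatial image statistics; the phantom is
  piecewise-constant with stylized geometry.
* BIC at n ≈ 69 has limited power: under the older-AD bimodal
  calibration it selects K = 2 only in a modest majority of replicates —
  consistent with how delicate the unimodal/bimodal call is at such
  sample sizes.
* DeLong CIs are asymptotic; very small groups should prefer the
  bootstrap flag.
* Exact Spearman p-values stop at n = 12 (the DP table grows as
  2ⁿ · n³); beyond that the t approximation is used even though the
  permutation null is still discrete.
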