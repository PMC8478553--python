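# Methods

This note documents the models, conventions, and design choices of the
package; it states nothing the tests or `scripts/acceptance.py` do not
themselves compute.

## Synthetic cohort generator

The generator stands in for an undeposited clinical cohort of 261 RCC
patients (ccRCC : pRCC : cRCC ≈ 209 : 25 : 29) imaged in four CT phases.
Each subject is built on a cubic grid (default 64³ voxels at 1 mm
isotropic; clinical 512×512×5 mm grids are reachable through the
`shape`/`spacing` knobs but desk-scale grids keep the feature
definitions — which are spacing-aware — exercised at low cost):

* **Lesion geometry.** An axis-aligned ellipsoid centered on the grid,
  semi-axes drawn uniformly from 25–40% of the grid size (≈ 32–51 mm
  diameters at the default grid, bracketing the published median
  diameter ≈ 45 mm). Geometry is shared across phases, as one
  segmentation per patient is.
* **Attenuation.** Per subtype and phase, the target lesion attenuation
  defaults to the published medians (HU):

  |       | NCP   | CMP    | NP    | EP    |
  |-------|-------|--------|-------|-------|
  | ccRCC | 33.89 | 105.31 | 86.98 | 69.93 |
  | pRCC  | 35.35 | 53.61  | 61.90 | 60.71 |
  | cRCC  | 26.61 | 85.21  | 77.81 | 65.95 |

  A per-subject, per-phase offset ~ N(0, 12 HU) models between-patient
  enhancement variability; offsets are independent across phases, so the
  four phases carry complementary first-order information — the
  condition under which combining phases can beat any single phase.
  Background tissue sits on a −20 HU plateau with 5 HU white noise.
* **Texture.** Lesion voxels carry a Gaussian random field (white noise
  smoothed with a Gaussian kernel) scaled to 15 HU SD. The kernel sigma —
  the texture correlation length — is subtype-specific (ccRCC 2.5, pRCC
  1.0, cRCC 4.0 voxels) with per-subject, per-phase jitter of SD 0.5
  voxels. The jitter matters: with a deterministic per-subtype
  correlation length, texture separates the classes almost noiselessly
  in *every* phase and the multiphase model has nothing to add; the
  jitter makes texture information phase-noisy, as acquisition phases
  are, so pooling phases genuinely helps.
* **Inclusions.** Cystic (−45 HU) and calcified (+180 HU) ellipsoidal
  inclusions are planted with the published per-subtype frequencies
  (cystic 161/207, 11/25, 9/29; the source table prints "161
  (91.6%)" although 161/207 ≈ 78% — the count ratio is used and the
  probability is a config knob). Inclusions sit eccentrically, 0.45–0.7
  lesion radii off-center.
* **Anchoring.** After composing noise and inclusions, the lesion field
  is shifted so the mean over the *margin-eroded core* equals the target
  attenuation exactly. The core is what the exported masks sample, so
  the measured attenuation column reproduces the configured medians by
  construction, up to the between-subject offsets.
* **Raters.** Rater 1's mask is the ideal ellipsoid eroded by
  `round(2 mm / spacing)` voxels, emulating the protocol of keeping the
  contour ≈ 2 mm inside the tumor margin; the same mask serves all
  phases (the corticomedullary segmentation is reused for the
  noncontrast image, whose lesion boundary is invisible). Rater 2 is a
  boundary perturbation: per magnitude step, inner- and outer-shell
  voxels flip independently with probability 0.3, leaving the interior
  untouched.
* **Clinical table.** Sex, side, symptoms, growth pattern, T/N/M stage
  are drawn from the published per-subtype frequencies; TNM stage is
  derived from T/N/M by the usual rule (M1 or T4 → IV, N1 or T3 → III,
  T2 → II, else I); age ~ N(52 or 54, 12) clipped to 18–90; diameter is
  the actual lesion extent; cystic/calcification flags reflect the
  planted inclusions; attenuations are recomputed from the voxels.

All randomness flows from `CohortConfig.seed` through per-subject
`SeedSequence` substreams: equal seeds give bit-identical cohorts, and
a cohort's leading subjects are unchanged when the configured counts
grow.

What the generator does **not** emulate: organ anatomy, partial-volume
effects at the kidney interface, scanner noise spectra, slice-thickness
anisotropy artifacts, or correlations between clinical covariates and
image phenotype beyond subtype membership. Passing tests therefore
demonstrate that the *pipeline machinery* is correct and that the
method recovers structure it is pointed at — not that the published
clinical effect sizes generalize.

## Feature extraction

105 features per phase; the four phases concatenate (phase-prefixed,
order NCP, CMP, NP, EP) to 420.

* **Discretization:** fixed bin width 25 HU anchored at the ROI minimum,
  `level = floor((v − min)/w) + 1`. Anchoring at the minimum makes every
  discretized feature invariant to constant HU shifts. The source
  analysis does not state its binning; 25 HU is the extraction
  platform's conventional default and is config-exposed.
* **First order (18):** mean, median, min, max, range, population
  variance/skewness/kurtosis (kurtosis not excess-corrected), energy,
  total energy (× voxel volume), entropy and uniformity (on the
  discretized histogram, log₂), MAD, robust MAD (10–90 percentile
  subset), RMS, P10, P90, IQR.
* **Shape (13):** mesh volume and surface area from marching cubes at
  level 0.5 on the zero-padded binary mask; surface/volume ratio;
  sphericity π^⅓(6V)^⅔/A; max 3D diameter and the three in-plane max 2D
  diameters from the mesh vertices (convex-hull pruned); major/minor/
  least axis lengths 4√λ from the PCA of physical voxel coordinates
  (sample covariance); elongation √(λ₂/λ₁) and flatness √(λ₃/λ₁).
  Voxel-count volume is available as a diagnostic
  (`features.voxel_volume`) but is not one of the 13. Note the known
  chamfer bias of level-set meshes on blocky masks: a digitized 10³ cube
  measures sphericity ≈ 0.85 against the ideal 0.806, the bias shrinking
  with resolution; the tests pin this behavior.
* **Texture:** GLCM and GLRLM use the 13 unique distance-1 3D
  directions, features computed per direction and averaged (directions
  with no pairs/runs are skipped); GLCM accumulates symmetrically.
  GLSZM zones and GLDM dependences use 26-connectivity; GLDM dependence
  tolerance α = 0 and the dependence size counts the center voxel, so
  size ≥ 1. NGTDM uses the 26-neighborhood mean with voxels lacking
  in-mask neighbors contributing zero difference. Degenerate
  single-level regions return limit values (entropies/contrasts 0,
  uniformity 1, GLCM correlation and MCC 1, NGTDM coarseness capped at
  10⁶), never NaN.
* Coordinates are (z, y, x), 0-based; masks binarize at 0.5; spacing
  comes from the volume (file header when reading NIfTI).

Every texture family, the first-order set, and the shape set are checked
against exhaustive loop-based oracles on ≤ 5³ volumes at 1e-10.

## ICC filter

ICC(2,1) — two-way random effects, absolute agreement, single
measurement — per feature across the two raters' matrices:
`(MS_R − MS_E) / (MS_R + MS_E + 2(MS_C − MS_E)/n)`. Features with
ICC > 0.80 (strict) are retained; zero-variance features get a NaN
sentinel and are dropped. A consistency variant (ICC(3,1)) is
config-switchable. Filtering is per phase; the ALL-P design matrix
concatenates each phase's own retained set (no intersection across
phases). The implementation is validated cell-for-cell against a
from-scratch ANOVA oracle and against pingouin.

## Stability selection

For each one-vs-rest indicator (or a numeric outcome directly): every
base learner runs `n_repeats` independent stratified 5-fold shuffles —
stratified on the full 3-class labels, so the 209:25:29 imbalance is
preserved per fold — giving 5 fits per shuffle (train 80% / validate
20%). Per fit, features are standardized on the training split only and
an L1 path is evaluated on a fixed grid (0.001–0.3); the penalty is the
largest one within one standard error of the minimum validation MSE
(the glmnet `lambda.1se` convention). The plain minimum-MSE rule is
available (`penalty_rule="min"`) but over-admits noise: at the
minimizing penalty, noise features carry nonzero coefficients in
20–60% of fits, which defeats frequency-based selection; the 1-SE rule
drops the noise median to ≈ 0. Fits with validation R² > 0.8 are
retained; frequency = nonzero count / retained fits; selected =
frequency ≥ 0.2; the 3-class selection is the union over the three
indicators. If no fit clears the R² bar the selection is empty with a
warning status (the pipeline then falls back to the ICC-retained set so
downstream models stay defined, and says so).

Study-scale defaults are 10 learners × 1000 repeats; tests and examples
scale `n_repeats` down (the selection frequencies stabilize quickly).

## Subtype models and evaluation

OvR logistic sub-models are fitted by unpenalized maximum likelihood
(lbfgs, tol 1e-8); quasi-separated fits — easy when a fold holds five
pRCC cases — fall back to a weak ridge (C = 10³) and are flagged.
Prediction is the highest class probability; exact ties resolve toward
the more prevalent training class. Repeated stratified 5-fold CV scores
every subject exactly once per repeat; reported accuracy is the mean of
per-repeat accuracies, and the aggregated confusion matrix uses each
subject's majority-vote prediction across repeats. Binary tasks
(subtype vs rest) rerun stability selection on the binary indicator
before fitting. The traditional control model screens clinical
covariates (Kruskal-Wallis for continuous, Pearson chi-square without
continuity correction for categorical; degenerate contingency tables
are excluded with a warning) at p < 0.05 and feeds the survivors —
dummy-coded — to the same OvR machinery.

AUC is the Mann-Whitney pair statistic with ties counted ½. The DeLong
test uses structural placement values; per-positive and per-negative
covariance components give `Var(ΔAUC)`, a two-sided normal p follows,
and a zero-variance difference (identical scores) returns p = 1 with a
degenerate flag. Paired model comparisons in the pipeline use each
subject's mean validation score across repeats. Displayed metrics round
half-up to 2 decimals; raw values are kept in the CSVs. No
multiple-testing adjustment is applied (comparison p-values are
reported unadjusted).

## Pipeline scales

The full study-scale configuration (263 subjects, 64³ grids, 10×1000
selection repeats, 1000 CV repeats) is expressible but slow; the shipped
tests use three scales chosen as reasonable desk-scale analogues: a
smoke scale (20/5/5 subjects, 16³ grids, 2×5 selection repeats, 10 CV
repeats) for end-to-end artifact and determinism checks, a dominance
scale (60/12/14 subjects, 24³ grids, 2×10 selection repeats, 100 CV
repeats) for the multiphase-vs-single-phase ordering, and full-scale
single subjects (64³) for the feature-roster checks. Every stage seed
derives from the run's global seed through named hash substreams, so
stages are individually rerunnable from cached artifacts with identical
output.

## Known limitations

* The published per-model AUCs on the real cohort are not reproducible
  without the patient images; the package substitutes property-based
  evidence (oracles, planted-signal recovery, calibration checks, the
  dominance ordering) on synthetic cohorts.
* Shape features inherit the resolution-dependent chamfer bias of
  level-set meshing on digitized masks.
* No filtered-image (wavelet/LoG) features, no resampling pipeline, no
  2D per-slice features, no DICOM ingestion.
* The logistic fallback ridge, while weak, means coefficients in
  separated folds are penalized estimates rather than MLEs (which do
  not exist there).
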