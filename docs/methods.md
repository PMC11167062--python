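# Methods

This note documents the models implemented in `braingap`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## The regional normative model

For a region *R* (an ordered set of atlas ROIs on one side) and a
participant with sparing profile *s* (per-ROI fraction of voxels outside the
lesion), the intact subset is

    intact(R) = { r ∈ R : s_r ≥ 0.99 } ,

with the threshold applied inclusively on exact voxel ratios.  On the
within-range controls, chronological age is regressed by ordinary least
squares on the TIV-normalized gray-matter volumes of `intact(R)` (intercept
always included); the participant's volumes are entered into the fitted
model to give the regional brain age, and BrainGAP = brain age −
chronological age.  Each participant therefore gets their own control
regression per region; identical intact subsets share one cached fit.

Choices worth stating explicitly:

* **Plain OLS, no regularization.**  Unpenalized fits are what make a
  single-ROI model's predictions perfectly (anti)correlated with that ROI's
  volume — a property the downstream correlation analyses rely on, and one
  the test suite asserts to 1e-12.
* **Hard identifiability contract.**  A fit requires more controls than
  ROIs plus one and a full-column-rank design; violations raise
  `ModelFitError` rather than falling back to a pseudo-inverse.  When the
  design is legal but has fewer than three controls per ROI (the
  whole-hemisphere regime: 94 ROIs on ~120 within-range controls), a
  `ConditioningWarning` is emitted and the fit proceeds — such models
  interpolate heavily and their coefficients should not be interpreted.
* **Residual diagnostics use in-sample control residuals**, the only
  residuals the procedure produces.  Because OLS with an intercept forces
  the residual mean to zero exactly, the "ROI count vs residual mean"
  correlation is reported as undefined-by-construction rather than computed
  from rounding noise; the "ROI count vs residual SD" correlation is the
  informative one and is negative on lesioned cohorts (fewer predictors →
  wider normative residuals).
* **Volumes enter TIV-normalized** (`Σ gm_fraction × voxel_volume / TIV`),
  the same quantity used everywhere else in the pipeline.

## The whole-brain screen

The screen needs only a whole-brain age per control.  Externally computed
brain ages can be supplied as a per-participant column and are used
verbatim.  The built-in surrogate mirrors the structure of published
voxelwise brain-age pipelines at ROI resolution: center the ROI-volume
matrix, take the smallest principal-component prefix whose cumulative
explained-variance ratio reaches the configured fraction (default 0.80;
zero-variance directions are never retained), and regress age on the
retained scores.  The component-count rule is implemented directly (numpy
SVD) so the "smallest prefix reaching the fraction" boundary is exact.

"Within 5% of chronological age" is read as |BA − CA| ≤ 0.05 · CA,
inclusive — the reading consistent with the worked example in which a brain
age of 82 at chronological age 80 is within range and 85 is not.  The
denominator is chronological age.

## The mixed ANCOVA

The 2 (group) × 2 (hemisphere) design with hemisphere within-participant and
covariates (age, education, sex, handedness) is computed by the exact
decomposition of the balanced two-condition repeated-measures design:

* between-participant terms (group, covariates) by OLS on participant
  hemisphere *means*;
* the hemisphere main effect and the group × hemisphere interaction by OLS
  on the left-minus-right *differences*, with sum-coded group and centered
  covariates so that the intercept of the difference model is the
  hemisphere effect.

For a balanced 2-level within factor this coincides with a participant-level
random-intercept model, but it yields exact finite-sample F tests — which is
why the interaction's type-I rate calibrates to its nominal 5% in the
Monte-Carlo checks, something a normal-approximation Wald test from an
iteratively fitted mixed model would not do at these sample sizes.
Categorical covariates are treatment-coded in the between stratum with
reference levels fixed by category order; a covariate with a single observed
level is dropped from the design.  All tests are two-sided.

## The synthetic cohort

Per participant *i* and ROI *r*:

    v_ir = b_r + m_r · (age_i + δ_i [+ Δ if patient and r is left]) + ε_ir ,
    ε_ir ~ N(0, (noise_sd · b_r)²),   δ_i ~ N(0, brainage_sd²)

* `b_r` defaults to the ROI's geometric volume fraction of the labelled
  grid, so volumes are TIV-normalized and sum to ~1 at age 0.
* `m_r = −rate_r · b_r` with per-ROI atrophy rates drawn once per seed from
  U(0.2%, 0.5%) per year — the magnitude of adult cortical gray-matter
  decline reported in longitudinal morphometry.
* `noise_sd` defaults to 1% of baseline, i.e. ≈ 3 years of age-equivalent
  measurement error per ROI — segmentation-level noise.
* `δ_i` (default SD 3.5 y) is the participant's biological brain-age
  deviation: the whole brain genuinely looks that much older or younger.
  It is what makes the whole-brain screen informative; with the default
  scale, roughly half of a 232-control cohort falls outside the 5% band,
  matching the proportions the screening step is designed around.  Brain-age
  model errors of a few years are typical of published estimators.
* Premature aging is injected as an **age offset** Δ (default 8 y) on
  left-hemisphere ROIs of patients, so the regional ground truth is
  literally `age + Δ` and recovery can be asserted exactly in the noiseless
  single-ROI limit.
* Lesions are spheres (radius U(4, 12) mm by default) centered uniformly on
  left-hemisphere-labelled voxels and clipped to left-hemisphere labels;
  ROI volumes are multiplied by their geometric spared fraction, so
  lesioned volumes never exceed their unlesioned counterfactuals.
* Behavior: `score = β₀ + β_gap·gap + β_gm·gm + β_lesion·lesion_volume +
  β_age·age + noise`, clipped to [0, 100], with distinct coefficient sets
  per WAB-R-type score and signs chosen so that larger gaps/lesions and
  older age score worse.  The generating `gap` is the left domain-general
  BrainGAP as the default analysis computes it at simulation time, recorded
  in `truth.json`.

All randomness flows from one seed through named `SeedSequence` spawn keys,
so each participant's draws are independent of cohort size and of lesion
settings (disabling lesions changes nothing else), and fixed seeds give
byte-identical cohort directories (masks are written as uncompressed NIfTI
for this reason).  TIV is recorded but constant per atlas — generated
volumes are already TIV-fractions, so an independently varying TIV would
never re-enter any computation.

### What the generator does *not* emulate

Realistic lesion topology (vascular territories), white-matter
hyperintensities, nonlinear atrophy trajectories, spatial covariance between
neighboring ROIs beyond the shared age factor, scanner/site effects, and
age-correlated lesion size.  Passing tests therefore demonstrate that the
*procedure* is correct and calibrated under its stated assumptions — linear
normative structure, exchangeable noise — not that real cohorts satisfy
those assumptions.

## Numerical and degenerate-input choices

* Lesion masks: integers must be 0/1; floats must lie in [0, 1] and are
  binarized at > 0.5 (smoothed hand-drawn masks); spared fractions are exact
  integer voxel ratios.
* Overlap and volume computations agree with brute-force voxel loops
  exactly (integer masks) or to 1e-9 (fractional gray matter); verified on
  grids up to 32³.
* In a noiseless linear cohort every ROI volume is exactly collinear with
  age, so any multi-ROI design is rank-deficient; per the identifiability
  contract this raises `ModelFitError`.  Exact offset recovery is therefore
  asserted on single-ROI regions, and multi-ROI recovery at small noise.
* Degenerate statistics are reported, not raised: identical t-test samples
  give t = 0, p = 1; correlations on constant inputs or fewer than 3 pairs
  are NaN with a note; constant behavior predictors are dropped from the
  design with a note; collinear predictors trigger a VIF warning.

## Validation scales

The test suite and acceptance script size their simulations to single-CPU
desk scale: the study-scale run uses 232 controls and 50 patients on the
packaged 189-parcel grid atlas (23×22×22 voxels of 2 mm), and the type-I
calibrations run hundreds of full-pipeline replicates on a 16-parcel
reduced atlas (60 controls, 24–30 patients per replicate).  Under these
conditions the pipeline recovers the injected 8-year offset to within a few
tenths of a year in the left hemisphere and ~0 in the right, rejects the
null interaction at ≈5% and null behavior predictors at ≈1%, and reproduces
the negative dispersion relationship between ROI count and residual SD.

## Known limitations

Single-timepoint design (no rates of aging); the surrogate screen shares
the training controls with the regional models (as does the emulated
procedure — out-of-range controls are the only lesion-free group that can
receive regional estimates); in-sample residual diagnostics understate
predictive error for near-saturated models; the packaged catalogue's parcel
names are representative, not an official atlas release.
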