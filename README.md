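# braingap

Lesion-adaptive **regional brain-age** estimation for stroke-aphasia research.

After a left-hemisphere stroke, the surviving tissue of the lesioned
hemisphere often looks *older* than the person's birth certificate says —
and how much older may matter for language outcomes.  `braingap` implements
a normative-modeling pipeline that quantifies this per brain region while
adapting, participant by participant, to where the lesion is:

1. **Whole-brain screen.**  A whole-brain age is estimated for every healthy
   control (either supplied externally, or by the built-in surrogate: PCA on
   ROI gray-matter volumes retaining 80% of the variance, then linear
   regression of age on the retained components).  Only controls whose
   estimated brain age lies within 5% of their chronological age
   ("within-range" controls) are allowed to train regional models; the rest
   ("out-of-range" controls) become the lesion-free comparison group.
2. **Lesion-adaptive regional models.**  For each participant and each named
   region *R* (hemispheres, domain-general, language-specific, four lobes,
   split by side), the ROIs of *R* at least **99% spared** by the
   participant's lesion are selected.  On the within-range controls an OLS
   normative model is fitted,

       age_i = β₀ + Σ_{r ∈ intact(R)} β_r · v_ir + ε_i ,

   where `v_ir` is the TIV-normalized gray-matter volume of ROI *r*.
   Entering the participant's own volumes gives their regional **brain age**,
   and

       BrainGAP = brain age − chronological age ,

   with positive values indicating premature regional aging.  A region with
   zero intact ROIs is excluded (flagged, never silently dropped).
3. **Statistics.**  A 2 (group) × 2 (hemisphere, within-participant) mixed
   ANCOVA on domain-general BrainGAP with age, education, sex and handedness
   as covariates; Pearson correlation batteries (left-vs-right brain age,
   Bonferroni α = 0.05/7; brain age vs gray-matter volume, α = 0.05/14);
   residual-dispersion diagnostics relating each model's ROI count to the
   spread of its control residuals; and per-score OLS regressions of WAB-R-type
   behavior (AQ + 4 subscores, α = 0.05/5 = 0.01) on BrainGAP, gray-matter
   volume, lesion volume, age and ROI count.

Because real cohorts of this kind cannot be redistributed, the package ships
a **synthetic-cohort generator** with known ground truth: controls with
ROI-specific linear age-atrophy, stroke participants with spherical
left-hemisphere lesions plus an injected premature-aging offset Δ (so the
regional ground truth is literally `age + Δ`), and behavior generated from a
known linear model.  Every pipeline stage is validated against this ground
truth.

## Worked example

```bash
braingap simulate --out demo/cohort --n-controls 120 --n-patients 20 --seed 42
braingap analyze --cohort demo/cohort --out demo/results --regions domain_general
```

prints (output of the exact commands above):

```
controls: 120 (within-range 62, out-of-range 58)
stroke participants: 20

mixed ANCOVA on domain-general BrainGAP:
  group: F(1,71) = 9.595, p = 0.002794
  age: F(1,71) = 7.982, p = 0.006128
  education: F(1,71) = 0.632, p = 0.4293
  sex: F(1,71) = 0.019, p = 0.8912
  handedness: F(2,71) = 0.233, p = 0.7925
  hemisphere: F(1,71) = 24.948, p = 4.065e-06
  group:hemisphere: F(1,71) = 234.726, p = 3.317e-24

age t-test (out-of-range controls vs stroke): t(76) = -0.173, p = 0.8633; means 46.20 vs 46.97
residual dispersion left_domain_general: r(n_rois, sd) = -0.609 (p = 0.004368), ...
```

Reading this: 62 of 120 controls passed the 5% whole-brain screen and
trained the regional models.  The stroke group was simulated with an 8-year
premature-aging offset in the left hemisphere only, and that is exactly what
the statistics find — a massive group × hemisphere interaction
(F(1,71) = 234.7) with no age difference between groups (t ≈ −0.17).  The
negative dispersion correlation (−0.61) shows that regional models built
from fewer intact ROIs have noisier control residuals, i.e. brain-age
estimates from heavily lesioned regions are less precise.  All effect tables
land in `demo/results/` as TSV/JSON, together with the full config and seed.

The library API mirrors the stages (`simulate_cohort`, `fit_global_model`,
`partition_controls`, `estimate_participant`, `mixed_ancova`,
`behavior_regression`, ...); see the module docstrings and
`docs/methods.md` for the model details and design choices.

## Atlas and region groupings

The packaged atlas catalogue (`braingap.packaged_roi_table()`) is a
**synthetic reconstruction** of a JHU-style parcellation: 189 parcels — 94
per hemisphere plus one midline parcel — grouped into hemispheres (94/94),
domain-general (8 per side), language-specific (9 per side), frontal (16),
temporal (13), parietal (6) and occipital (5) regions per side.  The region
sizes are faithful to the standard grouping; parcel names are
representative.  Real atlases load through `load_atlas()` (NIfTI labels +
TSV lookup) and `load_region_groupings()` (YAML), with lesion masks and
gray-matter images required to share the atlas grid exactly — no resampling
is ever performed.

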