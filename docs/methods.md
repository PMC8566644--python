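# Methods

`dynfet` re-implements, as a tested Python pipeline, the analysis chain that
takes dynamic amino-acid PET ([18F]FET) brain studies to a preoperative
classifier of TERTp-mutation status: parametric imaging, IBSI-style
radiomics, and class-balanced logistic modelling.  Because clinical dynamic
FET-PET cohorts are not redistributable, the package also ships a seeded
phantom generator that reproduces the *structure* of such data with known
ground truth; every empirical statement below is one the test suite or the
acceptance script computes itself.

## Dynamic acquisition model

A study is a 4D activity volume with a frame schedule.  The default schedule
is the fixed 16-frame, 40-min protocol of the ECAT HR+ era: 7 x 10 s,
3 x 30 s, 1 x 2 min, 3 x 5 min, 2 x 10 min (total 2380 s), with the
reconstructed voxel size 2.03 x 2.03 x 2.43 mm³.

## Synthetic phantoms

Each voxel's time-activity curve (TAC) is a piecewise-linear **tent**:
a linear rise from `baseline` to `amplitude` at `peak_time_min`, then a
linear limb with slope `washout_slope` (floored at the baseline when
decreasing; a positive slope encodes the slowly increasing pattern of
indolent tumours).  A tent rather than a compartment model, because the
downstream pipeline consumes only peak timing and late slope, and the tent
makes per-frame duration-weighted averages available in closed form — every
frame value is the exact integral of the curve over the frame, which is how
a scanner accumulates counts, and which gives the tests an analytic oracle
(the suite cross-checks the closed form against adaptive quadrature).

A phantom cohort contains, per patient:

* a flat "brain" background at activity 1.0 filling the grid (default
  32 x 32 x 22 voxels at the scanner spacing), with a **fixed
  crescent-shaped background VOI** in the contralateral half, emulating the
  clinical healthy-hemisphere reference region;
* an **ellipsoidal tumour** (jittered centre and semi-axes, roughly 200-400
  voxels) in the other hemisphere;
* per-tumour-voxel kinetics drawn from a two-archetype mixture: early
  peak (4-10 min) with washout, or late-increasing.  The patient-level
  mixing fraction `f` is where the label acts: mutants sit near `f = 0.5`
  (a salt-and-pepper mixture of kinetic archetypes — a spatially
  heterogeneous TTP map), wildtype tumours are shifted by
  `f -> 0.5 − 0.45·effect` toward a nearly pure late-increasing, homogeneous
  tumour.  At `effect = 0` the two classes are exchangeable by construction.
  The default `effect = 1.0` encodes the working hypothesis that kinetic
  heterogeneity separates the classes clearly; it is the generator's
  definition of "signal present", not a fitted quantity.
* additive zero-mean Gaussian frame noise (default sd 0.05, i.e. 5% of the
  background level), clipped at zero.  No quantitative noise model for real
  TACs was available, so this is a plain stand-in; nothing downstream
  depends on its realism.

Tumour TACs are rescaled multiplicatively (TTP categories are
scale-invariant) so that every tumour voxel's noise-free 20-40 min TBR
stays above the 1.6 segmentation threshold with 5% headroom.  Label counts
are exact: `round(n_patients x wildtype_fraction)` wildtype.  One master
seed is split into independent streams for labels, geometry, kinetics and
noise, so cohorts are bit-reproducible.

What the phantom does **not** emulate: scanner physics (attenuation,
scatter, reconstruction filters), motion, blood-pool input functions,
realistic anatomy, or spatially correlated noise.  Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover a planted
kinetic-heterogeneity signal — not clinical performance on real cohorts.

## Parametric images

* **Summation images** average the frames whose mid-time lies in
  `[t0, t1)` minutes, weighted by frame duration.  Mid-time selection is
  deliberate: the printed schedule's frame edges (4.67 / 14.67 / 19.67 /
  39.67 min) never align with the nominal 5 / 15 / 20 / 40-min cuts, and
  the mid-time rule selects exactly the intended two 5-min frames for the
  early window and the two 10-min frames for the late window.
* **TBR maps** divide a summation image by the mean activity of the
  background VOI, so the background mean of a TBR map is exactly 1.
* **Tumour segmentation** thresholds the late TBR map at TBR >= 1.6
  (inclusive, consistent with excluding tumours *below* 1.6) and keeps the
  largest 26-connected component; a study with no voxel above threshold
  raises a dedicated FET-negative error.  Connectivity handling is a
  package choice — a single contiguous VOI matches clinical delineation.
* **TTP maps**: each tumour voxel's TAC is classified into six
  time-to-peak categories (< 5, 5-10, 10-15, 15-20, 20-30, 30-40 min).
  Two special rules: (a) frames ending within the first 2.7 min (162 s;
  exactly the ten short early frames of the default schedule) are excluded
  from the arg-max, suppressing the vascular blood flush; (b) if the OLS
  slope of frame value against frame mid-time over the 15-40 min frames is
  strictly positive, the voxel is category 6 regardless of the arg-max.
  Arg-max ties go to the earliest frame.  Voxel values are the category
  midpoints in minutes (2.5 ... 35), a choice made so that the 5-min fixed
  bin width of the radiomics stage maps each category to its own discrete
  grey level; whether the original software stored indices, frame times or
  midpoints is not documented, so the midpoint encoding is our convention.
  Strict (rather than non-strict) positivity of the late slope is likewise
  a documented choice.

## Radiomics engine

107 features per image: 18 first-order, 14 shape, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM — the canonical default split of the standard
toolkit, adopted here as the definition of "107".  No image filters.
Settings and conventions:

* **Resampling** to 2.03-mm isotropic voxels; trilinear for the image,
  nearest-neighbour for the mask, origin-aligned grid with
  `floor(extent / spacing)` voxels per axis.  NaN voxels (outside-VOI
  values on TTP maps) are nearest-filled before interpolation so trilinear
  weights never mix tumour values with an arbitrary fill constant.
* **Discretisation**: fixed bin width anchored at the masked minimum
  (`level = floor((v − min)/w) + 1`).  Defaults: 0.18 (early TBR), 0.13
  (late TBR) — the published cohort-level IQR/4 values, also derivable from
  any training cohort via `iqr4_bin_width` (mean per-patient interquartile
  range / 4, quartiles by linear interpolation) — and 5 min for TTP maps,
  the smallest frame duration among the categories.
* **Texture matrices**: GLCM and GLRLM use the 13 unique 3D directions at
  distance 1, features computed per direction then averaged (grey levels
  with no pairs along a direction are dropped from that direction's
  matrix); GLCM matrices are symmetric.  GLSZM zones and GLDM dependence
  use the 26-neighbourhood; GLDM has alpha = 0 and its dependence size
  counts the centre voxel.  Matrices are indexed by the grey-level
  *values* present (fixed-bin discretisation can leave gaps), so
  intensity-weighted features use true bin numbers.
* **Degenerate conventions**: single grey level gives GLCM Correlation = 1
  and MCC = 1; NGTDM Coarseness returns 1e6 when its denominator vanishes,
  Busyness/Strength return 0; a single-voxel mask reports axis lengths 0.
* **Shape**: marching-cubes mesh of the zero-padded binary mask at level
  0.5 (surface area, mesh volume, sphericity), principal components of the
  physical voxel centres (population covariance) for the axis lengths,
  and maximum pairwise mesh-vertex distances for the 3D and in-plane 2D
  diameters (Slice fixes z, Column fixes x, Row fixes y).

The tests verify the whole vector against an independent naive reference
implementation (plain loops straight from the published definitions) to
1e-4 relative on 20 random fixtures, with third-party cross-checks where a
library offers one: scikit-image's 2D co-occurrence counts, scipy's
moments, trimesh's mesh volume/area, and scipy interpolation for the
resampler.

## Modelling

Stratified 70/30 split (per-class shuffle, `round(n_class x 0.7)` half-up
into training).  Feature z-standardisation uses training statistics only,
with the population (divisor n) convention of the common scaler — recorded
because divisor n vs n−1 is often left unstated.  Near-duplicate features
(|Pearson r| > 0.99) are dropped deterministically: features are visited
alphabetically and the later member of an offending pair is removed.

Feature selection is RFE under L2-regularised (C = 1), class-balanced
logistic regression (`w_k = n/(2 n_k)`): one feature removed per
iteration, importance = |coefficient| on standardised inputs, ties to the
alphabetically first name.  The feature count is chosen by mean
out-of-fold AUC over stratified 10-fold CV, re-ranking the path inside
every fold; ties go to the smallest count.  (The selection criterion is
fixed here as maximal mean AUC with smallest n — descriptions of this
step elsewhere are ambiguous, so the package documents its own rule.)
The final model is a balanced logistic fit on the selected features;
prediction is P = sigmoid(theta0 + theta^T x), "mutant" iff P > 0.5
strictly.

Evaluation reports AUC (rank statistic with tie correction), accuracy,
sensitivity, specificity, PPV and NPV at the 0.5 threshold with mutation
as the positive class, and 95% percentile CIs from 1000 bootstrap
resamples, stratified by class so no resample loses a class; whether the
original bootstrap was stratified is unstated, and stratification is the
variant that keeps all six metrics defined.

## Problem sizes and determinism

The end-to-end recovery checks run cohorts of n = 160 (20% wildtype) over
ten fixed seeds for the signalled case and ten for the null; the held-out
TTP-model AUC exceeds 0.75 in at least 8/10 signalled seeds while the null
seed-distribution straddles 0.5.  Unit fixtures stay below 20³ voxels.
Every random stage — cohort generation, split, CV folds, bootstrap — is
driven by explicit integer seeds, and rerunning any stage with the same
configuration reproduces its artifacts bit-for-bit.

## Known limitations

* The phantom's two-archetype tent kinetics are far simpler than real FET
  uptake; absolute feature values and model AUCs on phantoms say nothing
  about clinical cohorts.
* Real-cohort results (the published clinical AUCs) are not reproducible
  here because the patient data are unavailable; the package deliberately
  reproduces the *method*, the recomputable cohort arithmetic and the
  feature definitions instead.
* GLCM/GLRLM direction handling, the discretisation anchor, the TTP voxel
  encoding and the RFE regularisation strength are all documented package
  choices where the source protocol is silent; alternatives would change
  third-decimal feature values, not the pipeline's behaviour.
* Motion correction, scanner harmonisation (ComBat), MRI fusion and
  whole-image deep learning are out of scope.
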