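# Methods

`nephrotex` studies how MRI preprocessing choices — intensity
normalization, pixel resampling, and gray-level discretization — propagate
into radiomic feature values, feature reproducibility, and downstream
genotype classification for polycystic kidney disease imaging. Because the
clinical cohorts this design targets are access-restricted, every stage
runs on synthetic phantoms whose statistical structure mirrors what the
analysis assumes about T2-weighted fat-saturated (T2W-FS) abdominal MRI.

## Phantom model

Each case is a 2D image (default 320×320 px at 1.25 mm spacing, inside the
clinically typical 256–560 px / 0.63–1.8 mm ranges) containing:

- **Kidney**: an ellipse (default 90×45 mm) filled with a Gaussian random
  field: white noise convolved with an isotropic Gaussian kernel and
  rescaled to mean 100, SD 15 signal units. The kernel's correlation
  length is the class-separating knob: 2.0 mm for the PKD1-like class,
  3.5 mm for the PKD2-like class. A Gaussian random field was chosen
  because it produces a second-order (texture) difference detectable by
  GLCM-family features without any first-order mean shift, which is the
  kind of signal the feature panel is meant to detect. No quantitative
  estimate of the real parenchymal texture difference between genotypes
  exists, so the effect size is a simulation parameter, fixed once at a
  level a texture classifier can recover; setting both correlation
  lengths equal yields an exact null cohort.
- **Cysts**: disks (radius 3–10 mm, default 8 per kidney) at
  `cyst_contrast × parenchyma_mean` (default 2.5×), placed by rejection
  sampling inside the kidney eroded by the cyst radius (max 1000 retries,
  then a named error). Cysts are hyperintense, as on T2W-FS.
- **Psoas muscle**: a disjoint ellipse at mean 40, SD 5 — hypointense, as
  muscle is on T2W-FS — used as the reference tissue for normalization.
- **Site effect**: a per-site affine intensity map, scale ∈ [0.5, 2.0] and
  offset ∈ [0, 50], a pure function of the site id so all cases of a site
  share it; additive Gaussian noise (SD 5) is applied after the site map.
  This mimics the arbitrary signal scales of different scanners and is
  exactly removed by z-scoring and approximately by reference-tissue
  normalization.

Cohorts are class-balanced with sites assigned round-robin identically in
both classes (site-matched). Per-case seeds derive from the master seed
via `SeedSequence`, so a case is a pure function of
(parameters, class, site, seed) and reruns are bitwise identical.

What the phantoms deliberately do **not** model: anatomy (shape,
left/right kidneys, 3D volumes), MR physics (bias fields, partial volume,
rician noise), or any real genotype effect size. Passing tests therefore
demonstrate that the pipeline machinery is correct and sensitive to a
second-order texture signal under site-confounded intensity scales — not
that real PKD1/PKD2 kidneys are separable at any particular AUC.

## Preprocessing

Three normalization arms: `original` (none), `zscore`
(`(X − μ)/σ` with moments over the **entire** image, background included),
and `reference` (affine map sending the psoas ROI to mean 100, SD 10).
Both normalizations are affine, so affine-invariant statistics (skewness,
kurtosis, any correlation) are untouched by arm choice — the mechanism
behind the reproducible-feature results.

Spatial harmonization: resize to a 256×256 analysis matrix, then resample
to 1.0 mm (upsampling) or 2.0 mm (downsampling), both nearest-neighbor.
The pipeline order is fixed as **normalize → resize → resample**, with
normalization statistics always taken on the native-resolution image (the
reference stats from the native psoas mask); this keeps the normalization
parameters independent of interpolation. The nearest-neighbor convention
is pixel-center alignment with ties broken toward the lower index
(`index = ceil(center − ½)`), chosen so tests can be bit-exact. Masks are
always resampled nearest-neighbor and stay binary.

## Discretization

Fixed bin size (FBS). The bin width is cohort-derived:
`W = mean(per-image whole-image range) / N_b`, recomputed per
(normalization × resampling) arm — necessary for a given bin count to mean
the same physical width across arms — and recorded in the run manifest.
ROI intensities then map to `⌊X/W⌋ − ⌊min(X_roi)/W⌋ + 1`, anchoring the
minimum level of every ROI at 1 (the pyradiomics FBS dialect; IBSI
anchors at the ROI minimum intensity instead). Six bin counts are
studied: 8, 16, 32, 64, 128, 256. The whole-image (not ROI) range is used
for `W`; ROI-range is available via `cohort_bin_width` on ROI arrays for
sensitivity checks. Fixed-bin-number discretization is out of scope.

## Feature panel (93 features)

First-order (18), GLCM (24), GLRLM (16), GLSZM (16), NGTDM (5),
GLDM (14); the full name manifest is `nephrotex.features.names`.
Conventions, following the pyradiomics dialect:

- formulas weight by actual discretized level values; empty gray levels
  are dropped from the matrices;
- GLCM: symmetric, distance 1, four 2D directions (0°, 45°, 90°, 135°);
  features computed per direction, then averaged. Same for GLRLM.
  GLSZM uses 8-connected zones; NGTDM a 3×3 neighborhood (pixels without
  any in-mask neighbor are excluded); GLDM uses the 4-neighborhood at
  distance 1 with similarity tolerance 0, and the stored dependence size
  is the neighbor count plus one (so sizes start at 1).
- out-of-mask neighbors are ignored, never padded;
- first-order features use raw (normalized) intensities except entropy
  and uniformity, which use the discretized histogram; variance, skewness
  and kurtosis use population (1/N) moments and kurtosis is not excess;
- degenerate rules: GLCM correlation and MCC are 1 for a single-level
  ROI; NGTDM coarseness is capped at 1e6 when Σpᵢsᵢ = 0; single-pixel
  ROIs flag skewness/kurtosis. All degeneracies are reported in a flags
  map on the feature vector, never silently dropped.

Every texture feature is verified against an independent brute-force
enumeration (per-pixel loops over pairs, runs, flood-filled zones,
neighborhoods) on random grids.

## Reproducibility (ICC)

For each feature and each (bin count × resampling) cell, a rating matrix
is formed with kidneys as rows and normalization arms as "raters", and the
two-way mixed-effects, consistency, single-rater intraclass correlation is
computed from the ANOVA decomposition:
`ICC = (MSR − MSE) / (MSR + (k−1)·MSE)`. Consistency ICC ignores fixed
rater offsets; it can be negative, and negative values are reported as
computed (categorized poor) rather than truncated. Categories: poor
(< 0.5), moderate ([0.5, 0.75)), good-to-excellent (≥ 0.75; the good and
excellent bands merged, with 0.75 in the upper band). Matrices with zero
total variation are flagged degenerate and excluded from category
fractions with an exclusion count. Rater subsets of size two give the
pairwise comparison reports. The implementation is cross-checked against
pingouin's ICC(C,1) in the test suite only.

## Classification

Binary class labels, one feature vector per subject (phantoms model one
kidney per subject). Per training partition of a stratified 5-fold CV
repeated 10 times: features are ranked by orientation-folded univariate
AUC (`max(a, 1−a)`, rank-based with ties counted half; folding is for
ranking only), admitted greedily while |Pearson r| < 0.7 against every
already-admitted feature, capped at 10; training-partition z-scaling (for
numerical conditioning only) feeds an unpenalized maximum-likelihood
logistic regression; held-out AUC is recorded. Ties break
lexicographically on feature name; all RNG streams derive from one master
seed. The summary interval is the 95% normal-theory interval of the mean
over the 50 fold AUCs (an interval definition had to be fixed; this one
is recorded in the manifest). Selection and scaling never see held-out
rows — verified by a leak-detector test. The full grid is 2 ROI kinds ×
3 normalizations × 2 resamplings × 6 bin counts = 72 cells.

## Problem sizes and numerical choices

Default study conditions: a 29-kidney cohort for the reproducibility
study and a 136-subject (68 per class, 7 sites) cohort for
classification. The test suite exercises the reproducibility criterion on
the 29-kidney cohort over a representative sub-grid (bin counts 8 and 64,
both resamplings — the qualitative ICC contrast is monotone in bin count,
so the extremes span the range) and the recovery/null criterion on full
136-subject cohorts at one setting (z-score, downsampling, 32 levels);
determinism is checked by rerunning both studies end-to-end on a reduced
configuration and comparing output trees byte for byte. Oracle
equivalence for the texture engine runs on 260 random grids up to 8×8
with up to 6 levels, to float precision (rel 1e-9).

Known limitations: 2D only; no shape or filtered-image features; one
kidney per subject (no left/right aggregation); consistency ICC treats
kidneys as independent units; the phantom texture model cannot say
anything about real effect sizes.
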