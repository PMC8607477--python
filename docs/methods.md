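# Methods

This note documents the models, conventions and numerical choices behind
`mrinorm`, and what its synthetic phantoms do and do not show about real
data.

## Image model and geometry

A volume is a 3-D scalar array indexed `[row, column, slice]` with voxel
pitch `(dx, dy, dz)` in mm, an origin and direction cosines in patient
space (DICOM LPS). DICOM series are read one per patient directory; slices
are sorted by position along the slice normal, rescale slope/intercept is
applied at read time so all downstream math sees scanner-exported
real-world values, and adjacent slice gaps must agree to 1e-3 mm
(non-uniform stacks are rejected rather than resampled). NIfTI round trips
store intensities as float32; the declared round-trip precision is
1e-5 of the intensity range for DICOM (16-bit stored values with a
computed slope/intercept) and float32 epsilon for NIfTI.

### Contour rasterization

DICOM-RT contours are closed planar polygons in patient mm. Each contour is
assigned to the nearest slice within half the slice spacing (configurable)
and filled with a voxel-center containment rule: a voxel belongs to the
polygon iff its center is inside, using an even–odd crossing test with a
half-open boundary convention (a center exactly on an edge counts only on
the minimal-coordinate side). This rule is deterministic, independent of
vertex orientation, and makes mask areas exact for axis-aligned rectangles.
The inverse path (mask → polygons, used when exporting phantom cohorts as
RT structure sets) outlines the union of voxel squares, whose boundary runs
along half-integer indices; since voxel centers are integers, write →
rasterize is lossless.

## Standardization transforms

All methods operate on one image's intensities; `Original` is the identity
and is always included in evaluations as the baseline.

* **MinMax**, **Z-All**, **Z-External** and **Fat** are per-image affine
  maps. The z-score uses the population SD (divide by n); the choice only
  rescales outputs uniformly and is fixed for reproducibility.
* **Z-External** takes its statistics over a body mask but transforms every
  voxel with the same affine map.
* **Fat** uses μ_fat = the pooled-voxel mean over the union of the left and
  right cheek-fat masks — not the mean of the two ROI means; the two
  estimators differ only when the ROI sizes differ, and the pooled form is
  the single-estimator reading of "mean intensity of both cheek fat ROIs".
  The scaling constant defaults to 350, making the cheek-fat mean the fixed
  point of the transform. Because the reference is a ratio, the method
  cancels per-patient gain exactly but not additive offsets.
* **Nyul** learns landmark intensities at the percentiles
  {1, 10, 20, …, 90, 99} over each training image's statistics region
  (the body mask by default), maps each image's landmark vector linearly so
  that the 1st/99th landmarks hit a fixed standard scale, and averages the
  mapped vectors across the cohort to form the template. The standard scale
  is fixed to [0, 100]; any fixed scale yields identical SD NMI_c because
  the statistic is scale-invariant. Application maps all voxels
  piecewise-linearly between the image's own landmarks and the template's
  positions; values beyond [p1, p99] are extrapolated with the outermost
  segment slopes rather than clamped, which preserves strict monotonicity
  and avoids intensity pile-up at the scale bounds. Percentiles use linear
  interpolation between order statistics. Images whose 1st and 99th
  percentiles coincide are rejected as degenerate.

By default the body mask restricts Nyul *learning* only; the transform is
applied to all voxels. Masked application is available through the
estimator for analyses that want both restricted.

### External (body) mask

Gaussian smoothing (σ = 1 voxel) → Otsu threshold → largest connected
component → morphological closing (ball radius 3 voxels) → slice-wise hole
fill → largest component. All parameters are exposed in `MaskConfig`. This
is a standard body-mask pipeline, adequate for high-contrast body/air
separation; on very coarse grids the closing step can add a thin shell at
high-curvature poles of the discrete surface, which is negligible at
body-scale resolution. The phantom generator also carries its exact
ground-truth body ellipsoid, which the evaluation pipeline prefers when
present.

## The consistency statistic

For evaluated ROI r, the cohort range is (min, max) of the pooled voxel
intensities of that ROI across all patients — per ROI, not pooled over ROIs
(a pooled-range variant is available behind `pooled_range=True`). The
normalized mean intensity NMI_c(i, r) divides patient i's ROI mean by that
range with no minimum subtraction: subtracting a cohort constant would
shift all patients' NMI equally and leave the standard deviation unchanged.
SD NMI_c uses the sample SD (n − 1); the population convention would scale
every value by √((n−1)/n) and preserve all orderings. ROI voxels are pooled
over all five contoured slices. The two cheek-fat ROIs are excluded from
the evaluated set (12 of the 14 ROIs remain) because they are consumed as
the Fat method's reference and would bias its score.

Key properties, verified by the test suite: SD NMI_c ≥ 0 with equality iff
all patients coincide per ROI; invariance under one global positive affine
map applied to the whole cohort; exact zero for MinMax/Z-All/Z-External on
cohorts that are per-patient affine images of one volume; exact zero for
Fat under per-patient pure gain.

## Statistical comparison

SD NMI_c values form a complete blocks-by-treatments layout (12 ROIs × the
6 methods including Original). The Friedman statistic is computed from
within-block average ranks with ties mid-ranked and **no** tie-correction
factor; the p-value comes from χ²(k − 1). The chi-square approximation at
n = 12 blocks is slightly conservative (empirical type-I error ≈ 0.04 at
α = 0.05 in the null simulation run by the test suite). Pairwise post-hoc
comparisons use the two-sided Wilcoxon signed-rank test with zero
differences dropped before ranking (Pratt's treatment available via
`zero_method="pratt"`), the exact null for ≤ 25 non-zero pairs and the
continuity-corrected normal approximation above, Bonferroni-corrected by
all k(k−1)/2 = 15 pairs. The pairwise matrix is only computed when the
Friedman p-value clears α (default 0.05); an all-zero table (perfectly
consistent cohort) gives Q = 0, p = 1 and a recorded skip. The
Shapiro–Wilk gate is exposed as `test_normality` for checking whether a
parametric alternative would have been defensible.

## Synthetic phantom cohorts

The generator emulates the contrast between a multi-scanner cohort and a
single-protocol cohort without simulating MR physics. The base phantom is a
48 × 48 × 24 grid (1 × 1 × 2 mm) holding a soft-tissue body ellipsoid
(semi-axes 20 × 20 × 11 voxels) in an air background, with the 14 ROIs as
disjoint 5-slice cylinders placed inside the body. Default T2-w-like tissue
intensities (arbitrary units; only ordering/contrast matters): CSF 900,
fat 600, muscle 150, bone 80, brain 350, background 20, each with a
within-tissue texture SD of 5% of the mean. Per patient, the shared base is
modified by gain ~ U(gain_range), offset ~ U(offset_range), a smooth
multiplicative bias field (random second-order polynomial in normalized
coordinates, rescaled to the requested peak fractional deviation) and
additive Gaussian noise. Randomness derives from one seed via spawned
per-patient substreams, so cohorts are bitwise reproducible and independent
of generation order.

Presets: `het_like` = gain U(0.5, 2), offset U(−50, 50), bias amplitude
0.2, noise SD 5; `hom_like` = unit gain, zero offset, no bias, noise SD 2;
15 patients each. Sharing the textured base across patients is a deliberate
design choice: it makes noiseless heterogeneous cohorts *exact* affine
families, so the affine-invariance properties of the methods can be tested
to machine precision rather than statistically.

What passing these tests shows: the pipeline implements the transforms and
the statistic correctly, and reproduces the qualitative headline — intensity
standardization substantially improves ROI consistency when acquisition is
heterogeneous and is near-neutral when it is homogeneous. What it does not
show: behaviour on real anatomy (partial-volume effects, contoured-ROI
placement variability, non-polynomial coil profiles, artifacts), nor the
specific numeric SD NMI_c levels of any real cohort.

## Problem sizes and numerical conventions

Default phantom grids (55k voxels) keep a full 6-method, 15-patient
evaluation under half a second, so the test suite runs 10-seed cohort
sweeps comfortably. Exactness claims in tests use bit-level equality only
where floating-point arithmetic guarantees it (power-of-two gains, shared
base volumes, n-a-power-of-two means); everything else uses explicit
tolerances (1e-10 for affine invariances, 1e-6 for interpolation-level
agreement). Degenerate inputs (constant volumes, empty masks, zero pooled
ranges, collapsed histograms, incomplete blocks) raise typed errors rather
than propagating NaNs.

## Known limitations

* No bias-field *correction* (e.g., N4) — standardization is evaluated on
  images as given.
* No registration, contour editing, multi-frame/enhanced DICOM or
  non-axial acquisitions; one image series per patient directory.
* The Friedman statistic omits the tie-correction factor (ties are rare on
  continuous SD NMI_c values; documented rather than configurable).
* The body-mask recipe is a stated stand-in for site-specific pipelines;
  its parameters are exposed for tuning.
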