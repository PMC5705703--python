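# Methods

## Scope and model of the data

`myeliq` analyzes single-channel 2D micrographs of myelin
immunostaining in cortex: a field imaged at fixed distance from the
external capsule, containing bright, mostly radial (near-vertical)
myelinated axons that branch and cross, over a dim background, with
signal density decaying toward the outer cortical layers (the
myelination gradient). All operations assume an isotropic pixel scale
supplied by the user; nothing is read from proprietary microscope
metadata. Coordinates are 0-based `(row, col)`, origin top-left, row
increasing downward; reported angles are visual (y up), degrees in
(−90, 90] from the x-axis, counter-clockwise positive.

## Segmentation

The myelin-positive mask is produced by a fixed composition:

1. **Background subtraction.** The background estimate is the grayscale
   opening of the image by a Euclidean disk (default radius 50 px) —
   the classical rolling-ball contract: structures narrower than the
   disk survive `image − opening(image)`, broad intensity plateaus do
   not. The opening is computed exactly by decomposing the disk into
   its horizontal chords and running 1D min/max filters per row offset
   (O(radius · n)); pixels outside the image are ignored, so constant
   images are exact fixed points. Unit tests verify pixel-exact
   agreement with a brute-force double-loop disk opening.
2. **8-bit conversion.** Linear rescale of [min, max] to [0, 255] with
   round-half-away-from-zero; 8-bit input passes through unchanged; a
   constant image maps to 0.
3. **Threshold.** Otsu's method by default (exhaustive maximization of
   between-class histogram variance, smallest argmax for determinism;
   foreground is `intensity > t`), with a manual threshold available to
   mirror by-eye thresholding of a stained series. A field that is
   constant after background subtraction raises "no signal detected".
4. **Hole filling** (off by default) and **small-particle removal**:
   8-connected components below `min_particle_area` (default 20 px²)
   are deleted. 8-connectivity is deliberate — 4-connectivity would
   sever fibers running at 45°.

Thresholding after the 8-bit conversion keeps the histogram domain
fixed across bit depths; with a manual threshold the user value is
interpreted on the 8-bit scale.

## Density metrics

* `myelinated_cortex_fraction` = `100 · area(myelinated)/area(total)`
  on user-drawn ROIs (the band boundary is an anatomical judgement; no
  automatic detection is attempted).
* `immunodensity` = mean grey over the signal region − mean grey over a
  background-staining region. When no background ROI is given the
  darkest 5 % of pixels stand in (documented fallback). Negative values
  are reported as computed, with a warning — clipping at zero would
  bias group means.
* `normalize_to_control` maps values to percent of the control-group
  mean, which becomes exactly 100.
* `positive_area_fraction` = percent of the field (or an analysis ROI)
  covered by the mask. It may use a threshold chosen independently of
  the complexity segmentation.

## Structure-tensor coherency

Gradients are Gaussian-derivative filtered (`sigma_gradient`, default
1 px); the products `gx²`, `gx·gy`, `gy²` are smoothed by a Gaussian
window (`sigma_window`, default 4 px — about one fiber spacing at the
default scale); boundaries are reflective. The y-derivative is negated
so the gradient lives in visual (y-up) coordinates. Averaging the
tensor over the ROI (the whole micrograph by default) and taking
eigenvalues λ₁ ≥ λ₂ ≥ 0 gives

* coherency `C = (λ₁ − λ₂)/(λ₁ + λ₂) =
  sqrt((J̄yy − J̄xx)² + 4 J̄xy²)/(J̄xx + J̄yy)`, defined as 0 when the
  energy `J̄xx + J̄yy` is 0 (constant image);
* dominant orientation `θ = ½·atan2(−2 J̄xy, J̄yy − J̄xx)` mapped to
  (−90, 90] — the minus sign pairs with the y-up gradient convention so
  a texture running up-and-right reads as a positive angle.

C is exactly invariant to intensity scaling, ≥ 0.99 on parallel
gratings, ≤ 0.05 on equal-power orthogonal gratings, and agrees with an
explicit separable-convolution oracle to < 1e−10. Coherency is measured
on the grayscale signal, not the binary mask.

## Skeleton morphometry

The mask is thinned to a one-pixel centerline with topology-preserving
axial thinning (Zhang–Suen, via scikit-image), which preserves the
8-connected component count. Skeleton pixels are classified by their
8-neighbor count: endpoints (1), through pixels (2), branch pixels
(≥ 3). 8-adjacent branch pixels merge into one node so a thick junction
counts once; segments are traced between nodes, and a spanning tree
over each multi-pixel branch cluster contributes its internal extent so
junction pixels are not dropped from the length total.

* **Fiber length**: orthogonal steps count `1·pixel_size`, diagonal
  steps `√2·pixel_size`; isolated pixels contribute 0; reported as
  total µm and as µm/mm² of field (the density form is the robust one
  across field sizes). Both total and mean segment length are emitted
  because "fiber length" is ambiguous between the two in common usage.
* **Spur pruning** (default 3 µm): segments joining an endpoint to a
  branch node and shorter than the cutoff are deleted iteratively, with
  re-thinning between passes (deleting a spur can leave a diagonal nub
  that would fake a junction). Free-standing short segments are kept —
  they are fibers, not artifacts of thinning rough edges. The result is
  idempotent and matches an independent leaf-deletion oracle.
* **Intersections**: branch-point nodes after pruning. In
  `analyze_fibers` branch clusters within two fiber diameters of each
  other additionally merge: thinning renders one oblique crossing as a
  pair of Y-junctions separated by up to `w/sin θ ≈ 2w`, and one
  anatomical crossing must count once. The low-level
  `count_intersections` default (adjacency-only merging) keeps the
  textbook semantics (an X counts 1, an H counts 2).
* **Diameter**: the Euclidean distance transform sampled on the
  skeleton measures a pixel-center-to-pixel-center radius; half a pixel
  is subtracted before doubling (`2·(EDT − 0.5)`), so a digital bar
  exactly w pixels wide reads w along its axis and residual
  discretization error is below one pixel.
* **Porosity** = 1 − foreground/total pixels.

Scaling `pixel_size` by c scales lengths and diameters by c exactly and
leaves counts and porosity unchanged.

## Synthetic generator

`FiberFieldSpec` defaults describe a healthy cortical field and are the
conditions under which the package validates itself: 256×256 px at
0.5 µm/px; 20 primary fibers entering quasi-regularly along the bottom
edge with mean orientation 90° (SD 10°); heading random walk of
0.02 rad/step; branches as a Poisson process at 1 per 100 µm of
arclength with daughters offset by 75° ± 10° (crossing fibers in cortex
run near-horizontally); widths 3 ± 0.5 px; intensity 150 over
background 20 with a 30 % top-of-field gradient, 1 px Gaussian PSF and
noise SD 8 (peak SNR ≈ 19). Daughters grow and branch recursively; the
rates keep the branching process subcritical. Ground truth (recorded
before blur and noise) contains the exact polylines, their geometric
length, the hard-rasterized centerline and width masks, branch events,
and `n_true_intersections` — 8-connected clusters of positions where
two or more distinct centerlines pass within one pixel (crossings
between digital lines need not share a pixel).

`injury_variant(spec, severity)` models the injured phenotype: branch
rate × (1 − severity), primary count × (1 − 0.5·severity), gradient
pushed toward 1 by severity. At severity 0.5 with n = 8 fields per
group the package detects lower fiber length, fewer intersections and
higher coherency in essentially every replicate experiment.

`FiberFieldSpec.validation()` is the sparse "clean" variant (8 primaries,
branch rate 0.4, jitter 2°, curvature 0.005, fixed 3 px width) used for
ground-truth recovery: at realistic density fibers overlap and merge in
the mask, so exact length recovery is only meaningful when crossings
are rare. On these fields measured skeleton length lands within a few
percent of truth and the measured diameter within a small fraction of a
pixel of the commanded width.

What the generator does **not** emulate: out-of-focus light and uneven
illumination, chromatic DAB statistics, fiber-diameter variation along
a single axon, tissue tears and staining artifacts, anisotropic pixel
scales. Passing the synthetic validation therefore shows the
measurement chain is correct on images matching its geometric and noise
model, not that segmentation parameters transfer to any particular
microscope without adjustment.

## Statistics

Two groups: an F-test on the sample variances (two-sided, α = 0.05)
selects between the pooled-variance Student t-test and Welch's t-test
with Welch–Satterthwaite degrees of freedom; the branch taken is always
reported. Two identical constant groups return p = 1 by convention.
More than two groups: one-way fixed-effects ANOVA, then pooled-MSwithin
pairwise t-tests over a user-specified comparison set with Bonferroni
multiplication (capped at 1). Summaries are mean ± SEM with
SEM = SD(n−1)/√n, 0 when n = 1. Under the null (normal, n = 8 per
group) the two-stage two-group procedure holds its empirical type-I
error within [0.04, 0.06] at α = 0.05 over 5000 simulations.

Hemisphere pairs (ipsi/contra within animal) are compared with the same
unpaired machinery by default, matching the reference workflow; a
paired analysis would be more powerful but is deliberately not the
default.

## Pipeline

`run_pipeline` validates the config before any computation (fail-fast
on missing files or unknown comparison groups), measures every image
(segmentation → density + coherency + fiber metrics), averages fields
per animal *before* normalization and statistics (one value per
animal), then runs the comparison plan. Outputs (`per_image.csv`,
`per_animal.csv`, `comparisons.csv`, overlay PNGs, `run.log`) are
stamped with a SHA-256 config hash and the package version; reruns with
identical inputs are bit-identical. Every numeric parameter is echoed
to the log; there are no silent defaults.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: oracle checks on ≤ 64×64 fixtures; ground-truth recovery on 10
clean 256×256 fields; the group experiment on 20 replicates of 8 + 8
default fields; statistical calibration on 5000 simulated null
comparisons. These sizes were chosen as the smallest at which the
group-level effects and calibration bounds are stable across seeds.

## Known limitations

* Thinning is not pixel-exactly rotation-equivariant on blob-like
  masks; length invariance under 90° rotation is exact only for thin
  (already skeletal) geometry, and 45° fibers carry the ≈ 8 % chamfer
  bias of the √2 step metric, partially compensated in practice by
  raster shortcuts.
* At high fiber density, mask merging makes total length a lower bound
  on true summed fiber length; comparisons between groups remain valid
  because the bias is shared.
* The junction-zone merge radius (two diameters) trades double-counted
  oblique crossings against fusing genuinely distinct adjacent
  junctions in dense networks.
* DAB-stained material should be inverted to bright-signal grayscale
  first, and immunodensity is not meaningful on chromogenic stains.
* No 3D support; adjacent fields are combined by averaging per-animal
  metric values, not by image stitching.
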