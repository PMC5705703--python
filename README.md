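# myeliq

Quantitative microstructural analysis of myelinated axons in 2D
brain-section micrographs.

Immunostaining cortical sections for a myelin marker (MBP, PLP, or an
inverted DAB chromogen) shows a band of bright fibers ascending from the
deep white matter (external capsule) into the cortex, branching and
crossing, and fading toward the outer layers. `myeliq` turns such
single-channel micrographs into numbers:

* **Extent of myelination** — myelinated-cortex fraction
  (`100 · area(myelinated)/area(total cortex)`), background-corrected
  immunodensity (mean grey of the signal region minus mean grey of a
  background-staining region, optionally normalized so the control group
  mean is 100 %), and the myelin-positive area fraction of the field.
* **Coherency** — the eigenvalue contrast `C = (λ₁ − λ₂)/(λ₁ + λ₂)` of
  the ROI-averaged structure tensor
  `J = G_ρ ∗ [gx², gx·gy; gx·gy, gy²]`, an inverse proxy for the
  complexity of the fiber network: losing the crossing (horizontal)
  fibers leaves the near-vertical survivors dominant and raises C.
* **Microstructural complexity** — the segmented mask (rolling-ball
  style background subtraction → 8-bit → Otsu or manual threshold →
  small-particle removal) is thinned to a one-pixel centerline; from the
  resulting skeleton graph the package measures total fiber length
  (orthogonal steps 1·px, diagonal steps √2·px, in µm and µm/mm²), the
  number of intersections (merged branch-point clusters), the mean fiber
  diameter (distance-transform radius on the centerline), and porosity.
* **Group statistics** — unpaired two-sided t-tests with an F-test
  choosing the Welch branch, one-way ANOVA with Bonferroni-corrected
  pairwise comparisons, mean ± SEM summaries.
* **Synthetic validation** — a generator of fluorescence-like fiber
  fields with exact ground truth (centerline length, branch events,
  width), including an `injury_variant` that reproduces the injured
  phenotype (fewer, less branched fibers with a steeper myelination
  gradient), so the whole pipeline is testable without animal data.

Conventions: 0-based `(row, col)` indexing with the origin top-left;
angles in degrees within (−90, 90] measured from the image x-axis,
counter-clockwise positive; pixel scale (µm/px, isotropic) is always a
required user input.

## Worked example

Generate a synthetic cortical field, segment it, and measure the fiber
network:

```sh
$ myeliq simulate --seed 7 --out field.tif --truth truth.json
wrote field.tif: length=4819.5 µm, branches=45

$ myeliq segment field.tif --out mask.png --pixel-size 0.5
wrote mask.png (24107 foreground px)

$ myeliq fibers mask.png --pixel-size 0.5 --map thinning.png
total_fiber_length: 3696.4989 µm
fiber_length_density: 225616.3867 µm/mm²
mean_segment_length: 5.8370 µm
n_intersections: 110.0000 count
intersection_density: 6713.8672 count/mm²
mean_fiber_diameter: 1.6987 µm
porosity: 0.6322
n_endpoints: 34.0000 count

$ myeliq coherency field.tif --pixel-size 0.5
coherency: 0.4485
orientation_deg: 84.5132 deg CCW from x-axis, (-90,90]
energy: 326.5290 intensity^2
```

The simulated field at 0.5 µm/px carries 4.8 mm of true centerline; the
measured skeleton length (3.7 mm) is lower because this default field is
dense — overlapping fibers merge in the mask (the sparser
`FiberFieldSpec.validation()` fields recover length to within a few
percent). 110 intersections and a mean diameter of 1.7 µm (≈ 3.4 px,
commanded width 3 px) describe the crossing structure; the dominant
orientation of 84.5° confirms the near-vertical fiber population, with
coherency 0.45 reflecting the branching/crossing complexity.
`thinning.png` is the axial-thinning map overlaid on the mask.

A full study runs from one TOML config (image table with animal/group
labels, segmentation parameters, comparison plan):

```sh
myeliq run study.toml --out results/
# -> per_image.csv, per_animal.csv, comparisons.csv, overlays, run.log
```

Per-image values are averaged per animal before any statistics; every
output is stamped with the config hash and package version, and reruns
are bit-identical.

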