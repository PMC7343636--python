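# Methods

This note records the model implemented by `sccpipe`, the parameter
defaults and their rationale, what the synthetic phantoms do and do not
emulate, the numerical conventions, and known limitations. It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
actually compute.

## 1. Imaging model and assumptions

Each construct is imaged at two timepoints (pre / post treatment). Per
timepoint there are two excitation channels, and per channel a
simultaneously acquired reflectance + fluorescence stack — four 3D volumes
per timepoint. Axis order is `(z, y, x)` throughout; the default grid is
1.1 µm lateral pixels and 3.1 µm z-spacing (metadata accepts 1–6 µm, a
sanity band around typical confocal z-steps).

Assumptions the pipeline relies on:

* **Linearity of detection.** Recorded intensity is proportional to laser
  power and, by default, to detector gain (`gain_exponent = 1.0`). PMT gain
  response is instrument-specific and often supralinear, so the exponent is
  an explicit parameter rather than a hidden constant.
* **Rigid in-plane misalignment.** The two channels are acquired
  sequentially; any shift between them is modeled as one 2D rotation +
  translation common to all slices. Axial drift and non-rigid deformation
  are out of scope.
* **One connected component = one cell.** Valid only when cells are
  resolvable at the imaging resolution and smoothing scale; see §3.
* **Stable pairing.** A sample's pre and post stacks are acquired with the
  same settings per channel (normalization still removes any residual
  difference, since each stack carries its own power/gain metadata).

## 2. Processing chain and parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| smoothing kernel size | 8 voxels | assay-pinned; interpreted as the truncated filter window (radius 4 voxels) |
| smoothing sigma | kernel/4 = 2.0 voxels | common kernel-to-sigma convention; exposed for override |
| histogram bins (Otsu) | 256 | assay-pinned; matches 8-bit histogramming |
| connectivity | 26 | assay-pinned; merges face-, edge- and corner-touching voxels |
| minimum object size | 5 voxels (removes ≤4) | assay-pinned speckle filter |
| normalization reference | power 1.0, gain 1.0 | arbitrary common scale; only ratios matter |
| registration search | ±6° coarse 0.5°, fine 0.05°, subpixel 1/50 px | covers plausible stage drift with sub-tolerance resolution |
| bleed-through QC threshold | 0.5 coincident fraction at 4 µm radius | flags filter/bleed faults while tolerating chance overlap |

Numerical conventions that affect results and are therefore pinned:

* **Otsu threshold value** is the *upper edge* of the last background bin of
  the best cut, and foreground is `value > threshold` (strictly greater).
  The histogram spans `[min, max]` with equal-width bins. This matches
  scikit-image up to one bin width (scikit-image returns the bin center).
* **Gaussian smoothing** uses reflect padding and truncates the window at
  `kernel_size / 2` voxels per side, so the stated kernel size is the real
  spatial support of the filter.
* **Component labels** are assigned in lexicographic scan order of each
  component's first voxel, making label volumes deterministic and
  comparable across runs (and to the brute-force flood-fill oracle in the
  test suite).
* **Total fluorescence** is summed from the *pre-smoothing* normalized
  intensities over each object's voxels: smoothing is a detection aid, not
  part of quantification.
* **Registration** estimates T such that `apply_transform(moving, T)`
  aligns with `fixed`, on Hann-windowed z-sum reflectance projections,
  scoring candidates by normalized cross-correlation on a central crop
  (windowing and cropping suppress the artificial edges introduced by the
  rotation's zero fill). The transform is applied slice-wise with linear
  interpolation; out-of-bounds voxels become 0.
* **Normalization before registration.** Both are linear operators on
  intensities, so the order does not change results; normalizing first
  keeps the registration substrate (reflectance) untouched, since only
  fluorescence is normalized.
* **Hedges' g** uses the exact gamma-function small-sample correction
  `J = Γ(df/2) / (√(df/2) · Γ((df−1)/2))`; the familiar `1 − 3/(4df−1)`
  approximation is available via `exact=False`. With the convention
  *control summary first*, positive g means the treated arm retained less
  of its baseline biomarker.
* **Two-way ANOVA** uses sum-to-zero factor coding and Type III sums of
  squares (statsmodels OLS + `anova_lm(typ=3)`), the appropriate test for
  the unbalanced cell-type × treatment design; on balanced designs it
  reduces to the textbook decomposition (verified to 1e-8 in the tests).

## 3. What the phantoms emulate — and what they do not

The generator (`sccpipe.synthetic`) renders, in order: fluorescent scenes
(sums of Gaussian cell blobs, isotropic in micrometres and therefore
anisotropic in voxels), inter-channel bleed-through mixing **in the scene
frame**, rigid misregistration of the 532 nm channel, per-channel/timepoint
power × gain scaling, and Poisson shot + Gaussian read noise last. Mixing
bleed-through before misregistration reflects the physics: the fluorophores
co-exist in one specimen, and the channel shift happens at acquisition.

Emulated:

* tumor spheroids as shells of cells around a dark necrotic core
  (core radius = 0.45 × spheroid radius of 28 µm);
* a sparse labeled keratinocyte population (1% of 3000) in an epidermal
  band (~6–45 µm depth);
* stratified reflectance texture (bright speckled superficial band,
  honeycomb mid-band with dark nuclei, fibrous dermis) — enough structure
  for registration, not a histological simulation;
* treatment as per-cell independent removal: a kill fraction k keeps
  `round((1−k)·n)` cells sampled without replacement (tumor cells pooled
  across spheroids; labeled and unlabeled keratinocytes subsampled
  separately so the sentinel fraction stays representative);
* acquisition nuisances: power/gain variation, misregistration,
  bleed-through, sensor noise.

**Deliberately not emulated:** confluent cell packing. The assay's
one-component-one-cell reading requires resolvable cells, so the phantom
places 12 cells per spheroid shell (cell radius 3 µm, minimum separation
12 µm lateral / 28 µm axial, an ellipsoidal exclusion reflecting the
anisotropic point spread along z). At real confluent densities the
published segmentation parameters would merge neighbors, and counts would
become a density proxy rather than a census — a limitation of the assay
itself, which the phantom makes explicit instead of hiding. Ground truth
at the configured density is recovered exactly by the pinned chain (this
is asserted in the tests, not assumed).

Also not modeled: photobleaching between timepoints, depth-dependent
attenuation of fluorescence, cell migration or division between
acquisitions, optical sectioning blur beyond the Gaussian blob profile,
and axial (z) misregistration.

## 4. Study design defaults

The simulated study mirrors the assay's arms: controls lose ~12% of tumor
cells between acquisitions (handling/baseline attrition), the 1× dose kills
~50% of tumor cells and ~11% of keratinocytes, the 2× dose 70% / 15%
(`GROUP_KILL_FRACTIONS`). Default arm sizes are 15 control / 18 at 1× /
20 at 2×. Per-sample acquisition settings vary (power 0.7–1.3, gain
0.8–1.25, consistent within a sample's pre/post pair), with a small random
misregistration (≤2°, ≤4 voxels) and batches of three samples.

`simulate_effect_table` provides a fast design-level counterpart (binomial
cell survival + multiplicative measurement noise) for power analyses where
rendering voxel data would be wasteful.

## 5. Quality control

A sample is flagged when more than half of its GFP objects have an RFP
object centroid within one cell radius (4 µm, physical distance) — the
signature of bleed-through or a wrong filter set. Flagged samples stay in
the biomarker and effect tables (marked `qc_excluded`) but are left out of
the group statistics, mirroring the study's exclusion of a miscollected
batch. Samples whose baseline biomarker is zero contribute no
percent-of-pre effect for that unit (division by zero is refused, not
patched).

## 6. Limitations

* Registration is 2D rigid; severe rotation (>6° by default) or z-drift is
  outside the search space and will degrade alignment silently (QC on
  registration residuals is not implemented).
* Global Otsu assumes a bimodal intensity histogram; constructs with very
  few cells or strong depth attenuation may threshold poorly. The
  implementation raises on degenerate (constant) input but cannot detect a
  merely *bad* threshold.
* Counts are unbiased only while cells remain resolvable (§3).
* The pooled t-test and ANOVA assume approximately normal percent-of-pre
  values with similar variances; with strong kill fractions the binomial
  survival distribution is skewed at small cell counts.
* Phantom realism is sufficient for validating the measurement chain, not
  for training or benchmarking general segmentation models.
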