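# Methods

This note documents the models, parameter choices and numerical
decisions behind `npreflect`, and what the synthetic experiments do and
do not demonstrate about real microscopy data.

## Scene model and forward rendering

A ground-truth scene lives on a (z, y, x) voxel grid (default 200 nm
z-steps, 60 nm lateral pixels — the acquisition sampling of the study
conditions). It contains:

- an **ellipsoidal cell** with semi-axes drawn uniformly from 34–40% of
  the grid extent per axis, randomly rotated in-plane;
- one or more **nuclei**, ellipsoids at 30–38% of the cell's semi-axes,
  strictly inside it (multiple nuclei are spread along the lateral long
  axis — the double-nucleus configuration that makes automated
  point-set alignment well-posed);
- **NP clusters**: points with centre, peak amplitude and radius,
  sampled uniformly in the cytoplasm (cell minus nuclei), optionally
  with a minimum pairwise separation (3-D, or lateral-only when z
  profiles must stay uncontaminated) and a fraction of tight
  "agglomerate" pairs at fixed spacing.

Rendering a modality evaluates, at every voxel centre, the sum of
anisotropic Gaussians with σ per axis combining the PSF preset and the
cluster radius (σ_eff² = σ_PSF² + (r/2)²). This is the exact continuous
convolution of a point impulse with a Gaussian PSF, so the rendered
peak equals the cluster amplitude and the rendered FWHM equals the
preset — the property the impulse-response tests pin down. The PSF
presets carry the measured instrument resolutions:

| modality | FWHM lateral | FWHM axial |
|----------|--------------|------------|
| RCM      | 345 nm       | 1077 nm    |
| R-SIM    | 115 nm       | 685 nm     |
| TEM      | 4 nm         | — (2-D sections) |

**Cellular background.** Untreated cells reflect: the background
channel is smoothed (σ = 3 voxels) uniform noise rescaled to
0.5–1.5 × `background_level`, restricted to the cell mask, then blurred
with the modality PSF. `background_level` defaults to 10% of the
smallest cluster amplitude and can be set absolutely; scenes whose
background would fall below the read-noise floor are degenerate (the
texture becomes unmeasurable) and the comparison experiments therefore
fix it at 15 intensity units against read noise σ = 10.

**R-SIM axial window.** SIM reconstruction only retains high-contrast
in-focus signal; the renderer emulates this with a hard window: a
cluster contributes nothing to z-planes further than one axial FWHM
from its centre. The window's tail truncation is minor for FWHM
measurement (the half-max crossings sit at ±342 nm) but it caps R-SIM's
per-plane inclusion range, which drives the co-occurrence asymmetry and
persistence ordering below.

**Noise.** Poisson on intensity scaled by `photon_scale` (0.4), then
additive Gaussian read noise (σ = 10). With the recovery amplitudes
(800–1200) this gives peak SNR ≈ 20. Both the background texture and
the noise realisation derive from the `NoiseParams.seed`, so a stack is
bit-reproducible from (scene params, scene seed, noise seed).

**TEM sections** integrate by slab membership: each 2-D image (pixel
≤ 10 nm) shows dark Gaussian spots for the clusters whose centre falls
in its physical slab, over a bright background with faint cell/nucleus
shading; consecutive sections tile the axial range from a configurable
start depth. Stain channels (cytoplasm, nucleus) are the masks under a
light 1-voxel blur: a full axial PSF blur would erode the thin cell
caps and misstate the ground truth the segmentation is tested against.

## Segmentation

Cell and nuclei: Gaussian smoothing (σ = 1 voxel) then deterministic
two-class 1-D k-means on voxel intensities; the brighter class is the
mask. The 1-D k-means initialises centroids at evenly spaced weighted
quantiles and iterates Lloyd's algorithm on a 2048-bin histogram — no
RNG, exactly shift-covariant, and cross-checked against scikit-learn in
the tests.

NP segmentation (`segment_np`) is control-referenced:

1. jointly min–max normalise the pooled treated + control stacks;
2. Gaussian-smooth (σ = 0.7 voxels);
3. k-means (k = 3) on the pooled intensities; voxels in the lowest
   (image background) class are discarded;
4. keep voxels above `median + m·σ̂` of the control foreground, where
   the foreground is the brighter side of the control's own two-class
   split and σ̂ = 1.4826·MAD; `m` defaults to 3.5.

Two numerical points matter here. First, the robust statistics are
taken over the control's full cellular-reflectance distribution — not
over a k-means tail, whose truncated MAD collapses and lets noise
through. Second, the final arbiter is the control threshold rather
than the top k-means cluster: a pooled intensity-cluster boundary
shifts with the voxel mass of the bright spots, which differs by an
order of magnitude between a wide-PSF and a narrow-PSF modality and
would cut the two modalities at wildly different fractions of the spot
amplitude, invalidating any cross-modality comparison. With m = 3.5 the
false-positive volume on control scenes stays below 0.1% of the cell
volume (measured ≈ 0.02–0.03% over 10 seeds); m = 3 would admit
≈ 0.13% for a near-Gaussian background.

`subtract_background` is the unsharp mask used before intensity
registration and FWHM profiling: image minus its large-σ blur, clipped
at zero (the clip also zeroes the noise floor, removing the negative
bias a windowed minimum baseline would otherwise inherit).

## Quantification

Connected components are labelled under face (6/4-neighbour) or full
(26/8-neighbour) connectivity — full by default — and tabulated with
voxel counts, physical sizes, centroids (plain and intensity-weighted)
and intensity statistics. Co-occurrence is object-based: a component of
A co-occurs if any of its voxels lies in B's foreground; each source
component counts once. Per-cell uptake summaries can drop components
smaller than a plausible diffraction-limited spot (tens of voxels at
this sampling); isolated noise voxels occasionally survive any
intensity threshold and are not spots.

Axial persistence is the longest run of consecutive z-slices occupied
by a component. A path-connected component cannot skip a slice, so the
gap warning only concerns pre-labelled inputs.

The group comparison is a two-sided Student's t-test (pooled variance;
Welch optional).

## FWHM estimation

Line profiles are sampled at voxel pitch through the region's
intensity-weighted centroid. Two estimator details are deliberate:

- **Grid phase-locking.** Sample positions along the measured axis are
  snapped to the voxel grid (nearest on-grid line). For a separable
  spot, off-grid positions on the *perpendicular* axes only rescale the
  profile; re-interpolating *along* the measured axis, however, widens
  a sub-2-pixel peak by ~8% on average for the R-SIM preset at 60 nm
  pixels. Snapping also makes an on-grid profile return exactly the
  row's values.
- **Parabolic peak refinement.** The half-maximum level uses the peak
  height from a 3-point parabola through the samples around the
  maximum; a peak falling between two pixels is otherwise flattened and
  the width overestimated. Crossings themselves are located by linear
  interpolation between the bracketing samples on each side.

The baseline defaults to the profile minimum (robust to residual
background); recovery experiments measure on background-subtracted
images so that minimum is ≈ 0. Residual estimator bias at the study's
sampling, from the noiseless closed form: ≈ +6% for the R-SIM lateral
preset (FWHM 1.9 px — at the edge of Nyquist), under 1% for the other
three presets. Lateral FWHM is the mean of the x and y single-axis
estimates (line-scan methodology, not a 2-D fit); summaries report
mean, sample SD (n−1) and a fitted normal density.

## Registration

All transforms map moving → fixed in physical nm, (y, x) order; images
are resampled by pulling through the inverse map with linear
interpolation. Point-pair estimation is exact on consistent pairs
(Kabsch for rigid — rotation + translation, reflection disallowed;
normal equations for affine). Intensity registration preprocesses both
images (smooth σ = 2 px, background-subtract σ = 12 px), runs FFT phase
correlation for the translation at each candidate rotation (±10° in 2°
steps), then Powell-refines the metric: normalised cross-correlation
within a modality, 32-bin mutual information across modalities. On
synthetic RCM↔R-SIM pairs with a known rigid misalignment the mean
landmark error is ≈ 0.1 RCM pixel, and preprocessing roughly triples
the MI optimum when backgrounds differ — the reason preprocessing is on
by default.

CPD treats the moving set as Gaussian-mixture centroids fitted to the
fixed set by EM with a uniform outlier component (weight w, default
0.1), deterministic from identity initialisation and σ² = mean pairwise
squared distance; iteration stops when σ² changes by < 1e-8. The rigid
M-step updates rotation and translation only — scale is fixed at 1 so
the result honours the rigid-transform contract; anisotropic shrinkage
(the TEM case) is the affine model's job. The affine stage warm-starts
from the rigid solution: taken directly from identity with a wide
mixture variance, the affine M-step can collapse the linear part
towards zero on structured (ring-like) point sets. With w = 0 on clean
correspondence-free sets, CPD agrees with the known-correspondence
Procrustes solution to ≤ 1e-3 relative rotation error.

## Recovery experiments and their scope

`experiments.py` fixes the study conditions: Nyquist-ish sampling
(60/200 nm), peak SNR ≈ 20, bright isolated reflectors for FWHM
recovery (amplitudes 800–1200, ≥ 1.5 µm apart; 14 per deeper 8 µm stack
with lateral-only separation for axial profiles — 3-D separation at
that density both exceeds the random-packing limit and lets a
same-column neighbour contaminate a z profile), and mixed scenes with
30% tight pairs over a visible background for the modality
comparisons. Detected regions smaller than 20 voxels are excluded from
FWHM measurement as sub-spot noise. Co-occurrence is evaluated on
matched z-planes (counts summed over three planes per scene, in-plane
specks < 4 px removed from both masks): comparing full 3-D volumes is
uninformative because each modality images the whole stack and every
object trivially overlaps. Problem sizes (3–4 scenes of ~1–2 M voxels
per target, 10 seeds for the comparative properties) were chosen so the
whole suite and the acceptance script each run in about a minute.

What passing these experiments shows: the estimators recover the
forward model's parameters under realistic sampling and noise, the
control-referenced detection has the specificity the method claims, and
the cross-modality asymmetries follow from the PSF geometry alone.
What it does not show: robustness to structured cellular reflectance
(the texture model is a pragmatic stand-in — real background has
organelle-scale spatial statistics no one has characterised), to
aberrations or depth-dependent PSFs, to SIM reconstruction artefacts,
or to segmentation of touching cells (watershed splitting and
learning-based segmentation are out of scope).

## Known limitations

- The R-SIM axial suppression is a hard window; the real reconstruction
  roll-off is unknown and certainly smoother.
- The R-SIM lateral preset is marginally undersampled at 60 nm pixels
  (the renderer warns); the line-scan estimator then carries a ~+6%
  width bias that is a property of the estimator at that sampling, not
  of the optics.
- TEM sections are density projections with idealised contrast; no
  electron-optics or staining model.
- 3-D registration is not implemented; the study aligns matched 2-D
  planes, and so does the package.
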