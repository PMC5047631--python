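# npreflect

Correlative reflectance nanoparticle-imaging analysis: a tested pipeline
for quantifying label-free nanoparticle (NP) uptake in cells imaged by
reflectance confocal microscopy (RCM), reflectance structured
illumination microscopy (R-SIM) and TEM-like sections, driven by a
synthetic multi-modality scene generator.

## The problem

Metal-oxide nanoparticles (SPIONs, cerium dioxide) reflect light
strongly, so cells that have internalised them can be imaged without
fluorescent labels. But quantifying that signal is subtle:

- cellular constituents reflect weakly even in untreated cells, so NP
  detection must be referenced to **untreated control cells**;
- RCM is diffraction-limited (lateral FWHM ≈ 345 nm) while R-SIM
  resolves ≈ 115 nm, so the same NP cluster looks like one blob in one
  modality and several spots in the other — comparisons must be
  **object-based**, not pixel-based;
- the modalities have very different axial reach (z-FWHM 1077 nm vs
  685 nm), which changes how many consecutive optical sections a
  particle appears in and which objects co-occur on matched planes;
- overlaying modalities (and TEM sections, which shrink during
  processing) requires rigid/affine registration, by point pairs,
  image intensity, or Coherent Point Drift on nuclear features.

The package implements every step — scene simulation with known ground
truth, control-referenced k-means segmentation, connected-component
quantification, FWHM-based resolution measurement, object co-occurrence
and multimodal registration — so that each claim can be verified as a
parameter-recovery experiment.

## Core methods

**Forward model.** A scene is an ellipsoidal cell with nuclei and point
NP clusters of amplitude $A$ inside the cytoplasm. The reflectance
channel is rendered analytically as a sum of anisotropic Gaussians
(σ = FWHM/2√(2 ln 2) per axis, per modality preset) over a textured
cellular background restricted to the cell mask, followed by
Poisson–Gaussian noise. R-SIM additionally zeroes contributions more
than one axial FWHM from each cluster's focal plane (only high-contrast
in-focus signal survives SIM reconstruction).

**NP segmentation.** Treated and control stacks are normalised
together, smoothed, clustered by deterministic 1-D k-means (quantile
initialisation), and thresholded at $\mathrm{med} + m\,\hat\sigma$ of
the control's foreground, with $\hat\sigma$ the MAD-based robust sigma
($m = 3.5$ by default).

**Resolution.** For every detected region a line profile is sampled
through its intensity-weighted centroid at voxel pitch; the FWHM is the
distance between the two half-maximum crossings located by linear
interpolation, with the peak height refined by a 3-point parabola.

**Co-occurrence.** On matched planes, a component of modality A counts
as confirmed if ≥ 1 of its voxels lies in modality B's mask (the binary
product); percentages are per source component.

**Registration.** Rigid/affine least squares on point pairs (Kabsch /
normal equations), intensity-based registration (phase-correlation
coarse search + Powell refinement of NCC or mutual information after
smoothing and background subtraction), and rigid/affine Coherent Point
Drift (EM over a Gaussian mixture with an outlier component).

## Worked example

The numbered scripts under `analysis/` run the study end to end; each
writes its tables under `results/`. For example:

```sh
$ python analysis/03_resolution_fwhm.py --seed 1
RCM  lateral:   337.5 +/-  16.1 nm over 117 regions (preset 345 nm)
RSIM lateral:   123.5 +/-   5.0 nm over 160 regions (preset 115 nm)
RSIM axial  :   705.1 +/-  24.4 nm over 28 regions (preset 685 nm)
RCM  axial  :  1041.5 +/-  39.4 nm over 25 regions (preset 1077 nm)
lateral resolution gain RCM/R-SIM: 2.73x
```

i.e. the line-scan estimator recovers each instrument's point-spread
FWHM from detected spots, and the recovered lateral ratio reproduces
the greater-than-two-fold resolution gain of R-SIM over RCM.

```sh
$ python analysis/04_cooccurrence.py --seed 1
mean over 10 scenes: 99.8% of R-SIM objects also seen in RCM,
86.8% of RCM objects also seen in R-SIM
```

— the direction of the modality asymmetry: RCM's thicker axial range
confirms nearly every R-SIM object, while some RCM objects lie outside
R-SIM's narrower reconstruction plane. Similarly
`05_axial_persistence.py` reports a single point reflector persisting
for 7 consecutive 200 nm optical slices under RCM versus 3 under R-SIM,
`02_quantify_uptake.py` reports 24.5 ± 0.8 NP components per treated
cell versus 0.3 ± 0.8 in controls (t = 50.6, p ≈ 2×10⁻¹³), and
`06_registration.py` recovers a known RCM↔R-SIM misalignment to
0.08 RCM pixels mean landmark error.

A full configured run (`npreflect run --seed 1 --outdir results/pipeline`)
produces per-scene TIFF renderings, masks, region tables, co-occurrence
JSON and a seeded, hash-stamped report; `npreflect report` prints a
summary.

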