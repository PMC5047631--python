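"""Parameter-recovery experiments on the synthetic generator.

The instrument resolutions of the study (RCM 345/1077 nm, R-SIM 115/685
nm lateral/axial FWHM) are measurements on microscopy data that is not
deposited, so they are reproduced here as recovery experiments: render
scenes with the corresponding PSF preset at Nyquist sampling (60 nm
lateral pixels, 200 nm z-steps), detect spots against a control
rendering, and measure what the line-scan estimator returns.  The same
drivers feed the test suite, the numbered analysis scripts and
``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from skimage import morphology

from . import psf as psf_presets
from .quantify import axial_persistence, cooccurrence, connected_components
from .registration import PlanarTransform, max_projection, register_intensity
from .resolution import measure_regions, summarize_fwhm
from .segmentation import SegmentationParams, segment_np, subtract_background
from .simulate import (
    NoiseParams,
    SceneParams,
    generate_ground_truth,
    render_scene,
)

#: Nyquist-ish acquisition grid shared by the recovery experiments:
#: 200 nm z-steps, 60 nm lateral pixels.
VOXEL_NM = (200.0, 60.0, 60.0)

#: Moderate acquisition noise (peak SNR ~ 20 for the default amplitudes).
RECOVERY_NOISE = NoiseParams(photon_scale=0.4, read_sigma=10.0, seed=0)

#: Bright, well separated point reflectors used for FWHM recovery.
RECOVERY_SCENE = SceneParams(
    shape=(16, 288, 288),
    voxel_size_nm=VOXEL_NM,
    n_clusters=40,
    amplitude_range=(800.0, 1200.0),
    radius_range=(5.0, 10.0),
    min_separation_nm=1500.0,
)

#: Deeper grid for axial profiles (RCM z-FWHM is ~5.4 z-steps wide).
RECOVERY_SCENE_AXIAL = replace(
    RECOVERY_SCENE,
    shape=(40, 192, 192),
    n_clusters=14,
    min_separation_nm=1200.0,
    lateral_separation_only=True,
)

#: Partly agglomerated scenes for co-occurrence and persistence
#: comparisons: bright clusters (all detectable by both modalities),
#: 30% of them placed as 180 nm pairs that only R-SIM resolves, over a
#: visible cellular-reflectance background.
COMPARISON_SCENE = SceneParams(
    shape=(16, 192, 192),
    voxel_size_nm=VOXEL_NM,
    n_clusters=30,
    amplitude_range=(300.0, 1500.0),
    radius_range=(8.0, 30.0),
    min_separation_nm=900.0,
    pair_fraction=0.3,
    pair_spacing_nm=180.0,
    background_level=15.0,
)


def _subseed(seed: int, k: int) -> int:
    return int((seed * 1000003 + k) % (2**31 - 1))


def _render_pair(scene: SceneParams, preset, seed: int):
    """Render a treated scene and a matched control with derived seeds."""
    truth = generate_ground_truth(scene, _subseed(seed, 1))
    control = generate_ground_truth(
        replace(scene, control_flag=True), _subseed(seed, 2)
    )
    noise_t = replace(RECOVERY_NOISE, seed=_subseed(seed, 3))
    noise_c = replace(RECOVERY_NOISE, seed=_subseed(seed, 4))
    stack_t = render_scene(truth, preset, noise_t)
    stack_c = render_scene(control, preset, noise_c)
    return truth, stack_t, stack_c


def fwhm_recovery(
    modality: str,
    mode: str,
    n_target: int,
    seed: int,
    params: SegmentationParams | None = None,
    background_subtract_sigma: float | None = 6.0,
    min_region_voxels: int = 20,
) -> dict:
    """Recover the PSF FWHM of ``modality`` from detected spots.

    ``mode`` is ``'lateral'`` (x/y line scans averaged) or ``'axial'``
    (z line scans).  Scenes are rendered until at least ``n_target``
    regions have been measured.  Profiles are taken on the
    background-subtracted reflectance (diffuse cellular reflectance
    would otherwise bias the half-maximum level).  Returns the
    ``summarize_fwhm`` summary plus the preset value for reference.
    """
    preset = psf_presets.get_preset(modality)
    scene = RECOVERY_SCENE if mode == "lateral" else RECOVERY_SCENE_AXIAL
    axes = ("x", "y") if mode == "lateral" else ("z",)
    expected = preset.fwhm_lateral if mode == "lateral" else preset.fwhm_axial
    half_length = max(3.0 * expected, 700.0)
    params = params or SegmentationParams()

    estimates = []
    scene_idx = 0
    while len(estimates) < n_target and scene_idx < 20:
        truth, stack_t, stack_c = _render_pair(
            scene, preset, _subseed(seed, 100 + scene_idx)
        )
        refl = stack_t["reflectance"]
        mask = segment_np([refl], [stack_c["reflectance"]], params)[0]
        regions = connected_components(
            mask, params.connectivity, voxel_size_nm=scene.voxel_size_nm,
            intensity=refl,
        )
        # a genuine diffraction-limited spot covers tens of voxels at
        # Nyquist sampling; smaller components are noise excursions
        regions = regions[regions.n_voxels >= min_region_voxels]
        measured = (
            subtract_background(refl, background_subtract_sigma)
            if background_subtract_sigma
            else refl
        )
        estimates.extend(
            measure_regions(measured, regions, axes=axes, half_length_nm=half_length)
        )
        scene_idx += 1
    summary = summarize_fwhm(estimates[: max(n_target, len(estimates))])
    summary["modality"] = preset.modality
    summary["mode"] = mode
    summary["expected_nm"] = float(expected)
    summary["n_scenes"] = scene_idx
    return summary


def resolution_ratio(seed: int, n_regions: int = 60) -> dict:
    """Ratio of recovered RCM to R-SIM lateral FWHM (the resolution gain)."""
    rcm = fwhm_recovery("rcm", "lateral", n_regions, seed)
    rsim = fwhm_recovery("rsim", "lateral", n_regions, seed)
    return {
        "rcm_mean_nm": rcm["mean_nm"],
        "rsim_mean_nm": rsim["mean_nm"],
        "ratio": rcm["mean_nm"] / rsim["mean_nm"],
    }


def paired_modality_masks(seed: int, scene: SceneParams | None = None):
    """Segment the same ground truth rendered under both optical presets."""
    scene = scene or COMPARISON_SCENE
    truth = generate_ground_truth(scene, _subseed(seed, 1))
    control = generate_ground_truth(
        replace(scene, control_flag=True), _subseed(seed, 2)
    )
    masks = {}
    for k, name in enumerate(("rcm", "rsim")):
        preset = psf_presets.get_preset(name)
        stack_t = render_scene(
            truth, preset, replace(RECOVERY_NOISE, seed=_subseed(seed, 10 + k))
        )
        stack_c = render_scene(
            control, preset, replace(RECOVERY_NOISE, seed=_subseed(seed, 20 + k))
        )
        masks[name] = segment_np(
            [stack_t["reflectance"]], [stack_c["reflectance"]]
        )[0]
    return truth, masks


def cooccurrence_experiment(
    n_seeds: int,
    seed: int,
    planes: tuple = (5, 8, 11),
    min_area_voxels: int = 4,
) -> pd.DataFrame:
    """Object-based co-occurrence between paired RCM/R-SIM segmentations
    of matched optical planes.

    Each scene is segmented in 3-D under both presets, then matched
    z-planes are compared as the study compares co-aligned optical
    slices: RCM's thicker axial inclusion shows particles whose focal
    depth R-SIM's narrower reconstruction plane omits, so a larger share
    of R-SIM objects should be confirmed in RCM than vice versa.  One
    row per seeded scene, component counts summed over the planes;
    in-plane specks below ``min_area_voxels`` (single-pixel noise
    excursions) are removed from both masks before counting.
    """
    rows = []
    for s in range(n_seeds):
        _, masks = paired_modality_masks(_subseed(seed, 1000 + s))
        tot = {"n_rsim": 0, "n_rcm": 0, "rsim_in_rcm": 0, "rcm_in_rsim": 0}
        for z in planes:
            res = cooccurrence(
                morphology.remove_small_objects(
                    masks["rsim"][z], max_size=min_area_voxels - 1, connectivity=2
                ),
                morphology.remove_small_objects(
                    masks["rcm"][z], max_size=min_area_voxels - 1, connectivity=2
                ),
            )
            tot["n_rsim"] += res.n_a
            tot["n_rcm"] += res.n_b
            tot["rsim_in_rcm"] += res.n_a_in_b
            tot["rcm_in_rsim"] += res.n_b_in_a
        rows.append(
            {
                "seed_index": s,
                "n_rsim": tot["n_rsim"],
                "n_rcm": tot["n_rcm"],
                "pct_rsim_in_rcm": (
                    100.0 * tot["rsim_in_rcm"] / tot["n_rsim"]
                    if tot["n_rsim"] else np.nan
                ),
                "pct_rcm_in_rsim": (
                    100.0 * tot["rcm_in_rsim"] / tot["n_rcm"]
                    if tot["n_rcm"] else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def persistence_experiment(n_seeds: int, seed: int) -> pd.DataFrame:
    """Mean consecutive-slice persistence of detected spots per modality."""
    rows = []
    for s in range(n_seeds):
        _, masks = paired_modality_masks(_subseed(seed, 2000 + s))
        row = {"seed_index": s}
        for name, mask in masks.items():
            runs = axial_persistence(mask)
            row[f"mean_slices_{name}"] = float(np.mean(runs)) if runs else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def control_false_positive_rate(n_seeds: int, seed: int,
                                modality: str = "rcm") -> pd.DataFrame:
    """Detected NP volume when a control rendering is segmented as if it
    were a treated image, as a fraction of the cell volume."""
    preset = psf_presets.get_preset(modality)
    scene = replace(COMPARISON_SCENE, control_flag=True)
    rows = []
    for s in range(n_seeds):
        truth = generate_ground_truth(scene, _subseed(seed, 3000 + s))
        baseline = generate_ground_truth(scene, _subseed(seed, 4000 + s))
        stack_t = render_scene(
            truth, preset, replace(RECOVERY_NOISE, seed=_subseed(seed, 5000 + s))
        )
        stack_b = render_scene(
            baseline, preset, replace(RECOVERY_NOISE, seed=_subseed(seed, 6000 + s))
        )
        mask = segment_np(
            [stack_t["reflectance"]], [stack_b["reflectance"]]
        )[0]
        detected = int((mask & truth.cell_mask).sum())
        rows.append(
            {
                "seed_index": s,
                "detected_voxels": detected,
                "cell_voxels": int(truth.cell_mask.sum()),
                "pct_of_cell": 100.0 * detected / truth.cell_mask.sum(),
            }
        )
    return pd.DataFrame(rows)


def registration_recovery(
    n_seeds: int,
    seed: int,
    angle_deg: float = 4.0,
    shift_nm=(250.0, -150.0),
    preprocess: bool = True,
) -> pd.DataFrame:
    """Recover a known RCM<->R-SIM misalignment by intensity registration.

    The R-SIM stack is rendered from a rigidly transformed copy of the
    truth; registration runs on max projections of both reflectance
    stacks and the residual is the mean error at the true cluster
    positions, reported in nm and in RCM pixels.
    """
    rows = []
    for s in range(n_seeds):
        sub = _subseed(seed, 7000 + s)
        scene = replace(
            COMPARISON_SCENE,
            amplitude_range=(300.0, 1500.0),
            misalignment=PlanarTransform.rigid_about(
                np.deg2rad(angle_deg), shift_nm,
                centre_nm=(
                    COMPARISON_SCENE.shape[1] * VOXEL_NM[1] / 2,
                    COMPARISON_SCENE.shape[2] * VOXEL_NM[2] / 2,
                ),
            ),
        )
        truth = generate_ground_truth(scene, _subseed(sub, 1))
        stack_rcm = render_scene(
            truth, psf_presets.RCM, replace(RECOVERY_NOISE, seed=_subseed(sub, 3))
        )
        stack_rsim = render_scene(
            truth,
            psf_presets.RSIM,
            replace(RECOVERY_NOISE, seed=_subseed(sub, 4)),
            apply_misalignment=True,
        )
        fixed = max_projection(stack_rcm["reflectance"])
        moving = max_projection(stack_rsim["reflectance"])
        result = register_intensity(
            fixed, moving, pixel_size_nm=VOXEL_NM[1], preprocess=preprocess,
            cross_modality=True,
        )
        pts = np.array([c.center_nm[1:] for c in truth.np_clusters])
        roundtrip = result.transform.apply(scene.misalignment.apply(pts))
        err = float(np.linalg.norm(roundtrip - pts, axis=1).mean())
        rows.append(
            {
                "seed_index": s,
                "landmark_error_nm": err,
                "landmark_error_px": err / VOXEL_NM[1],
                "metric_value": result.metric_value,
            }
        )
    return pd.DataFrame(rows)
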