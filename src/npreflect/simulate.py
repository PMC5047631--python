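"""Synthetic multi-modality scene generation.

Generates ground-truth cellular scenes (ellipsoidal cell and nucleus
masks, point-like nanoparticle clusters of varying amplitude and
agglomeration inside the cytoplasm, diffuse cellular background
reflectance present also in untreated control scenes) and renders them
through RCM-like, R-SIM-like and TEM-like forward models so every
analysis stage is testable without deposited microscopy data.

Rendering model
---------------
The reflectance channel is the sum of (a) per-cluster anisotropic
Gaussians evaluated analytically at voxel centres — the exact continuous
convolution of a Gaussian impulse with the modality PSF, so the rendered
peak equals the cluster amplitude and the rendered FWHM equals the
preset FWHM (broadened by the cluster radius) — and (b) a low-amplitude
textured cellular background restricted to the cell mask and blurred by
the same PSF.  Poisson-Gaussian noise is then applied.  R-SIM rendering
additionally zeroes a cluster's contribution to z-planes further than
one axial FWHM from the cluster (emulating the reconstruction only
retaining high-contrast in-focus signal).  TEM sections integrate
cluster density over physical slabs at fine pixel pitch, dark particles
on a bright background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import MultiChannelStack, VolumeImage
from .psf import PSFPreset
from .registration import RIGID, PlanarTransform


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned-then-xy-rotated ellipsoid in physical nm coordinates."""

    center_nm: tuple[float, float, float]
    semiaxes_nm: tuple[float, float, float]
    xy_angle_rad: float = 0.0

    def contains(self, points_nm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float)) - np.asarray(
            self.center_nm
        )
        c, s = np.cos(self.xy_angle_rad), np.sin(self.xy_angle_rad)
        y = c * pts[:, 1] + s * pts[:, 2]
        x = -s * pts[:, 1] + c * pts[:, 2]
        az, ay, ax = self.semiaxes_nm
        return (pts[:, 0] / az) ** 2 + (y / ay) ** 2 + (x / ax) ** 2 <= 1.0

    def rasterize(
        self, shape: tuple[int, int, int], voxel_size_nm: tuple[float, float, float]
    ) -> np.ndarray:
        zz, yy, xx = np.meshgrid(
            np.arange(shape[0]) * voxel_size_nm[0],
            np.arange(shape[1]) * voxel_size_nm[1],
            np.arange(shape[2]) * voxel_size_nm[2],
            indexing="ij",
        )
        pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        return self.contains(pts).reshape(shape)


@dataclass(frozen=True)
class Cluster:
    """One nanoparticle cluster: centre (nm), rendered peak amplitude,
    physical radius (nm, broadens the rendered spot)."""

    center_nm: tuple[float, float, float]
    amplitude: float
    radius_nm: float


@dataclass(frozen=True)
class NoiseParams:
    """Poisson-Gaussian acquisition noise.

    ``photon_scale`` converts intensity to expected photon counts before
    Poisson sampling (0 disables shot noise); ``read_sigma`` is additive
    Gaussian read noise in intensity units.
    """

    photon_scale: float = 0.4
    read_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SceneParams:
    """Scene-generation parameters (grid, cell geometry, cluster statistics)."""

    shape: tuple[int, int, int] = (16, 192, 192)
    voxel_size_nm: tuple[float, float, float] = (200.0, 60.0, 60.0)
    n_clusters: int = 30
    amplitude_range: tuple[float, float] = (150.0, 1500.0)  # log-uniform peaks
    radius_range: tuple[float, float] = (10.0, 40.0)
    control_flag: bool = False
    min_separation_nm: float = 0.0
    lateral_separation_only: bool = False  # enforce separation in (y, x) only
    pair_fraction: float = 0.0  # fraction of clusters placed as tight pairs
    pair_spacing_nm: float = 180.0
    n_nuclei: int = 1
    background_fraction: float = 0.1  # of the minimum cluster amplitude
    background_level: float | None = None  # absolute override (intensity)
    misalignment: PlanarTransform | None = None


@dataclass
class SceneGroundTruth:
    """Generator truth for one scene."""

    shape: tuple[int, int, int]
    voxel_size_nm: tuple[float, float, float]
    cell: Ellipsoid
    nuclei: list[Ellipsoid]
    np_clusters: list[Cluster]
    background_level: float
    control_flag: bool
    misalignment: PlanarTransform | None = None
    _cell_mask: np.ndarray | None = field(default=None, repr=False)
    _nucleus_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def cell_mask(self) -> np.ndarray:
        if self._cell_mask is None:
            self._cell_mask = self.cell.rasterize(self.shape, self.voxel_size_nm)
        return self._cell_mask

    @property
    def nucleus_mask(self) -> np.ndarray:
        if self._nucleus_mask is None:
            mask = np.zeros(self.shape, dtype=bool)
            for nuc in self.nuclei:
                mask |= nuc.rasterize(self.shape, self.voxel_size_nm)
            self._nucleus_mask = mask
        return self._nucleus_mask

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_nm))

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {
                "z_nm": c.center_nm[0],
                "y_nm": c.center_nm[1],
                "x_nm": c.center_nm[2],
                "amplitude": c.amplitude,
                "radius_nm": c.radius_nm,
            }
            for c in self.np_clusters
        ]
        return pd.DataFrame(
            rows, columns=["z_nm", "y_nm", "x_nm", "amplitude", "radius_nm"]
        )


MIN_SHAPE = (8, 64, 64)


def generate_ground_truth(params: SceneParams, seed: int) -> SceneGroundTruth:
    """Sample a ground-truth scene; deterministic for a fixed seed.

    The cell is an ellipsoid filling most of the grid, each nucleus an
    ellipsoid strictly inside it, and cluster centres are drawn
    uniformly from the cytoplasm (cell minus nuclei), optionally with a
    minimum pairwise separation and a fraction of tightly spaced
    agglomerate pairs.
    """
    if any(s < m for s, m in zip(params.shape, MIN_SHAPE)):
        raise ValueError(f"grid shape must be at least {MIN_SHAPE}")
    if any(v <= 0 for v in params.voxel_size_nm):
        raise ValueError("voxel sizes must be positive")
    rng = np.random.default_rng(seed)
    extent = np.array(
        [s * v for s, v in zip(params.shape, params.voxel_size_nm)]
    )

    centre = extent / 2.0 + rng.uniform(-0.02, 0.02, size=3) * extent
    semiaxes = rng.uniform(0.34, 0.40, size=3) * extent
    cell = Ellipsoid(tuple(centre), tuple(semiaxes), rng.uniform(0.0, np.pi))

    nuclei = []
    for i in range(params.n_nuclei):
        nuc_axes = rng.uniform(0.30, 0.38, size=3) * semiaxes
        if params.n_nuclei == 1:
            offset = rng.uniform(-0.2, 0.2, size=3) * semiaxes
        else:
            # spread multiple nuclei along the cell's long lateral axis
            frac = -0.45 + 0.9 * i / max(params.n_nuclei - 1, 1)
            offset = np.array([0.0, 0.0, frac * semiaxes[2]])
            offset += rng.uniform(-0.05, 0.05, size=3) * semiaxes
        nuclei.append(
            Ellipsoid(tuple(centre + offset), tuple(nuc_axes), cell.xy_angle_rad)
        )

    truth = SceneGroundTruth(
        shape=params.shape,
        voxel_size_nm=params.voxel_size_nm,
        cell=cell,
        nuclei=nuclei,
        np_clusters=[],
        background_level=(
            params.background_level
            if params.background_level is not None
            else params.background_fraction * params.amplitude_range[0]
        ),
        control_flag=params.control_flag,
        misalignment=params.misalignment,
    )
    if params.control_flag or params.n_clusters == 0:
        return truth

    cytoplasm_voxels = int(truth.cell_mask.sum() - (truth.cell_mask & truth.nucleus_mask).sum())
    if params.n_clusters > cytoplasm_voxels:
        raise ValueError(
            f"requested {params.n_clusters} clusters but the cytoplasm only "
            f"contains {cytoplasm_voxels} voxels"
        )

    def in_cytoplasm(p: np.ndarray) -> bool:
        if not cell.contains(p[None, :])[0]:
            return False
        return not any(nuc.contains(p[None, :])[0] for nuc in nuclei)

    lo, hi = params.amplitude_range
    amplitudes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=params.n_clusters))
    radii = rng.uniform(*params.radius_range, size=params.n_clusters)

    n_pairs = int(round(params.pair_fraction * params.n_clusters / 2.0))
    centres: list[np.ndarray] = []
    max_tries = max(20000, 10000 * params.n_clusters)
    tries = 0
    bbox_lo = np.maximum(centre - semiaxes, 0.0)
    bbox_hi = np.minimum(centre + semiaxes, extent)

    def sample_point() -> np.ndarray:
        return rng.uniform(bbox_lo, bbox_hi)

    def far_enough(p: np.ndarray) -> bool:
        if params.min_separation_nm <= 0 or not centres:
            return True
        diff = np.asarray(centres) - p
        if params.lateral_separation_only:
            diff = diff[:, 1:]  # z-profiles must not cross a neighbour
        d = np.linalg.norm(diff, axis=1)
        return bool(d.min() >= params.min_separation_nm)

    while len(centres) < params.n_clusters and tries < max_tries:
        tries += 1
        p = sample_point()
        if not (in_cytoplasm(p) and far_enough(p)):
            continue
        centres.append(p)
        # place an agglomerate partner right next to some anchors
        if n_pairs > 0 and len(centres) < params.n_clusters:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            partner = p + params.pair_spacing_nm * np.array(
                [0.0, np.sin(theta), np.cos(theta)]
            )
            if in_cytoplasm(partner):
                centres.append(partner)
                n_pairs -= 1
    if len(centres) < params.n_clusters:
        raise ValueError(
            "could not place all clusters under the separation constraint; "
            "reduce n_clusters or min_separation_nm"
        )

    truth.np_clusters = [
        Cluster(tuple(c), float(a), float(r))
        for c, a, r in zip(centres, amplitudes, radii)
    ]
    return truth


def transform_scene(truth: SceneGroundTruth, transform: PlanarTransform) -> SceneGroundTruth:
    """Apply a rigid in-plane misalignment to a scene's geometry.

    Used to emulate inter-modality misalignment: the second modality is
    rendered from the transformed copy of the same ground truth.
    """
    if transform.model != RIGID:
        raise ValueError("scene misalignment supports rigid transforms only")

    def move(e: Ellipsoid) -> Ellipsoid:
        yx = transform.apply(np.array(e.center_nm[1:]))
        return replace(
            e,
            center_nm=(e.center_nm[0], float(yx[0]), float(yx[1])),
            xy_angle_rad=e.xy_angle_rad + transform.rotation_angle,
        )

    clusters = []
    for c in truth.np_clusters:
        yx = transform.apply(np.array(c.center_nm[1:]))
        clusters.append(
            replace(c, center_nm=(c.center_nm[0], float(yx[0]), float(yx[1])))
        )
    return SceneGroundTruth(
        shape=truth.shape,
        voxel_size_nm=truth.voxel_size_nm,
        cell=move(truth.cell),
        nuclei=[move(n) for n in truth.nuclei],
        np_clusters=clusters,
        background_level=truth.background_level,
        control_flag=truth.control_flag,
        misalignment=truth.misalignment,
    )


def _apply_noise(img: np.ndarray, noise: NoiseParams, rng: np.random.Generator):
    out = img
    if noise.photon_scale > 0:
        out = rng.poisson(np.clip(out, 0.0, None) * noise.photon_scale) / (
            noise.photon_scale
        )
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=img.shape)
    return out.astype(float)


def _add_gaussian_spot(
    vol: np.ndarray,
    voxel_size_nm,
    center_nm,
    amplitude: float,
    sigmas_nm,
    z_window_nm: float | None = None,
    cutoff_sigmas: float = 5.0,
) -> None:
    """Add a separable anisotropic Gaussian evaluated at voxel centres."""
    axes_1d = []
    slices = []
    for ax in range(3):
        sigma_vox = sigmas_nm[ax] / voxel_size_nm[ax]
        c_vox = center_nm[ax] / voxel_size_nm[ax]
        half = max(cutoff_sigmas * sigma_vox, 1.0)
        i0 = max(int(np.floor(c_vox - half)), 0)
        i1 = min(int(np.ceil(c_vox + half)) + 1, vol.shape[ax])
        if i0 >= i1:
            return
        coords = (np.arange(i0, i1) - c_vox) * voxel_size_nm[ax]
        g = np.exp(-(coords**2) / (2.0 * sigmas_nm[ax] ** 2))
        if ax == 0 and z_window_nm is not None:
            g = g * (np.abs(coords) <= z_window_nm)
        axes_1d.append(g)
        slices.append(slice(i0, i1))
    vol[tuple(slices)] += (
        amplitude
        * axes_1d[0][:, None, None]
        * axes_1d[1][None, :, None]
        * axes_1d[2][None, None, :]
    )


def render_scene(
    truth: SceneGroundTruth,
    psf: PSFPreset,
    noise: NoiseParams | None = None,
    apply_misalignment: bool = False,
) -> MultiChannelStack:
    """Render a ground-truth scene through an optical forward model.

    Returns a stack with ``reflectance``, ``cytoplasm`` and ``nucleus``
    channels sharing the truth's grid.  The background texture and the
    noise realisation are both drawn from ``noise.seed``.
    """
    if noise is None:
        noise = NoiseParams()
    if psf.fwhm_axial is None:
        raise ValueError("optical rendering requires an axial PSF; "
                         "use render_tem_sections for TEM")
    if apply_misalignment and truth.misalignment is not None:
        truth = transform_scene(truth, truth.misalignment)

    voxel = truth.voxel_size_nm
    fwhms = (psf.fwhm_axial, psf.fwhm_lateral, psf.fwhm_lateral)
    for ax in range(3):
        if fwhms[ax] < 2.0 * voxel[ax]:
            warnings.warn(
                f"{psf.modality} FWHM along axis {ax} ({fwhms[ax]:.0f} nm) is "
                f"under 2 voxels ({voxel[ax]:.0f} nm each): sampling is "
                "inadequate for faithful rendering",
                RuntimeWarning,
            )

    rng = np.random.default_rng(noise.seed)
    sigma_psf_nm = psf.sigmas_nm()
    sigma_psf_vox = tuple(s / v for s, v in zip(sigma_psf_nm, voxel))
    z_window = psf.fwhm_axial if psf.modality.upper() == "RSIM" else None

    reflectance = np.zeros(truth.shape, dtype=float)
    if truth.background_level > 0:
        tex = ndimage.gaussian_filter(rng.uniform(0.0, 1.0, truth.shape), 3.0)
        span = tex.max() - tex.min()
        if span > 0:
            tex = (tex - tex.min()) / span
        # 5-15% of the minimum cluster amplitude when background_fraction=0.1
        tex = truth.background_level * (0.5 + tex)
        reflectance += ndimage.gaussian_filter(
            tex * truth.cell_mask, sigma_psf_vox
        )
    for cl in truth.np_clusters:
        sigma_cluster = cl.radius_nm / 2.0
        sigmas = tuple(
            np.sqrt(s**2 + sigma_cluster**2) for s in sigma_psf_nm
        )
        _add_gaussian_spot(
            reflectance, voxel, cl.center_nm, cl.amplitude, sigmas, z_window
        )

    # Stain channels are smoothed mask renderings; a light 1-voxel blur
    # keeps the stained body faithful to the ground-truth mask (a full
    # axial PSF blur would erode the thin cell caps).
    cytoplasm = ndimage.gaussian_filter(truth.cell_mask.astype(float) * 100.0, 1.0)
    nucleus = ndimage.gaussian_filter(truth.nucleus_mask.astype(float) * 120.0, 1.0)

    channels = {}
    for name, arr in (
        ("reflectance", reflectance),
        ("cytoplasm", cytoplasm),
        ("nucleus", nucleus),
    ):
        channels[name] = VolumeImage(
            _apply_noise(arr, noise, rng), voxel, modality=psf.modality
        )
    return MultiChannelStack(channels=channels)


def render_tem_sections(
    truth: SceneGroundTruth,
    section_thickness_nm: float,
    n_sections: int,
    pixel_size_nm: float = 10.0,
    z_start_nm: float = 0.0,
) -> list[np.ndarray]:
    """Render serial TEM-like sections: dark NPs on a bright background.

    Consecutive sections tile the axial range from ``z_start_nm``; a
    cluster contributes to the section whose slab contains its centre.
    Faint cell and nucleus shading is included so section outlines can
    drive registration.
    """
    if section_thickness_nm <= 0:
        raise ValueError("section thickness must be positive")
    if pixel_size_nm > 10.0:
        raise ValueError("TEM pixel size must be <= 10 nm")
    depth = truth.shape[0] * truth.voxel_size_nm[0]
    if z_start_nm + n_sections * section_thickness_nm > depth:
        raise ValueError(
            f"{n_sections} sections of {section_thickness_nm} nm from "
            f"{z_start_nm} nm exceed the grid depth of {depth} nm"
        )
    ny = int(np.ceil(truth.extent_nm[1] / pixel_size_nm))
    nx = int(np.ceil(truth.extent_nm[2] / pixel_size_nm))
    yy, xx = np.meshgrid(
        np.arange(ny) * pixel_size_nm,
        np.arange(nx) * pixel_size_nm,
        indexing="ij",
    )

    sections = []
    for k in range(n_sections):
        z0 = z_start_nm + k * section_thickness_nm
        z_mid = z0 + section_thickness_nm / 2.0
        img = np.full((ny, nx), 200.0)
        pts = np.stack(
            [np.full(yy.size, z_mid), yy.ravel(), xx.ravel()], axis=1
        )
        cell2d = truth.cell.contains(pts).reshape(ny, nx)
        img[cell2d] = 180.0
        for nuc in truth.nuclei:
            nuc2d = nuc.contains(pts).reshape(ny, nx)
            img[nuc2d] = 150.0
        for cl in truth.np_clusters:
            if not (z0 <= cl.center_nm[0] < z0 + section_thickness_nm):
                continue
            sigma = max(cl.radius_nm / 2.0, pixel_size_nm)
            r2 = (yy - cl.center_nm[1]) ** 2 + (xx - cl.center_nm[2]) ** 2
            img -= 170.0 * np.exp(-r2 / (2.0 * sigma**2))
        sections.append(np.clip(img, 0.0, None))
    return sections


def write_scene(
    directory: str | Path,
    truth: SceneGroundTruth,
    stacks: dict[str, MultiChannelStack],
    seed: int,
) -> None:
    """Persist a scene: TIFF channels per modality, ground-truth CSV and
    a JSON sidecar with grid metadata and the misalignment transform."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for modality, stack in stacks.items():
        stack.save(directory / modality)
    truth.cluster_table().to_csv(directory / "clusters.csv", index=False)
    meta = {
        "shape": list(truth.shape),
        "voxel_size_nm": list(truth.voxel_size_nm),
        "background_level": truth.background_level,
        "control_flag": truth.control_flag,
        "seed": seed,
        "misalignment": (
            truth.misalignment.to_dict() if truth.misalignment else None
        ),
    }
    (directory / "scene.json").write_text(json.dumps(meta, indent=2))
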