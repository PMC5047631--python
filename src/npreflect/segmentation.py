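"""Denoise-then-cluster segmentation of cytoplasm, nuclei and NP signal.

The nanoparticle segmentation follows the control-baseline recipe:
treated and untreated (control) reflectance stacks are normalised
together, smoothed, clustered on pooled intensities by k-means, and the
brightest cluster is retained only where it exceeds a robust threshold
derived from the control images — untreated cells are the mandatory
negative baseline because cellular constituents reflect weakly even
without nanoparticles.

The 1-D k-means is deterministic: centroids are initialised at evenly
spaced quantiles and iterated with a histogram-weighted Lloyd's update,
so identical inputs always yield identical masks and adding a constant
offset to the image leaves the labelling unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .image import as_array

log = logging.getLogger(__name__)

FACE = "face"
FULL = "full"


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity separation to cluster."""


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the smooth + k-means + threshold segmentation.

    Defaults target the reflectance (NP) channel: sigma 0.7 voxels,
    k = 3 (background / cellular reflectance / NP signal) and a robust
    control threshold at median + 3.5 * MAD-sigma.  Use ``for_cell()``
    for the cytoplasm stain (sigma 1 voxel, k = 2).
    """

    smooth_sigma: float = 0.7
    n_clusters: int = 3
    threshold_multiplier: float = 3.5
    connectivity: str = FULL

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.smooth_sigma < 0 or self.threshold_multiplier < 0:
            raise ValueError("smooth_sigma and threshold_multiplier must be >= 0")
        if self.connectivity not in (FACE, FULL):
            raise ValueError("connectivity must be 'face' or 'full'")

    @classmethod
    def for_cell(cls) -> "SegmentationParams":
        return cls(smooth_sigma=1.0, n_clusters=2)


def connectivity_order(connectivity: str, ndim: int) -> int:
    """skimage connectivity order: 1 = face neighbours, ndim = full."""
    return 1 if connectivity == FACE else ndim


def kmeans_1d(
    values: np.ndarray,
    k: int,
    n_bins: int = 2048,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means on an intensity multiset.

    Initialises centroids at the (2i+1)/(2k) weighted quantiles and runs
    Lloyd's algorithm on a fine histogram.  Returns ``(centers,
    boundaries)`` where the k-1 sorted boundaries are the midpoints
    between adjacent centers; assignment of a value v is
    ``searchsorted(boundaries, v)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if not np.isfinite(vmin) or not np.isfinite(vmax):
        raise ValueError("values must be finite")
    if vmax == vmin:
        raise DegenerateImageError("constant intensities cannot be clustered")
    weights, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    mids = 0.5 * (edges[:-1] + edges[1:])
    cdf = np.cumsum(weights) / weights.sum()
    q = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    centers = mids[np.searchsorted(cdf, q, side="left").clip(0, n_bins - 1)]
    centers = np.unique(centers)
    while len(centers) < k:  # merge-degenerate init: nudge duplicates apart
        centers = np.sort(
            np.append(centers, centers[-1] + (vmax - vmin) / n_bins)
        )
    for _ in range(max_iter):
        boundaries = 0.5 * (centers[:-1] + centers[1:])
        idx = np.searchsorted(boundaries, mids)
        new = centers.copy()
        for j in range(k):
            sel = idx == j
            wj = weights[sel].sum()
            if wj > 0:
                new[j] = (weights[sel] * mids[sel]).sum() / wj
        if np.array_equal(new, centers):
            break
        centers = np.sort(new)
    boundaries = 0.5 * (centers[:-1] + centers[1:])
    return centers, boundaries


def _smooth(image, sigma: float) -> np.ndarray:
    arr = as_array(image)
    return ndimage.gaussian_filter(arr, sigma) if sigma > 0 else arr


def segment_cell(cytoplasm, params: SegmentationParams | None = None) -> np.ndarray:
    """Cell mask from the cytoplasm stain: Gaussian smoothing followed by
    k-means (k=2) on voxel intensities; the brighter cluster is the cell.
    """
    params = params or SegmentationParams.for_cell()
    sm = _smooth(cytoplasm, params.smooth_sigma)
    _, boundaries = kmeans_1d(sm, params.n_clusters)
    return sm > boundaries[-1]


def segment_nuclei(
    nucleus, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[tuple[float, ...]]]:
    """Labelled nuclear mask and physical centroids (nm), sorted by label.

    Uses the same smooth + cluster foreground rule as ``segment_cell``
    followed by connected-component labelling.  An image with empty
    foreground yields an empty centroid list.
    """
    params = params or SegmentationParams.for_cell()
    fg = segment_cell(nucleus, params)
    labels = measure.label(
        fg, connectivity=connectivity_order(params.connectivity, fg.ndim)
    )
    voxel = (
        nucleus.voxel_size_nm
        if hasattr(nucleus, "voxel_size_nm")
        else (1.0,) * fg.ndim
    )
    centroids = [
        tuple(c * v for c, v in zip(region.centroid, voxel))
        for region in sorted(measure.regionprops(labels), key=lambda r: r.label)
    ]
    return labels, centroids


def segment_np(
    treated: list,
    control: list,
    params: SegmentationParams | None = None,
) -> list[np.ndarray]:
    """Segment NP reflectance signal against the control baseline.

    Pipeline: (1) jointly min-max normalise the pooled treated+control
    stacks to [0, 1]; (2) Gaussian-smooth each; (3) k-means on the
    pooled intensities and discard the lowest-mean (image background)
    cluster; (4) of the remaining candidate voxels retain those
    exceeding ``median + m * sigma`` of the control images' robust
    foreground statistics (foreground = the brighter side of the
    control's own two-cluster split; sigma is MAD-based).  The
    control-referenced threshold, not the cluster partition, makes the
    final NP decision: a k-means cluster boundary on pooled intensities
    shifts with the voxel mass of the bright spots and would therefore
    cut the two modalities at very different fractions of the spot
    amplitude, invalidating any cross-modality comparison.  Returns one
    binary mask per treated image.
    """
    params = params or SegmentationParams()
    if not control:
        raise ValueError(
            "NP segmentation requires at least one untreated control image "
            "as the baseline"
        )
    if not treated:
        raise ValueError("no treated images supplied")
    treated_arr = [as_array(im) for im in treated]
    control_arr = [as_array(im) for im in control]
    gmin = min(a.min() for a in treated_arr + control_arr)
    gmax = max(a.max() for a in treated_arr + control_arr)
    if gmax == gmin:
        raise DegenerateImageError("pooled images are constant")
    sm_treated = [
        _smooth((a - gmin) / (gmax - gmin), params.smooth_sigma)
        for a in treated_arr
    ]
    sm_control = [
        _smooth((a - gmin) / (gmax - gmin), params.smooth_sigma)
        for a in control_arr
    ]
    pooled = np.concatenate([a.ravel() for a in sm_treated + sm_control])
    _, boundaries = kmeans_1d(pooled, params.n_clusters)
    background_cut = boundaries[0]

    # Control foreground = the brighter side of the control's own
    # two-cluster split (its cellular-reflectance voxels).  Statistics
    # are taken over that full distribution: thresholding on a k-means
    # tail would collapse the MAD and let noise through.
    ctrl_vals = np.concatenate([a.ravel() for a in sm_control])
    try:
        _, ctrl_split = kmeans_1d(ctrl_vals, 2)
        fg = ctrl_vals[ctrl_vals > ctrl_split[0]]
    except DegenerateImageError:
        fg = ctrl_vals
    if fg.size == 0:
        fg = ctrl_vals
    med = float(np.median(fg))
    sigma = 1.4826 * float(np.median(np.abs(fg - med)))
    threshold = med + params.threshold_multiplier * sigma
    log.info(
        "segment_np: background boundary %.4f, control threshold %.4f "
        "(median %.4f, robust sigma %.4f)", background_cut, threshold, med, sigma,
    )
    masks = [(a > background_cut) & (a > threshold) for a in sm_treated]
    for i, m in enumerate(masks):
        log.info("segment_np: treated image %d -> %d foreground voxels",
                 i, int(m.sum()))
    return masks


def subtract_background(image, sigma_bg: float):
    """Remove diffuse background: image minus its large-sigma Gaussian
    blur, clipped at zero.  ``sigma_bg`` (voxels) should exceed the
    smoothing sigma used for spot detection."""
    if sigma_bg <= 0:
        raise ValueError("sigma_bg must be positive")
    arr = as_array(image)
    out = np.clip(arr - ndimage.gaussian_filter(arr, sigma_bg), 0.0, None)
    if hasattr(image, "voxel_size_nm"):
        return replace(image, data=out) if hasattr(image, "__dataclass_fields__") else out
    return out
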