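"""Connected-component region tables, uptake summaries, cross-modality
co-occurrence and comparison statistics.

Because the two optical modalities differ in resolution, co-occurrence
is counted per connected component (object-based), not per voxel: a
component of one mask co-occurs if at least one of its voxels lies in
the foreground of the other mask (the voxel-wise product).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .image import as_array
from .segmentation import FULL, connectivity_order


def connected_components(
    mask: np.ndarray,
    connectivity: str = FULL,
    voxel_size_nm=None,
    intensity=None,
) -> pd.DataFrame:
    """Label maximal connected foreground sets and tabulate them.

    Returns a DataFrame sorted by label with voxel counts, physical
    area/volume (when ``voxel_size_nm`` is given), centroids in voxels
    and nm, and mean/max intensity (when ``intensity`` is given; the
    intensity-weighted centroid is then also included).  An empty mask
    yields an empty table.
    """
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    labels = measure.label(mask, connectivity=connectivity_order(connectivity, ndim))
    inten = as_array(intensity) if intensity is not None else None
    if inten is not None and inten.shape != mask.shape:
        raise ValueError("intensity image must match the mask shape")
    axes = ("z", "y", "x")[-ndim:]
    voxel = tuple(voxel_size_nm) if voxel_size_nm is not None else (1.0,) * ndim
    unit_volume = float(np.prod(voxel))
    size_col = "area_nm2" if ndim == 2 else "volume_nm3"

    rows = []
    for region in sorted(
        measure.regionprops(labels, intensity_image=inten), key=lambda r: r.label
    ):
        row = {"label": region.label, "n_voxels": int(region.area)}
        row[size_col] = region.area * unit_volume
        for ax, c, v in zip(axes, region.centroid, voxel):
            row[f"centroid_{ax}_vox"] = c
            row[f"centroid_{ax}_nm"] = c * v
        if inten is not None:
            row["mean_intensity"] = float(region.intensity_mean)
            row["max_intensity"] = float(region.intensity_max)
            for ax, c, v in zip(axes, region.centroid_weighted, voxel):
                row[f"centroid_{ax}_weighted_nm"] = c * v
        rows.append(row)
    columns = ["label", "n_voxels", size_col]
    columns += [f"centroid_{ax}_vox" for ax in axes]
    columns += [f"centroid_{ax}_nm" for ax in axes]
    if inten is not None:
        columns += ["mean_intensity", "max_intensity"]
        columns += [f"centroid_{ax}_weighted_nm" for ax in axes]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class CooccurrenceResult:
    """Object-based co-occurrence between two binary masks."""

    n_a: int
    n_b: int
    n_a_in_b: int
    n_b_in_a: int

    @property
    def pct_a_in_b(self) -> float:
        return 100.0 * self.n_a_in_b / self.n_a if self.n_a else 0.0

    @property
    def pct_b_in_a(self) -> float:
        return 100.0 * self.n_b_in_a / self.n_b if self.n_b else 0.0

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_a_in_b": self.n_a_in_b,
            "n_b_in_a": self.n_b_in_a,
            "pct_a_in_b": self.pct_a_in_b,
            "pct_b_in_a": self.pct_b_in_a,
        }


def cooccurrence(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    connectivity: str = FULL,
) -> CooccurrenceResult:
    """Count components of each mask that overlap the other mask.

    Each source component counts at most once regardless of how many
    components it touches on the other side, so the co-occurring count
    never exceeds the source component count.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape; equalise pixel size first")
    conn = connectivity_order(connectivity, mask_a.ndim)
    lab_a = measure.label(mask_a, connectivity=conn)
    lab_b = measure.label(mask_b, connectivity=conn)
    n_a = int(lab_a.max())
    n_b = int(lab_b.max())
    hit_a = np.unique(lab_a[mask_b])
    hit_b = np.unique(lab_b[mask_a])
    return CooccurrenceResult(
        n_a=n_a,
        n_b=n_b,
        n_a_in_b=int((hit_a > 0).sum()),
        n_b_in_a=int((hit_b > 0).sum()),
    )


def axial_persistence(mask3d: np.ndarray, connectivity: str = FULL) -> list[int]:
    """Per-component maximal run of consecutive z-slices containing signal.

    Accepts a binary mask (labelled internally under ``connectivity``)
    or an already-labelled integer image.  A path-connected component
    always occupies a contiguous z-range, but regions of a pre-labelled
    input may not: such z-gaps are flagged with a warning and the region
    contributes its longest consecutive run.
    """
    mask3d = np.asarray(mask3d)
    if mask3d.ndim != 3:
        raise ValueError("axial persistence requires a 3-D mask")
    if np.issubdtype(mask3d.dtype, np.integer) and mask3d.max() > 1:
        labels = mask3d
    else:
        labels = measure.label(
            mask3d.astype(bool), connectivity=connectivity_order(connectivity, 3)
        )
    runs = []
    for region in sorted(measure.regionprops(labels), key=lambda r: r.label):
        zs = np.unique(region.coords[:, 0])
        if zs.max() - zs.min() + 1 != len(zs):
            warnings.warn(
                f"component {region.label} spans z-slices with gaps "
                f"({zs.tolist()}); reporting its longest consecutive run",
                RuntimeWarning,
            )
        breaks = np.flatnonzero(np.diff(zs) > 1)
        segments = np.split(zs, breaks + 1)
        runs.append(max(len(s) for s in segments))
    return runs


def per_cell_summary(
    cell_mask: np.ndarray,
    np_mask: np.ndarray,
    intensity=None,
    voxel_size_nm=None,
    connectivity: str = FULL,
    min_voxels: int = 1,
) -> dict:
    """Uptake summary for one cell: NP components inside the cell mask,
    their total physical size and the mean spot intensity.

    ``min_voxels`` > 1 drops components smaller than a plausible
    diffraction-limited spot (isolated noise excursions survive any
    intensity threshold occasionally; a real spot covers tens of voxels
    at Nyquist sampling).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    np_mask = np.asarray(np_mask, dtype=bool)
    if cell_mask.shape != np_mask.shape:
        raise ValueError("cell and NP masks must share a shape")
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    restricted = np_mask & cell_mask
    table = connected_components(
        restricted, connectivity, voxel_size_nm=voxel_size_nm, intensity=intensity
    )
    if min_voxels > 1 and len(table):
        table = table[table.n_voxels >= min_voxels]
    size_col = "area_nm2" if cell_mask.ndim == 2 else "volume_nm3"
    inten = as_array(intensity) if intensity is not None else None
    mean_spot = (
        float(inten[restricted].mean())
        if inten is not None and restricted.any()
        else float("nan")
    )
    return {
        "n_components": int(len(table)),
        "n_voxels": int(restricted.sum()),
        f"total_{size_col}": float(table[size_col].sum()) if len(table) else 0.0,
        "mean_spot_intensity": mean_spot,
        "cell_voxels": int(cell_mask.sum()),
    }


def two_sample_ttest(group_a, group_b, equal_var: bool = True) -> dict:
    """Two-sided two-sample Student's t-test (pooled variance by default,
    Welch with ``equal_var=False``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p)}
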