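"""In-memory containers for 3-D microscopy data and their TIFF/JSON I/O.

Axis order is (z, y, x) throughout, 0-based voxel indices, voxel centres
at integer coordinates; the physical coordinate of voxel ``i`` along an
axis is ``i * voxel_size_nm[axis]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class VolumeImage:
    """Single-channel 3-D intensity grid with physical voxel size in nm."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != 3 or any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel_size_nm must be three positive lengths")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_nm))

    def save(self, path: str | Path) -> None:
        """Write the volume as a multi-page TIFF plus a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        sidecar = {
            "voxel_size_nm": list(self.voxel_size_nm),
            "modality": self.modality,
            "shape": list(self.shape),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        path = Path(path)
        data = tifffile.imread(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=np.asarray(data, dtype=float),
            voxel_size_nm=tuple(meta["voxel_size_nm"]),
            modality=meta.get("modality"),
        )


@dataclass
class MultiChannelStack:
    """Named set of co-registered single-channel volumes from one acquisition.

    Standard channel names: ``reflectance``, ``cytoplasm``, ``nucleus``
    and optionally ``lysosome``.
    """

    channels: dict[str, VolumeImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a stack needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        voxels = {c.voxel_size_nm for c in self.channels.values()}
        if len(shapes) != 1 or len(voxels) != 1:
            raise ValueError("channels must share shape and voxel size")

    def __getitem__(self, name: str) -> VolumeImage:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_size_nm(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).voxel_size_nm

    @property
    def modality(self) -> str | None:
        return next(iter(self.channels.values())).modality

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, vol in self.channels.items():
            vol.save(directory / f"{name}.tif")

    @classmethod
    def load(cls, directory: str | Path) -> "MultiChannelStack":
        directory = Path(directory)
        channels = {
            p.stem: VolumeImage.load(p) for p in sorted(directory.glob("*.tif"))
        }
        return cls(channels=channels)


def as_array(image) -> np.ndarray:
    """Accept a VolumeImage or a bare ndarray and return the ndarray."""
    if isinstance(image, VolumeImage):
        return image.data
    return np.asarray(image, dtype=float)
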