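"""Point-spread-function presets for the three imaging modalities.

The optical presets carry the instrument resolutions measured on
intracellular nanoparticle signal: reflectance confocal microscopy (RCM)
345 nm lateral / 1077 nm axial, reflectance structured illumination
(R-SIM) 115 nm lateral / 685 nm axial.  The TEM preset is effectively
unblurred at the pixel sizes simulated here (a few nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA: float = float(2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


@dataclass(frozen=True)
class PSFPreset:
    """Anisotropic Gaussian PSF described by lateral and axial FWHM (nm).

    ``fwhm_axial`` is ``None`` for TEM, which produces 2-D sections with
    no optical axial blur in this model.
    """

    modality: str
    fwhm_lateral: float
    fwhm_axial: float | None = None

    def __post_init__(self) -> None:
        if self.fwhm_lateral <= 0:
            raise ValueError("fwhm_lateral must be positive")
        if self.fwhm_axial is not None:
            if self.fwhm_axial <= 0:
                raise ValueError("fwhm_axial must be positive")
            if self.fwhm_axial <= self.fwhm_lateral:
                raise ValueError(
                    "optical modalities must have fwhm_axial > fwhm_lateral"
                )

    @property
    def sigma_lateral(self) -> float:
        return fwhm_to_sigma(self.fwhm_lateral)

    @property
    def sigma_axial(self) -> float | None:
        if self.fwhm_axial is None:
            return None
        return fwhm_to_sigma(self.fwhm_axial)

    def sigmas_nm(self) -> tuple[float, float, float]:
        """(sigma_z, sigma_y, sigma_x) in nm; requires an axial FWHM."""
        if self.fwhm_axial is None:
            raise ValueError(f"{self.modality} preset has no axial FWHM")
        return (self.sigma_axial, self.sigma_lateral, self.sigma_lateral)


RCM = PSFPreset("RCM", fwhm_lateral=345.0, fwhm_axial=1077.0)
RSIM = PSFPreset("RSIM", fwhm_lateral=115.0, fwhm_axial=685.0)
TEM = PSFPreset("TEM", fwhm_lateral=4.0, fwhm_axial=None)

PRESETS: dict[str, PSFPreset] = {"rcm": RCM, "rsim": RSIM, "tem": TEM}


def get_preset(name: str) -> PSFPreset:
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown modality {name!r}; choose from {sorted(PRESETS)}")
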