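"""Optical and run configuration.

All lengths are carried in the units stated on each field (mm for the 4f
relay geometry, nm for wavelengths and sampling steps).  The recovery grid
is defined here once and shared by the PSF engine, the forward simulator
and the solver so that the discrete 3D PSF, rendered frames and recovered
voxel grids are always geometrically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when an optical or run configuration is physically invalid."""


@dataclass(frozen=True)
class OpticalConfig:
    """Microscope + 4f-relay parameters governing PSF formation.

    Parameters
    ----------
    numerical_aperture : objective NA (dimensionless), must not exceed the
        medium index.
    medium_index : refractive index n of the objective immersion medium.
    pupil_radius_mm : effective beam radius r at the Fourier plane; equals
        the radius of the phase mask.
    relay_focal_length_mm : focal length f of the two identical 4f lenses.
    emission_wavelength_nm : fluorescence emission wavelength.
    camera_pixel_size_nm : detector pixel size in sample-plane units
        (i.e. after division by the total magnification).
    lateral_grid_step_nm : lateral voxel pitch of the recovery grid.  The
        default pipeline uses one voxel column per camera pixel.
    axial_grid_step_nm : axial voxel pitch of the recovery grid.
    axial_range_nm : full axial span of the PSF stack, symmetric about
        focus; must be an integer multiple of ``axial_grid_step_nm``.
    pupil_grid_size : samples per side of the (square, even) pupil grid.
    magnification_constant : dimensionless prefactor of the lateral
        magnification formula ``M_lat = C * n * f / r``; the constant is
        configurable so a calibrated value can be substituted.
    """

    numerical_aperture: float = 1.45
    medium_index: float = 1.518
    pupil_radius_mm: float = 1.5
    relay_focal_length_mm: float = 150.0
    emission_wavelength_nm: float = 580.0
    camera_pixel_size_nm: float = 100.0
    lateral_grid_step_nm: float = 100.0
    axial_grid_step_nm: float = 50.0
    axial_range_nm: float = 2000.0
    pupil_grid_size: int = 128
    magnification_constant: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.numerical_aperture <= self.medium_index):
            raise ConfigurationError(
                f"require 0 < NA <= n, got NA={self.numerical_aperture}, "
                f"n={self.medium_index}"
            )
        for name in (
            "pupil_radius_mm",
            "relay_focal_length_mm",
            "emission_wavelength_nm",
            "camera_pixel_size_nm",
            "lateral_grid_step_nm",
            "axial_grid_step_nm",
            "axial_range_nm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        n_steps = self.axial_range_nm / self.axial_grid_step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigurationError(
                "axial_range_nm must be an integer multiple of axial_grid_step_nm"
            )
        if self.pupil_grid_size % 2 != 0 or self.pupil_grid_size < 16:
            raise ConfigurationError("pupil_grid_size must be even and >= 16")
        if self.aperture_radius_px < 8.0:
            raise ConfigurationError(
                "pupil grid too coarse: aperture spans "
                f"{2 * self.aperture_radius_px:.1f} samples (< 16); increase "
                "pupil_grid_size or lateral_grid_step_nm"
            )
        if 2.0 * self.aperture_radius_px > self.pupil_grid_size:
            raise ConfigurationError(
                "aperture exceeds the pupil grid: decrease lateral_grid_step_nm "
                "or increase pupil_grid_size"
            )

    @property
    def aperture_radius_px(self) -> float:
        """Aperture radius in pupil-grid samples.

        The pupil plane samples spatial frequency; the coherent cutoff
        NA/lambda is mapped so that the image-plane sampling of the FFT
        equals ``lateral_grid_step_nm`` exactly.
        """
        return (
            self.pupil_grid_size
            * self.numerical_aperture
            * self.lateral_grid_step_nm
            / self.emission_wavelength_nm
        )

    @property
    def n_z_planes(self) -> int:
        return int(round(self.axial_range_nm / self.axial_grid_step_nm)) + 1

    @property
    def z_planes_nm(self) -> np.ndarray:
        half = self.axial_range_nm / 2.0
        return np.linspace(-half, half, self.n_z_planes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OpticalConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
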