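"""Pupil functions, phase masks and scalar-diffraction PSF stacks.

The image of a point emitter is computed by scalar Fourier optics: the
pupil amplitude (a uniform disk out to the NA cutoff) is multiplied by the
phase-mask transmission and a defocus phase, and the intensity PSF is the
squared modulus of its 2D Fourier transform.  Defocus uses the high-NA
angular-spectrum phase

    k_z(rho) = (2 pi n / lambda) * sqrt(1 - (NA rho / n)^2),

with ``rho`` the pupil radius normalized to the aperture edge.  The pupil
sampling is tied to :attr:`OpticalConfig.aperture_radius_px` so the FFT of
the pupil is sampled exactly at ``lateral_grid_step_nm`` in the sample
plane; no image-space resampling is needed.

A double-helix mask is generated as the phase of a coherent superposition
of Laguerre-Gauss modes whose (radial, azimuthal) indices lie on a line of
slope ``charge_step`` in the modal plane; such superpositions rotate
rigidly with the Gouy phase through focus, and the phase-only projection
retains the two-lobe, rotating structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import genlaguerre

from .config import ConfigurationError, OpticalConfig

TWO_PI = 2.0 * np.pi


class MaskFormatError(ValueError):
    """Raised for unreadable or malformed phase-mask files."""


class CalibrationWarning(UserWarning):
    """Emitted when a PSF slice is unusable for rotation calibration."""


# ---------------------------------------------------------------------------
# pupil geometry
# ---------------------------------------------------------------------------

def pupil_coordinates(config: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pupil coordinates (rho, theta) on the pupil grid.

    rho = 1 at the aperture edge (NA cutoff); theta in radians CCW from +x.
    """
    n = config.pupil_grid_size
    c = n / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - c) / config.aperture_radius_px
    y = (yy - c) / config.aperture_radius_px
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    return rho, theta


def make_pupil(config: OpticalConfig) -> np.ndarray:
    """Binary circular pupil amplitude: 1 inside the NA aperture, 0 outside."""
    rho, _ = pupil_coordinates(config)
    return (rho <= 1.0).astype(np.complex128)


# ---------------------------------------------------------------------------
# phase masks
# ---------------------------------------------------------------------------

@dataclass
class PhaseMask:
    """A pupil-plane phase-delay map.

    ``phase`` is stored wrapped to [0, 2pi) on the pupil grid.  ``params``
    records the free parameters of the generator (or the source file).
    """

    phase: np.ndarray
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise MaskFormatError("phase mask must be 2D")
        if not np.all(np.isfinite(self.phase)):
            raise MaskFormatError("phase mask contains non-finite values")
        self.phase = np.mod(self.phase, TWO_PI)
        # float rounding in np.mod can land exactly on the period
        self.phase[self.phase >= TWO_PI] = 0.0


def flat_mask(config: OpticalConfig) -> PhaseMask:
    """Clear aperture (zero phase): yields the diffraction-limited PSF."""
    n = config.pupil_grid_size
    return PhaseMask(np.zeros((n, n)), name="flat")


def double_helix_mask(
    config: OpticalConfig,
    n_modes: int = 4,
    charge_step: int = 2,
    waist_frac: float = 0.3,
) -> PhaseMask:
    """Double-helix phase mask from a rotating Laguerre-Gauss superposition.

    Modes (p_j, l_j) = (j, j * charge_step), j = 0..n_modes-1, are summed
    with equal energy and waist ``waist_frac`` times the aperture radius;
    the mask is the argument of the sum (phase-only projection).  Adjacent
    charges differing by ``charge_step`` interfere into ``charge_step``
    azimuthal lobes (two for the default step of 2), and the modal line of
    slope ``charge_step`` makes the pattern rotate through focus.
    """
    if n_modes < 2:
        raise ConfigurationError("n_modes must be >= 2")
    if charge_step < 1:
        raise ConfigurationError("charge_step must be >= 1")
    rho, theta = pupil_coordinates(config)
    w = waist_frac  # waist in units of the aperture radius
    s = 2.0 * rho**2 / w**2
    total = np.zeros_like(rho, dtype=np.complex128)
    for j in range(n_modes):
        l = j * charge_step
        radial = (np.sqrt(2.0) * rho / w) ** l * genlaguerre(j, l)(s) * np.exp(-s / 2.0)
        norm = np.sqrt(np.sum(radial**2))
        total += (radial / norm) * np.exp(1j * l * theta)
    phase = np.angle(total)
    phase[rho > 1.0] = 0.0
    return PhaseMask(
        phase,
        name="double_helix",
        params={
            "n_modes": n_modes,
            "charge_step": charge_step,
            "waist_frac": waist_frac,
        },
    )


def load_mask(
    path: str | Path,
    config: OpticalConfig,
    units: str = "radians",
) -> PhaseMask:
    """Load a phase mask from a single-plane TIFF or CSV file.

    ``units`` is ``"radians"`` or ``"turns"`` (normalized [0, 1] phase).
    The map is resampled to the pupil grid by bilinear interpolation.
    """
    path = Path(path)
    if units not in ("radians", "turns"):
        raise MaskFormatError(f"unknown mask units {units!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=np.float64)
    else:
        data = np.loadtxt(path, delimiter=",", dtype=np.float64)
        data = np.atleast_2d(data)
    if data.ndim != 2:
        raise MaskFormatError(f"{path}: expected a 2D phase map, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise MaskFormatError(f"{path}: phase map contains NaN/Inf")
    if units == "turns":
        data = data * TWO_PI
    n = config.pupil_grid_size
    if data.shape != (n, n):
        zoom = (n / data.shape[0], n / data.shape[1])
        data = ndimage.zoom(data, zoom, order=1, mode="nearest")
    return PhaseMask(data, name=path.stem, params={"source": str(path), "units": units})


def save_mask(mask: PhaseMask, path: str | Path) -> None:
    """Write a mask as float32 radians (TIFF) or CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, mask.phase.astype(np.float32))
    else:
        np.savetxt(path, mask.phase, delimiter=",")


# ---------------------------------------------------------------------------
# defocus and PSF stack
# ---------------------------------------------------------------------------

def defocus_phase(config: OpticalConfig, z_nm: float) -> np.ndarray:
    """Angular-spectrum defocus phase (radians) for axial displacement z.

    phase(rho) = (2 pi n / lambda) * z * sqrt(1 - (NA rho / n)^2) inside the
    aperture, 0 outside.  Odd in z; extrapolation beyond the configured
    axial range is permitted.
    """
    rho, _ = pupil_coordinates(config)
    na_over_n = config.numerical_aperture / config.medium_index
    arg = 1.0 - (na_over_n * rho) ** 2
    kz = (
        TWO_PI
        * config.medium_index
        / config.emission_wavelength_nm
        * np.sqrt(np.clip(arg, 0.0, None))
    )
    phase = kz * z_nm
    phase[rho > 1.0] = 0.0
    return phase


@dataclass
class PSFStack:
    """The discrete 3D PSF sampled on the recovery grid.

    ``values`` has axis order (z, y, x) with z ascending; slice k is the
    intensity pattern of an in-focus detector viewing a point source
    defocused by ``z_planes_nm[k]``.  Slices are normalized so the focal
    slice sums to 1; a phase-only pupil conserves energy, so every slice
    sum stays within a few percent of 1 (energy leaving the crop window at
    large defocus accounts for the tolerance).
    """

    values: np.ndarray
    z_planes_nm: np.ndarray
    lateral_step_nm: float
    axial_step_nm: float
    normalization: str = "focus_slice_sum"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.z_planes_nm = np.asarray(self.z_planes_nm, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PSFStack values must be 3D (z, y, x)")
        if len(self.z_planes_nm) != self.values.shape[0]:
            raise ValueError("z_planes_nm length must match the z axis")
        if np.any(self.values < 0):
            raise ValueError("PSF values must be nonnegative")

    @property
    def n_planes(self) -> int:
        return self.values.shape[0]

    @property
    def focus_index(self) -> int:
        return int(np.argmin(np.abs(self.z_planes_nm)))

    def slice_at(self, z_nm: float) -> np.ndarray:
        """Linearly interpolated slice at an arbitrary z within the range."""
        z = self.z_planes_nm
        if z_nm < z[0] or z_nm > z[-1]:
            raise ValueError(f"z={z_nm} nm outside the stack range [{z[0]}, {z[-1]}]")
        k = int(np.searchsorted(z, z_nm, side="right") - 1)
        k = min(k, len(z) - 2)
        f = (z_nm - z[k]) / (z[k + 1] - z[k])
        return (1.0 - f) * self.values[k] + f * self.values[k + 1]

    def save_tiff(self, path: str | Path) -> None:
        import tifffile

        meta = {
            "z_planes_nm": self.z_planes_nm.tolist(),
            "lateral_step_nm": self.lateral_step_nm,
            "axial_step_nm": self.axial_step_nm,
        }
        tifffile.imwrite(
            path, self.values.astype(np.float32), description=json.dumps(meta)
        )

    @classmethod
    def load_tiff(cls, path: str | Path) -> "PSFStack":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            values = tf.asarray().astype(np.float64)
            desc = tf.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        if "z_planes_nm" not in meta:
            raise MaskFormatError(f"{path}: missing z_planes_nm metadata")
        return cls(
            values=values,
            z_planes_nm=np.asarray(meta["z_planes_nm"]),
            lateral_step_nm=float(meta.get("lateral_step_nm", 0.0) or 0.0),
            axial_step_nm=float(meta.get("axial_step_nm", 0.0) or 0.0),
        )


def build_psf_stack(
    config: OpticalConfig,
    mask: PhaseMask,
    crop_px: int = 71,
) -> PSFStack:
    """Propagate the masked pupil to a z-stack of intensity PSF slices.

    Each slice is |FFT(pupil * exp(i mask) * exp(i defocus(z)))|^2, centered,
    cropped to ``crop_px`` per side (odd, so the PSF center falls on a
    pixel), and normalized to the focal-slice energy.
    """
    if mask.phase.shape != (config.pupil_grid_size, config.pupil_grid_size):
        raise ConfigurationError("mask grid does not match pupil_grid_size")
    if crop_px % 2 != 1:
        raise ConfigurationError("crop_px must be odd")
    if crop_px > config.pupil_grid_size:
        raise ConfigurationError("crop_px exceeds the pupil grid")
    pupil = make_pupil(config)
    masked = pupil * np.exp(1j * mask.phase)
    z_planes = config.z_planes_nm
    n = config.pupil_grid_size
    c = n // 2
    h = crop_px // 2
    slices = np.empty((len(z_planes), crop_px, crop_px))
    for k, z in enumerate(z_planes):
        field_k = masked * np.exp(1j * defocus_phase(config, z))
        psf = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field_k)))) ** 2
        slices[k] = psf[c - h : c + h + 1, c - h : c + h + 1]
    focus = int(np.argmin(np.abs(z_planes)))
    slices /= slices[focus].sum()
    return PSFStack(
        values=slices,
        z_planes_nm=z_planes,
        lateral_step_nm=config.lateral_grid_step_nm,
        axial_step_nm=config.axial_grid_step_nm,
    )


# ---------------------------------------------------------------------------
# rotation calibration
# ---------------------------------------------------------------------------

@dataclass
class RotationCalibration:
    """Lobe-pair orientation versus defocus, with a linear fit.

    Angles are degrees CCW from the +x (column) axis, defined modulo 180
    (a lobe pair has no head/tail) and unwrapped along z.
    """

    z_planes_nm: np.ndarray
    lobe_angle_deg: np.ndarray
    slope_deg_per_nm: float
    intercept_deg: float
    r_squared: float

    def angle_at(self, z_nm: float) -> float:
        return self.slope_deg_per_nm * z_nm + self.intercept_deg


def lobe_angle(slice_2d: np.ndarray, rel_threshold: float = 0.5) -> float:
    """Orientation (degrees, mod 180) of the axis through the two lobes.

    Lobes are the two strongest separated local maxima above
    ``rel_threshold`` of the slice peak; each is refined to an
    intensity-weighted centroid in a 9x9 window (smaller windows bias the
    angle of tightly spaced lobes).  Raises ``ValueError`` when two
    separated lobes cannot be found.
    """
    img = np.asarray(slice_2d, dtype=np.float64)
    smooth = ndimage.gaussian_filter(img, 1.0)
    peak = smooth.max()
    if peak <= 0:
        raise ValueError("empty slice")
    maxima = (ndimage.maximum_filter(smooth, size=3) == smooth) & (
        smooth > rel_threshold * peak
    )
    coords = np.argwhere(maxima)
    if len(coords) < 2:
        raise ValueError("fewer than two lobes above threshold")
    order = np.argsort(smooth[tuple(coords.T)])[::-1]
    coords = coords[order]
    first = coords[0]
    second = None
    for cand in coords[1:]:
        if np.hypot(*(cand - first)) >= 2.0:
            second = cand
            break
    if second is None:
        raise ValueError("lobes not separable")
    centroids = []
    for peak_rc in (first, second):
        r0, c0 = peak_rc
        r_lo, r_hi = max(r0 - 4, 0), min(r0 + 5, img.shape[0])
        c_lo, c_hi = max(c0 - 4, 0), min(c0 + 5, img.shape[1])
        win = img[r_lo:r_hi, c_lo:c_hi]
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        w = win.sum()
        centroids.append((np.sum(rr * win) / w, np.sum(cc * win) / w))
    (r1, c1), (r2, c2) = centroids
    ang = np.degrees(np.arctan2(r2 - r1, c2 - c1))
    return float(np.mod(ang, 180.0))


def fit_rotation_calibration(stack: PSFStack) -> RotationCalibration:
    """Fit lobe orientation vs z for a two-lobe (double-helix-type) stack.

    Slices where two lobes cannot be separated are excluded with a
    :class:`CalibrationWarning`.  Angles are unwrapped (period 180 deg)
    before the least-squares line fit.
    """
    if stack.n_planes < 3:
        raise ValueError("need at least 3 z planes for calibration")
    z_used, angles = [], []
    for k in range(stack.n_planes):
        try:
            angles.append(lobe_angle(stack.values[k]))
            z_used.append(stack.z_planes_nm[k])
        except ValueError as exc:
            warnings.warn(
                f"slice at z={stack.z_planes_nm[k]:.0f} nm excluded: {exc}",
                CalibrationWarning,
                stacklevel=2,
            )
    if len(z_used) < 3:
        raise ValueError("fewer than 3 usable slices for calibration")
    z_used = np.asarray(z_used)
    unwrapped = np.unwrap(np.asarray(angles), period=180.0)
    slope, intercept = np.polyfit(z_used, unwrapped, 1)
    fit = slope * z_used + intercept
    ss_res = np.sum((unwrapped - fit) ** 2)
    ss_tot = np.sum((unwrapped - unwrapped.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RotationCalibration(
        z_planes_nm=z_used,
        lobe_angle_deg=unwrapped,
        slope_deg_per_nm=float(slope),
        intercept_deg=float(intercept),
        r_squared=float(r2),
    )


# ---------------------------------------------------------------------------
# 4f magnification
# ---------------------------------------------------------------------------

def lateral_magnification(config: OpticalConfig) -> float:
    """Lateral magnification M_lat = C * n * f / r of the detection path.

    M_lat is inversely proportional to the ratio of beam radius to focal
    distance; the dimensionless prefactor C
    (``config.magnification_constant``) absorbs the objective/tube-lens
    factors and can be replaced by a calibrated value.
    """
    return (
        config.magnification_constant
        * config.medium_index
        * (config.relay_focal_length_mm * 1e6)
        / (config.pupil_radius_mm * 1e6)
    )


def axial_magnification(config: OpticalConfig) -> float:
    """Paraxial axial magnification M_ax = M_lat^2 / n."""
    m = lateral_magnification(config)
    return m * m / config.medium_index


def magnification_metadata(config: OpticalConfig) -> dict:
    """The formulas behind the magnification values, for substitution of a
    calibrated constant."""
    return {
        "lateral_formula": "M_lat = C * n * f / r",
        "axial_formula": "M_ax = M_lat**2 / n",
        "C": config.magnification_constant,
        "n": config.medium_index,
        "f_mm": config.relay_focal_length_mm,
        "r_mm": config.pupil_radius_mm,
        "lateral": lateral_magnification(config),
        "axial": axial_magnification(config),
    }
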