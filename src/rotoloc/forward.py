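"""Forward imaging model and synthetic frame generator.

A 3D emitter distribution convolved with the 3D PSF produces a 3D image
volume, but the camera records only the focal (z = 0) slice of that
volume.  An emitter displaced to +z therefore projects the PSF slice
computed at defocus -z onto the detector; that sign convention is fixed
here and used consistently by the solver and the refinement stage.

Sub-pixel lateral placement uses the Fourier shift theorem on the PSF
slice; sub-grid axial placement interpolates linearly between the two
bracketing stack slices.  All randomness (emitter sampling, shot noise,
read noise) is seeded for bit-reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .optics import PSFStack


@dataclass
class EmitterSet:
    """Continuous-coordinate point emitters.

    Coordinates are nm, origin at the field center (x = column axis,
    y = row axis, z = 0 at focus); ``photons`` are expected detected
    photons per emitter.
    """

    x_nm: np.ndarray
    y_nm: np.ndarray
    z_nm: np.ndarray
    photons: np.ndarray

    def __post_init__(self) -> None:
        self.x_nm = np.atleast_1d(np.asarray(self.x_nm, dtype=np.float64))
        self.y_nm = np.atleast_1d(np.asarray(self.y_nm, dtype=np.float64))
        self.z_nm = np.atleast_1d(np.asarray(self.z_nm, dtype=np.float64))
        self.photons = np.atleast_1d(np.asarray(self.photons, dtype=np.float64))
        n = len(self.x_nm)
        if not (len(self.y_nm) == len(self.z_nm) == len(self.photons) == n):
            raise ValueError("emitter coordinate arrays must share a length")
        if n and not np.all(np.isfinite(np.c_[self.x_nm, self.y_nm, self.z_nm])):
            raise ValueError("emitter positions must be finite")
        if n and np.any(self.photons <= 0):
            raise ValueError("photon counts must be > 0")

    def __len__(self) -> int:
        return len(self.x_nm)

    @classmethod
    def empty(cls) -> "EmitterSet":
        z = np.zeros(0)
        return cls(z, z, z, z)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: uniform Poisson background, Gaussian read noise, gain."""

    background: float = 10.0  # photons / pixel
    read_noise_sd: float = 1.0  # counts RMS
    gain: float = 1.0  # counts / photon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class Frame:
    """A single 2D measurement in camera counts."""

    pixels: np.ndarray
    pixel_size_nm: float
    noise: NoiseModel | None = None
    background_subtracted: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Frame pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


class SelectionVector:
    """One-hot selector of the observed (focal) plane of an image volume."""

    def __init__(self, length: int, index: int):
        if not 0 <= index < length:
            raise ValueError("selection index out of range")
        self.length = int(length)
        self.index = int(index)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SelectionVector":
        arr = np.asarray(arr)
        nz = np.flatnonzero(arr)
        if len(nz) != 1:
            raise ValueError("selection vector must be one-hot")
        return cls(len(arr), int(nz[0]))

    def as_array(self) -> np.ndarray:
        out = np.zeros(self.length)
        out[self.index] = 1.0
        return out


def apply_selection(volume: np.ndarray, selector: SelectionVector) -> np.ndarray:
    """Select the observed 2D slice of a (z, y, x) volume."""
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.shape[0] != selector.length:
        raise ValueError(
            f"volume z-extent {volume.shape[0] if volume.ndim == 3 else '?'} "
            f"does not match selector length {selector.length}"
        )
    return volume[selector.index]


def _place_slice(
    canvas: np.ndarray, tile: np.ndarray, row_f: float, col_f: float, weight: float
) -> None:
    """Accumulate ``weight * tile`` onto ``canvas`` centered at a continuous
    (row, col); fractional shifts via the Fourier shift theorem, integer
    shifts via array placement (clipped at the field edge)."""
    hc = tile.shape[0] // 2
    r_int, c_int = int(np.round(row_f)), int(np.round(col_f))
    dr, dc = row_f - r_int, col_f - c_int
    if abs(dr) > 1e-12 or abs(dc) > 1e-12:
        tile = np.fft.irfft2(
            ndimage.fourier_shift(np.fft.rfft2(tile), (dr, dc), n=tile.shape[1]),
            s=tile.shape,
        )
    r0, c0 = r_int - hc, c_int - hc
    r1, c1 = r0 + tile.shape[0], c0 + tile.shape[1]
    sr0, sc0 = max(0, -r0), max(0, -c0)
    sr1 = tile.shape[0] - max(0, r1 - canvas.shape[0])
    sc1 = tile.shape[1] - max(0, c1 - canvas.shape[1])
    if sr0 >= sr1 or sc0 >= sc1:
        return
    canvas[max(r0, 0) : min(r1, canvas.shape[0]), max(c0, 0) : min(c1, canvas.shape[1])] += (
        weight * tile[sr0:sr1, sc0:sc1]
    )


def render_frame(
    emitters: EmitterSet, stack: PSFStack, field_px: int
) -> np.ndarray:
    """Noiseless detector image of a set of emitters (counts = photons).

    Each emitter at (x, y, z) contributes ``photons`` times the stack slice
    at defocus -z, Fourier-shifted to its continuous lateral position.
    Raises ``ValueError`` (listing the offending emitters) when any z lies
    outside the stack range.
    """
    z_lo, z_hi = stack.z_planes_nm[0], stack.z_planes_nm[-1]
    bad = np.flatnonzero((-emitters.z_nm < z_lo) | (-emitters.z_nm > z_hi))
    if len(bad):
        raise ValueError(
            f"emitters outside axial range [{-z_hi:.0f}, {-z_lo:.0f}] nm: "
            f"indices {bad.tolist()}"
        )
    image = np.zeros((field_px, field_px))
    center = (field_px - 1) / 2.0
    px = stack.lateral_step_nm
    for i in range(len(emitters)):
        tile = stack.slice_at(-emitters.z_nm[i])
        row_f = center + emitters.y_nm[i] / px
        col_f = center + emitters.x_nm[i] / px
        _place_slice(image, tile, row_f, col_f, emitters.photons[i])
    return image


def add_noise(image: np.ndarray, model: NoiseModel, pixel_size_nm: float) -> Frame:
    """Apply the camera model: gain * Poisson(image + background) + read noise."""
    image = np.asarray(image, dtype=np.float64)
    # sub-pixel Fourier shifts of a cropped PSF leave tiny negative ringing;
    # anything beyond that is a caller error
    if image.size and image.min() < -1e-4 * max(image.max(), 1.0):
        raise ValueError("noiseless image must be nonnegative")
    rng = np.random.default_rng(model.seed)
    counts = model.gain * rng.poisson(np.clip(image, 0, None) + model.background)
    counts = counts.astype(np.float64)
    if model.read_noise_sd > 0:
        counts += rng.normal(0.0, model.read_noise_sd, size=image.shape)
    return Frame(
        pixels=counts,
        pixel_size_nm=pixel_size_nm,
        noise=model,
        provenance={"noise": asdict(model)},
    )


def sample_emitters(
    density_per_um2: float,
    field_px: int,
    pixel_size_nm: float,
    z_range_nm: float,
    photon_median: float = 3000.0,
    photon_sigma: float = 0.25,
    seed: int = 0,
    fixed_count: int | None = None,
    edge_margin_px: float = 3.0,
) -> EmitterSet:
    """Draw a random emitter field.

    The count is Poisson(density * area) unless ``fixed_count`` is given;
    lateral positions are uniform over the field (inset by
    ``edge_margin_px`` so PSFs stay mostly inside), z uniform over
    ``+-z_range_nm / 2``, and photons lognormal with the given median and
    log-sd.
    """
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    area_um2 = (field_px * pixel_size_nm * 1e-3) ** 2
    n = fixed_count if fixed_count is not None else rng.poisson(density_per_um2 * area_um2)
    if n == 0:
        return EmitterSet.empty()
    half = (field_px / 2.0 - edge_margin_px) * pixel_size_nm
    x = rng.uniform(-half, half, n)
    y = rng.uniform(-half, half, n)
    z = rng.uniform(-z_range_nm / 2.0, z_range_nm / 2.0, n)
    photons = np.exp(rng.normal(np.log(photon_median), photon_sigma, n))
    return EmitterSet(x, y, z, photons)


def simulate_frame(
    density_per_um2: float,
    stack: PSFStack,
    field_px: int = 64,
    noise: NoiseModel | None = None,
    z_range_nm: float | None = None,
    photon_median: float = 3000.0,
    seed: int = 0,
    fixed_count: int | None = None,
) -> tuple[Frame, EmitterSet]:
    """One seeded synthetic frame plus its ground truth.

    ``z_range_nm`` defaults to the central 80% of the stack's axial span so
    that emitters near the range edge remain refinable.
    """
    if z_range_nm is None:
        z_range_nm = 0.8 * (stack.z_planes_nm[-1] - stack.z_planes_nm[0])
    truth = sample_emitters(
        density_per_um2,
        field_px,
        stack.lateral_step_nm,
        z_range_nm,
        photon_median=photon_median,
        seed=seed,
        fixed_count=fixed_count,
    )
    clean = render_frame(truth, stack, field_px)
    model = noise if noise is not None else NoiseModel(seed=seed + 1)
    if noise is not None and noise.seed == 0:
        model = NoiseModel(noise.background, noise.read_noise_sd, noise.gain, seed + 1)
    frame = add_noise(clean, model, stack.lateral_step_nm)
    frame.provenance.update(
        {
            "density_per_um2": density_per_um2,
            "field_px": field_px,
            "z_range_nm": z_range_nm,
            "photon_median": photon_median,
            "seed": seed,
            "n_emitters": len(truth),
        }
    )
    return frame, truth
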