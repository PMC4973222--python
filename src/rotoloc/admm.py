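"""Sparse 3D deconvolution of a single focal-plane image by ADMM.

The recovery problem: find a nonnegative, sparse 3D voxel image ``x`` such
that the focal slice of the circular convolution ``A (x) x`` of the 3D PSF
with ``x`` matches the measured 2D frame ``y``.  We solve the penalized
program

    min_x  1/2 || S(A (x) x) - y ||^2  +  lambda ||x||_1,   x >= 0,

where ``S`` selects the observed z = 0 slice.  Splitting variables ``u0``
(for the observed slice) and ``u1`` (for ``x`` under the L1 term plus
nonnegativity) give the augmented Lagrangian with scaled duals ``eta0``,
``eta1`` and penalty weights ``mu`` (default 1) and ``nu`` (default 20);
each subproblem has a closed form, evaluated per iteration with 2D FFTs:

* x-update: per lateral frequency the normal equations are a rank-one
  correction of ``nu I`` solved by Sherman-Morrison;
* u0-update: ``u0 = (y + mu (s + eta0)) / (1 + mu)`` with ``s`` the
  observed slice of the current convolution;
* u1-update: nonnegative soft threshold at ``lambda / nu``;
* dual ascent on both constraints.

A fixed iteration budget (default 1000) is used; convolution is circular,
so the frame is reflect-padded by half the PSF lateral support and the
solution cropped back, suppressing wrap-around aliasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

from .forward import Frame, SelectionVector
from .optics import PSFStack


@dataclass(frozen=True)
class ADMMParams:
    """Penalty weights and iteration budget for the splitting scheme.

    ``mu = 1`` and ``nu = 20`` are retained from the splitting literature
    as a robust operating point; ``sparsity_weight`` (lambda) defaults to
    ``2 * sigma_bg * ||A_focus||_2`` estimated from the frame when None.
    ``noise_tolerance`` is the epsilon of the constrained formulation,
    kept as metadata only: the penalized form is what the updates solve.
    """

    mu: float = 1.0
    nu: float = 20.0
    sparsity_weight: float | None = None
    iterations: int = 1000
    noise_tolerance: float | None = None
    early_stop_tol: float | None = None
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.nu <= 0:
            raise ValueError("mu and nu must be > 0")
        if self.sparsity_weight is not None and self.sparsity_weight <= 0:
            raise ValueError("sparsity_weight must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class VoxelGrid:
    """Sparse nonnegative 3D solution on the recovery grid (z, y, x)."""

    values: np.ndarray
    lateral_step_nm: float
    axial_step_nm: float
    z_planes_nm: np.ndarray
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be 3D (z, y, x)")
        if np.any(self.values < 0):
            raise ValueError("VoxelGrid values must be nonnegative")

    def voxel_center_nm(self, k: int, i: int, j: int) -> tuple[float, float, float]:
        """Continuous (x, y, z) of voxel (z-index k, row i, col j).

        The voxel z index is the *emitter* plane: an emitter on plane k
        appears on the detector as the PSF slice at -z_planes_nm[k]."""
        nz, ny, nx = self.values.shape
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        return (
            (j - cx) * self.lateral_step_nm,
            (i - cy) * self.lateral_step_nm,
            float(self.z_planes_nm[k]),
        )


def soft_threshold(v: np.ndarray, t: float, nonneg: bool = True) -> np.ndarray:
    """Elementwise L1 proximal operator, optionally restricted to v >= 0.

    sign(v) * max(|v| - t, 0), then clipped at zero when ``nonneg`` (emitter
    intensities cannot be negative).
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(v)
    out = np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
    if nonneg:
        out = np.maximum(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# transfer function
# ---------------------------------------------------------------------------

def emitter_kernel(stack: PSFStack) -> np.ndarray:
    """Per-emitter-plane detector kernels: plane k maps to slice at -z_k.

    With a symmetric ascending z grid this is the stack reversed in z."""
    return stack.values[::-1]


def make_transfer(stack: PSFStack, shape: tuple[int, int]) -> np.ndarray:
    """rfft2 of the emitter kernels embedded (centered at the origin) in a
    (H, W) circular domain; shape (n_planes, H, W//2+1) complex64."""
    h, w = shape
    kern = emitter_kernel(stack)
    nz, kh, kw = kern.shape
    if kh > h or kw > w:
        raise ValueError("PSF support exceeds the padded frame")
    big = np.zeros((nz, h, w), dtype=np.float64)
    # center the (odd-sized) kernel on the ifftshift origin h//2
    r0, c0 = h // 2 - kh // 2, w // 2 - kw // 2
    big[:, r0 : r0 + kh, c0 : c0 + kw] = kern
    big = np.fft.ifftshift(big, axes=(1, 2))
    return spfft.rfft2(big, axes=(1, 2))


def forward_observed(x: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    """Observed (focal) slice of the circular convolution A (x) x."""
    x = np.asarray(x)
    tr = transfer.astype(np.complex64) if x.dtype == np.float32 else transfer
    xf = spfft.rfft2(x, axes=(1, 2))
    s = np.einsum("kij,kij->ij", tr, xf)
    return spfft.irfft2(s, s=x.shape[1:])


def selection_vector(stack: PSFStack) -> SelectionVector:
    """The one-hot selector of the focal plane of the image volume."""
    return SelectionVector(stack.n_planes, stack.focus_index)


def estimate_noise_sd(frame: Frame) -> float:
    """Background noise SD: from the noise model when known, else a robust
    MAD estimate of the pixel distribution."""
    if frame.noise is not None:
        m = frame.noise
        return math.sqrt(m.gain**2 * m.background + m.read_noise_sd**2)
    p = frame.pixels
    return float(1.4826 * np.median(np.abs(p - np.median(p)))) or float(np.std(p))


def auto_sparsity_weight(frame: Frame, stack: PSFStack) -> float:
    """Default lambda = 2 * sigma_bg * ||A_focus||_2."""
    focus_l2 = float(np.linalg.norm(stack.values[stack.focus_index]))
    return 2.0 * estimate_noise_sd(frame) * focus_l2


# ---------------------------------------------------------------------------
# subproblem updates
# ---------------------------------------------------------------------------

def x_update(
    b1: np.ndarray,
    beta: np.ndarray,
    transfer: np.ndarray,
    transfer_sq: np.ndarray,
    mu: float,
    nu: float,
) -> np.ndarray:
    """Exact minimizer of the x subproblem.

    Minimizes  mu/2 ||S(A (x) x) - beta||^2 + nu/2 ||x - b1||^2  where
    ``b1 = u1 - eta1`` and ``beta = u0 - eta0``.  Per lateral frequency the
    normal matrix is ``nu I + mu v v^H`` with ``v`` the transfer vector
    across planes; Sherman-Morrison gives the closed form.
    """
    b1 = np.asarray(b1)
    tr = transfer.astype(np.complex64) if b1.dtype == np.float32 else transfer
    b1f = spfft.rfft2(b1, axes=(1, 2))
    betaf = spfft.rfft2(np.asarray(beta, dtype=b1.dtype))
    rhs = nu * b1f + mu * betaf[None] * np.conj(tr)
    dot = np.einsum("kij,kij->ij", tr, rhs)
    corr = (mu / (nu + mu * transfer_sq)) * dot
    xf = (rhs - np.conj(tr) * corr[None]) / nu
    return spfft.irfft2(xf, s=b1.shape[1:], axes=(1, 2))


def u0_update(y: np.ndarray, s: np.ndarray, eta0: np.ndarray, mu: float) -> np.ndarray:
    """Closed-form data-fidelity subproblem: (y + mu (s + eta0)) / (1 + mu)."""
    if y.shape != s.shape:
        raise ValueError("frame / slice shape mismatch")
    return (y + mu * (s + eta0)) / (1.0 + mu)


def u1_update(x: np.ndarray, eta1: np.ndarray, nu: float, lam: float) -> np.ndarray:
    """Sparsity subproblem: nonnegative soft threshold of x + eta1 at lambda/nu."""
    return soft_threshold(x + eta1, lam / nu)


def dual_update(
    eta0: np.ndarray,
    eta1: np.ndarray,
    s: np.ndarray,
    u0: np.ndarray,
    x: np.ndarray,
    u1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dual ascent on both consensus constraints."""
    return eta0 + (s - u0), eta1 + (x - u1)


def objective_value(
    x: np.ndarray, y: np.ndarray, transfer: np.ndarray, lam: float
) -> float:
    """Penalized objective 1/2 ||S(A (x) x) - y||^2 + lambda ||x||_1."""
    resid = forward_observed(x, transfer) - y
    return 0.5 * float(np.sum(resid**2)) + lam * float(np.sum(np.abs(x)))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def admm_deconvolve(
    frame: Frame,
    stack: PSFStack,
    params: ADMMParams | None = None,
) -> VoxelGrid:
    """Deconvolve one background-subtracted frame into a sparse voxel grid.

    The frame is reflect-padded by half the PSF lateral support (then up to
    an FFT-friendly size); updates run x -> u0 -> u1 -> duals from
    ``x = u1 = 0, u0 = y``, duals zero; the returned grid is the sparse
    nonnegative split variable ``u1`` cropped back to the field.
    """
    params = params or ADMMParams()
    if not np.all(np.isfinite(frame.pixels)):
        raise ValueError("frame contains non-finite pixels")
    if abs(frame.pixel_size_nm - stack.lateral_step_nm) > 1e-6:
        raise ValueError(
            f"frame pixel size {frame.pixel_size_nm} nm does not match the "
            f"stack lateral step {stack.lateral_step_nm} nm"
        )
    lam = params.sparsity_weight
    if lam is None:
        lam = auto_sparsity_weight(frame, stack)

    fh, fw = frame.shape
    pad = stack.values.shape[1] // 2
    ph = spfft.next_fast_len(fh + 2 * pad, real=True)
    pw = spfft.next_fast_len(fw + 2 * pad, real=True)
    pr0, pc0 = (ph - fh) // 2, (pw - fw) // 2
    y = np.pad(
        frame.pixels,
        ((pr0, ph - fh - pr0), (pc0, pw - fw - pc0)),
        mode="reflect",
    ).astype(np.float64)

    transfer = make_transfer(stack, (ph, pw))
    transfer_sq = np.einsum("kij,kij->ij", transfer, np.conj(transfer)).real
    nz = stack.n_planes

    # single-precision hot loop; the x-spectrum is reused for the observed
    # slice so each iteration costs one batched rfft2 + one batched irfft2
    mu, nu = np.float32(params.mu), np.float32(params.nu)
    transfer = transfer.astype(np.complex64)
    conj_tr = np.conj(transfer)
    gain = (params.mu / (params.nu + params.mu * transfer_sq)).astype(np.float32)
    y32 = y.astype(np.float32)
    x = np.zeros((nz, ph, pw), dtype=np.float32)
    u1 = np.zeros_like(x)
    eta1 = np.zeros_like(x)
    u0 = y32.copy()
    eta0 = np.zeros_like(y32)
    thresh = np.float32(lam / params.nu)

    scale = float(np.linalg.norm(y32)) + 1e-12
    objective_log: list[tuple[int, float]] = []
    stopped_at = params.iterations
    for k in range(params.iterations):
        # x-update (Sherman-Morrison per lateral frequency)
        rhs = spfft.rfft2(u1 - eta1, axes=(1, 2))
        rhs *= nu
        betaf = spfft.rfft2(u0 - eta0)
        rhs += (mu * betaf)[None] * conj_tr
        corr = gain * np.einsum("kij,kij->ij", transfer, rhs)
        rhs -= conj_tr * corr[None]
        rhs *= np.float32(1.0 / params.nu)
        x = spfft.irfft2(rhs, s=(ph, pw), axes=(1, 2))
        # observed slice of A (x) x, from the spectrum already in hand
        sf = np.einsum("kij,kij->ij", transfer, rhs)
        s = spfft.irfft2(sf, s=(ph, pw))
        u0 = (y32 + mu * (s + eta0)) / (np.float32(1.0) + mu)
        u1 = np.maximum(x + eta1 - thresh, np.float32(0.0))
        eta0 += s - u0
        eta1 += x - u1
        if params.log_every and (k + 1) % params.log_every == 0:
            objective_log.append(
                (k + 1, objective_value(u1.astype(np.float64), y, transfer, lam))
            )
        if params.early_stop_tol is not None:
            r0 = float(np.linalg.norm(s - u0))
            r1 = float(np.linalg.norm(x - u1))
            if max(r0, r1) < params.early_stop_tol * scale:
                stopped_at = k + 1
                break

    sol = u1[:, pr0 : pr0 + fh, pc0 : pc0 + fw]
    return VoxelGrid(
        values=np.maximum(sol, 0.0),
        lateral_step_nm=stack.lateral_step_nm,
        axial_step_nm=stack.axial_step_nm,
        z_planes_nm=stack.z_planes_nm.copy(),
        log={
            "objective": objective_log,
            "iterations_run": stopped_at,
            "sparsity_weight": lam,
            "mu": params.mu,
            "nu": params.nu,
            "noise_tolerance": params.noise_tolerance,
            "pad": (pr0, pc0),
            "padded_shape": (ph, pw),
        },
    )
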