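"""Helmholtz-family EPT reconstructions used to exercise the evaluator.

These are the standard local reconstructions: the full complex Helmholtz
inversion lap(B)/B = -omega^2*mu0*eps_c, and its decoupled phase-only
(lap(phi) = omega*mu0*sigma) and magnitude-only
(lap(|B|)/|B| = -omega^2*mu0*eps0*eps_r) approximations.  Derivatives use
the symmetric 3-point second-difference kernel [1, -2, 1]/h^2 per axis;
denoising uses a spherical mean filter (default diameter 11 voxels).

Invalid-voxel bookkeeping: a voxel is valid only where the full stencil
(or filter kernel, renormalized) stays inside Omega; invalid voxels are
marked NaN and excluded from downstream statistics.  Input phases must be
unwrapped within Omega (synthetic phases are generated unwrapped; measured
phases are assumed pre-unwrapped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from b1eval.domain import ComplexField, DomainMask, VoxelGrid
from b1eval.fd_system import EPMap


@dataclass
class ReconConfig:
    """Reconstruction settings.

    denoise_diameter is the spherical mean filter diameter in voxels
    (odd, >= 1; 1 disables filtering); boundary_erosion drops that many
    extra voxel layers adjacent to the domain boundary before statistics.
    """

    method: str = "helmholtz_complex"
    denoise_diameter: int = 11
    boundary_erosion: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("helmholtz_complex", "phase_only", "magnitude_only"):
            raise ValueError(f"unknown reconstruction method {self.method!r}")
        if self.denoise_diameter < 1 or self.denoise_diameter % 2 == 0:
            raise ValueError("denoise_diameter must be odd and >= 1")
        if self.boundary_erosion < 0:
            raise ValueError("boundary_erosion must be >= 0")


def _valid_stencil(mask: DomainMask, erosion: int = 0) -> np.ndarray:
    """Voxels whose full 7-point stencil lies inside Omega, optionally eroded."""
    valid = mask.interior
    if erosion > 0:
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        valid = ndimage.binary_erosion(valid, structure=structure, iterations=erosion)
    return valid


def laplacian_3pt(
    volume: np.ndarray, mask: DomainMask, grid: VoxelGrid
) -> np.ndarray:
    """7-point discrete Laplacian, NaN where the stencil leaves Omega.

    Sum over axes of the 3-point second difference [1, -2, 1]/h^2; exact
    on quadratics, and on sampled exponentials exp(-i k z) it returns the
    stencil eigenvalue 2(cos(kh) - 1)/h^2 times the field.
    """
    volume = np.asarray(volume)
    grid.check_volume(volume)
    out_dtype = np.complex128 if np.iscomplexobj(volume) else np.float64
    work = np.where(mask.inside, volume, 0).astype(out_dtype)
    lap = np.full(volume.shape, np.nan, dtype=out_dtype)
    h2 = grid.spacing_h**2
    acc = -6.0 * work
    for axis in range(3):
        acc += np.roll(work, +1, axis=axis) + np.roll(work, -1, axis=axis)
    valid = _valid_stencil(mask)
    lap[valid] = acc[valid] / h2
    return lap


def spherical_mean_filter(
    volume: np.ndarray, mask: DomainMask, diameter: int = 11
) -> np.ndarray:
    """Mean over a spherical kernel of the given diameter, renormalized.

    The kernel contains all integer offsets with Euclidean norm
    <= (diameter - 1)/2.  At each valid voxel the mean is taken over the
    intersection of the kernel with valid voxels (finite values inside
    Omega), i.e. partial kernels renormalize rather than zero-pad, so a
    constant region is mapped to itself everywhere.
    """
    if diameter % 2 == 0 or diameter < 1:
        raise ValueError("diameter must be odd and >= 1")
    volume = np.asarray(volume)
    if diameter == 1:
        return volume.copy()
    radius = (diameter - 1) // 2
    r = np.arange(-radius, radius + 1)
    xx, yy, zz = np.meshgrid(r, r, r, indexing="ij")
    kernel = (xx**2 + yy**2 + zz**2 <= radius**2).astype(np.float64)

    out_dtype = np.complex128 if np.iscomplexobj(volume) else np.float64
    valid = mask.inside & np.isfinite(volume)
    filled = np.where(valid, volume, 0).astype(out_dtype)
    weights = valid.astype(np.float64)

    def conv(a: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(a):
            return conv(a.real) + 1j * conv(a.imag)
        return ndimage.convolve(a, kernel, mode="constant", cval=0.0)

    num = conv(filled)
    den = ndimage.convolve(weights, kernel, mode="constant", cval=0.0)
    out = np.full(volume.shape, np.nan, dtype=out_dtype)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[valid] = num[valid] / den[valid]
    return out


def _denoise(volume: np.ndarray, mask: DomainMask, cfg: ReconConfig) -> np.ndarray:
    if cfg.denoise_diameter <= 1:
        return volume
    return spherical_mean_filter(volume, mask, cfg.denoise_diameter)


def helmholtz_ept(
    field: ComplexField,
    mask: DomainMask,
    grid: VoxelGrid,
    cfg: ReconConfig | None = None,
) -> EPMap:
    """Complex Helmholtz inversion eps_c = -lap(B)/(omega^2 mu0 B).

    Conductivity is -omega * Im(eps_c_est) and relative permittivity
    Re(eps_c_est)/eps0; both are denoised per the config.  Voxels with
    |B| below 1e-12 are invalid.  Scaling B by any complex constant
    leaves the estimate unchanged.
    """
    cfg = cfg or ReconConfig(method="helmholtz_complex")
    lap = laplacian_3pt(field.values, mask, grid)
    b = field.values
    valid = np.isfinite(lap.real) & (np.abs(b) > 1e-12)
    eps_c_est = np.full(b.shape, np.nan, dtype=np.complex128)
    eps_c_est[valid] = -lap[valid] / (grid.omega**2 * grid.mu0 * b[valid])
    if valid.any() and np.nanmax(np.abs(eps_c_est[valid])) < 1e-3 * grid.eps0:
        warnings.warn(
            "Helmholtz estimate is ~0 (field has vanishing Laplacian); "
            "the resulting EPs are nonphysical",
            stacklevel=2,
        )
    sigma = np.where(valid, -grid.omega * eps_c_est.imag, np.nan)
    eps_r = np.where(valid, eps_c_est.real / grid.eps0, np.nan)
    sigma = _denoise(sigma, _masked(mask, valid), cfg)
    eps_r = _denoise(eps_r, _masked(mask, valid), cfg)
    return EPMap(sigma=sigma, eps_r=eps_r)


def phase_only_ept(
    phase: np.ndarray,
    mask: DomainMask,
    grid: VoxelGrid,
    cfg: ReconConfig | None = None,
) -> np.ndarray:
    """Phase-only conductivity: sigma = lap(phi) / (omega * mu0).

    The phase must be unwrapped within Omega.  Exact (to machine
    precision) on quadratic phases, and blind to linear phase ramps.
    """
    cfg = cfg or ReconConfig(method="phase_only")
    lap = laplacian_3pt(np.asarray(phase, dtype=np.float64), mask, grid)
    sigma = lap / (grid.omega * grid.mu0)
    return _denoise(sigma, mask, cfg)


def magnitude_only_ept(
    magnitude: np.ndarray,
    mask: DomainMask,
    grid: VoxelGrid,
    cfg: ReconConfig | None = None,
) -> np.ndarray:
    """Magnitude-only permittivity: eps_r = -lap(|B|)/(|B| omega^2 mu0 eps0)."""
    cfg = cfg or ReconConfig(method="magnitude_only")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    lap = laplacian_3pt(magnitude, mask, grid)
    valid = np.isfinite(lap) & (magnitude > 0)
    eps_r = np.full(magnitude.shape, np.nan)
    eps_r[valid] = -lap[valid] / (
        magnitude[valid] * grid.omega**2 * grid.mu0 * grid.eps0
    )
    return _denoise(eps_r, _masked(mask, valid), cfg)


def _masked(mask: DomainMask, valid: np.ndarray) -> DomainMask:
    """A DomainMask whose inside is restricted to ``valid`` (for filtering)."""
    return DomainMask(inside=mask.inside & valid, boundary=None, interior=None)
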