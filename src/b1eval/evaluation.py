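"""Turn predicted vs measured B1+ fields into confidence maps.

The headline outputs are:

* difference maps ``D_phi = wrap(angle(B_hat) - phi_measured)`` [rad] and
  ``D_B = |B_hat| - |B_measured|`` (both fields magnitude-normalized);
* surrogate EP-error maps ``L_phi = lap(S(D_phi)) / (omega mu0)`` [S/m]
  and ``L_B = lap(S(D_B)) / (omega^2 mu0 eps0)`` [dimensionless], where S
  is truncated Gaussian smoothing (default std 4 voxels in an 11-voxel
  kernel) that suppresses noise before the second derivative;
* the global conductivity-offset indicator ``L_phi_offset`` = median of
  L_phi over valid voxels, and mean-absolute-error summaries of D.

L maps localize where the input EPs disagree with the field physics; the
display mask thresholds |L| (the conventional cutoffs are 0.1 and
0.2 S/m) to hide noise-level values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from b1eval.domain import (
    ComplexField,
    DomainMask,
    VoxelGrid,
    normalize_magnitude,
    wrap_phase_difference,
)
from b1eval.recon import laplacian_3pt


@dataclass
class SmoothingSpec:
    """Truncated Gaussian smoothing: std and kernel size in voxels."""

    std: float = 4.0
    kernel_size: int = 11

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("smoothing std must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")

    def kernel(self) -> np.ndarray:
        radius = (self.kernel_size - 1) // 2
        r = np.arange(-radius, radius + 1, dtype=np.float64)
        g1 = np.exp(-0.5 * (r / self.std) ** 2)
        k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        return k / k.sum()


@dataclass
class EvaluationResult:
    """Volumes and scalars summarizing one predicted-vs-measured comparison."""

    D_phi: np.ndarray
    D_B: np.ndarray
    L_phi: np.ndarray
    L_B: np.ndarray
    L_phi_offset: float
    mae_phi: float
    mae_B: float
    display_mask_threshold: float = 0.1
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Flat key-value report for serialization."""
        out = {
            "mae_phi": self.mae_phi,
            "mae_B": self.mae_B,
            "L_phi_offset": self.L_phi_offset,
            "display_mask_threshold": self.display_mask_threshold,
        }
        out.update(self.extras)
        return out


def difference_maps(
    predicted: ComplexField,
    measured: ComplexField,
    mask: DomainMask,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """D_phi and D_B between a predicted and a measured field.

    Both fields are magnitude-normalized over Omega first (so D_B is
    insensitive to a global real scale).  Outside Omega the maps are NaN.
    """
    if predicted.values.shape != measured.values.shape:
        raise ValueError("predicted and measured fields live on different grids")
    if normalize:
        predicted = normalize_magnitude(predicted, mask)
        measured = normalize_magnitude(measured, mask)
    d_phi = wrap_phase_difference(predicted.phase, measured.phase)
    d_b = predicted.magnitude - measured.magnitude
    d_phi = np.where(mask.inside, d_phi, np.nan)
    d_b = np.where(mask.inside, d_b, np.nan)
    return d_phi, d_b


def _smooth_renormalized(
    volume: np.ndarray, mask: DomainMask, spec: SmoothingSpec
) -> np.ndarray:
    """Gaussian smoothing over valid voxels with kernel renormalization.

    Near mask edges the kernel is renormalized over the valid support
    (never zero-padded), so a constant map is reproduced exactly — which
    keeps the null test (D = const -> L = 0) intact at boundaries.
    """
    kernel = spec.kernel()
    valid = mask.inside & np.isfinite(volume)
    filled = np.where(valid, volume, 0.0).astype(np.float64)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(np.float64), kernel, mode="constant", cval=0.0)
    out = np.full(volume.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[valid] = num[valid] / den[valid]
    return out


def surrogate_error_maps(
    d_phi: np.ndarray,
    d_b: np.ndarray,
    mask: DomainMask,
    grid: VoxelGrid,
    smoothing: SmoothingSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """L_phi [S/m] and L_B from the difference maps.

    Each D map is Gaussian-smoothed (renormalized within valid voxels),
    then the 7-point Laplacian is applied and scaled by the phase-only /
    magnitude-only EPT constants.  Voxels whose Laplacian stencil leaves
    Omega are NaN.
    """
    smoothing = smoothing or SmoothingSpec()
    s_phi = _smooth_renormalized(d_phi, mask, smoothing)
    s_b = _smooth_renormalized(d_b, mask, smoothing)
    l_phi = laplacian_3pt(s_phi, mask, grid) / (grid.omega * grid.mu0)
    l_b = laplacian_3pt(s_b, mask, grid) / (grid.omega**2 * grid.mu0 * grid.eps0)
    return l_phi, l_b


def global_offset(l_phi: np.ndarray, mask: DomainMask) -> float:
    """Median of L_phi over valid voxels — the global offset indicator.

    The sign tracks the sign of a global conductivity offset in the input
    EPs.  Even-count medians use the midpoint convention (numpy default).
    """
    vals = l_phi[mask.inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid voxels for global offset")
    return float(np.median(vals))


def mae(
    difference_volume: np.ndarray,
    mask: DomainMask,
    region: np.ndarray | None = None,
) -> float:
    """Mean absolute error of a difference map over valid voxels.

    ``region`` optionally restricts to a sub-mask of Omega; default is the
    full valid Omega.
    """
    sel = mask.inside if region is None else (mask.inside & region)
    vals = difference_volume[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty region for MAE")
    return float(np.mean(np.abs(vals)))


def display_mask(l_volume: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask: True where |L| exceeds the display threshold."""
    with np.errstate(invalid="ignore"):
        return np.abs(np.nan_to_num(l_volume, nan=0.0)) > threshold


def roughness(values: np.ndarray, mask: DomainMask) -> float:
    """Median absolute deviation of each interior voxel from its 6-neighbor mean.

    Measures voxel-to-voxel graininess: smooth (even strongly curved)
    fields score near zero because the neighbor average tracks the local
    trend, while uncorrelated voxel noise survives.  Used to verify that
    predicted fields stay smooth when the measured (noisy) field only
    enters through the boundary condition.
    """
    values = np.asarray(values)
    work = np.where(mask.inside, values, 0)
    acc = np.zeros_like(work)
    for axis in range(3):
        acc = acc + np.roll(work, +1, axis=axis) + np.roll(work, -1, axis=axis)
    dev = np.abs(values - acc / 6.0)[mask.interior]
    dev = dev[np.isfinite(dev)]
    if dev.size == 0:
        raise ValueError("no interior voxels for roughness")
    return float(np.median(dev))


def evaluate(
    predicted: ComplexField,
    measured: ComplexField,
    mask: DomainMask,
    grid: VoxelGrid,
    smoothing: SmoothingSpec | None = None,
    display_threshold: float = 0.1,
    extras: dict | None = None,
) -> EvaluationResult:
    """Full evaluation: D maps, L maps, offset statistic and MAEs."""
    d_phi, d_b = difference_maps(predicted, measured, mask)
    l_phi, l_b = surrogate_error_maps(d_phi, d_b, mask, grid, smoothing)
    return EvaluationResult(
        D_phi=d_phi,
        D_B=d_b,
        L_phi=l_phi,
        L_B=l_b,
        L_phi_offset=global_offset(l_phi, mask),
        mae_phi=mae(d_phi, mask),
        mae_B=mae(d_b, mask),
        display_mask_threshold=display_threshold,
        extras=extras or {},
    )
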