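"""Core geometric and physical types shared by all modules.

Conventions fixed here and relied on everywhere else:

* voxel indices are 0-based; array axes (0, 1, 2) are the physical
  (x, y, z) axes; physical position = index * spacing_h;
* the domain Omega is a boolean volume; its boundary layer is the set of
  Omega voxels with at least one 6-connected (face) neighbor outside
  Omega or on the volume edge — matching the 6-neighbor finite-difference
  stencil, which must never read outside Omega;
* field magnitudes are normalized to a maximum of 1 over Omega;
* phases are principal values in (-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

MU0 = 4.0e-7 * math.pi
"""Vacuum permeability [H/m]."""

EPS0 = 8.8541878128e-12
"""Vacuum permittivity [F/m]."""

FieldRole = Literal[
    "b1_plus_measured", "b1_plus_predicted", "bz", "synthetic_reference"
]


class DegenerateDomainError(ValueError):
    """Raised when a mask has no interior voxel after boundary extraction."""


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid with its physical context.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry must be >= 3 so that
        central differences have two neighbors per axis.
    spacing_h
        Isotropic voxel edge length [m].
    frequency
        Larmor frequency f [Hz]; the angular frequency omega = 2*pi*f is
        exposed as a property.  Default 128 MHz (3 T).
    """

    shape: tuple[int, int, int]
    spacing_h: float
    frequency: float = 128e6

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 3 for n in shape):
            raise ValueError(
                f"grid shape must be a triple with all entries >= 3, got {self.shape}"
            )
        object.__setattr__(self, "shape", shape)
        if not self.spacing_h > 0:
            raise ValueError(f"spacing_h must be positive, got {self.spacing_h}")
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")

    @property
    def omega(self) -> float:
        """Angular Larmor frequency [rad/s]."""
        return 2.0 * math.pi * self.frequency

    @property
    def mu0(self) -> float:
        return MU0

    @property
    def eps0(self) -> float:
        return EPS0

    def check_volume(self, volume: np.ndarray) -> None:
        """Raise if ``volume`` does not live on this grid."""
        if tuple(volume.shape) != self.shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match grid shape {self.shape}"
            )


def _shift(volume: np.ndarray, axis: int, step: int, fill) -> np.ndarray:
    """Shift a volume by one voxel along an axis, filling the exposed face."""
    out = np.full_like(volume, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = volume[tuple(src)]
    return out


@dataclass(frozen=True)
class DomainMask:
    """Partition of the domain Omega into its boundary layer and interior.

    ``boundary`` is the outer voxel layer of Omega: voxels with at least
    one face neighbor outside Omega (volume edges count as outside).
    ``interior`` is the rest; every interior voxel has all six face
    neighbors inside Omega, so the FD stencil never leaves the domain.
    """

    inside: np.ndarray
    boundary: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    interior: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_voxels(self) -> int:
        """Number of voxels N in Omega."""
        return int(self.inside.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.inside.shape


def build_mask(inside: np.ndarray) -> DomainMask:
    """Partition a boolean domain into boundary layer and interior.

    A voxel of Omega belongs to the boundary layer if any of its six face
    neighbors is outside Omega or off the volume edge; otherwise it is
    interior.

    Raises
    ------
    DegenerateDomainError
        If no interior voxel remains (e.g. an isolated voxel or a sheet
        thinner than three voxels).
    """
    inside = np.asarray(inside, dtype=bool)
    if inside.ndim != 3:
        raise ValueError("mask must be a 3-D boolean volume")
    has_all_neighbors = inside.copy()
    for axis in range(3):
        for step in (-1, +1):
            has_all_neighbors &= _shift(inside, axis, step, False)
    interior = has_all_neighbors
    boundary = inside & ~interior
    if not interior.any():
        raise DegenerateDomainError(
            "degenerate domain: no interior voxel remains after boundary extraction"
        )
    return DomainMask(inside=inside, boundary=boundary, interior=interior)


@dataclass
class ComplexField:
    """A complex-valued volume with a role tag.

    The magnitude/phase views decompose values = |B| * exp(i*phi) with the
    phase as principal value in (-pi, pi].
    """

    values: np.ndarray
    role: FieldRole = "b1_plus_measured"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @classmethod
    def from_polar(
        cls, magnitude: np.ndarray, phase: np.ndarray, role: FieldRole = "b1_plus_measured"
    ) -> "ComplexField":
        return cls(values=magnitude * np.exp(1j * np.asarray(phase)), role=role)

    def check_finite(self, mask: DomainMask) -> None:
        if not np.all(np.isfinite(self.values[mask.inside])):
            raise ValueError("field contains non-finite values on Omega")


@dataclass
class PhasePair:
    """Transmit, receive, and transceive phase volumes [rad].

    The transceive phase is the wrapped sum of transmit and receive
    phases; in measurement only the transceive phase is accessible, and
    downstream the transmit phase is approximated by half of it.
    """

    transmit: np.ndarray
    receive: np.ndarray | None = None
    transceive: np.ndarray | None = None


def normalize_magnitude(field_: ComplexField, mask: DomainMask) -> ComplexField:
    """Scale a field so its maximum magnitude over Omega is 1.

    The scale factor is a positive real, so phases are untouched.
    Normalization is computed over Omega only; background voxels are
    ignored.  Idempotent.
    """
    peak = float(np.max(np.abs(field_.values[mask.inside])))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero field over Omega")
    if peak == 1.0:
        return field_
    return ComplexField(values=field_.values / peak, role=field_.role)


def wrap_phase_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal value of (a - b) in (-pi, pi], free of 2*pi jumps.

    Computed as the angle of exp(i*(a - b)).  Antisymmetric except exactly
    at +/-pi, where the principal value convention returns +pi for both
    orderings.
    """
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))
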