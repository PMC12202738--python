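"""Discrete linear system of the B1+ recurrence.

From a map of electrical properties this module derives the complex
permittivity eps_c = eps0*eps_r - i*sigma/omega, its log-gradient
g = grad(ln eps_c), and the sparse finite-difference operators A and A_z
with the diagonal denominator 6 - omega^2*mu0*eps_c*h^2.

Discretizing the vector wave equation for the transmit field,

    -lap(B) = w^2 mu0 eps_c B - (gx + i gy)(dB/dx - i dB/dy) - gz dB/dz
              - (gx + i gy)(1/2) dZ/dz + gz (1/2)(dZ/dx + i dZ/dy),

with the 7-point Laplacian and central first differences, and solving for
the center voxel, gives for each interior voxel

    (6 - w^2 mu0 eps_c h^2) B = sum_nb w_nb B_nb + (A_z Z)_row,

with neighbor weights

    x+/-: 1 -/+ (h/2)(gx + i gy)
    y+/-: 1 +/- i (h/2)(gx + i gy)
    z+/-: 1 -/+ (h/2) gz

and B_z coupling

    (A_z Z)_row = -(h/4)(gx + i gy)(Z_z+ - Z_z-)
                  + (h/4) gz [(Z_x+ - Z_x-) + i (Z_y+ - Z_y-)].

With g = 0 every interior row of A reduces to six unit weights (the plain
neighbor average over the denominator) and A_z vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from b1eval.domain import DomainMask, VoxelGrid


@dataclass
class EPMap:
    """Conductivity sigma [S/m] and relative permittivity eps_r volumes."""

    sigma: np.ndarray
    eps_r: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.eps_r = np.asarray(self.eps_r, dtype=np.float64)
        if self.sigma.shape != self.eps_r.shape:
            raise ValueError("sigma and eps_r must share a shape")

    def validate(self, mask: DomainMask) -> None:
        s = self.sigma[mask.inside]
        e = self.eps_r[mask.inside]
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
            raise ValueError("EP map contains non-finite values on Omega")
        if np.any(s < 0):
            raise ValueError("conductivity must be non-negative on Omega")
        if np.any(e < 1):
            raise ValueError("relative permittivity must be >= 1 on Omega")

    def copy(self) -> "EPMap":
        return EPMap(sigma=self.sigma.copy(), eps_r=self.eps_r.copy())


@dataclass
class ComplexPermittivityField:
    """Complex permittivity eps_c = eps0*eps_r - i*sigma/omega [F/m]."""

    eps_c: np.ndarray


@dataclass
class GradLogEps:
    """Components of g = grad(ln eps_c) [1/m], zero for homogeneous media."""

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray


@dataclass
class FDSystem:
    """Sparse operators of the recurrence over the N voxels of Omega.

    ``A`` holds the off-diagonal neighbor weights (zero diagonal; interior
    rows have exactly 6 nonzeros, boundary rows are empty because boundary
    voxels are Dirichlet-pinned).  ``A_z`` carries the optional B_z
    coupling.  ``denom`` is the per-voxel complex denominator
    6 - omega^2*mu0*eps_c*h^2.  ``index_map`` maps each Omega voxel (in
    C-order scan of the volume) to its row; ``flat_index`` holds the flat
    volume index of each row.
    """

    A: sp.csr_matrix
    A_z: sp.csr_matrix | None
    denom: np.ndarray
    flat_index: np.ndarray
    interior_rows: np.ndarray
    boundary_rows: np.ndarray

    @property
    def n(self) -> int:
        return self.denom.shape[0]


def complex_permittivity(ep: EPMap, grid: VoxelGrid) -> ComplexPermittivityField:
    """eps_c = eps0*eps_r - i*sigma/omega, voxelwise.

    The time-harmonic sign convention places losses in the negative
    imaginary part.
    """
    if np.any(ep.eps_r <= 0):
        raise ValueError("relative permittivity must be positive")
    eps_c = grid.eps0 * ep.eps_r - 1j * ep.sigma / grid.omega
    return ComplexPermittivityField(eps_c=eps_c.astype(np.complex128))


def _neighbor_value(volume: np.ndarray, inside: np.ndarray, axis: int, step: int):
    """Neighbor values along an axis with copy-edge replication outside Omega.

    Where the stencil neighbor falls outside Omega (or off the volume), the
    center value is used instead, realizing the homogeneous Neumann
    condition grad(eps_c) = 0 without EP knowledge beyond the boundary.
    """
    shifted = np.empty_like(volume)
    shifted_in = np.zeros_like(inside)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
        edge_dst = [slice(None)] * 3
        edge_dst[axis] = slice(-1, None)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
        edge_dst = [slice(None)] * 3
        edge_dst[axis] = slice(0, 1)
    shifted[tuple(dst)] = volume[tuple(src)]
    shifted[tuple(edge_dst)] = volume[tuple(edge_dst)]
    shifted_in[tuple(dst)] = inside[tuple(src)]
    return np.where(shifted_in, shifted, volume), shifted_in


def grad_log_eps(
    eps_c: ComplexPermittivityField, mask: DomainMask, grid: VoxelGrid
) -> GradLogEps:
    """Central difference of ln(eps_c) per axis, with copy-edge Neumann.

    The principal branch of the complex log is safe: Re eps_c > 0 and
    Im eps_c <= 0 keep arg(eps_c) in (-pi/2, 0], so no branch crossing
    occurs between neighboring voxels.  Where a stencil neighbor lies
    outside Omega its value is replicated from the center voxel, yielding
    a one-sided (or zero) contribution.
    """
    ec = eps_c.eps_c
    if np.any(ec[mask.inside] == 0):
        raise ValueError("eps_c must be nonzero on Omega")
    log_ec = np.log(np.where(mask.inside, ec, 1.0))
    two_h = 2.0 * grid.spacing_h
    comps = []
    for axis in range(3):
        plus, _ = _neighbor_value(log_ec, mask.inside, axis, +1)
        minus, _ = _neighbor_value(log_ec, mask.inside, axis, -1)
        g = (plus - minus) / two_h
        g[~mask.inside] = 0.0
        comps.append(g)
    return GradLogEps(gx=comps[0], gy=comps[1], gz=comps[2])


def assemble_system(
    eps_c: ComplexPermittivityField,
    g: GradLogEps,
    mask: DomainMask,
    grid: VoxelGrid,
    with_bz: bool = False,
) -> FDSystem:
    """Assemble the sparse operators A (and A_z) and the denominator.

    Rows/columns are Omega voxels in C-order scan; interior rows carry the
    six neighbor weights listed in the module docstring, boundary rows are
    left empty (their values are pinned to the Dirichlet data at solve
    time).
    """
    inside = mask.inside
    shape = inside.shape
    grid.check_volume(inside)

    flat_index = np.flatnonzero(inside.ravel())
    n = flat_index.size
    row_of = np.full(inside.size, -1, dtype=np.int64)
    row_of[flat_index] = np.arange(n)

    interior_rows = row_of[np.flatnonzero(mask.interior.ravel())]
    boundary_rows = row_of[np.flatnonzero(mask.boundary.ravel())]

    h = grid.spacing_h
    om2mu0 = grid.omega**2 * grid.mu0
    denom = 6.0 - om2mu0 * eps_c.eps_c.ravel()[flat_index] * h * h

    # Flat-index strides for the six face neighbors in C order.
    sx, sy, sz = shape[1] * shape[2], shape[2], 1
    int_flat = np.flatnonzero(mask.interior.ravel())
    rows = row_of[int_flat]

    gx = g.gx.ravel()[int_flat]
    gy = g.gy.ravel()[int_flat]
    gz = g.gz.ravel()[int_flat]
    gxy = gx + 1j * gy
    half_h = 0.5 * h

    # neighbor offsets and the corresponding stencil weights
    neighbor_weights = [
        (+sx, 1.0 - half_h * gxy),   # x+
        (-sx, 1.0 + half_h * gxy),   # x-
        (+sy, 1.0 + 1j * half_h * gxy),  # y+
        (-sy, 1.0 - 1j * half_h * gxy),  # y-
        (+sz, 1.0 - half_h * gz),    # z+
        (-sz, 1.0 + half_h * gz),    # z-
    ]
    r_list, c_list, v_list = [], [], []
    for offset, w in neighbor_weights:
        cols = row_of[int_flat + offset]
        if np.any(cols < 0):
            raise AssertionError("interior stencil escaped Omega; mask is inconsistent")
        r_list.append(rows)
        c_list.append(cols)
        v_list.append(np.broadcast_to(w, rows.shape))
    A = sp.csr_matrix(
        (np.concatenate(v_list), (np.concatenate(r_list), np.concatenate(c_list))),
        shape=(n, n),
        dtype=np.complex128,
    )

    A_z = None
    if with_bz:
        quarter_h = 0.25 * h
        bz_weights = [
            (+sz, -quarter_h * gxy),
            (-sz, +quarter_h * gxy),
            (+sx, +quarter_h * gz),
            (-sx, -quarter_h * gz),
            (+sy, +1j * quarter_h * gz),
            (-sy, -1j * quarter_h * gz),
        ]
        r_list, c_list, v_list = [], [], []
        for offset, w in bz_weights:
            cols = row_of[int_flat + offset]
            r_list.append(rows)
            c_list.append(cols)
            v_list.append(np.broadcast_to(w, rows.shape))
        A_z = sp.csr_matrix(
            (np.concatenate(v_list), (np.concatenate(r_list), np.concatenate(c_list))),
            shape=(n, n),
            dtype=np.complex128,
        )

    return FDSystem(
        A=A,
        A_z=A_z,
        denom=denom,
        flat_index=flat_index,
        interior_rows=interior_rows,
        boundary_rows=boundary_rows,
    )
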