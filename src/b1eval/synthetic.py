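"""Synthetic phantoms, reference fields, and measurement noise.

This module replaces full-wave coil simulation and MRI acquisition with
self-contained stand-ins so every experiment class runs at desk scale:

* phantom builders — a two-compartment sphere (outer radius 80 mm,
  sigma = 0.8 S/m, eps_r = 70, containing an off-center inner sphere of
  radius 40 mm with sigma = 0.3 S/m, eps_r = 60), a geometric brain-like
  phantom with white-matter / gray-matter / CSF tissue values
  (sigma = 0.35, 0.69, 2.26 S/m; eps_r = 51, 73, 80) and an optional
  three-compartment tumor (sigma = 0.7, 0.9, 1.2 S/m; eps_r = 60, 70,
  80), plus a uniform sphere;
* spherical/ellipsoidal conductivity anomalies of configurable size and
  offset (permittivity untouched);
* reference-field generation by direct solution of the same FD system
  driven by a synthetic boundary excitation (a plane wave with a mild
  transverse modulation by default) — forward/inverse consistency is
  then exact by construction, isolating EP-error detection from model
  error; a model-error mode generates the reference on a 2x-finer grid
  and downsamples to emulate discretization mismatch;
* Gaussian measurement noise at SNR 50 on |B1+| (complex channel) and
  SNR 80 on a synthetic T1-weighted carrier holding the transmit phase;
* transceive-phase synthesis phi_pm = wrap(phi_plus + phi_minus) with a
  mirror or smooth-bias receive-phase model.

The brain-like phantom is a geometric stand-in (nested smooth
compartments carrying realistic tissue values), not an anatomical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from b1eval.domain import (
    ComplexField,
    DomainMask,
    PhasePair,
    VoxelGrid,
    build_mask,
)
from b1eval.fd_system import EPMap, complex_permittivity
from b1eval.solver import SolverResult, direct_solve

# tissue EPs [sigma S/m, eps_r]
TWO_COMPARTMENT_OUTER = (0.8, 70.0)
TWO_COMPARTMENT_INNER = (0.3, 60.0)
BRAIN_WM = (0.35, 51.0)
BRAIN_GM = (0.69, 73.0)
BRAIN_CSF = (2.26, 80.0)
TUMOR_COMPARTMENTS = ((0.7, 60.0), (0.9, 70.0), (1.2, 80.0))


@dataclass
class PhantomSpec:
    """Geometry (mm) and tissue EPs of a synthetic phantom.

    ``radius_mm`` is the outer radius; the two-compartment sphere places
    its inner compartment (radius ``inner_radius_mm``) off-center by
    ``inner_offset_mm`` along +x.  ``center_mm`` defaults to the grid
    center.
    """

    kind: str = "two_compartment_sphere"
    radius_mm: float = 80.0
    inner_radius_mm: float = 40.0
    inner_offset_mm: float = 20.0
    center_mm: tuple[float, float, float] | None = None
    outer_ep: tuple[float, float] = TWO_COMPARTMENT_OUTER
    inner_ep: tuple[float, float] = TWO_COMPARTMENT_INNER
    with_tumor: bool = False
    tumor_center_offset_mm: tuple[float, float, float] = (25.0, 18.0, 0.0)
    tumor_radii_mm: tuple[float, float, float] = (12.0, 8.0, 4.0)

    def __post_init__(self) -> None:
        kinds = ("two_compartment_sphere", "brain_like", "brain_like_tumor",
                 "uniform_sphere")
        if self.kind not in kinds:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "brain_like_tumor":
            self.with_tumor = True


@dataclass
class AnomalySpec:
    """A conductivity anomaly inserted into an EP map.

    Either ``sigma_value`` (absolute) or ``sigma_offset`` (added to the
    local background) must be given.  ``core_radius_mm``/``core_sigma``
    optionally nest a smaller spherical compartment, applied last.
    Permittivity is never modified.
    """

    shape: str = "sphere"
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter_mm: float | tuple[float, float, float] = 13.0
    sigma_value: float | None = None
    sigma_offset: float | None = None
    core_radius_mm: float | None = None
    core_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown anomaly shape {self.shape!r}")
        if (self.sigma_value is None) == (self.sigma_offset is None):
            raise ValueError("give exactly one of sigma_value or sigma_offset")


@dataclass
class NoiseSpec:
    """Measurement-noise settings (defaults emulate a 3 T experiment)."""

    snr_magnitude: float = 50.0
    snr_phase_carrier: float = 80.0
    t1w_carrier: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.snr_magnitude > 0 and self.snr_phase_carrier > 0):
            raise ValueError("SNRs must be positive")


@dataclass
class BoundaryDriveSpec:
    """Synthetic boundary excitation standing in for a birdcage drive.

    ``plane_wave``: exp(-i k z) propagating along ``axis`` with a mild
    cosine transverse modulation of relative strength ``modulation``
    (default 0.2) to give the field the transverse curvature a real coil
    profile has.  ``quadrature_superposition``: the same longitudinal
    wave multiplied by a cos * cos standing-wave transverse profile.
    Both are nonzero everywhere on the boundary.
    """

    drive: str = "plane_wave"
    axis: int = 2
    amplitude: complex = 1.0 + 0.0j
    modulation: float = 0.2

    def __post_init__(self) -> None:
        if self.drive not in ("plane_wave", "quadrature_superposition"):
            raise ValueError(f"unknown drive {self.drive!r}")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")


def _coords_mm(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h_mm = grid.spacing_h * 1e3
    axes = [np.arange(n) * h_mm for n in grid.shape]
    return np.meshgrid(*axes, indexing="ij")


def _grid_center_mm(grid: VoxelGrid) -> tuple[float, float, float]:
    h_mm = grid.spacing_h * 1e3
    return tuple((n - 1) * h_mm / 2.0 for n in grid.shape)


def build_phantom(spec: PhantomSpec, grid: VoxelGrid) -> tuple[EPMap, DomainMask]:
    """Voxelize a phantom: EP map plus the domain mask (phantom support).

    Membership is by voxel center (a voxel belongs to the innermost
    compartment whose analytic surface contains its center).  Outside the
    phantom sigma = 0 and eps_r = 1 (air); those voxels are not in Omega.
    """
    x, y, z = _coords_mm(grid)
    center = spec.center_mm or _grid_center_mm(grid)
    cx, cy, cz = center
    h_mm = grid.spacing_h * 1e3
    max_extent = min(
        cx, cy, cz,
        (grid.shape[0] - 1) * h_mm - cx,
        (grid.shape[1] - 1) * h_mm - cy,
        (grid.shape[2] - 1) * h_mm - cz,
    )
    if spec.radius_mm > max_extent + 0.5 * h_mm:
        raise ValueError(
            f"phantom radius {spec.radius_mm} mm does not fit the grid "
            f"(max extent {max_extent:.1f} mm from center)"
        )

    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    sigma = np.zeros(grid.shape)
    eps_r = np.ones(grid.shape)

    if spec.kind in ("two_compartment_sphere", "uniform_sphere"):
        outer = r2 <= spec.radius_mm**2
        sigma[outer], eps_r[outer] = spec.outer_ep
        if spec.kind == "two_compartment_sphere":
            ix = cx + spec.inner_offset_mm
            inner = (x - ix) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= spec.inner_radius_mm**2
            if np.any(inner & ~outer):
                raise ValueError("inner compartment escapes the outer sphere")
            sigma[inner], eps_r[inner] = spec.inner_ep
        inside = outer
    else:  # brain-like: nested smooth ellipsoidal compartments
        a = spec.radius_mm
        def ellipsoid(scale, semi, offset=(0.0, 0.0, 0.0)):
            sx, sy, sz = (a * scale * s for s in semi)
            ox, oy, oz = offset
            return (
                ((x - cx - ox) / sx) ** 2
                + ((y - cy - oy) / sy) ** 2
                + ((z - cz - oz) / sz) ** 2
                <= 1.0
            )
        head = ellipsoid(1.0, (0.95, 0.8, 0.85))          # GM shell
        wm = ellipsoid(0.72, (0.95, 0.8, 0.85))           # WM core
        vent_l = ellipsoid(0.22, (0.6, 1.4, 0.8), (-0.12 * a, 0.0, 0.0))
        vent_r = ellipsoid(0.22, (0.6, 1.4, 0.8), (+0.12 * a, 0.0, 0.0))
        csf = vent_l | vent_r
        sigma[head], eps_r[head] = BRAIN_GM
        sigma[wm], eps_r[wm] = BRAIN_WM
        sigma[csf], eps_r[csf] = BRAIN_CSF
        if spec.with_tumor:
            ox, oy, oz = spec.tumor_center_offset_mm
            tc = (cx + ox, cy + oy, cz + oz)
            tr2 = (x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2
            for radius, (ts, te) in zip(
                sorted(spec.tumor_radii_mm, reverse=True), TUMOR_COMPARTMENTS
            ):
                shell = tr2 <= radius**2
                if np.any(shell & ~head):
                    raise ValueError("tumor compartment escapes the phantom")
                sigma[shell], eps_r[shell] = ts, te
        inside = head

    mask = build_mask(inside)
    return EPMap(sigma=sigma, eps_r=eps_r), mask


def insert_anomaly(
    ep: EPMap, spec: AnomalySpec, mask: DomainMask, grid: VoxelGrid
) -> EPMap:
    """Return a copy of the EP map with the conductivity anomaly applied.

    The anomaly region must lie entirely inside Omega.  Permittivity is
    left unchanged.
    """
    x, y, z = _coords_mm(grid)
    cx, cy, cz = spec.center_mm
    if spec.shape == "sphere":
        d = spec.diameter_mm if np.isscalar(spec.diameter_mm) else spec.diameter_mm[0]
        radii = (d / 2.0,) * 3
    else:
        diam = spec.diameter_mm
        if np.isscalar(diam):
            raise ValueError("ellipsoid anomaly needs a diameter triple")
        radii = tuple(di / 2.0 for di in diam)
    region = (
        ((x - cx) / radii[0]) ** 2
        + ((y - cy) / radii[1]) ** 2
        + ((z - cz) / radii[2]) ** 2
        <= 1.0
    )
    if not region.any():
        raise ValueError("anomaly contains no voxel at this resolution")
    if np.any(region & ~mask.inside):
        raise ValueError("anomaly escapes Omega")
    out = ep.copy()
    if spec.sigma_value is not None:
        out.sigma[region] = spec.sigma_value
    else:
        out.sigma[region] = out.sigma[region] + spec.sigma_offset
    if spec.core_radius_mm is not None:
        core = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= spec.core_radius_mm**2
        if np.any(core & ~mask.inside):
            raise ValueError("anomaly core escapes Omega")
        if spec.core_sigma is None:
            raise ValueError("core_radius_mm requires core_sigma")
        out.sigma[core] = spec.core_sigma
    return out


def drive_field(
    grid: VoxelGrid, ep: EPMap, mask: DomainMask, drive: BoundaryDriveSpec
) -> ComplexField:
    """Evaluate the synthetic excitation field on the full grid.

    The longitudinal wavenumber is k = omega*sqrt(mu0*<eps_c>) with
    <eps_c> the mean complex permittivity over Omega, so the drive is
    roughly consistent with the medium it excites.
    """
    eps_c = complex_permittivity(ep, grid).eps_c
    eps_c_mean = complex(eps_c[mask.inside].mean())
    k = np.sqrt(grid.mu0 * eps_c_mean) * grid.omega
    if k.imag > 0:
        k = -k
    x, y, z = _coords_mm(grid)
    coords = (x, y, z)
    cx, cy, cz = _grid_center_mm(grid)
    centers = (cx, cy, cz)
    prop = coords[drive.axis] * 1e-3
    t_axes = [a for a in range(3) if a != drive.axis]
    u = (coords[t_axes[0]] - centers[t_axes[0]]) * 1e-3
    v = (coords[t_axes[1]] - centers[t_axes[1]]) * 1e-3
    lu = max((grid.shape[t_axes[0]] - 1) * grid.spacing_h / 2.0, grid.spacing_h)
    lv = max((grid.shape[t_axes[1]] - 1) * grid.spacing_h / 2.0, grid.spacing_h)
    wave = np.exp(-1j * k * prop)
    if drive.drive == "plane_wave":
        profile = 1.0 + drive.modulation * np.cos(
            0.5 * np.pi * u / lu
        ) * np.cos(0.5 * np.pi * v / lv)
    else:  # quadrature standing-wave transverse profile, kept zero-free
        qu = np.pi / (4.0 * lu)
        qv = np.pi / (4.0 * lv)
        profile = np.cos(qu * u) * np.cos(qv * v)
    values = drive.amplitude * wave * profile
    return ComplexField(values=values.astype(np.complex128), role="synthetic_reference")


def generate_reference_field(
    ep: EPMap,
    mask: DomainMask,
    grid: VoxelGrid,
    drive: BoundaryDriveSpec | None = None,
    bz: ComplexField | None = None,
) -> SolverResult:
    """Self-consistent reference B1+ for ground-truth EPs.

    Solves the FD system directly with the synthetic drive as Dirichlet
    data; the returned field plays the role of the measured/simulated
    ground truth.  Deterministic for a fixed spec.
    """
    drive = drive or BoundaryDriveSpec()
    excitation = drive_field(grid, ep, mask, drive)
    result = direct_solve(excitation, ep, mask, grid,
                          with_bz=bz is not None, bz=bz)
    result.predicted.role = "synthetic_reference"
    return result


def make_t1w_carrier(ep: EPMap, mask: DomainMask) -> np.ndarray:
    """Piecewise-constant synthetic T1-weighted magnitude per compartment.

    Distinct (sigma, eps_r) pairs map to distinct magnitudes in
    [0.5, 1.5]; background is 0.
    """
    carrier = np.zeros(ep.sigma.shape)
    pairs = np.stack([ep.sigma[mask.inside], ep.eps_r[mask.inside]], axis=1)
    uniq, labels = np.unique(pairs, axis=0, return_inverse=True)
    n = max(len(uniq) - 1, 1)
    levels = 0.5 + 1.0 * (np.arange(len(uniq)) / n)
    carrier[mask.inside] = levels[labels]
    return carrier


def add_noise(
    magnitude: np.ndarray,
    phase: np.ndarray,
    spec: NoiseSpec,
    mask: DomainMask,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian measurement noise on |B1+| and on the phase carrier.

    Magnitude channel: independent real/imaginary Gaussian noise with
    std = mean(|B1+| over Omega)/snr_magnitude is added to the complex
    field and the magnitude retaken.  Phase channel: the same recipe on
    the complex image t1w_carrier*exp(i*phi) with
    std = mean(carrier over Omega)/snr_phase_carrier, phase retaken.
    Reproducible via ``spec.seed``; noise exists only inside Omega.
    """
    if spec.t1w_carrier is None:
        raise ValueError("NoiseSpec.t1w_carrier is required to add phase noise")
    rng = np.random.default_rng(spec.seed)
    inside = mask.inside

    b = magnitude * np.exp(1j * phase)
    std_m = float(np.mean(np.abs(magnitude)[inside])) / spec.snr_magnitude
    noise_b = rng.normal(0.0, std_m, b.shape) + 1j * rng.normal(0.0, std_m, b.shape)
    noisy_mag = np.abs(np.where(inside, b + noise_b, b))

    carrier = spec.t1w_carrier
    t1 = carrier * np.exp(1j * phase)
    std_p = float(np.mean(carrier[inside])) / spec.snr_phase_carrier
    noise_t = rng.normal(0.0, std_p, t1.shape) + 1j * rng.normal(0.0, std_p, t1.shape)
    noisy_phase = np.angle(np.where(inside, t1 + noise_t, t1))

    return noisy_mag, noisy_phase


def synthesize_transceive(
    phase_pair: PhasePair,
    receive_model: str = "mirror",
    bias_amplitude: float = 0.0,
    mask: DomainMask | None = None,
) -> PhasePair:
    """Generate a receive phase and compose the transceive phase.

    ``mirror``: the receive phase is the transmit phase of the
    reversed-polarization drive, approximated by mirroring along x.
    ``smooth_bias``: phi_minus = phi_plus + a smooth low-order polynomial
    field scaled to peak amplitude ``bias_amplitude`` [rad] (zero
    amplitude makes the transceive-phase assumption phi_pm/2 exact).
    The transceive phase is wrap(phi_plus + phi_minus).
    """
    phi = np.asarray(phase_pair.transmit)
    if receive_model == "mirror":
        receive = phi[::-1, :, :].copy()
    elif receive_model == "smooth_bias":
        nx, ny, nz = phi.shape
        u = np.linspace(-1, 1, nx)[:, None, None]
        v = np.linspace(-1, 1, ny)[None, :, None]
        w = np.linspace(-1, 1, nz)[None, None, :]
        poly = 0.5 * u + 0.3 * v - 0.2 * w + 0.4 * u * v + 0.3 * (w**2 - u**2)
        sel = mask.inside if mask is not None else np.ones(phi.shape, bool)
        peak = float(np.max(np.abs(poly[sel]))) or 1.0
        receive = phi + bias_amplitude * poly / peak
    else:
        raise ValueError(f"unknown receive model {receive_model!r}")
    transceive = np.angle(np.exp(1j * (phi + receive)))
    return PhasePair(transmit=phi, receive=receive, transceive=transceive)
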