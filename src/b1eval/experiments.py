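"""Canned desk-scale experiments used for validation and reporting.

Each function builds its inputs from the synthetic module, runs the
solver/evaluation pipeline, and returns plain scalars.  Problem sizes are
scaled-down analogues of the reference experiments (a 48^3 half-scale or
32^3 quarter-scale sphere instead of the ~2e6-voxel originals) so every
experiment runs in seconds to minutes on one CPU; geometry proportions,
tissue values, noise levels, and all method parameters are kept at their
reference values.

MAE statistics here are computed over the interior (the Dirichlet layer
is copied measurement data in every prediction, so it carries no
information about the EPs under test), and against the clean
ground-truth reference field; measurement noise enters a prediction only
through its boundary condition.
"""

from __future__ import annotations

import numpy as np

from b1eval.domain import (
    ComplexField,
    DomainMask,
    VoxelGrid,
    build_mask,
    normalize_magnitude,
)
from b1eval.evaluation import (
    SmoothingSpec,
    difference_maps,
    global_offset,
    mae,
    roughness,
    surrogate_error_maps,
)
from b1eval.fd_system import EPMap
from b1eval.solver import (
    SolverConfig,
    analytic_plane_wave,
    direct_solve,
    predict_b1,
)
from b1eval.synthetic import (
    AnomalySpec,
    BoundaryDriveSpec,
    NoiseSpec,
    PhantomSpec,
    add_noise,
    build_phantom,
    generate_reference_field,
    insert_anomaly,
    make_t1w_carrier,
)

# scaled-down grids used throughout
SPHERE_32 = dict(shape=(32, 32, 32), spacing_h=5e-3)      # radius 75 mm phantom
SPHERE_48 = dict(shape=(48, 48, 48), spacing_h=4e-3)      # radius 80 mm phantom


def _sphere_32_phantom(kind: str = "two_compartment_sphere",
                       outer_ep=(0.8, 70.0)) -> tuple[VoxelGrid, EPMap, DomainMask]:
    grid = VoxelGrid(**SPHERE_32)
    spec = PhantomSpec(kind=kind, radius_mm=75.0, inner_radius_mm=37.5,
                       inner_offset_mm=18.75, outer_ep=outer_ep)
    ep, mask = build_phantom(spec, grid)
    return grid, ep, mask


def _sphere_48_phantom() -> tuple[VoxelGrid, EPMap, DomainMask]:
    """The reference two-compartment sphere (80/40 mm) at 4 mm voxels."""
    grid = VoxelGrid(**SPHERE_48)
    ep, mask = build_phantom(PhantomSpec(), grid)
    return grid, ep, mask


def plane_wave_validation(n: int = 48, h: float = 2e-3, sigma: float = 0.5,
                          eps_r: float = 78.0,
                          convergence_limit_C: float = 1e-6) -> dict:
    """Homogeneous-medium recovery of the analytic plane wave.

    Returns the maximum interior complex deviation between the relaxed
    solution (plane-wave Dirichlet data) and the analytic wave, which is
    bounded by the closed-form discrete-dispersion error.
    """
    grid = VoxelGrid(shape=(n, n, n), spacing_h=h)
    mask = build_mask(np.ones(grid.shape, bool))
    ep = EPMap(sigma=np.full(grid.shape, sigma),
               eps_r=np.full(grid.shape, eps_r))
    eps_c = grid.eps0 * eps_r - 1j * sigma / grid.omega
    wave = analytic_plane_wave(grid, eps_c)
    result = predict_b1(
        wave, ep, mask, grid,
        SolverConfig(convergence_limit_C=convergence_limit_C),
    )
    dev = np.abs(result.predicted.values - wave.values)[mask.interior].max()
    return {
        "max_interior_deviation": float(dev),
        "iterations": result.iterations_used,
        "converged": result.converged,
    }


def oracle_equivalence(convergence_limit_C: float = 1e-6) -> dict:
    """Jacobi relaxation vs sparse factorization on the 32^3 sphere."""
    grid, ep, mask = _sphere_32_phantom()
    ref = generate_reference_field(ep, mask, grid)
    jac = predict_b1(ref.predicted, ep, mask, grid,
                     SolverConfig(convergence_limit_C=convergence_limit_C))
    delta = np.abs(jac.predicted.values - ref.predicted.values)[mask.inside].max()
    return {"max_delta": float(delta), "limit": 100 * convergence_limit_C}


def ept_round_trips() -> dict:
    """Phase-only and Helmholtz round trips on analytic fields."""
    from b1eval.recon import ReconConfig, helmholtz_ept, phase_only_ept

    no_filter = ReconConfig(denoise_diameter=1)
    out: dict = {}

    # quadratic phase -> exact conductivity
    sigma0 = 0.5
    grid = VoxelGrid(shape=(16, 16, 16), spacing_h=1e-3)
    mask = build_mask(np.ones(grid.shape, bool))
    z = np.arange(grid.shape[2])[None, None, :] * grid.spacing_h
    phase = np.broadcast_to(grid.omega * grid.mu0 * sigma0 * z**2 / 2.0,
                            grid.shape).copy()
    sig = phase_only_ept(phase, mask, grid, no_filter)
    out["phase_only_max_rel_err"] = float(
        np.abs(sig[np.isfinite(sig)] / sigma0 - 1.0).max()
    )

    # plane wave -> Helmholtz EPs within the stencil dispersion bias
    sigma1, eps_r1 = 0.61, 78.0
    grid2 = VoxelGrid(shape=(8, 8, 24), spacing_h=1e-3)
    mask2 = build_mask(np.ones(grid2.shape, bool))
    eps_c = grid2.eps0 * eps_r1 - 1j * sigma1 / grid2.omega
    wave = analytic_plane_wave(grid2, eps_c)
    ep = helmholtz_ept(wave, mask2, grid2, no_filter)
    valid = np.isfinite(ep.sigma)
    out["helmholtz_sigma_max_rel_err"] = float(
        np.abs(ep.sigma[valid] / sigma1 - 1.0).max()
    )
    out["helmholtz_eps_r_max_rel_err"] = float(
        np.abs(ep.eps_r[valid] / eps_r1 - 1.0).max()
    )
    return out


def _noisy_measured(field: ComplexField, ep: EPMap, mask: DomainMask,
                    seed: int) -> ComplexField:
    carrier = make_t1w_carrier(ep, mask)
    spec = NoiseSpec(t1w_carrier=carrier, seed=seed)
    nmag, nphase = add_noise(field.magnitude, field.phase, spec, mask)
    return ComplexField.from_polar(nmag, nphase)


def null_vs_offset(sigma_offset: float = 0.05, seed: int = 0) -> dict:
    """Null-test contrast on the 48^3 two-compartment sphere (80/40 mm).

    One direct-solve reference field; four predictions — ground-truth
    EPs vs globally offset input conductivity, each from the clean and
    from the SNR-50/80 noisy boundary data — all compared against the
    clean reference field.
    """
    grid, ep, mask = _sphere_48_phantom()
    ref = generate_reference_field(ep, mask, grid)
    clean = normalize_magnitude(ref.predicted, mask)
    noisy = _noisy_measured(clean, ep, mask, seed)

    cfg = SolverConfig()
    ep_off = EPMap(sigma=ep.sigma + sigma_offset, eps_r=ep.eps_r)
    out: dict = {}
    for noise_label, measured in (("clean", clean), ("noisy", noisy)):
        for label, ep_in in (("null", ep), ("offset", ep_off)):
            res = predict_b1(measured, ep_in, mask, grid, cfg)
            d_phi, d_b = difference_maps(res.predicted, clean, mask)
            key = f"{label}_{noise_label}"
            out[f"mae_phi_{key}"] = mae(d_phi, mask, region=mask.interior)
            out[f"mae_B_{key}"] = mae(d_b, mask, region=mask.interior)
            if label == "null" and noise_label == "noisy":
                out["predicted_roughness"] = roughness(res.predicted.values, mask)
        out[f"contrast_phi_{noise_label}"] = (
            out[f"mae_phi_offset_{noise_label}"] / out[f"mae_phi_null_{noise_label}"]
        )
        out[f"contrast_B_{noise_label}"] = (
            out[f"mae_B_offset_{noise_label}"] / out[f"mae_B_null_{noise_label}"]
        )
    out["measured_roughness"] = roughness(noisy.values, mask)
    return out


def offset_sweep(offsets=(-0.1, -0.05, 0.05, 0.1), seed: int = 0) -> dict:
    """Global-offset indicator L_phi_off vs imposed conductivity offset.

    Runs on the 32^3 two-compartment sphere with the SNR-50/80 noise of a
    measurement on the reference data.
    """
    grid, ep, mask = _sphere_32_phantom()
    ref = generate_reference_field(ep, mask, grid)
    clean = normalize_magnitude(ref.predicted, mask)
    measured = _noisy_measured(clean, ep, mask, seed)
    cfg = SolverConfig()
    smoothing = SmoothingSpec()
    results = {}
    for off in offsets:
        ep_in = EPMap(sigma=ep.sigma + off, eps_r=ep.eps_r)
        res = predict_b1(measured, ep_in, mask, grid, cfg)
        d_phi, d_b = difference_maps(res.predicted, clean, mask)
        l_phi, _ = surrogate_error_maps(d_phi, d_b, mask, grid, smoothing)
        results[off] = global_offset(l_phi, mask)
    return results


def _anomaly_region(grid: VoxelGrid, center_mm, diameter_mm) -> np.ndarray:
    h_mm = grid.spacing_h * 1e3
    axes = [np.arange(n) * h_mm for n in grid.shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r = diameter_mm / 2.0
    return ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
            + (z - center_mm[2]) ** 2) <= r**2


def anomaly_l_phi(grid, ep_true, mask, measured, clean, center_mm,
                  diameter_mm, sigma_offset, smoothing=None):
    """Predict with an anomalous input conductivity; return the L_phi map
    and the anomaly-region mean |L_phi|."""
    smoothing = smoothing or SmoothingSpec()
    spec = AnomalySpec(center_mm=center_mm, diameter_mm=diameter_mm,
                       sigma_offset=sigma_offset)
    ep_in = insert_anomaly(ep_true, spec, mask, grid)
    res = predict_b1(measured, ep_in, mask, grid, SolverConfig())
    d_phi, d_b = difference_maps(res.predicted, clean, mask)
    l_phi, _ = surrogate_error_maps(d_phi, d_b, mask, grid, smoothing)
    region = _anomaly_region(grid, center_mm, diameter_mm)
    vals = np.abs(l_phi[region & np.isfinite(l_phi)])
    return l_phi, float(vals.mean())


def anomaly_sensitivity(seed: int = 0) -> dict:
    """Anomaly localization and sensitivity ordering on a uniform sphere.

    Mirrors the phantom sensitivity experiment at quarter scale: a
    spherical conductivity anomaly varied in diameter (9-21 voxels) and
    offset (0.2-0.8 S/m), placed centrally and peripherally, in a
    sigma = 0.61 S/m, eps_r = 78 sphere.
    """
    grid, ep, mask = _sphere_32_phantom(kind="uniform_sphere",
                                        outer_ep=(0.61, 78.0))
    ref = generate_reference_field(ep, mask, grid)
    clean = normalize_magnitude(ref.predicted, mask)
    measured = _noisy_measured(clean, ep, mask, seed)
    h_mm = grid.spacing_h * 1e3
    center = tuple((n - 1) * h_mm / 2 for n in grid.shape)
    off_center = (center[0] + 3 * h_mm, center[1], center[2])
    peripheral = (center[0] + 7 * h_mm, center[1], center[2])
    smoothing = SmoothingSpec()

    out: dict = {}
    # localization: 13-voxel anomaly, dsigma 0.6, off-center
    l_phi, _ = anomaly_l_phi(grid, ep, mask, measured, clean, off_center,
                             13 * h_mm, 0.6, smoothing)
    work = np.where(np.isfinite(l_phi), np.abs(l_phi), 0.0)
    peak = np.unravel_index(np.argmax(work), l_phi.shape)
    half_width = (smoothing.kernel_size - 1) // 2
    dilated = _anomaly_region(grid, off_center,
                              13 * h_mm + 2 * half_width * h_mm)
    out["peak_inside_dilated_anomaly"] = bool(dilated[peak])

    out["mean_abs_l_phi_by_diameter"] = {
        d: anomaly_l_phi(grid, ep, mask, measured, clean, off_center,
                         d * h_mm, 0.6, smoothing)[1]
        for d in (9, 13, 17, 21)
    }
    out["mean_abs_l_phi_by_offset"] = {
        ds: anomaly_l_phi(grid, ep, mask, measured, clean, off_center,
                          13 * h_mm, ds, smoothing)[1]
        for ds in (0.2, 0.4, 0.6, 0.8)
    }
    out["central_mean_abs_l_phi"] = anomaly_l_phi(
        grid, ep, mask, measured, clean, center, 13 * h_mm, 0.6, smoothing
    )[1]
    out["peripheral_mean_abs_l_phi"] = anomaly_l_phi(
        grid, ep, mask, measured, clean, peripheral, 13 * h_mm, 0.6, smoothing
    )[1]
    return out


def fixed_point_certificate(convergence_limit_C: float = 1e-6) -> dict:
    """Determinism and fixed-point certificate on the 32^3 sphere.

    Two identical runs must agree bit-for-bit, and one extra Jacobi
    application to the converged result must change no interior voxel by
    more than C.
    """
    from b1eval.fd_system import (
        assemble_system,
        complex_permittivity,
        grad_log_eps,
    )

    grid, ep, mask = _sphere_32_phantom()
    ref = generate_reference_field(ep, mask, grid)
    cfg = SolverConfig(convergence_limit_C=convergence_limit_C)
    r1 = predict_b1(ref.predicted, ep, mask, grid, cfg)
    r2 = predict_b1(ref.predicted, ep, mask, grid, cfg)
    bit_identical = bool(np.array_equal(r1.predicted.values, r2.predicted.values))

    eps_c = complex_permittivity(ep, grid)
    g = grad_log_eps(eps_c, mask, grid)
    system = assemble_system(eps_c, g, mask, grid)
    b = r1.predicted.values.ravel()[system.flat_index]
    b_next = (system.A @ b) / system.denom
    extra_step = float(
        np.abs(b_next[system.interior_rows] - b[system.interior_rows]).max()
    )
    return {
        "bit_identical": bit_identical,
        "extra_step_max_change": extra_step,
        "iterations": r1.iterations_used,
        "converged": r1.converged,
    }
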