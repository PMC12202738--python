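"""Phantom builders, anomaly insertion, noise, and transceive synthesis."""

import numpy as np
import pytest

from b1eval import (
    AnomalySpec,
    BoundaryDriveSpec,
    NoiseSpec,
    PhantomSpec,
    PhasePair,
    VoxelGrid,
    add_noise,
    build_phantom,
    generate_reference_field,
    insert_anomaly,
    normalize_magnitude,
    synthesize_transceive,
)
from b1eval.synthetic import (
    BRAIN_CSF,
    BRAIN_GM,
    BRAIN_WM,
    TUMOR_COMPARTMENTS,
    make_t1w_carrier,
)


class TestBuildPhantom:
    def test_reference_sphere_voxel_count(self):
        """80 mm-radius sphere at 2 mm: voxel count within 1% of the
        analytic volume (4/3)pi(80/2)^3 voxels."""
        grid = VoxelGrid(shape=(88, 88, 88), spacing_h=2e-3)
        spec = PhantomSpec(kind="two_compartment_sphere")
        ep, mask = build_phantom(spec, grid)
        expected = 4.0 / 3.0 * np.pi * (80.0 / 2.0) ** 3
        assert abs(mask.n_voxels - expected) / expected < 0.01

    def test_two_compartment_values(self):
        """Inner voxels carry sigma 0.3/eps_r 60; the rest 0.8/70."""
        grid = VoxelGrid(shape=(44, 44, 44), spacing_h=4e-3)
        ep, mask = build_phantom(PhantomSpec(), grid)
        vals = set(zip(ep.sigma[mask.inside], ep.eps_r[mask.inside]))
        assert vals == {(0.8, 70.0), (0.3, 60.0)}
        inner = mask.inside & (ep.sigma == 0.3)
        assert np.all(ep.eps_r[inner] == 60.0)
        assert inner.sum() > 0

    def test_brain_like_tissues_and_tumor(self):
        grid = VoxelGrid(shape=(48, 48, 48), spacing_h=4e-3)
        spec = PhantomSpec(kind="brain_like_tumor", radius_mm=90.0)
        ep, mask = build_phantom(spec, grid)
        sig_vals = set(np.round(np.unique(ep.sigma[mask.inside]), 6))
        assert {BRAIN_WM[0], BRAIN_GM[0], BRAIN_CSF[0]} <= sig_vals
        tumor_sigmas = {s for s, _ in TUMOR_COMPARTMENTS}
        assert tumor_sigmas <= sig_vals

    def test_phantom_must_fit_grid(self):
        grid = VoxelGrid(shape=(20, 20, 20), spacing_h=2e-3)
        with pytest.raises(ValueError):
            build_phantom(PhantomSpec(radius_mm=80.0), grid)

    def test_boundary_scaling_with_resolution(self):
        """Halving h roughly quadruples the boundary-layer voxel count."""
        c1 = build_phantom(
            PhantomSpec(kind="uniform_sphere", radius_mm=40.0),
            VoxelGrid(shape=(24, 24, 24), spacing_h=4e-3),
        )[1].boundary.sum()
        c2 = build_phantom(
            PhantomSpec(kind="uniform_sphere", radius_mm=40.0),
            VoxelGrid(shape=(48, 48, 48), spacing_h=2e-3),
        )[1].boundary.sum()
        assert 2.5 < c2 / c1 < 6.0


class TestInsertAnomaly:
    @pytest.fixture
    def phantom(self):
        grid = VoxelGrid(shape=(32, 32, 32), spacing_h=5e-3)
        ep, mask = build_phantom(
            PhantomSpec(kind="uniform_sphere", radius_mm=75.0,
                        outer_ep=(0.61, 78.0)),
            grid,
        )
        return grid, ep, mask

    def test_zero_offset_no_change(self, phantom):
        grid, ep, mask = phantom
        spec = AnomalySpec(center_mm=(77.5, 77.5, 77.5), diameter_mm=40.0,
                           sigma_offset=0.0)
        out = insert_anomaly(ep, spec, mask, grid)
        assert np.array_equal(out.sigma, ep.sigma)
        assert np.array_equal(out.eps_r, ep.eps_r)

    def test_sphere_volume(self):
        """13 mm-diameter sphere at 1 mm within 5% of (4/3)pi*6.5^3."""
        grid = VoxelGrid(shape=(32, 32, 32), spacing_h=1e-3)
        ep, mask = build_phantom(
            PhantomSpec(kind="uniform_sphere", radius_mm=15.0,
                        outer_ep=(0.61, 78.0)),
            grid,
        )
        # center on a voxel center so the discrete ball is symmetric
        spec = AnomalySpec(center_mm=(15.0, 15.0, 15.0), diameter_mm=13.0,
                           sigma_offset=0.2)
        out = insert_anomaly(ep, spec, mask, grid)
        count = (out.sigma != ep.sigma).sum()
        expected = 4.0 / 3.0 * np.pi * 6.5**3
        assert abs(count - expected) / expected < 0.05

    def test_invivo_style_nested_core(self, phantom):
        """Ellipsoid sigma 0.9 with a 0.5-voxel-scaled core sigma 1.3:
        the region histogram holds exactly {0.9, 1.3} plus background."""
        grid, ep, mask = phantom
        spec = AnomalySpec(shape="ellipsoid", center_mm=(77.5, 77.5, 77.5),
                           diameter_mm=(60.0, 50.0, 40.0), sigma_value=0.9,
                           core_radius_mm=12.0, core_sigma=1.3)
        out = insert_anomaly(ep, spec, mask, grid)
        assert set(np.unique(out.sigma[mask.inside])) == {0.61, 0.9, 1.3}
        assert np.array_equal(out.eps_r, ep.eps_r)

    def test_anomaly_escaping_domain_rejected(self, phantom):
        grid, ep, mask = phantom
        spec = AnomalySpec(center_mm=(150.0, 77.5, 77.5), diameter_mm=40.0,
                           sigma_offset=0.2)
        with pytest.raises(ValueError, match="escapes"):
            insert_anomaly(ep, spec, mask, grid)


class TestReferenceField:
    def test_deterministic(self, sphere_grid, two_compartment):
        ep, mask = two_compartment
        r1 = generate_reference_field(ep, mask, sphere_grid)
        r2 = generate_reference_field(ep, mask, sphere_grid)
        assert np.array_equal(r1.predicted.values, r2.predicted.values)

    def test_continuous_across_interface(self, sphere_grid, two_compartment):
        """Among interior voxel pairs (which straddle the compartment
        interface), no jump exceeds 10x the median neighbor jump.  The
        Dirichlet layer is excluded: it holds the raw excitation, which
        legitimately differs from the relaxed interior."""
        ep, mask = two_compartment
        ref = generate_reference_field(ep, mask, sphere_grid)
        v = ref.predicted.values
        work = np.where(mask.inside, v, 0)
        acc = np.zeros_like(work)
        for ax in range(3):
            acc += np.roll(work, 1, ax) + np.roll(work, -1, ax)
        # relative deviation from the 6-neighbor mean: ~ (kh)^2/6 for a
        # smooth wave, spikes by the jump size at a discontinuity
        dev = np.abs(v - acc / 6.0)[mask.interior] / np.abs(v)[mask.interior]
        assert dev.max() <= 10 * np.median(dev)

    def test_homogeneous_plane_wave_drive_matches_analytic(self):
        from b1eval import EPMap, analytic_plane_wave, build_mask, direct_solve
        from b1eval.domain import EPS0

        grid = VoxelGrid(shape=(24, 24, 24), spacing_h=2e-3)
        mask = build_mask(np.ones(grid.shape, bool))
        ep = EPMap(sigma=np.full(grid.shape, 0.5), eps_r=np.full(grid.shape, 78.0))
        wave = analytic_plane_wave(grid, EPS0 * 78 - 1j * 0.5 / grid.omega)
        res = direct_solve(wave, ep, mask, grid)
        err = np.abs(res.predicted.values - wave.values)[mask.interior].max()
        assert err < 1e-3


class TestNoise:
    @pytest.fixture
    def field_and_mask(self, sphere_grid, two_compartment):
        ep, mask = two_compartment
        ref = generate_reference_field(ep, mask, sphere_grid)
        field = normalize_magnitude(ref.predicted, mask)
        carrier = make_t1w_carrier(ep, mask)
        return field, mask, carrier

    def test_seeded_reproducibility(self, field_and_mask):
        field, mask, carrier = field_and_mask
        spec = NoiseSpec(t1w_carrier=carrier, seed=42)
        m1, p1 = add_noise(field.magnitude, field.phase, spec, mask)
        m2, p2 = add_noise(field.magnitude, field.phase, spec, mask)
        assert np.array_equal(m1, m2) and np.array_equal(p1, p2)
        m3, _ = add_noise(field.magnitude, field.phase,
                          NoiseSpec(t1w_carrier=carrier, seed=43), mask)
        assert not np.array_equal(m1, m3)

    def test_infinite_snr_limit(self, field_and_mask):
        field, mask, carrier = field_and_mask
        spec = NoiseSpec(snr_magnitude=1e12, snr_phase_carrier=1e12,
                         t1w_carrier=carrier, seed=0)
        m, p = add_noise(field.magnitude, field.phase, spec, mask)
        assert np.allclose(m[mask.inside], field.magnitude[mask.inside], atol=1e-9)
        assert np.allclose(p[mask.inside], field.phase[mask.inside], atol=1e-9)

    def test_empirical_snr_within_10pct(self):
        """Measured SNR (mean |B| / noise std) within 10% of the nominal
        50, estimated over >= 1e5 voxels of a uniform region."""
        rng_shape = (50, 50, 50)
        grid = VoxelGrid(shape=rng_shape, spacing_h=2e-3)
        from b1eval import build_mask

        mask = build_mask(np.ones(rng_shape, bool))
        mag = np.full(rng_shape, 0.8)
        phase = np.zeros(rng_shape)
        carrier = np.ones(rng_shape)
        spec = NoiseSpec(t1w_carrier=carrier, seed=3)
        noisy_mag, _ = add_noise(mag, phase, spec, mask)
        # for |B| >> noise std the magnitude perturbation is ~ the real
        # noise component: std estimate from the residual
        noise_std = np.std(noisy_mag - mag)
        snr = np.mean(mag) / noise_std
        assert abs(snr - 50.0) / 50.0 < 0.10

    def test_missing_carrier_rejected(self, field_and_mask):
        field, mask, _ = field_and_mask
        with pytest.raises(ValueError, match="carrier"):
            add_noise(field.magnitude, field.phase, NoiseSpec(), mask)


class TestTransceive:
    def test_zero_bias_makes_half_transceive_exact(self, sphere_grid,
                                                   two_compartment):
        ep, mask = two_compartment
        ref = generate_reference_field(ep, mask, sphere_grid)
        pair = PhasePair(transmit=ref.predicted.phase)
        out = synthesize_transceive(pair, receive_model="smooth_bias",
                                    bias_amplitude=0.0, mask=mask)
        half = np.angle(np.exp(1j * out.transceive / 2))
        # phi_pm/2 equals phi_plus wherever phi_plus is in (-pi/2, pi/2]
        sel = mask.inside & (np.abs(pair.transmit) < np.pi / 2)
        assert np.allclose(half[sel], pair.transmit[sel], atol=1e-12)

    def test_transceive_is_wrapped_sum(self, sphere_grid, two_compartment):
        ep, mask = two_compartment
        ref = generate_reference_field(ep, mask, sphere_grid)
        pair = PhasePair(transmit=ref.predicted.phase)
        for model, amp in (("mirror", 0.0), ("smooth_bias", 0.4)):
            out = synthesize_transceive(pair, receive_model=model,
                                        bias_amplitude=amp, mask=mask)
            expect = np.angle(np.exp(1j * (out.transmit + out.receive)))
            assert np.array_equal(out.transceive, expect)


def test_t1w_carrier_distinct_per_compartment(sphere_grid, two_compartment):
    ep, mask = two_compartment
    carrier = make_t1w_carrier(ep, mask)
    inner = mask.inside & (ep.sigma == 0.3)
    outer = mask.inside & (ep.sigma == 0.8)
    assert len(np.unique(carrier[inner])) == 1
    assert len(np.unique(carrier[outer])) == 1
    assert carrier[inner][0] != carrier[outer][0]
    assert np.all(carrier[~mask.inside] == 0)


def test_prediction_smoother_than_noisy_reference(sphere_grid, two_compartment):
    """With ground-truth EPs and a noisy boundary, the predicted field's
    interior roughness stays below 20% of the noisy reference's."""
    from b1eval import SolverConfig, predict_b1, roughness

    ep, mask = two_compartment
    ref = generate_reference_field(ep, mask, sphere_grid)
    field = normalize_magnitude(ref.predicted, mask)
    carrier = make_t1w_carrier(ep, mask)
    nmag, nphase = add_noise(field.magnitude, field.phase,
                             NoiseSpec(t1w_carrier=carrier, seed=11), mask)
    noisy = nmag * np.exp(1j * nphase)
    from b1eval import ComplexField

    res = predict_b1(ComplexField(values=noisy), ep, mask, sphere_grid,
                     SolverConfig())
    assert roughness(res.predicted.values, mask) < 0.2 * roughness(noisy, mask)
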