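# b1eval

**Physics-based B1+ prediction for evaluating MR-EPT reconstructions.**

Electrical properties tomography (EPT) reconstructs tissue conductivity
σ and relative permittivity ε_r from the measured MRI transmit field
B1+ = |B1+| e^{iϕ+}.  Reconstructed EP maps vary widely between methods,
and in vivo there is no ground truth to check them against — which makes
it hard to trust any particular map, especially one from a black-box
deep-learning reconstruction.

`b1eval` attacks this by solving the *forward* problem: given an EP map
(from any reconstruction) and the measured B1+ on the boundary of the
region of interest, it predicts the B1+ field everywhere inside.  If the
EPs are right, the predicted field matches the measurement; where they
are wrong, the mismatch is localized and converted back into
conductivity/permittivity units.  The package is aimed at EPT researchers
and method developers who want a fast, self-contained confidence check
for arbitrary reconstructions.

## The model

The transmit field obeys (with ε_c = ε₀ε_r − iσ/ω, g = ∇ln ε_c, and the
longitudinal component B_z neglected via ∇B_z ≈ 0):

    −∇²B1+ = ω²μ₀ ε_c B1+ − (g_x + i g_y)(∂_x B1+ − i ∂_y B1+) − g_z ∂_z B1+ .

Discretized with central differences on an isotropic grid (spacing h)
and solved for each voxel, this becomes the fixed-point recurrence

    B_{i+1} = A B_i / (6 − ω²μ₀ ε_c h²),

iterated with the measured field pinned on the boundary layer ∂Ω
(Dirichlet) and ∇ε_c = 0 at the domain edge (Neumann, so no EP knowledge
is needed outside Ω), until the distance to the fixed point falls below
the convergence limit C (default 10⁻⁶).  A sparse-LU direct solver of
the same system serves as an independent oracle.

Prediction quality is summarized by difference maps and surrogate
EP-error maps

    D_ϕ = ∠B̂ − ϕ⁺,                L_ϕ = ∇²S(D_ϕ)/(ωμ₀)   [S/m],
    D_B = |B̂| − |B1+|,            L_B = ∇²S(D_B)/(ω²μ₀ε₀),

with S a Gaussian smoother (std 4, 11-voxel kernel).  L_ϕ localizes
conductivity errors; its median L_ϕ^off indicates a global offset in the
input conductivity.  A synthetic subsystem (phantoms, reference fields,
SNR-50/80 noise, transceive-phase composition) makes every experiment
reproducible without scanner or full-wave-simulation data, and
Helmholtz / phase-only / magnitude-only EPT reconstructions are included
so that reconstruct-then-evaluate workflows run end to end.

## Worked example

Build a two-compartment sphere phantom (outer σ = 0.8 S/m, ε_r = 70;
inner σ = 0.3 S/m, ε_r = 60), generate its reference field, then predict
B1+ twice — once with the true EPs and once with conductivity globally
offset by +0.05 S/m:

```python
import numpy as np
from b1eval import (
    PhantomSpec, VoxelGrid, build_phantom, generate_reference_field,
    normalize_magnitude, predict_b1, SolverConfig, EPMap, evaluate,
)

grid = VoxelGrid(shape=(32, 32, 32), spacing_h=5e-3)   # 5 mm voxels
ep_truth, mask = build_phantom(
    PhantomSpec(kind="two_compartment_sphere", radius_mm=75.0,
                inner_radius_mm=37.5, inner_offset_mm=18.75),
    grid,
)
reference = generate_reference_field(ep_truth, mask, grid)
measured = normalize_magnitude(reference.predicted, mask)

for label, ep_in in [
    ("ground truth", ep_truth),
    ("sigma + 0.05", EPMap(sigma=ep_truth.sigma + 0.05, eps_r=ep_truth.eps_r)),
]:
    result = predict_b1(measured, ep_in, mask, grid, SolverConfig())
    report = evaluate(result.predicted, measured, mask, grid)
    print(f"{label:>13}: mae_phi = {report.mae_phi:.2e} rad, "
          f"mae_B = {report.mae_B:.2e}, "
          f"L_phi_off = {report.L_phi_offset:+.3f} S/m "
          f"({result.iterations_used} iterations)")
```

Output:

```
 ground truth: mae_phi = 4.83e-07 rad, mae_B = 1.55e-07, L_phi_off = +0.000 S/m (3634 iterations)
 sigma + 0.05: mae_phi = 1.78e-02 rad, mae_B = 1.89e-03, L_phi_off = +0.010 S/m (3586 iterations)
```

With correct EPs the prediction reproduces the measurement to solver
tolerance (MAE ≈ 5·10⁻⁷ rad).  The +0.05 S/m input error raises the
phase MAE by more than four orders of magnitude, and the offset
indicator L_ϕ^off turns positive, matching the sign of the imposed
offset.  The `report.L_phi` volume shows *where* the input conductivity
disagrees with the field physics (here: everywhere, consistent with a
global offset).

## Command line

```bash
b1eval simulate --config phantom.yaml --out sim/     # phantom + fields as NIfTI
b1eval predict  --sigma s.nii.gz --epsr e.nii.gz --mask m.nii.gz \
                --mag mag.nii.gz --phase ph.nii.gz --out pred/
b1eval recon    --mag mag.nii.gz --phase ph.nii.gz --mask m.nii.gz \
                --method phase_only --out rec/
b1eval evaluate --pred-mag ... --pred-phase ... --meas-mag ... \
                --meas-phase ... --mask m.nii.gz --out eval/
b1eval pipeline --config experiment.yaml             # all of the above
```

Volumes are NIfTI (complex fields as magnitude/phase pairs); the YAML
config mirrors `b1eval.io.RunConfig`, whose defaults are the reference
settings (C = 10⁻⁶, 128 MHz, smoothing 4/11, filter diameter 11).

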