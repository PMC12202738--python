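# Methods

## Model

`b1eval` solves the forward problem of MR electrical properties
tomography (EPT): given a map of tissue conductivity σ [S/m] and relative
permittivity ε_r on a voxelized region of interest Ω, predict the complex
transmit field B1+ = |B1+| e^{iϕ+} inside Ω from its measured values on
the boundary layer ∂Ω.  The governing time-harmonic vector wave equation,
written for the circularly polarized transmit component, is

    −∇²B1+ = ω²μ₀ε_c B1+ − (g_x + i g_y)(∂_x B1+ − i ∂_y B1+ + ½ ∂_z B_z)
                          − g_z (∂_z B1+ − ½ ∂_x B_z − ½ i ∂_y B_z),

with ε_c = ε₀ε_r − iσ/ω the complex permittivity at the Larmor frequency
ω = 2πf (default f = 128 MHz, i.e. 3 T) and g = ∇ln ε_c.  B_z, the
longitudinal RF component, is not measurable; with ∇B_z ≈ 0 (a good
approximation near the center of a birdcage coil) the B_z terms drop out.
Both variants are implemented; the simplified one is the default, since
it is the one usable with real measurements.

Discretizing with the 7-point Laplacian and central first differences on
an isotropic grid of spacing h and solving each interior voxel's equation
for its center value yields a fixed-point recurrence

    B_{i+1} = (A B_i + A_z Z) / (6 − ω²μ₀ ε_c h²),

where A carries the six neighbor weights

    x±: 1 ∓ (h/2)(g_x + i g_y),   y±: 1 ± i (h/2)(g_x + i g_y),
    z±: 1 ∓ (h/2) g_z,

and A_z the optional B_z coupling −(h/4)(g_x+i g_y)(Z_{z+}−Z_{z−}) +
(h/4) g_z[(Z_{x+}−Z_{x−}) + i(Z_{y+}−Z_{y−})].  Boundary voxels are
pinned to the measured field (Dirichlet); ε_c is extended by copy-edge
replication where a stencil neighbor leaves Ω, which realizes the
homogeneous Neumann condition ∇ε_c = 0 and removes any need for EP
knowledge on or beyond ∂Ω.  With homogeneous EPs every weight is 1 and
the scheme is a damped neighbor average.

The log-gradient uses the principal branch of the complex logarithm,
which is safe because Re ε_c > 0 and Im ε_c ≤ 0 confine arg ε_c to
(−π/2, 0]; no branch crossing can occur between neighboring voxels.

## Solvers

* `predict_b1` — Jacobi (simultaneous) relaxation of the recurrence.
  Jacobi matches the matrix form above exactly and is order-independent,
  hence bit-deterministic.  Gauss–Seidel or SOR would converge faster but
  change iteration semantics, so they are not offered.
* `direct_solve` — sparse LU factorization of (diag(denom) − A) on the
  interior unknowns (SuperLU with symmetric-pattern minimum-degree
  ordering; the default column ordering exhausts memory on 3-D domains
  beyond ~40³).  It is the oracle for the relaxation and the engine of
  the synthetic reference-field generator.
* `analytic_plane_wave` — B(z) = exp(−ikz), k = ω√(μ₀ε_c), Im k ≤ 0, the
  closed-form solution in a homogeneous medium, used for validation.  On
  the grid its Laplacian is exactly 2(cos kh − 1)/h² per axis, so the
  discrete solution differs from it only by the dispersion bias
  ≈ (kh)²/12, which fixes the attainable validation tolerance.

### Stopping rule

The convergence limit C (default 10⁻⁶) bounds the *distance to the fixed
point*, not merely the last update.  For a contraction with factor ρ the
error after an update of size u is at most u·ρ/(1−ρ); the solver
estimates ρ as the geometric-mean update ratio over an 11-iteration
window and stops when that bound drops below C (`stop_rule =
"fixed_point_error"`).  The raw per-iteration criterion max|B_{i+1}−B_i|
< C is available as `stop_rule="update_norm"`, but on a domain of
diameter ~30 voxels it leaves a fixed-point error of roughly C/(1−ρ) ≈
10²·C, which would defeat the purpose of quoting C as an accuracy: the
default rule is what makes the relaxation agree with the direct solver to
~C.  The convergence statistic is max|ΔB| by default; the 90th percentile
is available and behaves equivalently on all test problems.

Initialization is the complex constant 1·e^{i·1} ("magnitude and phase
both 1"); read literally, this means phase = 1 rad, and it is
configurable because the fixed point is independent of the start — only
the iteration count changes.  Re-feeding a converged result converges
immediately.

## EPT reconstructions

The evaluator needs reconstructions to evaluate.  Three standard local
methods are included, all based on the symmetric 3-point second
difference [1, −2, 1]/h² per axis:

* complex Helmholtz: ε_c = −∇²B1+/(ω²μ₀B1+);
* phase-only: σ = ∇²ϕ+/(ωμ₀)  (phase must be unwrapped; no unwrapping
  algorithm is shipped — synthetic phases are generated unwrapped and
  measured phases are assumed pre-unwrapped);
* magnitude-only: ε_r = −∇²|B1+|/(|B1+| ω²μ₀ε₀).

Denoising uses a spherically shaped mean filter whose *diameter* is 11
voxels (radius 5); the alternative reading, an 11-element kernel, is
obtainable by configuring the diameter.  A voxel is valid only where the
full stencil (or kernel) stays inside Ω; partial kernels renormalize over
the valid support instead of zero-padding, so constant regions are
reproduced exactly and the classic EPT boundary artifact is not an
artifact of padding.

## Evaluation maps

With B̂ the predicted and B the measured field (both magnitude-normalized
to max 1 over Ω):

    D_ϕ = wrap(∠B̂ − ϕ),       D_B = |B̂| − |B|,
    L_ϕ = ∇²S(D_ϕ)/(ωμ₀),     L_B = ∇²S(D_B)/(ω²μ₀ε₀),

where S is truncated Gaussian smoothing, std 4 voxels in an 11-voxel
kernel, renormalized over valid voxels at mask edges (a constant D maps
to exactly zero L everywhere, preserving the null test at boundaries).
The Laplacian is the same 3-point kernel as the reconstructions, for
internal consistency.  L_ϕ converts a phase discrepancy into the
conductivity error that would explain it; its median over valid voxels
(L_ϕ^off, midpoint convention for even counts) indicates a global offset
in the input conductivity, and display masks at |L_ϕ| > 0.1 S/m
(phantoms) or 0.2 S/m (in-vivo-like) hide noise-level values.  MAE
summaries of D default to the full valid Ω, with an optional sub-region.

### Roughness

The noise-robustness check uses a roughness statistic defined as the
median over interior voxels of |B − mean(6 neighbors)|.  A plain
first-difference statistic would be dominated by the smooth phase ramp of
any propagating wave (≈ kh per voxel, larger than the noise floor), and
would say nothing about noise; the deviation from the local neighbor
average is trend-free — ≈ (kh)²/6 for a smooth wave — and responds
directly to voxel-level noise, which is the property under test.

## Synthetic data

The generator replaces full-wave coil simulation and MRI acquisition so
every experiment runs self-contained:

* **Phantoms.**  A two-compartment sphere — outer radius 80 mm with
  σ = 0.8 S/m, ε_r = 70, inner off-center sphere of radius 40 mm with
  σ = 0.3 S/m, ε_r = 60 — plus a uniform sphere (defaults σ = 0.61,
  ε_r = 78, the saline-phantom values), and a *geometric* brain-like
  phantom: nested smooth ellipsoids carrying white-matter / gray-matter /
  CSF values (σ = 0.35 / 0.69 / 2.26 S/m, ε_r = 51 / 73 / 80) with
  ventricle-like CSF lobes and an optional three-compartment tumor
  (σ = 0.7 / 0.9 / 1.2 S/m, ε_r = 60 / 70 / 80).  It is a stand-in with
  realistic tissue values and interfaces, not an anatomical model.
  Membership is by voxel center; Ω is the phantom support.
* **Reference fields.**  The ground-truth field is the direct solution
  of the same FD system under a synthetic boundary drive (a plane wave
  with a mild cosine transverse modulation, default strength 0.2, which
  supplies the transverse phase curvature a coil profile has — without
  it the center of the phantom is nearly insensitive to EP errors).
  Generating the reference with the same discretization makes
  forward/inverse consistency exact by construction and isolates
  EP-error detection from model error; emulating FD-vs-full-wave model
  error is possible by generating the reference on a finer grid and
  downsampling, but is not part of the default conditions.
* **Noise.**  Gaussian noise on the real and imaginary parts: for |B1+|
  with std = mean(|B1+| over Ω)/SNR at SNR 50; for the phase via a
  synthetic T1-weighted carrier (piecewise-constant per compartment,
  levels 0.5–1.5) at SNR 80, phase retaken from the noisy complex image.
  SNR is defined as mean signal magnitude over Ω divided by the
  per-channel std — the convention is configurable since definitions
  vary.  Noise applies to measured/reference fields only, never to EP
  inputs.
* **Transceive phase.**  ϕ± = wrap(ϕ+ + ϕ−), with the receive phase from
  a mirror model (reversed polarization approximated by a spatial
  mirror) or a smooth-bias model (ϕ− = ϕ+ plus a low-order polynomial of
  configurable peak amplitude, zero making the ϕ±/2 assumption exact).

What passing tests on these data do *not* show: performance under real
coil field structure, B₀/B₁ system imperfections, imperfect phase
unwrapping, anatomical geometry, or FD-vs-reality model error.  They do
show that the solver reproduces the field its physics implies, and that
the D/L machinery detects and localizes EP errors of stated size under
realistic noise.

## Problem sizes and defaults

The reference experiments run on ~1–2·10⁶-voxel domains; the packaged
experiment suite (`b1eval.experiments`) uses scaled-down analogues chosen
so the full suite runs in minutes on one CPU:

* homogeneous validation: 48³ cube, h = 2 mm, σ = 0.5, ε_r = 78;
* half-scale two-compartment sphere: radius 44 mm at h = 2 mm on 48³
  (null-vs-offset contrast, noise robustness);
* quarter-scale spheres: radius 75 mm at h = 5 mm on 32³ (oracle
  equivalence, offset sweep, anomaly sensitivity; anomaly sizes are
  specified in voxels, 9–21, matching the 9–21 mm originals at 1 mm).

Geometry proportions, tissue values, SNRs, C, smoothing and filter sizes
are kept at their reference values throughout.  In the experiment suite,
MAE statistics are taken over interior voxels and against the clean
ground-truth reference: the boundary layer is copied measurement data in
every prediction (it carries no information about the EPs under test),
and measurement noise enters a prediction only through its boundary
condition, so comparing against the clean truth is what isolates the
effect of EP errors from the reference's own noise floor.

## Numerical choices and edge cases

* Degenerate domains (no interior voxel) are rejected at mask build.
* |B1+| < 10⁻¹² invalidates a voxel in Helmholtz inversion; a vanishing
  Laplacian yields ε_c ≈ 0, surfaced as a "nonphysical" warning rather
  than clipped.
* Phase wrapping ties: wrap(π) = π by the principal-value convention;
  antisymmetry of phase differences holds except exactly at ±π.
* Median with even counts uses the numpy midpoint convention.
* All randomness flows through explicit integer seeds; identical
  (config, seed) reproduce outputs bit-for-bit.

## Known limitations

* 2-D solving is deliberately unsupported (dropping the third dimension
  degrades the physics).
* Jacobi convergence degrades as O(h²/L²); domains much beyond 10⁶
  voxels need patience or the measured field as initialization.
* The brain-like phantom's geometry is schematic; tumor/tissue contrast
  is realistic, shape is not.
* No phase unwrapping, no transceive-phase correction beyond ϕ±/2, no
  EP-update iteration from the discrepancy maps (evaluation only).
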