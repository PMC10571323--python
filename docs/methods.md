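# Methods

## Model

monocard solves the monodomain description of cardiac tissue
electrophysiology: on a domain Ω ⊂ R³ partitioned into labelled subdomains
Ω_i,

    ∂u/∂t + I_ion(u, w_i) − ∇·(D_i ∇u) = I_app(x, t)   in Ω_i,
    dw_i/dt = H_i(u, w_i)                               in Ω_i,

with homogeneous Neumann conditions on ∂Ω (electrically isolated tissue)
and flux continuity across subdomain interfaces — both natural in the weak
form, so no boundary bookkeeping exists anywhere in the code.  The
diffusion tensor is built from the local orthonormal fiber frame,

    D_i = σ_l f₀⊗f₀ + σ_t s₀⊗s₀ + σ_n n₀⊗n₀,

whose eigenvalues are exactly the three conductivities (m²/s).  A subdomain
may be flagged non-conductive: its elements are excluded from assembly and
its interior DOFs from the solve entirely, creating a conduction block
(scar); DOFs shared with a conductive neighbour are retained (a choice —
the continuous problem does not determine the discrete treatment of such
interface DOFs).

The equations are written in the capacitance-rescaled form: I_ion, I_app
carry units of potential per second and D of m²/s.  Literature values given
as Î (A/m²-type) and D̂ (S/m) convert through Î/C_m and D̂/(χ_m C_m); the
conversion is a single function (`normalize_formulation`), and the
parameter-file interface applies it from the `Membrane scaling` section
(defaults C_m = χ_m = 1, i.e. file values are already rescaled).

## Ionic models

Four membrane models are transcribed from their original publications, each
with its published parameter table and resting initial condition:

| model | variables | native units | role |
|---|---|---|---|
| Aliev–Panfilov | 1 | dimensionless, 1 t.u. = 12.9 ms | phenomenological excitation–recovery |
| Bueno–Orovio (epi/endo/M sets) | 3 | dimensionless, ms | minimal human ventricular |
| ten Tusscher–Panfilov 2006 (epi/endo/M cell types) | 18 | mV, ms, mM | detailed human ventricular |
| Courtemanche–Ramirez–Nattel | 20 | mV, ms, mM | detailed human atrial |

All unit conversion between a model's native units and the tissue solver's
SI units lives in four small adapter methods on the model base class; the
model files themselves transcribe the published equations verbatim.  The
dimensionless potentials map to millivolts for output via u_mV = 100u − 80
(Aliev–Panfilov) and u_mV = 85.7u − 84 (Bueno–Orovio).

Conventions worth noting:

* Removable singularities in rate expressions (e.g. the L-type calcium
  driving force at V = 15 mV, the CRN α_m at V = −47.13 mV) are evaluated
  by their analytic limits on a guarded branch.
* The stimulus current is not added to the potassium balance of the
  detailed models (some 0D references include I_stim in dK_i/dt).  This
  keeps the 0D integrator exactly equivalent to the tissue stepper, at the
  cost of a slow K_i drift under very long pacing protocols.
* Published resting states are near- but not exact equilibria: unpaced,
  TTP06 drifts 0.3 mV and CRN 0.009 mV over 1 s; Aliev–Panfilov (0,0) and
  the Bueno–Orovio potential rest exactly.  Tests that demand machine-level
  equilibrium preservation therefore use Aliev–Panfilov.

## Time discretization

BDF schemes of order σ ∈ {1,2,3} with matching explicit extrapolation.  Per
step: (i) gating variables — every variable whose dynamics is affine in
itself at frozen potential, which includes the 12+15 Hodgkin–Huxley gates,
the TTP06 release gate R̄ and the CRN release gates u, v, w — are advanced
by closed-form inversion of the BDF relation with w∞, τ evaluated at
(u_EXT, w_EXT); concentrations and the Aliev–Panfilov recovery variable are
advanced explicitly from extrapolated arguments.  No Newton iteration
exists anywhere.  Gates are clamped to [0,1] after the update (guards
against extrapolation overshoot; occurrences are counted and logged).
(ii) I_ion is evaluated nodally at (u_EXT, w_{n+1}) and enters the PDE via
the subdomain mass matrices (ionic current interpolation, ICI), and one
linear solve with the constant matrix A = (α_BDF/Δt)M + K yields u_{n+1}.
The right-hand side uses (1/Δt) M u_BDF,n, the form consistent with the BDF
derivative approximation (recovering backward Euler at σ = 1).

Runs requested at order σ bootstrap with orders 1, …, σ−1 for the first
σ−1 steps (extrapolation order raised alongside).  Order verification on
u' = −u therefore initializes the history with exact solution values, the
standard device for observing the nominal rate of the σ = 3 scheme.

## Space discretization

Lagrange elements: Q_p (any p ≥ 1) on hexahedra, P_1/P_2 on tetrahedra.
Quadrature is the minimum rule that integrates the mass matrix exactly on
affine elements: (p+1)³ tensor Gauss–Legendre points per hexahedron and a
conical-product Gauss–Jacobi rule of matching degree per tetrahedron
(exactness verified against analytic monomial integrals).  The mass matrix
is consistent — never lumped.  For trilinear hexahedra the exactness claims
hold on parallelepiped elements; the same rule is applied to general hexes.

The nodal fiber frame is interpolated to quadrature points by the FE basis
and re-orthonormalized there (Gram–Schmidt with fiber priority), so the
assembled conductivity tensor keeps eigenvalues {σ_l, σ_t, σ_n} exactly at
every quadrature point.

### Partition-stable ICI assembly

The reaction vector s_{n+1} = Σ_i M^i I^i_ion is accumulated element by
element, in global element order, from precomputed element mass blocks
(`numpy.bincount` over flattened DOF indices, whose accumulation order is
deterministic).  This is algebraically identical to the subdomain-matrix
product but makes the floating-point result independent of how the domain
is partitioned: splitting a homogeneous domain into several subdomains with
identical properties reproduces the unpartitioned trajectory bit for bit,
which is how the test suite verifies that interface handling ("continuity
of flux") introduces no artefacts.  M and K are likewise assembled from the
single global conductive-element list.  At interface DOFs shared by two
subdomains, each subdomain integrates its own copy of w (u is shared).

## Linear solver

A is symmetric positive definite on the active DOFs and assembled once per
run (one matrix per effective BDF order during bootstrap).  Default:
conjugate gradients, relative residual 1e-10, preconditioned by an
incomplete LU factorization (`scipy.sparse.linalg.spilu`, drop tolerance
1e-4, fill factor 10) computed once — on the 58k-DOF benchmark grid this
needs ~3 iterations/step versus ~50 with Jacobi.  Jacobi, unpreconditioned
CG and a full sparse-LU "direct" mode remain selectable; direct is
attractive only for small problems (3D fill-in).  The activation times of
the benchmark are insensitive to the CG tolerance well beyond the default
(discretization-dominated).

## Stimuli

I_app(x,t) = Σ_i amplitude_i · g_t^i(t) · g_x^i(x) with indicator shapes
(cube, sphere, plane slab — boundary inclusive) or a Gaussian normalized to
peak 1 so the amplitude is read directly in V/s.  Time gates are half-open
[t₀, t₀+duration), so a pulse ending exactly on a step boundary fires once;
pulse trains are given as explicit start-time lists or a (period, count)
shorthand.  g_x is evaluated at DOF support points and carried through the
mass matrix, consistent with the ICI treatment of the reaction term.

## Activation mapping

The activation time of a DOF is the time at which the discrete backward
difference ∂u/∂t attains its maximum, tracked online (no history stored);
the first occurrence wins on ties.  A DOF counts as activated only if its
maximal rate exceeds a threshold (default 10 model-units/s) — DOFs that
never depolarize (e.g. behind a conduction block) report a NaN sentinel.

## Checkpointing

`checkpoint`/`restore` serialize the full history (u and per-subdomain w
stacks, step index, activation tracker) with a metadata header (mesh hash,
Δt, scheme order, model names); restoring onto a different mesh or
discretization is rejected.  Because the stepper is deterministic, a run
checkpointed at half time and resumed reproduces the uninterrupted
trajectory to the last bit.

## The slab benchmark

The verification surface is the community N-version benchmark: a
3×7×20 mm slab, fibers along the long axis, transversely isotropic
conduction with σ = harmonic mean of intra-/extracellular values divided by
χ_m C_m = 1400 (σ_l = 9.530e-5, σ_t = σ_n = 1.258e-5 m²/s), TTP06
epicardial membrane, and a 2 ms, 35.714 V/s stimulus in a (1.5 mm)³ corner
cube.  The harness samples activation at 50 points of the P1→P8 diagonal
(trilinear interpolation on the structured lattice), at P1 (stimulated
corner), P8 (opposite corner) and P9 (centroid), and reports the latest
activation over the slab.  Tetrahedral runs split each cell into six Kuhn
tetrahedra (conforming across faces).

Problem sizes used routinely (BDF2, p = 1, hexahedra): dx = 0.5 mm /
Δt = 0.05 ms (4 305 DOFs, run to 70 ms since the under-resolved transverse
wavefront delays the far corner to ≈62 ms on this grid) and dx = 0.2 mm /
Δt = 0.01 ms (58 176 DOFs, 5 000 steps, ≈7 min on one CPU), where the slab
fully activates at 42.9 ms and P8 already sits in the 42–43 ms cross-code
converged band.  The finer study points (dx = 0.1 mm ≈ hours, 0.05 mm ≈
days on one CPU) are exercised by `scripts/benchmark_convergence.py`.
Consistent with the published convergence behaviour, activation times
decrease monotonically under refinement here (measured transverse CV: 0.13
→ 0.21 → 0.23 m/s at dx = 0.5/0.2/0.1 mm; longitudinal ≈ 0.6 m/s already
at dx = 0.5 mm).

## Anisotropy verification

The monodomain scaling law CV ∝ √σ is checked on a 12×0.4×0.4 mm bar at
dx = 0.05 mm with the Bueno–Orovio model, comparing plane waves running
along x when x carries σ_l = 2e-4 versus σ_t = 5e-5 m²/s.  The σ-ratio of 4
is chosen so that both wavefronts are resolved on a grid that runs in
minutes; with the benchmark's ratio of 7.6 the transverse front (≈0.08 mm
wide) would need dx ≈ 0.02 mm.  Measured ratio: 1.991 vs √4 = 2 (0.43%).

## What the synthetic experiments do and do not show

All verification inputs are generated in code (structured slabs, rule-based
or constant fiber frames, square pulses); there are no measured geometries
or imaging-derived fiber fields.  Passing tests therefore demonstrate the
correctness of the discretization, the cell models and the subdomain
machinery under controlled conditions — not fidelity to any particular
patient anatomy, realistic fibrosis distribution or clinically calibrated
conduction map.  Mesh import (gmsh MSH v2.2/v4.1, VTU with volume labels,
arbitrary rescaling to meters) and fiber import (normalized VTU point-data
arrays) are round-trip tested so that such data can be supplied when
available.

## Known limitations

* Shared-memory, single-process execution only; no distributed parallelism.
* Tetrahedral spaces stop at p = 2; hierarchical refinement exists for
  hexahedra only.
* The slab transmural rule is the only built-in fiber generator; full
  ventricular/atrial Laplace–Dirichlet rule-based methods must be computed
  externally and imported.
* ICI is the only reaction-assembly mode (no SVI), mirroring the reference
  discretization choice.
* Benchmark diagonal sampling assumes the structured slab lattice (p = 1).
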