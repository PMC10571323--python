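# monocard

Finite-element simulation of cardiac tissue electrophysiology with the
monodomain model, for researchers who need a compact, scriptable solver to
study action-potential propagation in slabs and imported heart geometries —
including heterogeneous and pathological tissue — without a C++/MPI stack.

## The model

The transmembrane potential u and the ionic state **w** evolve as

    ∂u/∂t + I_ion(u, **w**) − ∇·(D ∇u) = I_app(x, t),
    d**w**/dt = H(u, **w**),
    D = σ_l f₀⊗f₀ + σ_t s₀⊗s₀ + σ_n n₀⊗n₀,

on a tetrahedral or hexahedral mesh partitioned into labelled subdomains,
each with its own ionic model, parameter overrides and conductivities
(non-conductive regions model scar tissue as conduction blocks).  The
cellular layer provides Aliev–Panfilov, Bueno–Orovio, ten Tusscher–Panfilov
2006 and Courtemanche–Ramirez–Nattel, transcribed from their original
publications.  Time integration is implicit–explicit BDF (orders 1–3):
gating variables by closed-form inversion, the PDE by one preassembled SPD
solve per step with ionic current interpolation (ICI).  Internally all
quantities are SI (m, s, V); mesh/fiber files in other units are rescaled
at import.  See `docs/methods.md` for the complete numerical description.

## Worked example: the N-version slab benchmark

The standard verification problem for cardiac tissue solvers is a
3×7×20 mm slab, fibers along the long axis, paced by a 2 ms, 35.714 V/s
stimulus in a (1.5 mm)³ corner cube, with the ten Tusscher–Panfilov 2006
epicardial model.  The quantity of record is the activation time — when
∂u/∂t peaks — at the stimulated corner P1, the opposite corner P8 and the
centroid P9:

```bash
$ monocard benchmark --dx 0.5e-3 --dt 0.05e-3 --final-time 0.07 -o bench.json
P1 1.250 ms, P9 27.100 ms, P8 62.350 ms
latest activation 62.350 ms (complete)
```

The wave leaves the stimulated corner at 1.25 ms, reaches the centroid at
27.1 ms and the far corner last — on this deliberately coarse 0.5 mm grid
at 62.35 ms, roughly 50% late because the transverse wavefront (≈0.1 mm
wide) is unresolved.  One refinement (`--dx 0.2e-3 --dt 0.01e-3`, ≈5 min)
brings the latest activation down to 42.93 ms, inside the 42–43 ms band
that established community codes converge to; the finest study grids
(`scripts/benchmark_convergence.py`, hours) continue the same monotone
trend.  The JSON file also carries the activation profile along the
P1→P8 diagonal for plotting.

The same study is available from Python:

```python
from monocard.bench import run_niederer_benchmark
res = run_niederer_benchmark(0.2e-3, 0.01e-3, T=0.045)
print(res.p8_ms, res.latest_ms)   # 42.93 42.93
```

## General simulations

Simulations are configured through self-documenting parameter files, with
one section per tissue region (`-vol` labels must match between generation
and run):

```bash
monocard generate-params full -o case.prm -vol Healthy -vol Fibrosis -vol Scar
# edit case.prm: mesh file + scaling factor, conductivities, ionic model
# and overrides per region, stimuli, fibers (slab rule or VTU import), ...
monocard run -f case.prm -vol Healthy -vol Fibrosis -vol Scar
```

Outputs are VTU snapshot series (potential in model units and millivolts),
activation maps (VTU + CSV) and CSV min/max/probe traces.  The library API
(`MonodomainProblem`, `run_simulation`, `single_cell_run`, …) exposes every
building block for scripted studies; long runs can be checkpointed and
resumed bit-exactly.

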