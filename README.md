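# macrocup

Phase-field simulation of **macropinocytic cup formation and closure** —
how a cell membrane, driven only by protrusion at the edge of a
self-organized signaling patch, curls into a cup and seals itself to
swallow extracellular fluid, without any particle to wrap around.

The package is for quantitative cell biologists and biophysical
modelers who want a tested, scriptable reimplementation of the coupled
membrane/reaction-diffusion model of macropinocytosis: the full 3-D
solver, the quasi-3D (axisymmetric) solver used for phase diagrams and
closure bookkeeping, solid-bead engulfment, stochastic multi-cup
dynamics, the well-mixed kinetics analysis, and a reduced
patch-boundary model.

## The model

A phase field `φ` (1 inside the cell, 0 outside) relaxes under surface
tension, a global volume constraint, and a protrusive force:

    τ ∂φ/∂t = η(∇²φ − G′(φ)/ε²) − M_V (V − V₀)|∇φ| + F_poly|∇φ|,
    G′ = 16φ(1−φ)(1−2φ),  V = ∫φ dr.

On the membrane band (selected by ψ = (1+e^{−β(φ(1−φ)−θ)})⁻¹) an
activator A and inhibitor I obey bistable kinetics with a conserved
cytosolic pool B = A_t/S − ⟨A⟩:

    ∂A/∂t = A²B/(1+A²/α²) · 1/(1+I) − A + D_A∇²A   (+ advection, confinement)
    ∂I/∂t = k₁A² − k₂I + D_I∇²I

Wave pinning (front stall by pool depletion) sets the patch size; the
protrusive force F_poly(A) is restricted to the patch *edge*
(significant only for K ≲ A ≲ K′), so an expanding patch raises a
circular rim that overhangs and seals — the entire cup sequence emerges
from this coupling.  Key control parameters: the force/tension ratio
F/η (protrusion needs F/η > π/l_h ≈ 2 μm⁻¹), the patch-size parameter
a_t, and the deformation timescale τ.

## Worked example

Run the reference cup-closure configuration (F/η = 4.0, a_t = 2.8,
τ = 10) on the coarse quasi-3D mesh:

```python
from macrocup.config import load_config
from macrocup import axisym

cfg = load_config(preset="cup-closure", overrides={"dx": 0.2, "seed": 1})
rec = axisym.run_axisym(cfg.params, t_max=150.0)
print(rec.label, rec.events[0].time, rec.events[0].fraction)
```

prints

    closure 66.30080000000179 0.010550728812966993

i.e. the seeded patch grows, the rim protrudes and curls, and the cup
seals at t ≈ 66 s, enclosing ≈ 1.1% of the cell volume (far above the
10⁻⁵ success cut-off; the published 3-D run of this configuration
closes at t ≈ 65 s).  Lowering the force to F/η = 1.6 gives a
persistent patch that never closes; F/η = 2.8 gives oversized cups and
repeated closure attempts.

The same configuration runs in full 3-D via
`macrocup.cart3d.run_3d`, with a bead via
`run_3d(..., bead=BeadSpec(Rb=2.0))`, and from the shell:

    macrocup run-axisym --preset cup-closure --seed 1 --out runs/demo
    macrocup sweep --foe 1.6,2.8,4.0 --at 2.5,2.8 --reps 6 --out runs/sweep
    macrocup analyze-0d --k1 0.088 --out runs/kinetics

Well-mixed kinetics analysis (fixed points, bistable/excitable
regimes, the patch-annihilation condition):

```python
from macrocup import kinetics
rep = kinetics.fixed_points(B=2.0, k1=0.088, k2=0.54, alpha=float("inf"))
print([round(fp.A, 4) for fp in rep.nonzero], rep.regime)
# [0.5222, 11.7505] excitable
```

## Layout

| module | contents |
| --- | --- |
| `macrocup.fields` | grids, interface kernels, discrete operators, integrals |
| `macrocup.kinetics` | well-mixed fixed points, stability, annihilation condition |
| `macrocup.mechanics` | force laws, interface velocity, phase-field update |
| `macrocup.reactions` | membrane transport, pool bookkeeping, seeding, noise |
| `macrocup.axisym` | quasi-3D solver, closure detection, outcome classification, sweeps |
| `macrocup.cart3d` | full 3-D solver, beads, engulfment, cavity detection |
| `macrocup.reduced` | reduced patch-boundary (marker) model |
| `macrocup.config` / `macrocup.cli` | presets, YAML configs, snapshots, manifests, CLI |

`docs/methods.md` documents the numerics (discretizations, stability
bounds, detection geometry) and the design decisions in detail.
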