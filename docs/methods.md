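# Model and numerical methods

## The model

`macrocup` simulates macropinocytic cup formation as the coupling of two
processes on a single moving interface:

1. **Membrane mechanics.** The cell is described by a phase field
   `phi(x, t)` (1 inside, 0 outside) whose level set `phi = 0.5` tracks
   the plasma membrane.  `phi` relaxes under

       tau dphi/dt = eta (lap phi - G'(phi)/eps^2)
                     - MV (V - V0) |grad phi| + Fpoly |grad phi|,

   with the double-well derivative `G' = 16 phi(1-phi)(1-2phi)`, cell
   volume `V = int phi`, target volume `V0 = 4 pi R0^3/3`, cortical
   tension `eta` (nN/um), volume stiffness `MV`, and a protrusive force
   density `Fpoly` generated by dendritic actin polymerization.  The
   interface has width `eps` (0.8 um), playing the role of the
   membrane-plus-cortex layer.  Sign conventions are fixed once:
   outward normal `n = -grad phi/|grad phi|`; tension shrinks a sphere
   at normal speed `-2 eta/(tau R)`; positive `Fpoly` pushes outward.
   Bending energy is neglected: for micrometer-scale protrusions the
   bending/surface energy ratio is `Kb/(2 eta r^2) ~ 1e-3`.

2. **Patch biochemistry.** An activator `A` (active GTPase/PIP3
   analogue) and an inhibitor `I` live on the membrane band, selected
   by the auxiliary indicator
   `psi = 1/(1 + exp(-beta(phi(1-phi) - theta)))` (`beta = 100`,
   `theta = 0.105`), which is ~1 in a band of width ~`eps` around the
   interface.  The kinetics are bistable with a conserved pool:

       dA/dt = A^2 B / (1 + A^2/alpha^2) * 1/(1 + I) - A  (+ transport)
       dI/dt = k1 A^p - k2 I                              (+ transport)

   with `p = 2` by default (the linear variant `p = 1` is exposed but
   does not support the excitable splitting phenomenology).  The
   inactive pool `B` is global (fast cytosolic diffusion):
   `B = At/S - <A>`, where `S = int psi/eps` is the instantaneous
   surface area, `At = at * 4 pi R0^2`, and `<A>` is the psi-weighted
   mean of A.  This enslavement conserves `<A> + B = At/S` exactly by
   construction; the residual audit in the run time series tracks the
   discretization drift of `S` only.

   Wave pinning arises because an expanding high-A domain depletes B
   until the front stalls; the patch size is set by `at`.  For
   unsaturated autocatalysis (large `alpha`) the system is excitable
   rather than bistable when `k2 < 1`: the nonzero fixed point
   `A+ = (B + sqrt(B^2 - 4 k1/k2))/(2 k1/k2)` is unstable (the
   Jacobian trace at `A+` is exactly `1 - k2` in the
   `alpha -> inf` limit), and small perturbations of the rest state
   trigger large transient excursions.

3. **The protrusive force law** localizes force to the patch *edge*:

       edge law:       Fpoly = F (A/K)^nh/(1+(A/K)^nh) * 1/(1+(A^2/K')^nh)
       inhibited law:  Fpoly = F (A/K)^nh/(1+(A/K)^nh) * 1/(1+(I/K')^nh)

   The edge law turns on near `A ~ K` and off above `A ~ K'`, so only
   the rim of a patch (where A traverses the window) protrudes; the
   defaults (K = 0.005, K' = 0.25, nh = 3) put the protrusive rim width
   at ~1.5 um, hence the minimal-force estimate `F*/eta = pi/l_h ~ 2.0
   um^-1`.  The inhibited law suppresses force where the inhibitor has
   accumulated instead, which restricts force to the *leading* edge of
   a traveling patch.  The second factor of the edge law uses `A^2/K'`
   verbatim from the source model (dimensionally odd, but kept as
   printed).

## Discretization

Uniform Cartesian meshes: a full 3-D box (default 25.6 um at
dx = 0.2 um) and a quasi-3D axisymmetric z-r half-plane (default
Lr = 15 um, Lz = 40 um, cell centred on the axis) used for exhaustive
parameter sweeps and closure bookkeeping.  All updates are explicit
Euler.  Spatial operators are second-order central differences, with
the axisymmetric forms `lap = r^-1 d/dr(r d/dr) + d2/dz2`
(on-axis limit `2 d2/dr2 + d2/dz2`) and the conservative upwind flux
form for membrane advection `-div(c v)`.  Boundary conditions:
Neumann symmetry on the axis, Dirichlet `phi = A = I = 0` on the other
axisymmetric boundaries, no-flux on all faces in 3-D.

**Membrane-confined transport.**  The species are solved only where
`psi > 1e-3`; elsewhere they decay at `gamma2 = 10 s^-1`.  The
transport operator combines bulk diffusion with the confinement drift
`D beta (1-psi)(1-2 phi) grad(phi).grad(c)` (analytically
`D (grad psi/psi).grad(c)`).  We discretize their *sum* in
conservative flux form,

    (1/psi) div(psi grad c)  ->  face flux D psi_f (c_nb - c_i)/dx,
    psi_f = geometric mean of the adjacent psi,

rather than the expanded drift + Laplacian: the drift's cell Peclet
number reaches ~6 at dx = 0.2 near the band skirt, where the expanded
central form develops node-to-node oscillations (activator spikes of
10-50, held only by the clamp) that corrupt the front dynamics under
deformation.  The flux form is monotone, exact for the exponential
psi profile, and reproduces the expanded form under refinement (the
test suite verifies mutual convergence).  The geometric face mean is
additionally capped at 8x the smaller adjacent psi so the explicit
diffusion stability bound is respected on very coarse meshes; the cap
is inactive for dx <= 0.2.

**Time step.**  `dt = 4e-4 s (dx/0.1 um)^2` from the diffusion bound,
further capped by `tau/(MV 4 pi R0^2)`: the global volume constraint
relaxes V at rate `~ MV S/tau`, which does not shrink with the mesh,
and exceeding its stability bound destroys coarse-mesh runs.  A and I
are clamped to [0, 50] after each step, and velocities are zeroed
where `|grad phi| <= 1e-3`.

**Closure detection.**  Along the line r = dx, the number of 0 -> 1
transitions of thresholded phi (threshold 0.5), scanned from z = Lz to
0, equals 2 exactly when an enclosed extracellular region exists.  The
enclosed volume integrates, per z-slice between the two transition
heights, the vacant disc (or annulus when cell material sits on the
axis) with 2 pi r weights, counting only runs bounded by cell material
on the outside.  Closure events are debounced: a new event is
registered only when the transition count rises to 2 or beyond (a
count above 2 means a new cavity sealed while an earlier vesicle still
persists on the scan line).  In 3-D, enclosed
cavities are connected components of `phi < 0.5` not touching the
domain boundary.  An enclosure is a successful uptake when its volume
exceeds 1e-5 V0; runs are classified closure / small-closure /
repetitive (>= 2 events) / no-closure.

**Protocol.**  Runs start from a volume-constrained sphere with
A = I = 0 except a seeded patch of radius `rinit` (1.0 or 1.5 um) at
the top pole where A ~ U(0, 5) per node; elapsed times are measured
from seeding.  Default horizon 600 s; a run also ends once max A stays
below 1e-3 for 5 s (patch extinction).  Stochastic nucleation adds
Gaussian bumps `N0 exp(-|x-xc|^2/2 d^2)` at Poisson rate
`lam V_domain`, N0 ~ Exponential(mean sigma), xc uniform in the
domain, applied on the membrane band; `d` is interpreted in um
(1.5 um = 15 lattice units of the reference mesh).  One RNG per run,
seeded from the configuration, drives seeding and nucleation.

**Beads.**  A rigid particle is the static field
`chi = (1 + tanh((Rb - |r - rb|)/(eps/2)))/2` with excluded-volume
force `-Arep chi^2 phi` and adhesion `+Aatt |grad chi||grad phi|`.
Bead runs subtract a spatially uniform drift velocity
`v_d = -(1/(tau V)) int (r - rc) f_total dr` (and advect phi, A, I
with it) so the net force does not translate the cell.  Default
placement is tangent to the membrane on the seed-patch axis with gap
eps/2.  Engulfment is quantified as `int(chi phi)/int(chi)`, complete
at >= 0.95.  Bead phase sweeps are run in the axisymmetric solver
with the bead on-axis; the 3-D path is for representative runs.

## Reduced patch-boundary model

The reaction-diffusion system is replaced by a marker `rb` on the
phi = 0.5 contour.  `rb` is advected with the membrane and slides
tangentially at `vt (A0 - A)`, where `A` is the normalized membrane
area between `rb` and the symmetry axis on the patch side and `A0` is
the target patch size (the proxy for `at`).  The protrusion site `rp`
sits at arc length `dl` from `rb` on the patch side and exerts
`F f(rf - |x - rp|)`, `f(x) = 1/(1+exp(-2.5 x))`.  The contour is
extracted by marching squares each update interval (0.04 s), arc
lengths by piecewise-linear summation, and `rb` is re-projected onto
the contour by continuous orthogonal projection (vertex snapping would
quantize away the slow tangential motion).

The tangential speed `vt`, target area `A0`, offset `dl` and site
half-width `rf` are not constrained by the source model; the defaults
(vt = 1.0 um/s, A0 = 0.35, dl = 0.8 um, rf = 1.2 um) are package
choices calibrated to the full model's scales: `vt A0` matches the
full model's patch front speed (~0.3 um/s; an order of magnitude
slower and the protrusion outruns the patch edge, producing a runaway
finger instead of a cup), and `rf` is comparable to the protrusive rim
width of the full model (a site much narrower than the interface width
eps cannot deform it).  The placement of `rp` on the patch side of
`rb` mirrors the full model, where the force window K <= A <= K' lies
on the flank of the activator front, and is what lets the rim force
rotate inward (toward the axis) once the rim overhangs.

## What the synthetic runs do and do not show

The seeded-sphere initial condition, uniform-random patch seed, and
the bead/noise generators emulate the study conditions of the source
model, not real imaging data: the membrane is a single closed surface
with uniform tension, there is no substrate, no membrane turnover, no
fluctuating cortex, and the biochemistry is a two-species caricature.
Passing tests therefore demonstrate internal correctness of the
numerics (operators, conservation, detection geometry) and
reproduction of the model's published phenomenology (closure at the
reference Phase-I point, failure below the minimal force ratio,
inhibitor-limited patch lifetime), not agreement with experiments.

## Numerical choices, degenerate inputs, known limitations

- Coarse production mesh: dx = 0.2 um (half the reference resolution)
  for the axisymmetric phase-diagram work; front speeds and closure
  times agree with dx = 0.1 within ~10%.  The 3-D default is 128^3 at
  dx = 0.2; representative tests use smaller cells.
- The clamp A, I <= 50 interacts badly with fully unsaturated
  autocatalysis: at `alpha = inf` a seeded site saturates both fields
  at the clamp, and the state A = I = 50 is then self-sustaining
  whenever `50 B/51 > 1` (B > 1.02), walled in by its own inhibitor
  halo.  The excitable phenomenology (traveling pulses, re-ignition)
  is recovered at the finite table value `alpha = 50`, which the
  splitting scenario presets therefore adopt for simulation use;
  `alpha = inf` remains first-class for the well-mixed analysis,
  where no clamp applies.
- Azimuthal symmetry breaking (patch splitting into daughter patches
  around the ring, multi-cup coexistence) is outside the reach of the
  axisymmetric solver by construction; only full 3-D runs can show it.
- B is clipped at 0 (with a warning) if the activator total ever
  exceeds At; the clip is a conservation violation and does not occur
  in healthy runs.
- Degenerate inputs: rinit = 0 seeds nothing and the sphere is then an
  exact stationary state; zero-length closure bounds give zero volume;
  a lost phi = 0.5 contour terminates a reduced-model run.
- The axisymmetric Dirichlet walls require clearance: a cup rim can
  extend ~8 um above the resting sphere, which dictated the default
  Lz = 40 (10 um headroom).  Runs whose protrusions reach a wall are
  invalid (the Phase-I configuration stalled against the ceiling at
  Lz = 30).
- Sealing events at coarse resolution destroy part of the activator:
  the deep cup channel is narrower than ~2 eps, so the opposing
  membrane bands overlap, and when the channel collapses into cell
  interior the species stored there are removed by the off-band decay
  (their mass returns to the pool).  As a consequence the patch
  crashes (dx = 0.2) or dies (dx = 0.15) at the moment of closure, and
  re-formed cups at the repetitive-regime parameters do not seal again
  within practical horizons, even though the first closure time
  (~230 s) and the cyclic re-formation itself are reproduced.  In
  long force-sustained runs without a bead the cell also translates
  (the model conserves no momentum and bead-less runs apply no drift
  correction), which eventually carries it toward a domain wall.
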