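"""Quasi-3D (axisymmetric) cup solver: coupled integration, cup-closure
detection, enclosed-volume estimation and outcome classification.

A run starts from a volume-constrained sphere with a seeded activator
patch at the top pole, integrates the coupled phase-field /
reaction-diffusion system, scans for membrane enclosure events every
step along the line r = dx, and classifies the outcome:

- ``closure``       at least one enclosure with fraction >= 1e-5 of V0
- ``small-closure`` enclosure(s) below the success cut-off
- ``repetitive``    two or more enclosure events
- ``no-closure``    none within the horizon
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from . import _kernels, fields, reactions
from .params import SimulationParams, NoiseParams, BeadSpec

#: enclosed fraction of V0 above which a closure counts as successful
SUCCESS_CUTOFF = 1e-5
#: activator level below which the patch is considered extinct
EXTINCT_LEVEL = 1e-3
#: time the patch must stay extinct before the run terminates (s)
EXTINCT_HOLD = 5.0


@dataclass
class ClosureEvent:
    time: float          # s since patch seeding
    volume: float        # enclosed volume, um^3
    fraction: float      # volume / V0
    zb: float
    zt: float

    def __post_init__(self):
        if self.volume < 0 or self.zb > self.zt:
            raise ValueError("inconsistent closure event")


@dataclass
class OutcomeRecord:
    events: List[ClosureEvent]
    label: str
    t_final: float
    elapsed: Optional[float] = None      # seeding -> first closure (s)
    fraction: Optional[float] = None     # intake fraction (last event)
    efficiency: Optional[float] = None   # fraction per minute
    timeseries: Optional[pd.DataFrame] = None

    @classmethod
    def classify(cls, events, t_final, timeseries=None):
        if len(events) >= 2:
            label = "repetitive"
        elif any(ev.fraction >= SUCCESS_CUTOFF for ev in events):
            label = "closure"
        elif events:
            label = "small-closure"
        else:
            label = "no-closure"
        elapsed = events[0].time if events else None
        frac = events[-1].fraction if events else None
        eff = None
        if events and events[-1].time > 0:
            eff = events[-1].fraction / (events[-1].time / 60.0)
        return cls(events=list(events), label=label, t_final=t_final,
                   elapsed=elapsed, fraction=frac, efficiency=eff,
                   timeseries=timeseries)


@dataclass
class AxisymState:
    """Bundled fields and global scalars advanced by the solver."""
    grid: fields.AxisymGrid
    phi: np.ndarray
    A: np.ndarray
    I: np.ndarray
    B: float = 0.0
    V: float = 0.0
    S: float = 0.0
    t: float = 0.0

    @property
    def psi(self):
        return fields.compute_psi(self.phi)


def make_cell(p: SimulationParams, grid: Optional[fields.AxisymGrid] = None):
    """Volume-constrained spherical cell centred on the axis at
    z = Lz/2, with A = I = 0."""
    if grid is None:
        grid = fields.AxisymGrid.from_extents(p.Lr, p.Lz, p.dx)
    center = (0.0, grid.Lz / 2.0)
    phi = fields.init_sphere_phi(grid, center, p.R0, p.eps)
    A = np.zeros_like(phi)
    I = np.zeros_like(phi)
    st = AxisymState(grid=grid, phi=phi, A=A, I=I)
    st.V = fields.volume_of(phi, grid)
    st.S = fields.surface_area_of(
        fields.compute_psi(phi, p.beta, p.theta), grid, p.eps)
    st.B = p.at * 4.0 * math.pi * p.R0**2 / st.S
    return st


def seed_patch(state: AxisymState, p: SimulationParams, rng):
    """Seed the activator patch at the top pole (r=0, z = zc + R0)."""
    psi = fields.compute_psi(state.phi, p.beta, p.theta)
    reactions.seed_initial_patch(state.A, state.phi, psi, state.grid,
                                 p.rinit, rng)
    return state


def bead_fields_axisym(grid: fields.AxisymGrid, bead: BeadSpec, eps: float,
                       p: SimulationParams):
    """Static bead indicator chi and |grad chi| on the axisymmetric
    grid.  The default placement is tangent to the undeformed membrane
    on the seed-patch axis: center (0, Lz/2 + R0 + Rb + eps/2)."""
    center = bead.center
    if center is None:
        center = (0.0, grid.Lz / 2.0 + p.R0 + bead.Rb + eps / 2.0)
    r, z = grid.coords()
    dist = np.sqrt((r - center[0]) ** 2 + (z - center[1]) ** 2)
    e2 = eps / 2.0
    u = (bead.Rb - dist) / e2
    chi = 0.5 * (1.0 + np.tanh(u))
    gchi = (1.0 / np.cosh(u)) ** 2 / (2.0 * e2)
    return chi, gchi


def detect_closure(phi, dx, delta_r_cells: int = 1, thresh: float = 0.5):
    """Transition count and closure flag along the scan line
    r = delta_r_cells * dx.  Returns (count, flag, zt, zb)."""
    count, zt, zb = _kernels.closure_scan(phi, dx, delta_r_cells, thresh)
    return count, count == 2, zt, zb


def enclosed_volume(phi, dx, zb, zt, thresh: float = 0.5):
    """Enclosed extracellular volume between zb and zt (um^3)."""
    if zb < 0 or zt < zb:
        raise ValueError("enclosed_volume requires a detected closure "
                         f"(zb={zb}, zt={zt})")
    return _kernels.enclosed_volume(phi, dx, zb, zt, thresh)


class _Buffers:
    def __init__(self, shape):
        self.psi = np.zeros(shape)
        self.vr = np.zeros(shape)
        self.vz = np.zeros(shape)
        self.ftot = np.zeros(shape)
        self.nphi = np.zeros(shape)
        self.nA = np.zeros(shape)
        self.nI = np.zeros(shape)


_DUMMY = np.zeros((1, 1))


def step(state: AxisymState, p: SimulationParams, buffers=None,
         chi=None, gchi=None, bead: Optional[BeadSpec] = None,
         drift_on=False, solve_I=None):
    """Advance the coupled state by one time step (in place)."""
    if buffers is None:
        buffers = _Buffers(state.phi.shape)
    if solve_I is None:
        solve_I = p.k1 > 0 or np.any(state.I > 0)
    use_bead = chi is not None
    b = buffers
    V, S, B, _ = _kernels.step_axisym(
        state.phi, state.A, state.I, b.psi, b.vr, b.vz, b.ftot,
        b.nphi, b.nA, b.nI,
        state.grid.dx, p.dt, p.tau, p.eta, p.eps, p.MV, p.V0, p.At_total,
        p.F, p.K, p.Kprime, p.nh, 0 if p.force_law == "edge" else 1,
        p.inv_alpha2, p.k1, p.k2, p.p, p.DA, p.DI,
        p.beta, p.theta, p.gamma2, p.psi_cut, p.grad_cut, p.clamp,
        chi if use_bead else _DUMMY, gchi if use_bead else _DUMMY,
        use_bead, bead.Arep if bead else 0.0, bead.Aatt if bead else 0.0,
        drift_on, solve_I)
    state.phi, b.nphi = b.nphi, state.phi
    state.A, b.nA = b.nA, state.A
    if solve_I:
        state.I, b.nI = b.nI, state.I
    state.V, state.S, state.B = V, S, B
    state.t += p.dt
    return state


def run_axisym(p: SimulationParams, rng=None, *, noise: Optional[NoiseParams] = None,
               bead: Optional[BeadSpec] = None, t_max: Optional[float] = None,
               record_every: float = 0.5, grid=None, stop_after_closures=None,
               snapshot_cb=None, snapshot_every=None) -> OutcomeRecord:
    """Integrate a full seeded run and classify the outcome.

    ``rng`` (numpy Generator) drives seeding and nucleation; defaults
    to ``np.random.default_rng(p.seed)``.  ``stop_after_closures``
    terminates early once that many enclosure events are recorded.
    Returns an :class:`OutcomeRecord` with the per-interval time series
    attached.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    t_max = p.t_max if t_max is None else t_max
    state = make_cell(p, grid)
    seed_patch(state, p, rng)
    buffers = _Buffers(state.phi.shape)
    chi = gchi = None
    drift_on = False
    if bead is not None:
        chi, gchi = bead_fields_axisym(state.grid, bead, p.eps, p)
        drift_on = True
    solve_I = p.k1 > 0

    dx = state.grid.dx
    n_steps = int(round(t_max / p.dt))
    rec_stride = max(1, int(round(record_every / p.dt)))
    snap_stride = (int(round(snapshot_every / p.dt))
                   if snapshot_every else None)

    events: List[ClosureEvent] = []
    rows = []
    prev_count = 1
    extinct_since = None

    for n in range(n_steps):
        step(state, p, buffers, chi, gchi, bead, drift_on, solve_I)
        if noise is not None:
            psi = buffers.psi  # psi of the pre-step phi; adequate for noise
            reactions.nucleate(state.A, psi, state.grid, noise, p.dt, rng,
                               p.psi_cut, p.clamp)
        count, zt, zb = _kernels.closure_scan(state.phi, dx, 1, 0.5)
        # a new enclosure appears whenever the transition count rises
        # to 2 or beyond (counts > 2 mean a new cavity sealed while an
        # earlier vesicle still persists on the scan line)
        if count >= 2 and count > prev_count:
            vol = _kernels.enclosed_volume(state.phi, dx, zb, zt, 0.5)
            events.append(ClosureEvent(time=state.t, volume=vol,
                                       fraction=vol / p.V0, zb=zb, zt=zt))
            if stop_after_closures and len(events) >= stop_after_closures:
                break
        prev_count = count

        if (n + 1) % rec_stride == 0:
            maxA = _kernels.max_abs(state.A)
            if not np.isfinite(state.V) or not np.isfinite(maxA):
                raise FloatingPointError(
                    f"solver blow-up at t={state.t:.3f}s")
            meanA = (fields.integrate(state.A * buffers.psi, state.grid)
                     / p.eps / state.S)
            rows.append({"t": state.t, "V": state.V, "S": state.S,
                         "B": state.B, "meanA": meanA, "maxA": maxA,
                         "closure_count": count, "n_events": len(events),
                         "mass": (meanA + state.B) * state.S / p.At_total})
            if maxA < EXTINCT_LEVEL:
                if extinct_since is None:
                    extinct_since = state.t
                elif state.t - extinct_since >= EXTINCT_HOLD:
                    break
            else:
                extinct_since = None
        if snap_stride and (n + 1) % snap_stride == 0 and snapshot_cb:
            snapshot_cb(state)

    ts = pd.DataFrame(rows)
    return OutcomeRecord.classify(events, state.t, timeseries=ts)


def patch_count(A, thresh: float = 0.5):
    """Number of distinct active patches: connected components (in the
    z-r half-plane) of A > thresh.  In axisymmetric geometry each
    component is a polar cap or a ring around the axis."""
    from scipy import ndimage

    _, n = ndimage.label(np.asarray(A) > thresh)
    return int(n)


def sweep_phase_diagram(base: SimulationParams, F_over_eta, at_values,
                        reps: int = 6, rinits=(1.0, 1.5), t_max=None,
                        seed0: int = 0, **run_kw) -> pd.DataFrame:
    """Outcome table over a grid of F/eta x at.

    Each cell aggregates ``reps`` runs split evenly over the initial
    patch radii in ``rinits``: success rate, mean enclosed fraction
    over successes, mean elapsed time, efficiency, and a phase label
    (I all close / II some / III repetitive / IV none).
    """
    rows = []
    for foe in np.atleast_1d(F_over_eta):
        for at in np.atleast_1d(at_values):
            outcomes = []
            for rep in range(reps):
                rinit = rinits[rep % len(rinits)]
                p = base.replace(F=foe * base.eta, at=float(at),
                                 rinit=rinit, seed=seed0 + rep)
                outcomes.append(run_axisym(p, t_max=t_max, **run_kw))
            succ = [o for o in outcomes if o.label in ("closure", "repetitive")
                    and o.fraction is not None
                    and o.fraction >= SUCCESS_CUTOFF]
            n_rep = sum(o.label == "repetitive" for o in outcomes)
            if n_rep:
                phase = "III"
            elif len(succ) == len(outcomes):
                phase = "I"
            elif succ:
                phase = "II"
            else:
                phase = "IV"
            rows.append({
                "F_over_eta": foe, "at": at,
                "success_rate": len(succ) / len(outcomes),
                "mean_fraction": (np.mean([o.fraction for o in succ])
                                  if succ else 0.0),
                "mean_elapsed": (np.mean([o.elapsed for o in succ])
                                 if succ else np.nan),
                "mean_efficiency": (np.mean([o.efficiency for o in succ])
                                    if succ else np.nan),
                "n_repetitive": n_rep,
                "phase": phase,
            })
    return pd.DataFrame(rows)
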