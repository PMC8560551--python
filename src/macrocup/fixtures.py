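"""Constructed field fixtures for detector and integrator tests.

All fixtures are generated programmatically; the cavity and open-cup
shapes are synthetic geometries (not simulation output) built to have
known analytic volumes and scan-line signatures.
"""

from __future__ import annotations

import numpy as np

from . import fields
from .axisym import make_cell, seed_patch
from .params import SimulationParams, BeadSpec

KINDS = ("sphere", "sphere+seed", "sphere+cavity", "cup-open", "sphere+bead")


def make_fixture(kind: str, p: SimulationParams, rng=None, *,
                 cavity_radius: float = 2.0, R_cell: float = None,
                 bead: BeadSpec = None, grid=None):
    """Axisymmetric CellState fixtures.

    - ``sphere``: resting cell, A = I = 0 (closure scan count 1).
    - ``sphere+seed``: sphere with the random activator seed patch.
    - ``sphere+cavity``: cell of radius ``R_cell`` (default R0) with a
      concentric spherical vacancy of radius ``cavity_radius`` --
      closure scan count 2, enclosed volume 4 pi a^3/3.
    - ``cup-open``: sphere with a spherical bite removed at the top
      pole: crescent cross-section, no enclosed region (count 1).
    - ``sphere+bead``: resting cell plus a tangent bead field
      (returned as (state, chi, gchi)).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; one of {KINDS}")
    if kind == "sphere":
        return make_cell(p, grid)
    if kind == "sphere+seed":
        if rng is None:
            rng = np.random.default_rng(p.seed)
        state = make_cell(p, grid)
        return seed_patch(state, p, rng)
    if kind == "sphere+cavity":
        R = R_cell if R_cell is not None else p.R0
        state = make_cell(p.replace(R0=R), grid)
        g = state.grid
        center = (0.0, g.Lz / 2.0)
        ball = fields.init_sphere_phi(g, center, cavity_radius, p.eps)
        state.phi = state.phi * (1.0 - ball)
        state.V = fields.volume_of(state.phi, g)
        return state
    if kind == "cup-open":
        R = R_cell if R_cell is not None else p.R0
        state = make_cell(p.replace(R0=R), grid)
        g = state.grid
        bite_center = (0.0, g.Lz / 2.0 + R)
        bite = fields.init_sphere_phi(g, bite_center, 0.6 * R, p.eps)
        state.phi = state.phi * (1.0 - bite)
        state.V = fields.volume_of(state.phi, g)
        return state
    # sphere + bead
    from .axisym import bead_fields_axisym

    state = make_cell(p, grid)
    bead = bead or BeadSpec()
    chi, gchi = bead_fields_axisym(state.grid, bead, p.eps, p)
    return state, chi, gchi
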