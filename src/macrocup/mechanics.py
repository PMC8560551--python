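"""Membrane mechanics: phase-field relaxation, interface velocity, and
the protrusive force laws.

Sign conventions (fixed once, used everywhere): phi = 1 inside the
cell; the outward unit normal is n = -grad(phi)/|grad(phi)|; a positive
normal speed s moves the interface outward, d(phi)/dt = s |grad phi|.
Surface tension shrinks a sphere (s = -2 eta / (tau R)); a positive
protrusive force pushes outward.
"""

from __future__ import annotations

import math

import numpy as np

from . import fields
from .params import SimulationParams


def protrusive_force(A, F, K, Kprime, nh):
    """Edge-localized force law: F (A/K)^nh / (1 + (A/K)^nh)
    * 1 / (1 + (A^2/K')^nh).

    Rises at A ~ K and is suppressed for large A, so Fpoly ~ F on the
    band K <~ A <~ K' -- the periphery of an active patch.  The
    suppression factor uses A^2/K' as printed in the source model.
    """
    A = np.asarray(A, dtype=float)
    x = (A / K) ** nh
    y = (A * A / Kprime) ** nh
    return F * x / (1.0 + x) / (1.0 + y)


def protrusive_force_inhibited(A, I, F, K, Kprime, nh):
    """Inhibitor-suppressed force law: F (A/K)^nh / (1 + (A/K)^nh)
    * 1 / (1 + (I/K')^nh).

    The inhibitor I competitively suppresses force generation; the
    patch edge (high A, low I) remains protrusive even for patches
    whose interior A is large, which is what permits split patches to
    develop their own rims.
    """
    A = np.asarray(A, dtype=float)
    I = np.asarray(I, dtype=float)
    x = (A / K) ** nh
    y = (I / Kprime) ** nh
    return F * x / (1.0 + x) / (1.0 + y)


def force_field(A, I, p: SimulationParams):
    """Dispatch on the configured force law."""
    if p.force_law == "edge":
        return protrusive_force(A, p.F, p.K, p.Kprime, p.nh)
    return protrusive_force_inhibited(A, I, p.F, p.K, p.Kprime, p.nh)


def _curvature_force(phi, p: SimulationParams, grid):
    if isinstance(grid, fields.AxisymGrid):
        lap = fields.laplacian_axisym(phi, grid.dx)
    else:
        lap = fields.laplacian_cart3d(phi, grid.dx)
    return p.eta * (lap - fields.double_well_prime(phi) / p.eps**2)


def normal_speed(phi, Fpoly, V, p: SimulationParams, grid):
    """Normal interface speed s (um/s) and the gradient components.

    s = (1/tau) [ eta (lap phi - G'/eps^2)/|grad phi|
                  - MV (V - V0) + Fpoly ]

    evaluated where |grad phi| > grad_cut, zero elsewhere.  The
    velocity vector is s * n with n = -grad(phi)/|grad phi|.
    """
    if isinstance(grid, fields.AxisymGrid):
        grads = fields.gradient_axisym(phi, grid.dx)
    else:
        grads = fields.gradient_cart3d(phi, grid.dx)
    gmag = fields.grad_magnitude(grads)
    curv = _curvature_force(phi, p, grid)
    mask = gmag > p.grad_cut
    s = np.zeros_like(phi)
    s[mask] = (curv[mask] / gmag[mask] - p.MV * (V - p.V0) + Fpoly[mask]) / p.tau
    return s, grads, gmag


def velocity_field(phi, Fpoly, V, p: SimulationParams, grid):
    """Interface velocity components v = s * (-grad phi / |grad phi|)."""
    s, grads, gmag = normal_speed(phi, Fpoly, V, p, grid)
    safe = np.where(gmag > p.grad_cut, gmag, 1.0)
    return tuple(-s * g / safe for g in grads), s, gmag


def advance_phi(phi, Fpoly, p: SimulationParams, grid, dt=None):
    """One explicit-Euler step of the phase-field equation

    tau d(phi)/dt = eta (lap phi - G'/eps^2)
                    - MV (V - V0) |grad phi| + Fpoly |grad phi|.

    V is recomputed once from the current phi before the update.
    Raises on non-finite values (blow-up detection).
    """
    dt = p.dt if dt is None else dt
    V = fields.volume_of(phi, grid)
    curv = _curvature_force(phi, p, grid)
    if isinstance(grid, fields.AxisymGrid):
        grads = fields.gradient_axisym(phi, grid.dx)
    else:
        grads = fields.gradient_cart3d(phi, grid.dx)
    gmag = fields.grad_magnitude(grads)
    out = phi + dt / p.tau * (curv - p.MV * (V - p.V0) * gmag + Fpoly * gmag)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("phase field blew up (non-finite values)")
    return out


# ----------------------------------------------------------------------
# analytic estimates
# ----------------------------------------------------------------------

def minimal_force_ratio(l_h):
    """Minimal protrusive force per tension, F*/eta = 1/R = pi/l_h
    (um^-1), for a protrusion whose semicircular head has arc length
    l_h = pi R."""
    if l_h <= 0:
        raise ValueError("l_h must be positive")
    return math.pi / l_h


def minimal_protrusion_width(eta, F):
    """Smallest sustainable protrusion width 2R = 2 eta / F (um), from
    the force balance F/eta > 1/R."""
    return 2.0 * eta / F


def bending_surface_ratio(Kb, eta, r):
    """Bending-to-surface energy ratio Gb/Gs ~ Kb / (2 eta r^2) for a
    cylindrical protrusion of radius r.  Kb in nN um, eta in nN/um,
    r in um."""
    if r <= 0:
        raise ValueError("r must be positive")
    return Kb / (2.0 * eta * r**2)
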