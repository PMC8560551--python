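"""Reaction-advection-diffusion of the activator A and inhibitor I on
the membrane band, global pool bookkeeping, seeding and stochastic
nucleation.

The operational form solved on the grid (derived from the psi-weighted
transport equations via grad(psi)/psi = beta (1-psi)(1-2 phi) grad phi)
is

    dA/dt = -div(A v) + DA beta (1-psi)(1-2 phi) grad(phi).grad(A)
            + DA lap A + A^2 B /(1 + A^2/alpha^2) * 1/(1+I) - A

(analogously for I with production k1 A^p and decay k2 I), solved only
where psi > psi_cut; elsewhere A and I decay at rate gamma2.  After
the reaction step both species are clamped to [0, clamp].

B is global and algebraic (fast-diffusion limit):
B = At/S - <A> with <A> = (integral of A psi/eps) / S.
"""

from __future__ import annotations

import math

import numpy as np

from . import fields
from .params import SimulationParams, NoiseParams

#: cap on the face transmissivity ratio of the confined-diffusion
#: operator (matches the production kernels)
FACE_RATIO_CAP = 8.0


def _face_psi(a, b):
    return np.minimum(np.sqrt(a * b), FACE_RATIO_CAP * np.minimum(a, b))


def reaction_terms(A, I, B, alpha, k1, k2, p=2):
    """Pointwise reaction rates (dA, dI)."""
    A = np.asarray(A, dtype=float)
    I = np.asarray(I, dtype=float)
    inv_a2 = 0.0 if math.isinf(alpha) else 1.0 / alpha**2
    dA = A * A * B / (1.0 + A * A * inv_a2) / (1.0 + I) - A
    dI = k1 * A**p - k2 * I
    return dA, dI


def global_B(A, psi, grid, p: SimulationParams):
    """Available pool B = At/S - <A>, clipped at zero.

    S is the instantaneous surface area; <A> is the psi-weighted total
    of A divided by S.  A negative value (conservation violation)
    should not occur and is clipped with a warning.
    """
    S = fields.surface_area_of(psi, grid, p.eps)
    if S < 1e-9:
        raise ZeroDivisionError("vanishing surface area")
    totalA = fields.integrate(A * psi, grid) / p.eps
    B = p.At_total / S - totalA / S
    if B < 0.0:
        import warnings
        warnings.warn(f"global pool B={B:.3g} clipped to 0", RuntimeWarning)
        B = 0.0
    return B, S, totalA


def confinement_term(c, phi, psi, D, grid, beta, scheme="upwind"):
    """Membrane-confinement correction: the drift c_vec . grad(c) with
    c_vec = D beta (1-psi)(1-2 phi) grad(phi), which equals
    D (grad psi / psi) . grad(c) analytically.

    The production scheme upwinds grad(c) against the drift
    characteristic (the drift's cell Peclet exceeds 2 near the band
    skirt at practical resolutions); ``scheme="central"`` gives the
    plain second-order form used in the analytic-identity test.
    """
    dx = grid.dx
    if isinstance(grid, fields.AxisymGrid):
        pgrads = fields.gradient_axisym(phi, dx)
    else:
        pgrads = fields.gradient_cart3d(phi, dx)
    coef = D * beta * (1.0 - psi) * (1.0 - 2.0 * phi)
    cvec = [coef * g for g in pgrads]
    if scheme == "central":
        if isinstance(grid, fields.AxisymGrid):
            cgrads = fields.gradient_axisym(c, dx)
        else:
            cgrads = fields.gradient_cart3d(c, dx)
        return sum(cv * cg for cv, cg in zip(cvec, cgrads))
    out = np.zeros_like(c)
    ndim = c.ndim
    for axis, cv in enumerate(cvec):
        fwd = np.zeros_like(c)
        bwd = np.zeros_like(c)
        lo = [slice(None)] * ndim
        hi = [slice(None)] * ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        d = (c[tuple(hi)] - c[tuple(lo)]) / dx
        fwd[tuple(lo)] = d
        bwd[tuple(hi)] = d
        # drift characteristic velocity is -c_vec: backward difference
        # where the component is negative, forward where positive
        out += cv * np.where(cv < 0.0, bwd, fwd)
        if axis == 0 and isinstance(grid, fields.AxisymGrid):
            out[0, :] -= (cvec[0] * np.where(cvec[0] < 0.0, bwd, fwd))[0, :]
    return out


def band_diffusion(c, psi, grid):
    """Membrane-confined diffusion operator (1/psi) div(psi grad c):
    the sum of bulk diffusion and the confinement drift, in
    conservative flux form with geometric-mean face weights.

    This is the production discretization (mirrored by the numba
    kernels): unlike the expanded drift + Laplacian form it is
    monotone, so the steep psi skirt cannot generate node-to-node
    oscillations at practical mesh sizes.
    """
    dx = grid.dx
    out = np.zeros_like(c)
    if isinstance(grid, fields.AxisymGrid):
        nr, nz = c.shape
        r = dx * np.arange(nr)[:, None]
        rf = dx * (np.arange(nr - 1) + 0.5)[:, None]
        psf_r = _face_psi(psi[:-1, :], psi[1:, :])
        Fr = psf_r * (c[1:, :] - c[:-1, :])          # face flux * dx
        psf_z = _face_psi(psi[:, :-1], psi[:, 1:])
        Fz = psf_z * (c[:, 1:] - c[:, :-1])
        out[1:-1, 1:-1] = ((rf[1:] * Fr[1:, 1:-1] - rf[:-1] * Fr[:-1, 1:-1])
                           / r[1:-1]
                           + Fz[1:-1, 1:] - Fz[1:-1, :-1]) / dx**2
        out[0, 1:-1] = (4.0 * Fr[0, 1:-1]
                        + Fz[0, 1:] - Fz[0, :-1]) / dx**2
        out /= np.maximum(psi, 1e-300)
        out[-1, :] = 0.0
        out[:, 0] = 0.0
        out[:, -1] = 0.0
        return out
    # Cartesian 3-D
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        psf = _face_psi(psi[tuple(lo)], psi[tuple(hi)])
        F = psf * (c[tuple(hi)] - c[tuple(lo)])
        interior = [slice(None)] * 3
        interior[axis] = slice(1, -1)
        fhi = [slice(None)] * 3
        fhi[axis] = slice(1, None)
        flo = [slice(None)] * 3
        flo[axis] = slice(None, -1)
        out[tuple(interior)] += (F[tuple(fhi)] - F[tuple(flo)]) / dx**2
    out /= np.maximum(psi, 1e-300)
    for axis in range(3):
        edge = [slice(None)] * 3
        for idx in (0, -1):
            edge[axis] = idx
            out[tuple(edge)] = 0.0
        edge[axis] = slice(None)
    return out


def rd_step(A, I, phi, psi, v, B, p: SimulationParams, grid, dt=None):
    """One explicit-Euler step of the membrane reaction-transport
    system (reference implementation; the solvers use the fused numba
    kernels validated against this).

    ``v`` is the tuple of velocity components from the mechanics
    module.  Returns updated (A, I).
    """
    dt = p.dt if dt is None else dt
    dx = grid.dx
    axisym = isinstance(grid, fields.AxisymGrid)
    newA = np.empty_like(A)
    newI = np.empty_like(I)
    for c, D, new, which in ((A, p.DA, newA, "A"), (I, p.DI, newI, "I")):
        if axisym:
            adv = -fields.upwind_div_axisym(c, v[0], v[1], dx)
        else:
            adv = -upwind_div_cart3d(c, v, dx)
        diff = D * band_diffusion(c, psi, grid)
        if which == "A":
            react, _ = reaction_terms(A, I, B, p.alpha, p.k1, p.k2, p.p)
        else:
            _, react = reaction_terms(A, I, B, p.alpha, p.k1, p.k2, p.p)
        new[:] = c + dt * (adv + diff + react)
        # off the membrane band: pure decay
        off = psi <= p.psi_cut
        new[off] = c[off] * (1.0 - p.gamma2 * dt)
        np.clip(new, 0.0, p.clamp, out=new)
    if not (np.all(np.isfinite(newA)) and np.all(np.isfinite(newI))):
        raise FloatingPointError("reaction-diffusion step produced NaN/inf")
    return newA, newI


def upwind_div_cart3d(c, v, dx):
    """Conservative first-order upwind div(c v) on the Cartesian grid;
    boundary faces carry zero flux (no-flux walls)."""
    out = np.zeros_like(c)
    for axis in range(3):
        vax = v[axis]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        vf = 0.5 * (vax[tuple(sl_lo)] + vax[tuple(sl_hi)])
        cf = np.where(vf > 0.0, c[tuple(sl_lo)], c[tuple(sl_hi)])
        flux = vf * cf  # flux through face between node i and i+1
        interior = [slice(None)] * 3
        interior[axis] = slice(1, -1)
        fhi = [slice(None)] * 3
        fhi[axis] = slice(1, None)
        flo = [slice(None)] * 3
        flo[axis] = slice(None, -1)
        out[tuple(interior)] += (flux[tuple(fhi)] - flux[tuple(flo)]) / dx
        # first and last planes: one-sided (zero flux at the wall)
        first = [slice(None)] * 3
        first[axis] = 0
        last = [slice(None)] * 3
        last[axis] = -1
        f0 = [slice(None)] * 3
        f0[axis] = 0
        fN = [slice(None)] * 3
        fN[axis] = -1
        out[tuple(first)] += flux[tuple(f0)] / dx
        out[tuple(last)] += -flux[tuple(fN)] / dx
    return out


# ----------------------------------------------------------------------
# initial condition and noise
# ----------------------------------------------------------------------

def seed_initial_patch(A, phi, psi, grid, rinit, rng, surface_point=None,
                       amplitude=5.0):
    """Seed a circular activator patch: membrane-band nodes (psi > 0.5)
    within Euclidean distance rinit of ``surface_point`` get
    A ~ U(0, amplitude) i.i.d.

    ``surface_point`` defaults to the topmost membrane node on the
    symmetry axis (axisym) / the +z pole (3-D).  Returns the modified A
    (in place) and the number of seeded nodes.
    """
    if rinit <= 0:
        return A, 0
    coords = grid.coords()
    band = psi > 0.5
    if surface_point is None:
        # topmost band node on the axis of symmetry / pole
        if isinstance(grid, fields.AxisymGrid):
            j = np.nonzero(band[0, :])[0]
            if len(j) == 0:
                raise ValueError("no membrane band found on the axis")
            surface_point = (0.0, grid.dx * j.max())
        else:
            raise ValueError("surface_point required on a 3-D grid")
    d2 = sum((x - c) ** 2 for x, c in zip(coords, surface_point))
    sel = band & (d2 <= rinit**2)
    n = int(sel.sum())
    A[sel] = rng.uniform(0.0, amplitude, size=n)
    return A, n


def nucleate(A, psi, grid, noise: NoiseParams, dt, rng, psi_cut=1e-3,
             clamp=50.0):
    """Stochastic patch nucleation over one interval dt.

    The number of events is Poisson(lam * V_domain * dt); each event
    adds N0 exp(-|x-xc|^2 / 2 d^2) to A on membrane-band nodes
    (psi > psi_cut), with N0 ~ Exponential(mean sigma) and xc uniform
    in the domain.  Returns the number of events applied.
    """
    if noise.lam <= 0.0 or dt <= 0.0:
        return 0
    if isinstance(grid, fields.AxisymGrid):
        Vdom = math.pi * grid.Lr**2 * grid.Lz
    else:
        Vdom = (grid.dx * (grid.nx - 1)) * (grid.dx * (grid.ny - 1)) \
            * (grid.dx * (grid.nz - 1))
    n_events = rng.poisson(noise.lam * Vdom * dt)
    if n_events == 0:
        return 0
    coords = grid.coords()
    band = psi > psi_cut
    for _ in range(n_events):
        if isinstance(grid, fields.AxisymGrid):
            # uniform in the cylinder: r ~ sqrt(U) * Lr
            xc = (grid.Lr * math.sqrt(rng.uniform()), rng.uniform(0, grid.Lz))
        else:
            xc = tuple(o + rng.uniform(0, (n - 1) * grid.dx)
                       for o, n in zip(grid.origin, grid.shape))
        d2 = sum((x - c) ** 2 for x, c in zip(coords, xc))
        bump = rng.exponential(noise.sigma) * np.exp(-d2 / (2.0 * noise.d**2))
        A[band] += bump[band]
    np.clip(A, 0.0, clamp, out=A)
    return int(n_events)
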