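"""Fused numba kernels for the Cartesian 3-D solver.

Array convention: shape (nx, ny, nz), node (i, j, k) at
origin + (i, j, k)*dx.  All six faces carry no-flux (mirror) boundary
conditions for phi, A and I.
"""

import numpy as np
from numba import njit

from ._kernels import hill_force, _face_psi


@njit(cache=True, inline="always")
def _mirror(idx, n):
    if idx < 0:
        return 1
    if idx > n - 1:
        return n - 2
    return idx


@njit(cache=True)
def psi_and_integrals_3d(phi, A, psi, dx, eps, beta, theta):
    nx, ny, nz = phi.shape
    w = dx * dx * dx
    V = 0.0
    S = 0.0
    intA = 0.0
    psi0 = 1.0 / (1.0 + np.exp(beta * theta))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                f = phi[i, j, k]
                if f <= 1e-4 or f >= 0.9999:
                    ps = psi0
                else:
                    ps = 1.0 / (1.0 + np.exp(-beta * (f * (1.0 - f) - theta)))
                psi[i, j, k] = ps
                V += w * f
                S += w * ps / eps
                intA += w * A[i, j, k] * ps / eps
    return V, S, intA


@njit(cache=True)
def force_and_velocity_3d(phi, A, I, vx, vy, vz, ftot,
                          dx, tau, eta, eps, MVterm,
                          F, K, Kp, nh, force_law,
                          chi, gchi, use_bead, Arep, Aatt, grad_cut):
    nx, ny, nz = phi.shape
    dx2 = dx * dx
    eps2 = eps * eps
    for i in range(nx):
        im = _mirror(i - 1, nx)
        ip = _mirror(i + 1, nx)
        for j in range(ny):
            jm = _mirror(j - 1, ny)
            jp = _mirror(j + 1, ny)
            for k in range(nz):
                km = _mirror(k - 1, nz)
                kp = _mirror(k + 1, nz)
                f0 = phi[i, j, k]
                fxm = phi[im, j, k]
                fxp = phi[ip, j, k]
                fym = phi[i, jm, k]
                fyp = phi[i, jp, k]
                fzm = phi[i, j, km]
                fzp = phi[i, j, kp]
                dpx = (fxp - fxm) / (2.0 * dx)
                dpy = (fyp - fym) / (2.0 * dx)
                dpz = (fzp - fzm) / (2.0 * dx)
                lap = (fxp + fxm + fyp + fym + fzp + fzm - 6.0 * f0) / dx2
                gmag = np.sqrt(dpx * dpx + dpy * dpy + dpz * dpz)
                Gp = 16.0 * f0 * (1.0 - f0) * (1.0 - 2.0 * f0)
                curv = eta * (lap - Gp / eps2)
                Fp = hill_force(A[i, j, k], I[i, j, k], F, K, Kp, nh,
                                force_law)
                fb = 0.0
                if use_bead:
                    ch = chi[i, j, k]
                    fb = -Arep * ch * ch * f0 + Aatt * gchi[i, j, k] * gmag
                ft = curv - MVterm * gmag + Fp * gmag + fb
                ftot[i, j, k] = ft
                if gmag > grad_cut:
                    s = ft / (gmag * tau)
                    vx[i, j, k] = -s * dpx / gmag
                    vy[i, j, k] = -s * dpy / gmag
                    vz[i, j, k] = -s * dpz / gmag
                else:
                    vx[i, j, k] = 0.0
                    vy[i, j, k] = 0.0
                    vz[i, j, k] = 0.0


@njit(cache=True)
def drift_velocity_3d(phi, ftot, dx, tau, V):
    """Drift velocity cancelling centroid motion from the net force."""
    nx, ny, nz = phi.shape
    w = dx * dx * dx
    cx = cy = cz = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                f = phi[i, j, k]
                cx += w * f * i
                cy += w * f * j
                cz += w * f * k
    cx = cx * dx / V
    cy = cy * dx / V
    cz = cz * dx / V
    mx = my = mz = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ft = ftot[i, j, k]
                mx += w * (i * dx - cx) * ft
                my += w * (j * dx - cy) * ft
                mz += w * (k * dx - cz) * ft
    return -mx / (tau * V), -my / (tau * V), -mz / (tau * V)


@njit(cache=True)
def update_phi_3d(phi, ftot, nphi, vx, vy, vz, dx, dt, tau,
                  vdx, vdy, vdz):
    nx, ny, nz = phi.shape
    drift = vdx != 0.0 or vdy != 0.0 or vdz != 0.0
    for i in range(nx):
        im = _mirror(i - 1, nx)
        ip = _mirror(i + 1, nx)
        for j in range(ny):
            jm = _mirror(j - 1, ny)
            jp = _mirror(j + 1, ny)
            for k in range(nz):
                adv = 0.0
                if drift:
                    km = _mirror(k - 1, nz)
                    kp = _mirror(k + 1, nz)
                    dpx = (phi[ip, j, k] - phi[im, j, k]) / (2.0 * dx)
                    dpy = (phi[i, jp, k] - phi[i, jm, k]) / (2.0 * dx)
                    dpz = (phi[i, j, kp] - phi[i, j, km]) / (2.0 * dx)
                    adv = -(vdx * dpx + vdy * dpy + vdz * dpz)
                    vx[i, j, k] += vdx
                    vy[i, j, k] += vdy
                    vz[i, j, k] += vdz
                nphi[i, j, k] = phi[i, j, k] + dt * (ftot[i, j, k] / tau + adv)


@njit(cache=True)
def species_step_3d(c, A, I, phi, psi, vx, vy, vz, nc, which_A,
                    D, B, inv_a2, k1, k2, p_exp, dx, dt,
                    gamma2, psi_cut, clamp):
    nx, ny, nz = c.shape
    dx2 = dx * dx
    for i in range(nx):
        im = _mirror(i - 1, nx)
        ip = _mirror(i + 1, nx)
        for j in range(ny):
            jm = _mirror(j - 1, ny)
            jp = _mirror(j + 1, ny)
            for k in range(nz):
                ps = psi[i, j, k]
                c0 = c[i, j, k]
                if ps <= psi_cut:
                    v = c0 * (1.0 - gamma2 * dt)
                    nc[i, j, k] = v if v > 0.0 else 0.0
                    continue
                km = _mirror(k - 1, nz)
                kp = _mirror(k + 1, nz)
                # upwind advection; domain walls carry zero flux
                adv = 0.0
                if i < nx - 1:
                    vf = 0.5 * (vx[i, j, k] + vx[i + 1, j, k])
                    adv += vf * (c0 if vf > 0.0 else c[i + 1, j, k])
                if i > 0:
                    vf = 0.5 * (vx[i - 1, j, k] + vx[i, j, k])
                    adv -= vf * (c[i - 1, j, k] if vf > 0.0 else c0)
                if j < ny - 1:
                    vf = 0.5 * (vy[i, j, k] + vy[i, j + 1, k])
                    adv += vf * (c0 if vf > 0.0 else c[i, j + 1, k])
                if j > 0:
                    vf = 0.5 * (vy[i, j - 1, k] + vy[i, j, k])
                    adv -= vf * (c[i, j - 1, k] if vf > 0.0 else c0)
                if k < nz - 1:
                    vf = 0.5 * (vz[i, j, k] + vz[i, j, k + 1])
                    adv += vf * (c0 if vf > 0.0 else c[i, j, k + 1])
                if k > 0:
                    vf = 0.5 * (vz[i, j, k - 1] + vz[i, j, k])
                    adv -= vf * (c[i, j, k - 1] if vf > 0.0 else c0)
                adv = -adv / dx
                # membrane-confined diffusion (1/psi) div(psi grad c)
                diff = (_face_psi(ps, psi[ip, j, k]) * (c[ip, j, k] - c0)
                        + _face_psi(ps, psi[im, j, k]) * (c[im, j, k] - c0)
                        + _face_psi(ps, psi[i, jp, k]) * (c[i, jp, k] - c0)
                        + _face_psi(ps, psi[i, jm, k]) * (c[i, jm, k] - c0)
                        + _face_psi(ps, psi[i, j, kp]) * (c[i, j, kp] - c0)
                        + _face_psi(ps, psi[i, j, km]) * (c[i, j, km] - c0)
                        ) / (dx2 * ps)
                a = A[i, j, k]
                if which_A:
                    react = (a * a * B / (1.0 + a * a * inv_a2)
                             / (1.0 + I[i, j, k]) - a)
                else:
                    if p_exp == 2:
                        react = k1 * a * a - k2 * I[i, j, k]
                    else:
                        react = k1 * a - k2 * I[i, j, k]
                val = c0 + dt * (adv + D * diff + react)
                if val < 0.0:
                    val = 0.0
                elif val > clamp:
                    val = clamp
                nc[i, j, k] = val


@njit(cache=True)
def step_3d(phi, A, I, psi, vx, vy, vz, ftot, nphi, nA, nI,
            dx, dt, tau, eta, eps, MV, V0, At_total,
            F, K, Kp, nh, force_law,
            inv_a2, k1, k2, p_exp, DA, DI,
            beta, theta, gamma2, psi_cut, grad_cut, clamp,
            chi, gchi, use_bead, Arep, Aatt, drift_on, solve_I):
    """One fully coupled 3-D step; returns (V, S, B, vd) with vd the
    drift velocity vector applied (zeros unless drift_on)."""
    V, S, intA = psi_and_integrals_3d(phi, A, psi, dx, eps, beta, theta)
    B = At_total / S - intA / S
    if B < 0.0:
        B = 0.0
    MVterm = MV * (V - V0)
    force_and_velocity_3d(phi, A, I, vx, vy, vz, ftot,
                          dx, tau, eta, eps, MVterm,
                          F, K, Kp, nh, force_law,
                          chi, gchi, use_bead, Arep, Aatt, grad_cut)
    vdx = vdy = vdz = 0.0
    if drift_on:
        vdx, vdy, vdz = drift_velocity_3d(phi, ftot, dx, tau, V)
    update_phi_3d(phi, ftot, nphi, vx, vy, vz, dx, dt, tau, vdx, vdy, vdz)
    species_step_3d(A, A, I, phi, psi, vx, vy, vz, nA, True,
                    DA, B, inv_a2, k1, k2, p_exp, dx, dt,
                    gamma2, psi_cut, clamp)
    if solve_I:
        species_step_3d(I, A, I, phi, psi, vx, vy, vz, nI, False,
                        DI, B, inv_a2, k1, k2, p_exp, dx, dt,
                        gamma2, psi_cut, clamp)
    return V, S, B, vdx, vdy, vdz
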