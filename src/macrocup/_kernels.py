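"""Fused numba kernels for the axisymmetric (z-r half-plane) solver.

Array convention: shape (nr, nz), node (i, j) at r = i*dx, z = j*dx.
Boundary conditions: Neumann symmetry at r = 0 (mirror); Dirichlet
phi = A = I = 0 on the outer-r and both z boundaries (the boundary ring
is simply never updated and stays zero).

These kernels are validated step-for-step against the numpy reference
operators in :mod:`macrocup.fields` / :mod:`macrocup.reactions`.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


#: cap on the face transmissivity ratio psi_face/psi_node of the
#: confined-diffusion operator; keeps the explicit step stable on very
#: coarse meshes (inactive for dx <= 0.2 um at beta = 100)
FACE_RATIO_CAP = 8.0


@njit(cache=True, inline="always")
def _face_psi(ps_a, ps_b):
    m = ps_a if ps_a < ps_b else ps_b
    f = np.sqrt(ps_a * ps_b)
    cap = FACE_RATIO_CAP * m
    return f if f < cap else cap


@njit(cache=True, inline="always")
def _powh(x, nh):
    """x**nh specialized for the Hill coefficients used in practice."""
    if nh == 3.0:
        return x * x * x
    if nh == 5.0:
        x2 = x * x
        return x2 * x2 * x
    return x ** nh


@njit(cache=True, inline="always")
def hill_force(a, Ii, F, K, Kp, nh, force_law):
    """Protrusive force density at one node."""
    if a <= 0.0:
        return 0.0
    x = _powh(a / K, nh)
    if force_law == 0:
        y = _powh(a * a / Kp, nh)
    else:
        y = _powh(Ii / Kp, nh) if Ii > 0.0 else 0.0
    return F * x / (1.0 + x) / (1.0 + y)


@njit(cache=True)
def psi_and_integrals(phi, A, psi, dx, eps, beta, theta):
    """Fill psi from phi and return (V, S, intA) with midpoint-rule
    2 pi r dr dz weights (the axis row has zero weight)."""
    nr, nz = phi.shape
    V = 0.0
    S = 0.0
    intA = 0.0
    psi0 = 1.0 / (1.0 + np.exp(beta * theta))  # bulk value (phi = 0 or 1)
    for i in range(nr):
        w = TWO_PI * (i * dx) * dx * dx
        for j in range(nz):
            f = phi[i, j]
            if f <= 1e-4 or f >= 0.9999:
                ps = psi0
            else:
                ps = 1.0 / (1.0 + np.exp(-beta * (f * (1.0 - f) - theta)))
            psi[i, j] = ps
            V += w * f
            S += w * ps / eps
            intA += w * A[i, j] * ps / eps
    return V, S, intA


@njit(cache=True)
def force_and_velocity(phi, A, I, psi, vr, vz, ftot,
                       dx, tau, eta, eps, MVterm,
                       F, K, Kp, nh, force_law,
                       chi, gchi, use_bead, Arep, Aatt, grad_cut):
    """Total force density on phi (stored in ftot) and the interface
    velocity components (vr, vz)."""
    nr, nz = phi.shape
    dx2 = dx * dx
    eps2 = eps * eps
    for i in range(nr - 1):
        r = i * dx
        for j in range(1, nz - 1):
            f0 = phi[i, j]
            fE = phi[i + 1, j]
            fW = phi[1, j] if i == 0 else phi[i - 1, j]
            fN = phi[i, j + 1]
            fS = phi[i, j - 1]
            dpr = 0.0 if i == 0 else (fE - fW) / (2.0 * dx)
            dpz = (fN - fS) / (2.0 * dx)
            if i == 0:
                lap = 4.0 * (fE - f0) / dx2 + (fN - 2.0 * f0 + fS) / dx2
            else:
                lap = ((fE - 2.0 * f0 + fW) / dx2 + dpr / r
                       + (fN - 2.0 * f0 + fS) / dx2)
            gmag = np.sqrt(dpr * dpr + dpz * dpz)
            Gp = 16.0 * f0 * (1.0 - f0) * (1.0 - 2.0 * f0)
            curv = eta * (lap - Gp / eps2)
            Fp = hill_force(A[i, j], I[i, j], F, K, Kp, nh, force_law)
            fb = 0.0
            if use_bead:
                ch = chi[i, j]
                fb = -Arep * ch * ch * f0 + Aatt * gchi[i, j] * gmag
            ft = curv - MVterm * gmag + Fp * gmag + fb
            ftot[i, j] = ft
            if gmag > grad_cut:
                s = ft / (gmag * tau)
                vr[i, j] = -s * dpr / gmag
                vz[i, j] = -s * dpz / gmag
            else:
                vr[i, j] = 0.0
                vz[i, j] = 0.0


@njit(cache=True)
def drift_velocity_z(phi, ftot, dx, tau, V):
    """Axial drift velocity cancelling net centroid motion:
    v_drift = -(1/(tau V)) * integral (z - zc) f_total dV."""
    nr, nz = phi.shape
    mz = 0.0
    for i in range(nr):
        w = TWO_PI * (i * dx) * dx * dx
        for j in range(nz):
            mz += w * phi[i, j] * (j * dx)
    zc = mz / V
    mom = 0.0
    for i in range(nr):
        w = TWO_PI * (i * dx) * dx * dx
        for j in range(nz):
            mom += w * (j * dx - zc) * ftot[i, j]
    return -mom / (tau * V)


@njit(cache=True)
def update_phi(phi, ftot, nphi, vz, dx, dt, tau, vdz):
    """Explicit Euler phi update, including the drift advection
    -v_drift d(phi)/dz when a bead is present.  The drift is also added
    to vz so the species are advected consistently."""
    nr, nz = phi.shape
    for i in range(nr - 1):
        for j in range(1, nz - 1):
            adv = 0.0
            if vdz != 0.0:
                dpz = (phi[i, j + 1] - phi[i, j - 1]) / (2.0 * dx)
                adv = -vdz * dpz
                vz[i, j] += vdz
            nphi[i, j] = phi[i, j] + dt * (ftot[i, j] / tau + adv)


@njit(cache=True)
def species_step(c, A, I, phi, psi, vr, vz, nc, which_A,
                 D, B, inv_a2, k1, k2, p_exp, beta, dx, dt,
                 gamma2, psi_cut, clamp):
    """One explicit Euler step of a membrane species (A if which_A else
    I): upwind advection + confinement correction + diffusion +
    reaction on the band psi > psi_cut, decay at rate gamma2 off it,
    clamp to [0, clamp]."""
    nr, nz = c.shape
    dx2 = dx * dx
    for i in range(nr - 1):
        r = i * dx
        for j in range(1, nz - 1):
            ps = psi[i, j]
            c0 = c[i, j]
            if ps <= psi_cut:
                v = c0 * (1.0 - gamma2 * dt)
                nc[i, j] = v if v > 0.0 else 0.0
                continue
            cE = c[i + 1, j]
            cW = c[1, j] if i == 0 else c[i - 1, j]
            cN = c[i, j + 1]
            cS = c[i, j - 1]
            # conservative upwind advection
            vfE = 0.5 * (vr[i, j] + vr[i + 1, j])
            cfE = c0 if vfE > 0.0 else cE
            if i == 0:
                div_r = 4.0 * vfE * cfE / dx
            else:
                vfW = 0.5 * (vr[i - 1, j] + vr[i, j])
                cfW = c[i - 1, j] if vfW > 0.0 else c0
                rE = (i + 0.5) * dx
                rW = (i - 0.5) * dx
                div_r = (rE * vfE * cfE - rW * vfW * cfW) / (r * dx)
            vfN = 0.5 * (vz[i, j] + vz[i, j + 1])
            cfN = c0 if vfN > 0.0 else cN
            vfS = 0.5 * (vz[i, j - 1] + vz[i, j])
            cfS = cS if vfS > 0.0 else c0
            adv = -(div_r + (vfN * cfN - vfS * cfS) / dx)
            # membrane-confined diffusion: bulk diffusion + confinement
            # drift combine into (1/psi) div(psi grad c), discretized in
            # conservative flux form with geometric-mean face weights
            # (exact for the exponential psi skirt; monotone, so the
            # band boundary layer cannot oscillate at coarse dx)
            psE = _face_psi(ps, psi[i + 1, j])
            psN = _face_psi(ps, psi[i, j + 1])
            psS = _face_psi(ps, psi[i, j - 1])
            if i == 0:
                diff = (4.0 * psE * (cE - c0)
                        + psN * (cN - c0) + psS * (cS - c0)) / (dx2 * ps)
            else:
                psW = _face_psi(ps, psi[i - 1, j])
                rE = (i + 0.5) * dx
                rW = (i - 0.5) * dx
                diff = ((rE * psE * (cE - c0) + rW * psW * (cW - c0)) / r
                        + psN * (cN - c0) + psS * (cS - c0)) / (dx2 * ps)
            a = A[i, j]
            if which_A:
                react = a * a * B / (1.0 + a * a * inv_a2) / (1.0 + I[i, j]) - a
            else:
                if p_exp == 2:
                    react = k1 * a * a - k2 * I[i, j]
                else:
                    react = k1 * a - k2 * I[i, j]
            val = c0 + dt * (adv + D * diff + react)
            if val < 0.0:
                val = 0.0
            elif val > clamp:
                val = clamp
            nc[i, j] = val


@njit(cache=True)
def step_axisym(phi, A, I, psi, vr, vz, ftot, nphi, nA, nI,
                dx, dt, tau, eta, eps, MV, V0, At_total,
                F, K, Kp, nh, force_law,
                inv_a2, k1, k2, p_exp, DA, DI,
                beta, theta, gamma2, psi_cut, grad_cut, clamp,
                chi, gchi, use_bead, Arep, Aatt, drift_on, solve_I):
    """One fully coupled explicit Euler step.  New fields are written
    into nphi/nA/nI (caller swaps buffers).  Returns (V, S, B, vdz)."""
    V, S, intA = psi_and_integrals(phi, A, psi, dx, eps, beta, theta)
    B = At_total / S - intA / S
    if B < 0.0:
        B = 0.0
    MVterm = MV * (V - V0)
    force_and_velocity(phi, A, I, psi, vr, vz, ftot,
                       dx, tau, eta, eps, MVterm,
                       F, K, Kp, nh, force_law,
                       chi, gchi, use_bead, Arep, Aatt, grad_cut)
    vdz = 0.0
    if drift_on:
        vdz = drift_velocity_z(phi, ftot, dx, tau, V)
    update_phi(phi, ftot, nphi, vz, dx, dt, tau, vdz)
    species_step(A, A, I, phi, psi, vr, vz, nA, True,
                 DA, B, inv_a2, k1, k2, p_exp, beta, dx, dt,
                 gamma2, psi_cut, clamp)
    if solve_I:
        species_step(I, A, I, phi, psi, vr, vz, nI, False,
                     DI, B, inv_a2, k1, k2, p_exp, beta, dx, dt,
                     gamma2, psi_cut, clamp)
    return V, S, B, vdz


@njit(cache=True)
def step_phi_external_force(phi, Fpoly, nphi, vr, vz,
                            dx, dt, tau, eta, eps, MVterm, grad_cut):
    """Phase-field step under an externally prescribed protrusive force
    field (used by the reduced patch-boundary model).  Also fills the
    interface velocity components."""
    nr, nz = phi.shape
    dx2 = dx * dx
    eps2 = eps * eps
    for i in range(nr - 1):
        r = i * dx
        for j in range(1, nz - 1):
            f0 = phi[i, j]
            fE = phi[i + 1, j]
            fW = phi[1, j] if i == 0 else phi[i - 1, j]
            fN = phi[i, j + 1]
            fS = phi[i, j - 1]
            dpr = 0.0 if i == 0 else (fE - fW) / (2.0 * dx)
            dpz = (fN - fS) / (2.0 * dx)
            if i == 0:
                lap = 4.0 * (fE - f0) / dx2 + (fN - 2.0 * f0 + fS) / dx2
            else:
                lap = ((fE - 2.0 * f0 + fW) / dx2 + dpr / r
                       + (fN - 2.0 * f0 + fS) / dx2)
            gmag = np.sqrt(dpr * dpr + dpz * dpz)
            Gp = 16.0 * f0 * (1.0 - f0) * (1.0 - 2.0 * f0)
            curv = eta * (lap - Gp / eps2)
            ft = curv - MVterm * gmag + Fpoly[i, j] * gmag
            nphi[i, j] = f0 + dt * ft / tau
            if gmag > grad_cut:
                s = ft / (gmag * tau)
                vr[i, j] = -s * dpr / gmag
                vz[i, j] = -s * dpz / gmag
            else:
                vr[i, j] = 0.0
                vz[i, j] = 0.0


@njit(cache=True)
def volume_axisym(phi, dx):
    nr, nz = phi.shape
    V = 0.0
    for i in range(nr):
        w = TWO_PI * (i * dx) * dx * dx
        for j in range(nz):
            V += w * phi[i, j]
    return V


@njit(cache=True)
def closure_scan(phi, dx, i_scan=1, thresh=0.5):
    """Count 0->1 transitions of thresholded phi along the line
    r = i_scan*dx scanned from z = Lz down to z = 0.  Returns
    (count, zt, zb): the z of the first and second transitions
    (face midpoints), -1.0 when absent.  count == 2 flags an enclosed
    region."""
    nz = phi.shape[1]
    count = 0
    zt = -1.0
    zb = -1.0
    prev = phi[i_scan, nz - 1] >= thresh
    for j in range(nz - 2, -1, -1):
        cur = phi[i_scan, j] >= thresh
        if cur and not prev:
            count += 1
            z = (j + 0.5) * dx
            if count == 1:
                zt = z
            elif count == 2:
                zb = z
        prev = cur
    return count, zt, zb


@njit(cache=True)
def enclosed_volume(phi, dx, zb, zt, thresh=0.5):
    """Volume (um^3) of the enclosed phi < thresh region between
    z = zb and z = zt: per z-slice, a central disc (if the axis is
    vacant) or an annulus (if cell material sits on the axis), counted
    only when the run is bounded by cell material on the outside."""
    nr, nz = phi.shape
    jb = int(np.ceil(zb / dx))
    jt = int(np.floor(zt / dx))
    if jb < 0:
        jb = 0
    if jt > nz - 1:
        jt = nz - 1
    vol = 0.0
    for j in range(jb, jt + 1):
        i = 0
        if phi[0, j] >= thresh:
            # skip the central cell-material run -> annulus case
            while i < nr and phi[i, j] >= thresh:
                i += 1
        run = 0.0
        while i < nr and phi[i, j] < thresh:
            run += TWO_PI * (i * dx) * dx * dx
            i += 1
        if i < nr:  # bounded outside by cell material -> enclosed
            vol += run
    return vol


@njit(cache=True)
def max_abs(f):
    m = 0.0
    for v in f.flat:
        a = abs(v)
        if a > m:
            m = a
    return m
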