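"""Reduced patch-boundary model.

The reaction-diffusion patch is replaced by a single marker rb on the
membrane contour (phi = 0.5 level set in the z-r half-plane).  rb is
advected with the membrane and slides tangentially at vt (A0 - A),
where A is the normalized area of the membrane cap between rb and the
symmetry axis on the patch side:

    d(rb)/dt = v + vt T (A0 - A),     A = 2 pi int_C r ds / (4 pi R0^2)

with T the unit tangent oriented away from the patch interior, so the
patch expands while A < A0.  The protrusion site rp sits at arc length
dl beyond rb (outside the patch) and exerts a normal force
F f(rf - |x - rp|) with the sigmoid f(x) = 1/(1 + exp(-2.5 x)); phi
evolves under the same membrane mechanics as the full model.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np
import pandas as pd
from skimage import measure

from . import _kernels, fields
from .axisym import ClosureEvent, OutcomeRecord
from .params import SimulationParams, ReducedParams


def interface_contour(phi, dx, level=0.5):
    """Longest phi = level contour as an (N, 2) array of (r, z) points,
    ordered from the top axis endpoint (largest z) to the bottom, with
    cumulative arc length.  Raises if no contour reaches the axis."""
    contours = measure.find_contours(phi, level)
    if not contours:
        raise RuntimeError("interface contour lost")
    c = max(contours, key=len) * dx
    if c[0, 1] < c[-1, 1]:
        c = c[::-1]
    if min(c[0, 0], c[-1, 0]) > 2.0 * dx:
        raise RuntimeError("interface contour does not reach the axis")
    ds = np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    return c, s


def snap_to_contour(contour, s, point):
    """Continuous orthogonal projection of ``point`` onto the contour
    polyline; returns (arc length, projected point).  Projection is
    continuous (not vertex-quantized) so sub-cell tangential motion of
    the boundary marker accumulates."""
    p = np.asarray(point, dtype=float)
    seg = np.diff(contour, axis=0)                    # (N-1, 2)
    seg_len2 = np.maximum((seg ** 2).sum(axis=1), 1e-30)
    rel = p[None, :] - contour[:-1]
    tpar = np.clip((rel * seg).sum(axis=1) / seg_len2, 0.0, 1.0)
    proj = contour[:-1] + tpar[:, None] * seg
    d2 = ((proj - p[None, :]) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    sb = s[k] + tpar[k] * np.sqrt(seg_len2[k])
    return sb, proj[k]


def point_at_arc(contour, s, target):
    """Contour point at arc length ``target`` (clamped, interpolated)."""
    target = min(max(target, 0.0), s[-1])
    k = int(np.searchsorted(s, target))
    if k == 0:
        return contour[0]
    f = (target - s[k - 1]) / max(s[k] - s[k - 1], 1e-30)
    return contour[k - 1] + f * (contour[k] - contour[k - 1])


def tangent_at_arc(contour, s, target):
    """Unit tangent along increasing arc length (away from the patch,
    which occupies the top/low-s side)."""
    k = int(np.clip(np.searchsorted(s, target), 1, len(s) - 1))
    d = contour[k] - contour[k - 1]
    n = np.hypot(d[0], d[1])
    return d / max(n, 1e-30)


def patch_area(phi, rb, dx, R0, level=0.5):
    """Normalized patch area: 2 pi int r ds along the contour from the
    top axis endpoint to rb, over 4 pi R0^2.  rb at the top pole gives
    0; the whole contour gives ~1 for an undeformed sphere."""
    contour, s = interface_contour(phi, dx, level)
    sb, _ = snap_to_contour(contour, s, rb)
    mask = s <= sb
    if mask.sum() < 2:
        return 0.0
    r = contour[mask, 0]
    z = contour[mask, 1]
    ds = np.hypot(np.diff(r), np.diff(z))
    rmid = 0.5 * (r[:-1] + r[1:])
    return float(2.0 * math.pi * np.sum(rmid * ds) / (4.0 * math.pi * R0**2))


def sigmoid(x, slope=2.5):
    return 1.0 / (1.0 + np.exp(-slope * np.asarray(x, dtype=float)))


def force_profile_reduced(grid, rp, F, rf, slope=2.5):
    """Protrusive force field F * f(rf - |x - rp|) on the grid."""
    r, z = grid.coords()
    dist = np.hypot(r - rp[0], z - rp[1])
    return F * sigmoid(rf - dist, slope)


def advance_boundary(rb, v_rb, A, rp_tangent, rparams: ReducedParams, dt):
    """One update of the boundary marker: membrane advection plus
    tangential expansion at vt (A0 - A)."""
    vt_term = rparams.vt * (rparams.A0 - A) * rp_tangent
    return rb + dt * (np.asarray(v_rb) + vt_term)


def _bilinear(f, pt, dx):
    i = pt[0] / dx
    j = pt[1] / dx
    i0 = int(np.clip(np.floor(i), 0, f.shape[0] - 2))
    j0 = int(np.clip(np.floor(j), 0, f.shape[1] - 2))
    fi = i - i0
    fj = j - j0
    return ((1 - fi) * (1 - fj) * f[i0, j0] + fi * (1 - fj) * f[i0 + 1, j0]
            + (1 - fi) * fj * f[i0, j0 + 1] + fi * fj * f[i0 + 1, j0 + 1])


def run_reduced(p: SimulationParams, rparams: Optional[ReducedParams] = None,
                *, t_max=None, record_every: float = 1.0,
                update_every: float = 0.04, grid=None,
                stop_after_closures=None) -> OutcomeRecord:
    """Integrate the reduced model from a sphere with rb seeded near
    the top pole; same closure detection and outcome classification as
    the full axisymmetric solver."""
    rparams = rparams or ReducedParams()
    t_max = p.t_max if t_max is None else t_max
    if grid is None:
        grid = fields.AxisymGrid.from_extents(p.Lr, p.Lz, p.dx)
    center = (0.0, grid.Lz / 2.0)
    phi = fields.init_sphere_phi(grid, center, p.R0, p.eps)
    nphi = np.zeros_like(phi)
    vr = np.zeros_like(phi)
    vz = np.zeros_like(phi)
    dx = grid.dx

    contour, s = interface_contour(phi, dx)
    rb = np.array(point_at_arc(contour, s, max(p.rinit, dx)))

    n_steps = int(round(t_max / p.dt))
    upd_stride = max(1, int(round(update_every / p.dt)))
    rec_stride = max(1, int(round(record_every / p.dt)))

    Fpoly = np.zeros_like(phi)
    events: List[ClosureEvent] = []
    rows = []
    prev_count = 1
    t = 0.0
    A = 0.0

    for n in range(n_steps):
        if n % upd_stride == 0:
            contour, s = interface_contour(phi, dx)
            sb, rb_snap = snap_to_contour(contour, s, rb)
            rb = np.array(rb_snap)
            A = patch_area(phi, rb, dx, p.R0)
            rp = point_at_arc(contour, s, sb - rparams.dl)
            Fpoly = force_profile_reduced(grid, rp, p.F, rparams.rf,
                                          rparams.slope)
        V = _kernels.volume_axisym(phi, dx)
        _kernels.step_phi_external_force(phi, Fpoly, nphi, vr, vz,
                                         dx, p.dt, p.tau, p.eta, p.eps,
                                         p.MV * (V - p.V0), p.grad_cut)
        phi, nphi = nphi, phi
        if not np.isfinite(phi[::8, ::8]).all():
            raise FloatingPointError(f"reduced model blow-up at t={t:.2f}s")
        v_rb = (_bilinear(vr, rb, dx), _bilinear(vz, rb, dx))
        tang = tangent_at_arc(contour, s, sb)
        rb = advance_boundary(rb, v_rb, A, tang, rparams, p.dt)
        t += p.dt

        count, zt, zb = _kernels.closure_scan(phi, dx, 1, 0.5)
        if count >= 2 and count > prev_count:
            vol = _kernels.enclosed_volume(phi, dx, zb, zt, 0.5)
            events.append(ClosureEvent(time=t, volume=vol,
                                       fraction=vol / p.V0, zb=zb, zt=zt))
            if stop_after_closures and len(events) >= stop_after_closures:
                break
        prev_count = count
        if (n + 1) % rec_stride == 0:
            rows.append({"t": t, "V": V, "A_patch": A,
                         "rb_r": rb[0], "rb_z": rb[1],
                         "closure_count": count, "n_events": len(events)})

    return OutcomeRecord.classify(events, t, timeseries=pd.DataFrame(rows))
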