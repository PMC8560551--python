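"""Grids, interface kernels and discrete differential operators.

Two meshes are supported: a uniform Cartesian 3-D grid and an
axisymmetric (z-r half-plane) grid whose first radial sample lies on
the symmetry axis.  Axisymmetric arrays are indexed ``[i, j]`` with
``r = i*dx`` and ``z = j*dx``; 3-D arrays ``[i, j, k]`` with
``x = i*dx`` etc., offset by ``origin``.

All operators here are plain-numpy reference implementations, second
order in dx; the fused production steppers in :mod:`macrocup._kernels`
are validated against compositions of these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: steepness of the tanh interface kernel phi = (1 - tanh(a_k n/eps))/2.
#: Fixed by the double-well derivative G' = 16 phi(1-phi)(1-2phi)
#: = 4 a_k^2 phi(1-phi)(1-2phi), i.e. a_k = 2.  (Distinct from the
#: kinetic half-saturation alpha.)
KERNEL_STEEPNESS = 2.0


@dataclass(frozen=True)
class CartesianGrid3D:
    nx: int
    ny: int
    nz: int
    dx: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self):
        return (self.nx, self.ny, self.nz)

    def coords(self):
        """Meshgrid of physical coordinates (um)."""
        ax = [o + self.dx * np.arange(n)
              for o, n in zip(self.origin, self.shape)]
        return np.meshgrid(*ax, indexing="ij")

    @property
    def cell_volume(self):
        return self.dx**3


@dataclass(frozen=True)
class AxisymGrid:
    """z-r half-plane grid; node (i, j) sits at r = i*dx, z = j*dx."""

    nr: int
    nz: int
    dx: float

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self):
        return (self.nr, self.nz)

    @property
    def Lr(self):
        return (self.nr - 1) * self.dx

    @property
    def Lz(self):
        return (self.nz - 1) * self.dx

    def coords(self):
        r = self.dx * np.arange(self.nr)
        z = self.dx * np.arange(self.nz)
        return np.meshgrid(r, z, indexing="ij")

    def node_volumes(self):
        """Midpoint-rule volume weights 2 pi r dr dz (axis row weight 0)."""
        r = self.dx * np.arange(self.nr)
        return np.broadcast_to(
            (2.0 * np.pi * r * self.dx**2)[:, None], self.shape)

    @classmethod
    def from_extents(cls, Lr, Lz, dx):
        return cls(nr=int(round(Lr / dx)) + 1, nz=int(round(Lz / dx)) + 1, dx=dx)


# ----------------------------------------------------------------------
# interface kernels
# ----------------------------------------------------------------------

def phi_kernel(n, eps):
    """Interface profile (1 - tanh(2 n / eps))/2 of signed distance n
    (positive outside the cell)."""
    return 0.5 * (1.0 - np.tanh(KERNEL_STEEPNESS * np.asarray(n) / eps))


def init_sphere_phi(grid, center, R0, eps):
    """Phase field of a sphere of radius R0 at ``center``.

    ``center`` is (r, z) on an AxisymGrid (r must be 0 for a sphere
    respecting the symmetry axis) or (x, y, z) on a CartesianGrid3D.
    The sphere must fit inside the grid with a margin of 3*eps.
    """
    coords = grid.coords()
    if isinstance(grid, AxisymGrid):
        extents = (grid.Lr, grid.Lz)
        lows = (0.0, 0.0)
    else:
        extents = tuple(o + (n - 1) * grid.dx
                        for o, n in zip(grid.origin, grid.shape))
        lows = grid.origin
    for c, lo, hi, ax in zip(center, lows, extents, "rz" if len(center) == 2 else "xyz"):
        # the axis side of an axisymmetric grid may be tangent to the sphere
        if ax == "r":
            if c + R0 + 3 * eps > hi:
                raise ValueError("sphere exceeds grid bounds radially")
            continue
        if c - R0 - 3 * eps < lo or c + R0 + 3 * eps > hi:
            raise ValueError(f"sphere exceeds grid bounds along {ax}")
    dist = np.sqrt(sum((x - c) ** 2 for x, c in zip(coords, center)))
    return phi_kernel(dist - R0, eps)


def double_well_prime(phi):
    """G'(phi) = 16 phi (1-phi)(1-2 phi)."""
    phi = np.asarray(phi)
    return 16.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def compute_psi(phi, beta=100.0, theta=0.105):
    """Membrane indicator psi = 1/(1 + exp(-beta (phi(1-phi) - theta)))."""
    phi = np.asarray(phi)
    return 1.0 / (1.0 + np.exp(-beta * (phi * (1.0 - phi) - theta)))


# ----------------------------------------------------------------------
# integrals
# ----------------------------------------------------------------------

def integrate(values, grid):
    """Midpoint-rule integral of a nodal field over the grid (um^3 weights)."""
    if isinstance(grid, AxisymGrid):
        return float(np.sum(values * grid.node_volumes()))
    return float(np.sum(values) * grid.cell_volume)


def volume_of(phi, grid):
    """Cell volume V = integral of phi (um^3)."""
    return integrate(phi, grid)


def surface_area_of(psi, grid, eps):
    """Surface area S = integral of psi/eps (um^2)."""
    return integrate(psi, grid) / eps


# ----------------------------------------------------------------------
# discrete operators (reference implementations)
# ----------------------------------------------------------------------

def laplacian_cart3d(f, dx):
    """7-point Laplacian; boundary layer is left zero."""
    out = np.zeros_like(f)
    c = f[1:-1, 1:-1, 1:-1]
    out[1:-1, 1:-1, 1:-1] = (
        f[2:, 1:-1, 1:-1] + f[:-2, 1:-1, 1:-1]
        + f[1:-1, 2:, 1:-1] + f[1:-1, :-2, 1:-1]
        + f[1:-1, 1:-1, 2:] + f[1:-1, 1:-1, :-2] - 6.0 * c) / dx**2
    return out


def laplacian_axisym(f, dx):
    """r^-1 d/dr(r d/dr) + d2/dz2 with the on-axis limit 2 d2/dr2 + d2/dz2.

    Assumes Neumann symmetry at r=0; the outer-r and z boundary layers
    are left zero (they are pinned by Dirichlet conditions in the
    solvers).
    """
    out = np.zeros_like(f)
    r = dx * np.arange(f.shape[0])[:, None]
    dzz = np.zeros_like(f)
    dzz[:, 1:-1] = (f[:, 2:] - 2.0 * f[:, 1:-1] + f[:, :-2]) / dx**2
    # interior radial rows
    drr = (f[2:, :] - 2.0 * f[1:-1, :] + f[:-2, :]) / dx**2
    dr = (f[2:, :] - f[:-2, :]) / (2.0 * dx)
    out[1:-1, 1:-1] = drr[:, 1:-1] + dr[:, 1:-1] / r[1:-1] + dzz[1:-1, 1:-1]
    # axis row: 2 d2/dr2 + d2/dz2 with mirror symmetry f[-1] = f[1]
    out[0, 1:-1] = 4.0 * (f[1, 1:-1] - f[0, 1:-1]) / dx**2 + dzz[0, 1:-1]
    return out


def gradient_axisym(f, dx):
    """Central-difference (df/dr, df/dz); df/dr = 0 on the axis by
    symmetry.  Boundary layers are zero."""
    fr = np.zeros_like(f)
    fz = np.zeros_like(f)
    fr[1:-1, :] = (f[2:, :] - f[:-2, :]) / (2.0 * dx)
    fz[:, 1:-1] = (f[:, 2:] - f[:, :-2]) / (2.0 * dx)
    return fr, fz


def gradient_cart3d(f, dx):
    gx = np.zeros_like(f)
    gy = np.zeros_like(f)
    gz = np.zeros_like(f)
    gx[1:-1] = (f[2:] - f[:-2]) / (2.0 * dx)
    gy[:, 1:-1] = (f[:, 2:] - f[:, :-2]) / (2.0 * dx)
    gz[:, :, 1:-1] = (f[:, :, 2:] - f[:, :, :-2]) / (2.0 * dx)
    return gx, gy, gz


def grad_magnitude(grads):
    """|grad f| from component arrays."""
    return np.sqrt(sum(g * g for g in grads))


def divergence_axisym(vr, vz, dx):
    """(1/r) d(r vr)/dr + d(vz)/dz; on-axis limit 2 d(vr)/dr + d(vz)/dz
    (vr is odd in r, so the mirrored neighbor is -vr[1])."""
    out = np.zeros_like(vr)
    r = dx * np.arange(vr.shape[0])[:, None]
    dvz = np.zeros_like(vz)
    dvz[:, 1:-1] = (vz[:, 2:] - vz[:, :-2]) / (2.0 * dx)
    rvr = r * vr
    out[1:-1, 1:-1] = ((rvr[2:, 1:-1] - rvr[:-2, 1:-1]) / (2.0 * dx)
                       / r[1:-1]) + dvz[1:-1, 1:-1]
    out[0, 1:-1] = 2.0 * vr[1, 1:-1] / dx + dvz[0, 1:-1]
    return out


def upwind_div_axisym(c, vr, vz, dx):
    """Conservative first-order upwind divergence of the flux c*v on the
    axisymmetric grid: (1/r) d(r c vr)/dr + d(c vz)/dz.

    Face velocities are arithmetic means of the adjacent nodes; the
    upwind node value of c is used on each face.  On the axis the
    control volume is the disc r in [0, dx/2], giving 4 F_{1/2} / dx.
    Boundary layers are zero.
    """
    nr, nz = c.shape
    out = np.zeros_like(c)

    # radial face fluxes F[i] at r_{i+1/2}, i = 0..nr-2
    vf = 0.5 * (vr[:-1, :] + vr[1:, :])
    cf = np.where(vf > 0.0, c[:-1, :], c[1:, :])
    Fr = vf * cf
    rf = dx * (np.arange(nr - 1) + 0.5)[:, None]
    r = dx * np.arange(nr)[:, None]
    out[1:-1, :] = (rf[1:] * Fr[1:, :] - rf[:-1] * Fr[:-1, :]) / (r[1:-1] * dx)
    out[0, :] = 4.0 * Fr[0, :] / dx

    # axial face fluxes
    wf = 0.5 * (vz[:, :-1] + vz[:, 1:])
    cfz = np.where(wf > 0.0, c[:, :-1], c[:, 1:])
    Fz = wf * cfz
    out[:, 1:-1] += (Fz[:, 1:] - Fz[:, :-1]) / dx
    out[:, 0] = 0.0
    out[:, -1] = 0.0
    out[-1, :] = 0.0
    return out


def interface_band_width(psi, dx, axis_row=0):
    """Thickness (um) of the psi > 0.5 band along a radial ray --
    diagnostic used by the band-width property test."""
    mask = psi > 0.5
    return float(mask.sum(axis=0).max() * dx)
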