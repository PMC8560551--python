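"""Well-mixed (space-free) analysis of the activator/inhibitor kinetics.

The patch kinetics, stripped of space, are

    da/dt = a^2 b / (1 + a^2/alpha^2) * 1/(1 + I) - a
    dI/dt = k1 a^p - k2 I          (p = 2 by default)

with b the available inactive pool (treated as a parameter here; in the
full model b is enslaved to the conservation relation <a> + b = at).
Fixed points satisfy a b = (1 + a^2/alpha^2)(1 + kappa a^p) with
kappa = k1/k2.  In the unsaturated limit alpha -> inf and p = 2 the
nonzero fixed points are the roots of kappa a^2 - b a + 1 = 0:

    A+- = (b +- sqrt(b^2 - 4 kappa)) / (2 kappa).

A+ is stable for k2 > 1 (bistable regime) and unstable for k2 < 1
(excitable regime); the trace of the Jacobian at A+ is exactly 1 - k2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


@dataclass
class DimensionalParams:
    """Dimensional kinetic constants prior to nondimensionalization."""

    kA: float        # autocatalysis rate
    KA: float        # half-saturation of A
    KI: float        # inhibitor scale
    dA: float        # A -> B conversion rate
    at_dim: float    # dimensional total per area
    DA: float = 0.0
    DI: float = 0.0
    k1: float = 0.0
    k2: float = 1.0

    def __post_init__(self):
        for name in ("kA", "KA", "KI", "dA", "at_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def nondimensionalize(dp: DimensionalParams):
    """Map dimensional constants to the reduced parameter set.

    Returns (alpha, at_tilde, k1_tilde, k2_tilde, DA_tilde, DI_tilde)
    with alpha = kA/(KI dA), at_tilde = at_dim * alpha / KA,
    k1_tilde = k1 KA^2 / kA, k2_tilde = k2 / dA and diffusivities
    divided by dA.
    """
    alpha = dp.kA / (dp.KI * dp.dA)
    at_t = dp.at_dim * alpha / dp.KA
    k1_t = dp.k1 * dp.KA**2 / dp.kA
    k2_t = dp.k2 / dp.dA
    return alpha, at_t, k1_t, k2_t, dp.DA / dp.dA, dp.DI / dp.dA


@dataclass
class FixedPoint:
    A: float
    I: float
    eigenvalues: tuple
    stable: bool


@dataclass
class FixedPointReport:
    points: List[FixedPoint]
    regime: str  # "mono-stable" | "bistable" | "excitable"

    @property
    def nonzero(self):
        return [fp for fp in self.points if fp.A > 0]

    @property
    def A_plus(self) -> Optional[FixedPoint]:
        nz = self.nonzero
        return max(nz, key=lambda fp: fp.A) if nz else None

    @property
    def A_minus(self) -> Optional[FixedPoint]:
        nz = self.nonzero
        return min(nz, key=lambda fp: fp.A) if len(nz) >= 2 else None


def _fp_residual(a, B, kappa, inv_a2, p=2):
    """f(a) = a B - (1 + a^2/alpha^2)(1 + kappa a^p); roots are the
    nonzero fixed points."""
    return a * B - (1.0 + a * a * inv_a2) * (1.0 + kappa * a**p)


def jacobian(a, I, B, alpha, k1, k2, p=2):
    """Jacobian of (da/dt, dI/dt) at state (a, I) for fixed pool B."""
    inv_a2 = 0.0 if math.isinf(alpha) else 1.0 / alpha**2
    sat = 1.0 + a * a * inv_a2
    dfda = (2.0 * a * B / sat - a * a * B * 2.0 * a * inv_a2 / sat**2) / (1.0 + I) - 1.0
    dfdI = -a * a * B / sat / (1.0 + I) ** 2
    dgda = p * k1 * a ** (p - 1)
    dgdI = -k2
    return np.array([[dfda, dfdI], [dgda, dgdI]])


def fixed_points(B, k1, k2, alpha=math.inf, p=2) -> FixedPointReport:
    """All nonnegative fixed points of the well-mixed system with their
    linear stability, plus a regime label.

    Nonzero roots solve a B = (1 + a^2/alpha^2)(1 + kappa a^p),
    kappa = k1/k2; for p = 2 this is a polynomial solved exactly.
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    kappa = k1 / k2
    inv_a2 = 0.0 if math.isinf(alpha) else 1.0 / alpha**2

    if p == 2:
        # kappa*inv_a2 a^4 + (kappa + inv_a2) a^2 - B a + 1 = 0
        coeffs = [kappa * inv_a2, 0.0, kappa + inv_a2, -B, 1.0]
        roots = np.roots(np.trim_zeros(np.array(coeffs), "f"))
    else:
        # p = 1: inv_a2*kappa a^3 + inv_a2 a^2 + kappa a ... solve generically
        coeffs = [kappa * inv_a2, inv_a2, kappa - B, 1.0]
        roots = np.roots(np.trim_zeros(np.array(coeffs), "f"))
    real = [float(r.real) for r in roots
            if abs(r.imag) < 1e-9 * max(1.0, abs(r)) and r.real > 1e-12]

    pts = []
    for a in [0.0] + sorted(real):
        I = kappa * a**p
        J = jacobian(a, I, B, alpha, k1, k2, p)
        ev = np.linalg.eigvals(J)
        pts.append(FixedPoint(A=a, I=I, eigenvalues=tuple(ev),
                              stable=bool(np.all(ev.real < 0))))

    nz = [fp for fp in pts if fp.A > 0]
    if not nz:
        regime = "mono-stable"
    else:
        a_plus = max(nz, key=lambda fp: fp.A)
        regime = "bistable" if a_plus.stable else "excitable"
    return FixedPointReport(points=pts, regime=regime)


def stability_scan(k1, k2_range, B, alpha=math.inf, p=2, tol=1e-6):
    """Locate the k2 at which A+ changes linear stability.

    Bisects the sign of the leading eigenvalue's real part of the
    Jacobian at A+ over ``k2_range = (lo, hi)``.  Raises if A+ does not
    exist at either end (boundary of existence, a degenerate double
    root, is reported as such).
    """

    def leading_real(k2):
        rep = fixed_points(B, k1, k2, alpha, p)
        ap = rep.A_plus
        if ap is None:
            raise ValueError(
                f"A+ does not exist at k2={k2}: boundary of existence, "
                "not a stability boundary")
        return max(ev.real for ev in ap.eigenvalues)

    lo, hi = k2_range
    flo, fhi = leading_real(lo), leading_real(hi)
    if flo * fhi > 0:
        raise ValueError("leading eigenvalue does not change sign on the range")
    return brentq(leading_real, lo, hi, xtol=tol)


def annihilation_condition(at, alpha, kappa):
    """Sufficient condition for patch annihilation:
    kappa > (9/32) at^2 - 1/alpha^2.

    When true, no nonzero fixed point exists for any pool value
    0 <= b <= at, so an activated patch must decay.
    """
    inv_a2 = 0.0 if math.isinf(alpha) else 1.0 / alpha**2
    return kappa > (9.0 / 32.0) * at**2 - inv_a2


def has_nonzero_fixed_point(at, alpha, kappa, p=2, n_b=200, n_a=2000):
    """Brute-force oracle: scan b over [0, at] and test f(a) = 0 for
    some a > 0 by dense root bracketing.  f is maximal at b = at, so it
    suffices to scan a at b = at -- but we scan b anyway to keep this
    independent of that monotonicity argument."""
    inv_a2 = 0.0 if math.isinf(alpha) else 1.0 / alpha**2
    a_grid = np.linspace(1e-6, max(10.0 * at, 50.0), n_a)
    for b in np.linspace(0.0, at, n_b):
        f = _fp_residual(a_grid, b, kappa, inv_a2, p)
        if np.any(f >= 0.0):
            return True
    return False


def simulate_wellmixed(A0, I0, B, k1, k2, alpha=math.inf, p=2, T=200.0,
                       at=None, rtol=1e-8, atol=1e-10):
    """Integrate the well-mixed kinetics with an adaptive ODE solver.

    If ``at`` is given, the pool is enslaved to conservation,
    b = at - a; otherwise ``B`` is held fixed.  Serves as the
    brute-force oracle for the fixed-point and annihilation analyses.
    """
    inv_a2 = 0.0 if math.isinf(alpha) else 1.0 / alpha**2

    def rhs(t, y):
        a, I = y
        b = (at - a) if at is not None else B
        da = a * a * b / (1.0 + a * a * inv_a2) / (1.0 + I) - a
        dI = k1 * a**p - k2 * I
        return [da, dI]

    sol = solve_ivp(rhs, (0.0, T), [A0, I0], rtol=rtol, atol=atol,
                    dense_output=True, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def regime_table(at_values, k2_values, k1, alpha=math.inf, p=2):
    """Regime map over (at, k2) at fixed k1, mirroring the well-mixed
    phase diagram axes; returns a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = []
    for at in np.atleast_1d(at_values):
        for k2 in np.atleast_1d(k2_values):
            kappa = k1 / k2
            # existence threshold at = B = 2 sqrt(kappa) for alpha -> inf
            rep = fixed_points(at, k1, k2, alpha, p)
            rows.append({
                "at": at, "k2": k2,
                "n_fixed_points": len(rep.points),
                "regime": rep.regime,
                "A_plus": rep.A_plus.A if rep.A_plus else np.nan,
                "A_minus": rep.A_minus.A if rep.A_minus else np.nan,
                "annihilates": annihilation_condition(at, alpha, kappa),
            })
    return pd.DataFrame(rows)
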