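"""Parameter blocks for the cup-formation model.

All quantities carry the units noted on each field.  The model couples a
phase field ``phi`` (1 inside the cell, 0 outside) evolved by curvature
flow + volume constraint + protrusive force, to membrane-bound
reaction-diffusion species A (activator) and I (inhibitor) with a
globally conserved inactive pool B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict
from typing import Optional

#: reference explicit-Euler time step at the reference mesh dx = 0.1 um
DT_REF = 4.0e-4
DX_REF = 0.1

FORCE_LAWS = ("edge", "inhibited")


@dataclass
class SimulationParams:
    """Physical and numerical constants of the coupled model.

    Geometry / mesh
    ---------------
    R0 : cell radius (um); V0 = 4 pi R0^3 / 3 is the target volume.
    eps : interface width of the phase field (um).
    dx : mesh spacing (um); dt scales as dt_ref * (dx/0.1)^2 unless given.
    Lr, Lz : extents of the axisymmetric half-plane domain (um).
    box : edge length of the cubic 3-D domain (um).

    Mechanics
    ---------
    tau : deformation timescale (s nN/um^3); 1/tau is membrane velocity
        per unit stress.
    eta : cortical surface tension (nN/um).
    MV : volume-constraint stiffness (nN/um^5).
    F : protrusive force magnitude (nN/um^2).
    K, Kprime : half-maximal activator levels for force induction /
        suppression (concentration units).
    nh : Hill coefficient of the force law.
    force_law : "edge" (force suppressed at high A, so it localizes to
        the patch edge) or "inhibited" (force competitively suppressed
        by the inhibitor I).

    Patch kinetics (dimensionless concentration units)
    --------------------------------------------------
    at : total A+B per unit minimal surface area, at = At / (4 pi R0^2).
    alpha : half-saturation of the autocatalytic B->A step; ``inf`` is a
        first-class value (unsaturated autocatalysis).
    k1, k2 : inhibitor production (s^-1 c^-(p)) / decay (s^-1) rates.
    p : exponent of A in inhibitor production (2 default; 1 exposed as
        the linear variant, which does not support patch splitting).
    DA, DI : diffusivities of A and I (um^2/s).

    Interface band and numerics
    ---------------------------
    beta, theta : sharpness and threshold of the membrane indicator
        psi = 1/(1 + exp(-beta(phi(1-phi) - theta))).
    gamma2 : off-membrane decay rate of A and I (s^-1).
    psi_cut : below this psi the RD equations are replaced by decay.
    grad_cut : |grad phi| below which the interface velocity is zero.
    clamp : upper limit applied to A and I after each step.

    Protocol
    --------
    rinit : radius of the seeded activator patch (um).
    t_max : simulation horizon (s).
    seed : RNG seed for seeding / nucleation noise.
    """

    # geometry / mesh
    R0: float = 10.0
    eps: float = 0.8
    dx: float = 0.1
    dt: Optional[float] = None
    Lr: float = 15.0
    Lz: float = 40.0
    box: float = 25.6

    # mechanics
    tau: float = 10.0
    eta: float = 0.5
    MV: float = 5.0
    F: float = 2.0
    K: float = 0.005
    Kprime: float = 0.25
    nh: float = 3.0
    force_law: str = "edge"

    # patch kinetics
    at: float = 2.8
    alpha: float = 1.0
    k1: float = 0.0
    k2: float = 2.0e-4
    p: int = 2
    DA: float = 0.1
    DI: float = 0.01

    # interface band + numerics
    beta: float = 100.0
    theta: float = 0.105
    gamma2: float = 10.0
    psi_cut: float = 1.0e-3
    grad_cut: float = 1.0e-3
    clamp: float = 50.0

    # protocol
    rinit: float = 1.5
    t_max: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if self.dt is None:
            dt = DT_REF * (self.dx / DX_REF) ** 2
            # The global volume constraint relaxes V at rate ~ MV S / tau,
            # which is independent of dx; explicit stability requires
            # dt < 2 tau / (MV S).  Cap with margin for surface growth.
            if self.MV > 0:
                dt = min(dt, self.tau / (self.MV * 4.0 * math.pi * self.R0**2))
            self.dt = dt
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def V0(self) -> float:
        """Target cell volume (um^3)."""
        return 4.0 * math.pi * self.R0**3 / 3.0

    @property
    def At_total(self) -> float:
        """Total amount of A+B, at * 4 pi R0^2."""
        return self.at * 4.0 * math.pi * self.R0**2

    @property
    def inv_alpha2(self) -> float:
        """1/alpha^2, with the unsaturated limit alpha=inf mapping to 0."""
        return 0.0 if math.isinf(self.alpha) else 1.0 / self.alpha**2

    def validate(self) -> None:
        positive = ("R0", "eps", "dx", "dt", "Lr", "Lz", "box", "tau", "eta",
                    "K", "Kprime", "nh", "at", "alpha", "k2", "beta",
                    "gamma2", "clamp", "t_max")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        nonneg = ("MV", "F", "k1", "DA", "DI", "psi_cut", "grad_cut", "rinit")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.force_law not in FORCE_LAWS:
            raise ValueError(f"force_law must be one of {FORCE_LAWS}")
        if not 0.0 < self.theta < 0.25:
            raise ValueError("theta must lie in (0, 1/4) so the psi=1 band exists")
        if self.p not in (1, 2):
            raise ValueError("p must be 1 or 2")
        dt_max = DT_REF * (self.dx / DX_REF) ** 2
        if self.dt > dt_max * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} exceeds stability bound {dt_max} for dx={self.dx}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(self.alpha):
            d["alpha"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if isinstance(d.get("alpha"), str):
            d["alpha"] = float(d["alpha"])
        return cls(**d)

    def replace(self, **kw) -> "SimulationParams":
        d = asdict(self)
        d.update(kw)
        return SimulationParams(**d)


@dataclass
class NoiseParams:
    """Stochastic nucleation of activator patches.

    Events occur as a Poisson process at rate ``lam`` per um^3 per
    second; each adds a Gaussian bump N0 exp(-|x-xc|^2 / 2 d^2) to A,
    with amplitude N0 ~ Exponential(mean sigma) and xc uniform in the
    domain.  ``d`` is in um (1.5 um = 15 lattice units at the reference
    mesh dx = 0.1 um).
    """

    sigma: float = 8.0
    d: float = 1.5
    lam: float = 3.0e-5

    def __post_init__(self):
        if self.sigma < 0 or self.d < 0 or self.lam < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class BeadSpec:
    """A rigid spherical particle described by a static indicator field
    chi(r) = (1 + tanh((Rb - |r - rb|) / (eps/2))) / 2.

    Arep penalizes cell/bead overlap (excluded volume); Aatt rewards
    membrane/bead-surface contact (adhesion).  ``center=None`` places
    the bead tangent to the membrane on the seed-patch axis.
    """

    Rb: float = 2.0
    Arep: float = 5.0
    Aatt: float = 0.8
    center: Optional[tuple] = None

    def __post_init__(self):
        if self.Rb <= 0:
            raise ValueError("Rb must be positive")
        if self.Arep < 0 or self.Aatt < 0:
            raise ValueError("Arep, Aatt must be nonnegative")


@dataclass
class ReducedParams:
    """Reduced patch-boundary model: the reaction-diffusion patch is
    replaced by a marker rb on the interface contour.

    vt : tangential speed coefficient (um/s) -- rb moves along the
        membrane at vt*(A0 - A) until the normalized patch area A
        reaches A0 (the proxy for at).  The default makes vt*A0
        comparable to the full model's patch front speed (~0.3 um/s);
        much slower and the protrusion outruns the patch edge.
    A0 : target patch area, as a fraction of the sphere area 4 pi R0^2.
    dl : arc-length offset of the protrusion site from rb, on the
        patch side (um).
    rf : half-width of the protrusion site (um); must be comparable to
        the interface width eps to deform it.
    slope : sigmoid slope of the force profile f(x)=1/(1+exp(-slope*x)).
    """

    vt: float = 1.0
    A0: float = 0.35
    dl: float = 0.8
    rf: float = 1.2
    slope: float = 2.5

    def __post_init__(self):
        if min(self.vt, self.dl, self.rf, self.slope) <= 0:
            raise ValueError("vt, dl, rf, slope must be positive")
        if not 0.0 < self.A0 <= 1.0:
            raise ValueError("A0 must lie in (0, 1]")
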