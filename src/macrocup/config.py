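"""Configuration files, named parameter presets, snapshots and run
manifests.

Config files are YAML with up to four blocks::

    preset: cup-closure        # optional named preset (applied first)
    params: {F: 2.0, at: 2.8}  # SimulationParams overrides
    noise:  {sigma: 8.0, d: 1.5, lam: 3.0e-5}
    bead:   {Rb: 2.0, Arep: 5.0, Aatt: 0.8}
    reduced: {vt: 0.1, A0: 0.35, dl: 0.8, rf: 0.5}

Unknown keys are rejected; an empty file yields the documented
defaults and round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .params import SimulationParams, NoiseParams, BeadSpec, ReducedParams

#: Named parameter presets.  Values follow the published model's
#: parameter table and the scenario each regime demonstrates.
PRESETS = {
    # patch dynamics on a (nearly) static membrane: no protrusive force
    "spot-static":   dict(F=0.0, at=2.6, alpha=1.0, DA=0.1, k1=0.0),
    "spot-decay":    dict(F=0.0, at=2.6, alpha=1.0, DA=0.1, DI=0.01,
                          k1=2.0e-4, k2=2.0e-4),
    "spot-splitting": dict(F=0.0, at=1.985, alpha=50.0, DA=0.085, DI=0.11,
                           k1=0.088, k2=0.54),
    # cup phase-diagram regimes (eta = 0.5, so F = (F/eta)/2)
    "cup-closure":      dict(F=2.0, at=2.8, tau=10.0, k1=0.0, alpha=1.0,
                             DA=0.1, K=0.005, Kprime=0.25, nh=3.0, rinit=1.5),
    "small-cup":        dict(F=2.6, at=2.6, tau=10.0, k1=0.0, alpha=1.0,
                             DA=0.1),
    "weak-force":       dict(F=0.8, at=2.8, tau=10.0, k1=0.0, alpha=1.0,
                             DA=0.1),
    "small-patch":      dict(F=1.6, at=2.5, tau=10.0, k1=0.0, alpha=1.0,
                             DA=0.1),
    "repetitive-waist": dict(F=1.4, at=2.8, tau=10.0, k1=0.0, alpha=1.0,
                             DA=0.1),
    "repetitive-stall": dict(F=1.2, at=2.7, tau=10.0, k1=0.0, alpha=1.0,
                             DA=0.1),
    # excitable / splitting regime (weakly saturated autocatalysis,
    # inhibitor-suppressed force).  alpha = 50 is the finite table
    # value: with the A, I <= 50 clamp a fully unsaturated seeded site
    # freezes at the clamp instead of pulsing (see docs/methods.md);
    # alpha = inf remains available for the well-mixed analysis.
    "splitting-cup":   dict(F=3.7, at=1.985, tau=7.0, alpha=50.0,
                            k1=0.088, k2=0.54, DA=0.085, DI=0.11,
                            K=0.01, Kprime=0.1, nh=5.0,
                            force_law="inhibited"),
    "splitting-cup-2": dict(F=3.0, at=1.94, tau=20.0, alpha=50.0,
                            k1=0.088, k2=0.54, DA=0.26, DI=0.87,
                            K=0.086, Kprime=1.8, nh=3.0,
                            force_law="inhibited"),
}

#: extra (non-SimulationParams) blocks some presets carry
PRESET_EXTRAS = {
    "multi-cup-noise": {"base": "cup-closure",
                        "noise": dict(sigma=8.0, d=1.5, lam=3.0e-5)},
    "bead-uptake": {"base": "cup-closure",
                    "params": dict(k1=2.0e-4, k2=2.0e-4, DI=0.01),
                    "bead": dict(Rb=2.0, Arep=5.0, Aatt=0.8)},
}


@dataclass
class RunConfig:
    params: SimulationParams
    noise: Optional[NoiseParams] = None
    bead: Optional[BeadSpec] = None
    reduced: Optional[ReducedParams] = None

    def to_dict(self):
        d = {"params": self.params.to_dict()}
        for name in ("noise", "bead", "reduced"):
            block = getattr(self, name)
            if block is not None:
                d[name] = dataclasses.asdict(block)
        return d


def resolve_preset(name: str):
    """Parameter overrides + extra blocks for a named preset."""
    if name in PRESETS:
        return dict(PRESETS[name]), {}
    if name in PRESET_EXTRAS:
        spec = PRESET_EXTRAS[name]
        base, _ = resolve_preset(spec["base"])
        base.update(spec.get("params", {}))
        extras = {k: v for k, v in spec.items() if k in ("noise", "bead")}
        return base, extras
    raise KeyError(f"unknown preset {name!r}; available: "
                   f"{sorted(list(PRESETS) + list(PRESET_EXTRAS))}")


def load_config(path=None, preset: Optional[str] = None,
                overrides: Optional[dict] = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file and/or preset name.

    Precedence (low to high): defaults < preset < file blocks <
    ``overrides``.
    """
    doc = {}
    if path is not None:
        text = pathlib.Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ValueError("config root must be a mapping")
    unknown = set(doc) - {"preset", "params", "noise", "bead", "reduced"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")

    pdict = {}
    extras = {}
    name = preset or doc.get("preset")
    if name:
        pdict, extras = resolve_preset(name)
    pdict.update(doc.get("params") or {})
    pdict.update(overrides or {})
    params = SimulationParams.from_dict(pdict)

    def build(cls, block):
        if block is None:
            return None
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(block) - known
        if bad:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
        return cls(**block)

    noise = build(NoiseParams, doc.get("noise", extras.get("noise")))
    bead = build(BeadSpec, doc.get("bead", extras.get("bead")))
    reduced = build(ReducedParams, doc.get("reduced"))
    return RunConfig(params=params, noise=noise, bead=bead, reduced=reduced)


def save_config(cfg: RunConfig, path):
    pathlib.Path(path).write_text(yaml.safe_dump(cfg.to_dict(),
                                                 sort_keys=False))


# ----------------------------------------------------------------------
# snapshots, time series, manifests
# ----------------------------------------------------------------------

def write_snapshot_csv(state, path, extra=None):
    """Axisymmetric field dump: one row per node with coordinates in
    um (columns r, z, phi, A, I [+ extras])."""
    import pandas as pd

    grid = state.grid
    r, z = grid.coords()
    cols = {"r": r.ravel(), "z": z.ravel(), "phi": state.phi.ravel(),
            "A": state.A.ravel(), "I": state.I.ravel()}
    for name, arr in (extra or {}).items():
        cols[name] = arr.ravel()
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_snapshot_csv(path, grid):
    import pandas as pd

    df = pd.read_csv(path)
    shape = grid.shape
    return {c: df[c].to_numpy().reshape(shape)
            for c in df.columns if c not in ("r", "z")}


def write_vtk_structured(path, grid, fields_dict):
    """Legacy ASCII VTK STRUCTURED_POINTS file of 3-D nodal scalars
    (readable by ParaView/VisIt); coordinates in um."""
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "macrocup snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {grid.dx} {grid.dx} {grid.dx}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields_dict.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr).transpose(2, 1, 0).ravel()  # x fastest
        lines.extend(" ".join(f"{v:.6g}" for v in flat[k:k + 9])
                     for k in range(0, flat.size, 9))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def save_timeseries_hdf5(df, path, meta=None):
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("timeseries")
        for col in df.columns:
            g.create_dataset(col, data=df[col].to_numpy())
        if meta:
            for k, v in meta.items():
                f.attrs[k] = v


def write_manifest(cfg: RunConfig, path, seed=None, extra=None):
    """JSON manifest sufficient to re-run a simulation exactly."""
    doc = {"version": __version__, "config": cfg.to_dict(),
           "seed": cfg.params.seed if seed is None else seed}
    doc.update(extra or {})
    pathlib.Path(path).write_text(json.dumps(doc, indent=2, default=str))
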