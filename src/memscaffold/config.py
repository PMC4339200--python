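"""Run configuration: YAML schema, validation, CSV output with manifests.

All lengths in a config carry an explicit unit tag ("a" for scaffold radii,
"nm" for the BAR preset); energies are always k_B T.  Unknown keys are
rejected so typos fail loudly.  Written tables get a JSON manifest sidecar
with a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .geometry import ModelParameters, ScaffoldShape, preset, PRESETS

__all__ = ["RunConfig", "load_config", "config_hash", "write_curve",
           "read_curve"]

_SHAPE_KEYS = {"preset", "rho_a", "rho_b", "r_a", "r_b", "units",
               "cb_over_ca", "c_b", "aspect"}
_MODEL_KEYS = {"kappa", "gamma", "L", "L_factor", "h", "gtol", "ftol",
               "max_iter", "n_cycles", "xyz_stages", "n_levels", "energy_tol",
               "n_phi_nodes", "n_theta_nodes", "theta_window_kbt", "seed"}
_SWEEP_KEYS = {"d", "d_min", "d_max", "n_d", "d_ref", "phi", "theta",
               "phi_grid", "theta_grid"}
_TOP_KEYS = {"shape", "model", "sweep", "profile", "outdir", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (shape + model + sweep grids)."""

    shape: ScaffoldShape
    model: ModelParameters
    sweep: dict = field(default_factory=dict)
    profile: str = "coarse"
    outdir: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(
            shape=dict(rho_a=self.shape.rho_a,
                       rho_b=None if np.isinf(self.shape.rho_b) else self.shape.rho_b,
                       r_a=self.shape.r_a, r_b=self.shape.r_b,
                       units=self.shape.units),
            model={k: v for k, v in asdict(self.model).items()},
            sweep=dict(self.sweep), profile=self.profile,
            outdir=self.outdir, seed=self.seed)
        return d


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build_shape(sd: dict) -> ScaffoldShape:
    _reject_unknown(sd, _SHAPE_KEYS, "shape")
    if "preset" in sd:
        name = sd["preset"]
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
        kw = {}
        if name == "shallow_circular" and "cb_over_ca" in sd:
            kw["cb_over_ca"] = float(sd["cb_over_ca"])
        if name == "endophilin_nbar" and "c_b" in sd:
            kw["c_b"] = float(sd["c_b"])
        return preset(name, **kw)
    missing = {"rho_a", "r_a", "r_b", "units"} - set(sd)
    if missing:
        raise ValueError(f"shape config missing key(s): {sorted(missing)} "
                         "(explicit shapes must carry a unit tag)")
    rho_b = sd.get("rho_b")
    return ScaffoldShape(rho_a=float(sd["rho_a"]),
                         rho_b=np.inf if rho_b in (None, "inf") else float(rho_b),
                         r_a=float(sd["r_a"]), r_b=float(sd["r_b"]),
                         units=sd["units"])


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Minimal configs need only a shape preset; the membrane bending modulus
    defaults to 20 k_B T and tension to zero.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    if "shape" not in raw:
        raise ValueError("config must define a shape")
    shape = _build_shape(raw["shape"] or {})
    md = dict(raw.get("model") or {})
    _reject_unknown(md, _MODEL_KEYS, "model")
    if "seed" in raw:
        md.setdefault("seed", int(raw["seed"]))
    model = ModelParameters(**md)
    sweep = dict(raw.get("sweep") or {})
    _reject_unknown(sweep, _SWEEP_KEYS, "sweep")
    return RunConfig(shape=shape, model=model, sweep=sweep,
                     profile=raw.get("profile", "coarse"),
                     outdir=raw.get("outdir"), seed=int(raw.get("seed", 0)))


def config_hash(config) -> str:
    """Stable hash of a configuration mapping (or RunConfig)."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_curve(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    """Write a table as CSV (12 significant digits) with a manifest sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    manifest = dict(columns=list(df.columns), n_rows=int(len(df)))
    if config is not None:
        manifest["config"] = config
        manifest["config_hash"] = config_hash(config)
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def read_curve(path) -> pd.DataFrame:
    return pd.read_csv(path)
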