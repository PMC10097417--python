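"""Configuration, presets, serialization and reproducibility plumbing.

A run is fully described by a strict YAML config with four blocks
(geometry, material, transport, solver) plus a seed; unknown keys are
rejected with a message naming the offending key. Named presets mirror
the in-silico experiments (OSVZ division-rate sweeps, VZ/OSVZ tradeoff,
MST sweep, heterogeneous OSVZ patterns). Output formats are plain text:
legacy-ASCII VTK unstructured grids for fields, tidy CSV for metric
series, JSON for the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import MaterialParams, lame_lambda, shear_modulus_profile
from .geometry import GeometryParams, zone_weight_osvz, zone_weight_vz
from .morphometrics import MorphoTrace
from .solver import SolverConfig
from .transport import (
    HeterogeneityPattern,
    TransportParams,
    pattern_multiplier,
    source_osvz,
    source_vz,
)

__all__ = [
    "RunConfig",
    "PRESETS",
    "load_config",
    "config_hash",
    "config_to_dict",
    "write_state_vtk",
    "read_vtk",
    "emit_metrics_csv",
    "load_metrics_csv",
    "write_manifest",
    "GW0",
    "gestational_week",
]

GW0 = 11.0  # the reference configuration represents gestational week 11


def gestational_week(t_days):
    """Gestational week for simulation time t (days): GW = 11 + t/7."""
    return GW0 + np.asarray(t_days, dtype=float) / 7.0


@dataclasses.dataclass(frozen=True)
class RunConfig:
    geometry: GeometryParams = GeometryParams()
    material: MaterialParams = MaterialParams()
    transport: TransportParams = TransportParams()
    solver: SolverConfig = SolverConfig()
    seed: int = 0

    def with_(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


# Named experiment presets. Stiffness ratio: 8 for constant stiffness,
# 3 for varying stiffness; G_vz = 120 for the division-rate sweeps.
def _p(mode, beta_mu, gvz, gosvz, **extra):
    d = {
        "material": {"stiffness_mode": mode, "beta_mu": beta_mu},
        "transport": {"G_vz": gvz, "G_osvz": gosvz},
    }
    for k, v in extra.items():
        d.setdefault(k, {}).update(v)
    return d


PRESETS = {
    "varying_g120_o0": _p("varying", 3, 120, 0),
    "varying_g120_o10": _p("varying", 3, 120, 10),
    "varying_g120_o20": _p("varying", 3, 120, 20),
    "varying_g120_o30": _p("varying", 3, 120, 30),
    "constant_g120_o0": _p("constant", 8, 120, 0),
    "constant_g120_o10": _p("constant", 8, 120, 10),
    "constant_g120_o20": _p("constant", 8, 120, 20),
    "tradeoff_120_0": _p("varying", 3, 120, 0),
    "tradeoff_90_10": _p("varying", 3, 90, 10),
    "tradeoff_60_20": _p("varying", 3, 60, 20),
    "tradeoff_30_30": _p("varying", 3, 30, 30),
    "mst_sweep": _p("varying", 3, 30, 30),
    "hetero_gradient": _p(
        "varying", 3, 120, 20,
        transport={"heterogeneity": {"kind": "circumferential_gradient"}},
    ),
    "hetero_random": _p(
        "varying", 3, 120, 20,
        transport={"heterogeneity": {"kind": "random_sectors"}},
    ),
}


_BLOCKS = {
    "geometry": GeometryParams,
    "material": MaterialParams,
    "transport": TransportParams,
    "solver": SolverConfig,
}


def _build_block(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key '{path}.{key}'")
        if key == "heterogeneity" and isinstance(val, dict):
            val = _build_block(HeterogeneityPattern, val, f"{path}.{key}")
        if key == "relative_range" and val is not None:
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid '{path}' block: {exc}") from exc


def _deep_update(base: dict, extra: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, preset: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``path`` is a YAML file (may be empty -> all defaults); ``preset``
    applies one of the named experiment presets before the file and
    ``overrides`` (a nested dict) after it.
    """
    data: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset '{preset}'; available: {sorted(PRESETS)}"
            )
        data = _deep_update(data, PRESETS[preset])
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data = _deep_update(data, loaded)
    if overrides:
        data = _deep_update(data, overrides)

    seed = 0
    blocks = {}
    for key, val in data.items():
        if key == "seed":
            seed = int(val)
            continue
        if key not in _BLOCKS:
            raise ValueError(f"unknown config block '{key}'")
        if not isinstance(val, dict):
            raise ValueError(f"config block '{key}' must be a mapping")
        blocks[key] = _build_block(_BLOCKS[key], val, key)
    cfg = RunConfig(
        geometry=blocks.get("geometry", GeometryParams()),
        material=blocks.get("material", MaterialParams()),
        transport=blocks.get("transport", TransportParams()),
        solver=blocks.get("solver", SolverConfig()),
        seed=seed,
    )
    # route the top-level seed into the solver's perturbation seed unless
    # the solver block set one explicitly
    if "solver" not in blocks or "seed" not in data.get("solver", {}):
        cfg = cfg.with_(solver=cfg.solver.with_(seed=cfg.seed))
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 over the canonical JSON form of the config."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# VTK (legacy ASCII unstructured grid)


def write_state_vtk(state, path, mat: MaterialParams | None = None,
                    trans: TransportParams | None = None):
    """Write a state as a legacy-ASCII VTK unstructured grid.

    Point data: displacement, density. Cell data (element means): shear
    modulus, growth multipliers, zone weights and division-rate fields
    when ``mat``/``trans`` are given. Points are the deformed coordinates.
    """
    mesh = state.mesh
    xdef = mesh.nodes + state.u
    lines = [
        "# vtk DataFile Version 3.0",
        f"cortigrow state t={state.time}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in xdef:
        lines.append(f"{p[0]:.17g} {p[1]:.17g} 0")
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    for e in mesh.elements:
        lines.append("4 " + " ".join(str(int(i)) for i in e))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["9"] * mesh.n_elements)

    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS displacement double")
    for v in state.u:
        lines.append(f"{v[0]:.17g} {v[1]:.17g} 0")
    lines.append("SCALARS density double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.17g}" for v in state.c)

    cell_fields = {}
    if hasattr(state, "growth"):
        cell_fields["theta_perp"] = state.growth.theta_perp.mean(axis=1)
        cell_fields["theta_par"] = state.growth.theta_par.mean(axis=1)
    ri_c = state.mesh.material_radius[mesh.elements].mean(axis=1)
    theta_c = np.arctan2(
        mesh.nodes[mesh.elements, 1].mean(axis=1),
        mesh.nodes[mesh.elements, 0].mean(axis=1),
    )
    c_cell = state.c[mesh.elements].mean(axis=1)
    geom = state.geom
    if mat is not None:
        cell_fields["mu"] = shear_modulus_profile(ri_c, c_cell, mat, geom.r_cp)
    cell_fields["zone_vz"] = zone_weight_vz(ri_c, geom)
    cell_fields["zone_osvz"] = zone_weight_osvz(ri_c, state.time, geom)
    if trans is not None:
        s = getattr(state, "s", 1.0)
        cell_fields["rate_vz"] = source_vz(ri_c, s, trans, geom)
        cell_fields["rate_osvz"] = source_osvz(
            ri_c, theta_c, state.time, s, trans, geom
        )
    if cell_fields:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        for name, arr in cell_fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.17g}" for v in np.asarray(arr, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path) -> dict:
    """Read a legacy-ASCII VTK unstructured grid written by this package.

    Returns a dict with 'points', 'cells', 'point_data', 'cell_data'.
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    out = {"points": None, "cells": None, "point_data": {}, "cell_data": {}}

    def floats(n_vals, start):
        vals = []
        j = start
        while len(vals) < n_vals:
            vals.extend(float(x) for x in tokens[j].split())
            j += 1
        return np.array(vals), j

    npts = ncells = 0
    section = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            npts = int(line.split()[1])
            vals, i = floats(npts * 3, i + 1)
            out["points"] = vals.reshape(npts, 3)[:, :2]
            continue
        if line.startswith("CELLS"):
            ncells = int(line.split()[1])
            cells = []
            for j in range(ncells):
                parts = tokens[i + 1 + j].split()
                cells.append([int(x) for x in parts[1:]])
            out["cells"] = np.array(cells)
            i += ncells + 1
            continue
        if line.startswith("POINT_DATA"):
            section = "point_data"
            i += 1
            continue
        if line.startswith("CELL_DATA"):
            section = "cell_data"
            i += 1
            continue
        if line.startswith("VECTORS"):
            name = line.split()[1]
            n = npts if section == "point_data" else ncells
            vals, i = floats(n * 3, i + 1)
            out[section][name] = vals.reshape(n, 3)[:, :2]
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            n = npts if section == "point_data" else ncells
            vals, i = floats(n, i + 2)  # skip LOOKUP_TABLE line
            out[section][name] = vals
            continue
        i += 1
    return out


# ---------------------------------------------------------------------------
# metrics CSV


def morpho_to_frame(morpho: MorphoTrace) -> pd.DataFrame:
    """Tidy long-format frame: time, gw, metric, label, value."""
    rows = []
    for i, t in enumerate(morpho.times):
        gw = float(gestational_week(t))
        rows.append((t, gw, "folding_evolution", "", morpho.folding_evolution[i]))
        rows.append((t, gw, "max_density", "", morpho.max_density[i]))
        rows.append((t, gw, "max_stretch", "", morpho.max_stretch[i]))
        for j, d in enumerate(morpho.sulcus_depths[i]):
            rows.append((t, gw, "sulcus_depth", f"s{j}", float(d)))
    return pd.DataFrame(
        rows, columns=["time", "gw", "metric", "label", "value"]
    )


def emit_metrics_csv(morpho: MorphoTrace, path):
    morpho_to_frame(morpho).to_csv(path, index=False)


def load_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"time": float, "gw": float, "metric": str, "value": float},
        keep_default_na=False,
    )


def write_manifest(path, cfg: RunConfig, status: str, events: list,
                   started: float | None = None, finished: float | None = None):
    """Atomic JSON manifest with config hash, seed and event log."""
    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "config": config_to_dict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "started": started,
        "finished": finished if finished is not None else _time.time(),
        "status": status,
        "events": events,
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(path)
    return manifest
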