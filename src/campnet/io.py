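"""Configuration and file round-tripping.

FORMATS
-------
All files are delimited text with header rows; cell ids are 0-based and
times are in minutes.

* **Cell-level trace table** (CSV): columns ``cell_id, role, time_min,
  camp, pka_on, erk_active, ktr_nc``.
* **Interface-level table** (CSV): columns ``cell_i, cell_j, time_min,
  rho, flux_into_i, gj_parsed_i, gj_parsed_j``.
* **Synthetic trace table** (CSV): ``cell_id, role, time_min, ktr_nc``
  plus ground-truth columns ``ktr_nc_true, camp_true, nonresponder``.
* **Metrics table** (CSV): ``cell_id, role, pulse_index, s_start, s_max,
  s_end, time_to_max_min, time_to_ss_min, overshoot_ratio,
  undershoot_depth, valid``.
* **Adjacency edge list** (text): one ``i j`` (whitespace or comma
  separated) pair per line, 0-based ids.
* **Metadata sidecars / manifests**: JSON.
* **Run configuration**: YAML with sections ``scenario, params, coupling,
  protocol, pharmacology, noise, heterogeneity`` plus top-level ``preset,
  variant, seed, out_dir``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import PulseMetrics
from .model_core import IntracellularParams, LightProtocol, PharmacologySpec
from .tissue import TraceSet

__all__ = [
    "ConfigError",
    "load_config",
    "protocol_from_config",
    "params_from_config",
    "pharm_from_config",
    "read_edge_list",
    "write_edge_list",
    "write_trace_set",
    "read_cell_table",
    "write_metrics_table",
]

_CONFIG_KEYS = {
    "preset", "variant", "seed", "out_dir", "scenario", "params", "coupling",
    "protocol", "pharmacology", "noise", "heterogeneity",
}


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration.

    Unknown top-level keys raise :class:`ConfigError` naming the key.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    for key in cfg:
        if key not in _CONFIG_KEYS:
            raise ConfigError(
                f"unknown configuration key {key!r}; expected one of "
                f"{sorted(_CONFIG_KEYS)}"
            )
    return cfg


def _build(cls, section: dict | None, what: str):
    section = dict(section or {})
    valid = set(cls.__dataclass_fields__)
    for key in section:
        if key not in valid:
            raise ConfigError(f"unknown {what} key {key!r}")
    return cls(**section)


def params_from_config(cfg: dict) -> IntracellularParams:
    return _build(IntracellularParams, cfg.get("params"), "params")


def pharm_from_config(cfg: dict) -> PharmacologySpec:
    section = cfg.get("pharmacology")
    if isinstance(section, str):
        from .tissue import drug_spec

        return drug_spec(section)
    return _build(PharmacologySpec, section, "pharmacology")


def protocol_from_config(cfg: dict) -> LightProtocol:
    section = dict(cfg.get("protocol") or {})
    if "pulses" in section:
        pulses = tuple(tuple(map(float, p)) for p in section.pop("pulses"))
        t_end = float(section.pop("t_end", pulses[-1][1] + 40.0))
        if section:
            raise ConfigError(f"unknown protocol keys {sorted(section)}")
        return LightProtocol(pulses=pulses, t_end=t_end)
    known = {"on_minutes", "off_minutes", "amplitudes"}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown protocol keys {sorted(unknown)}")
    return LightProtocol.two_pulse(**section)


def read_edge_list(path: str | Path) -> np.ndarray:
    """Read a whitespace- or comma-delimited 0-based edge list."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip().replace(",", " ")
        if not line:
            continue
        i, j = line.split()[:2]
        edges.append((int(i), int(j)))
    return np.array(edges, dtype=int)


def write_edge_list(edges: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{i} {j}\n" for i, j in np.asarray(edges, dtype=int))
    )


def trace_set_to_cell_frame(ts: TraceSet) -> pd.DataFrame:
    n, nt = ts.camp.shape
    return pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n), nt),
            "role": np.repeat(ts.roles.astype(str), nt),
            "time_min": np.tile(ts.time, n),
            "camp": ts.camp.ravel(),
            "pka_on": ts.pka_on.ravel(),
            "erk_active": ts.erk_active.ravel(),
            "ktr_nc": ts.ktr_nc.ravel(),
        }
    )


def trace_set_to_interface_frame(ts: TraceSet) -> pd.DataFrame:
    m, nt = ts.rho.shape
    return pd.DataFrame(
        {
            "cell_i": np.repeat(ts.edges[:, 0], nt),
            "cell_j": np.repeat(ts.edges[:, 1], nt),
            "time_min": np.tile(ts.time, m),
            "rho": ts.rho.ravel(),
            "flux_into_i": ts.flux.ravel(),
            "gj_parsed_i": ts.gj_parsed_i.ravel(),
            "gj_parsed_j": ts.gj_parsed_j.ravel(),
        }
    )


def write_trace_set(ts: TraceSet, out_dir: str | Path, stem: str = "run") -> dict:
    """Write cell table, interface table and metadata sidecar; returns the
    paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out_dir / f"{stem}_cells.csv",
        "interfaces": out_dir / f"{stem}_interfaces.csv",
        "metadata": out_dir / f"{stem}_metadata.json",
    }
    trace_set_to_cell_frame(ts).to_csv(
        paths["cells"], index=False, float_format="%.10g"
    )
    trace_set_to_interface_frame(ts).to_csv(
        paths["interfaces"], index=False, float_format="%.10g"
    )
    paths["metadata"].write_text(
        json.dumps(ts.metadata, indent=2, default=str) + "\n"
    )
    return paths


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "time_min", "ktr_nc"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trace table missing columns {sorted(missing)}")
    return df


def write_metrics_table(
    rows: list[tuple[int, str, PulseMetrics]], path: str | Path
) -> pd.DataFrame:
    """Write per-cell per-pulse metrics as the standard delimited table."""
    df = pd.DataFrame(
        [
            {
                "cell_id": cid,
                "role": role,
                "pulse_index": m.pulse_index,
                "s_start": m.s_start,
                "s_max": m.s_max,
                "s_end": m.s_end,
                "time_to_max_min": m.time_to_max,
                "time_to_ss_min": m.time_to_ss,
                "overshoot_ratio": m.overshoot_ratio,
                "undershoot_depth": m.undershoot_depth,
                "valid": m.valid,
            }
            for cid, role, m in rows
        ]
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return df
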