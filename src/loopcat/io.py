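"""Text-format input/output: XYZ trajectory frames, bond lists, event
logs and the run-configuration file.

Bead indices are 0-based internally; all file output is 1-based with a
header line saying so, matching common MD conventions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .units import BeadType, ParticleSystem, Topology

__all__ = ["write_xyz", "write_bondlist", "write_events", "read_events",
           "load_config", "config_hash"]

_ELEMENT = {int(BeadType.DNA): "D", int(BeadType.NUC_DNA): "N",
            int(BeadType.VIRAL): "V", int(BeadType.VIRAL_STICKY): "S",
            int(BeadType.NCP): "H"}

EVENT_COLUMNS = ["replica", "seed", "step", "site_bead", "site_bp",
                 "in_loop", "delta_U", "delta_U_angle", "outcome"]


def write_xyz(path, system: ParticleSystem, comment: str = "",
              append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{system.n_particles}\n{comment}\n")
        for t, (x, y, z) in zip(system.btype, system.positions):
            fh.write(f"{_ELEMENT[int(t)]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_bondlist(path, topology: Topology, frame: int = 0,
                   append: bool = False) -> None:
    """Tab-separated bond list (frame, bond_kind, i, j); indices 1-based."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("# frame\tbond_kind\ti\tj (bead indices 1-based)\n")
        for i, j, kind in topology.bonds():
            fh.write(f"{frame}\t{kind.name.lower()}\t{i + 1}\t{j + 1}\n")


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    """Load a YAML run configuration; returns the raw mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration, for output provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
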