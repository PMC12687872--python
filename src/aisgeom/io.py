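"""Shared I/O: morphology CSV reading/writing with validation, config
loading, run manifests, and deterministic test fixtures.

Canonical units are fixed across all files: µm (geometry), ms, mV, pA, nS.
A column-mapping config (YAML) adapts external table headers to the
canonical schema at read time; all conversion happens in the readers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .records import (CellRecord, COLUMNS, ValidationError, frame_to_records,
                      records_to_frame)
from .builder import load_biophys, load_template, save_biophys  # re-exported

__all__ = [
    "read_morphology_csv",
    "write_morphology_csv",
    "load_column_map",
    "load_biophys",
    "load_template",
    "save_biophys",
    "RunManifest",
    "write_table",
    "make_fixtures",
]


class RowValidationError(ValueError):
    """A morphology table row violating an invariant, addressed by row."""

    def __init__(self, row: int, cause: Exception):
        self.row = row
        self.cause = cause
        super().__init__(f"row {row}: {cause}")


def load_column_map(path) -> Dict[str, str]:
    """YAML mapping of canonical column name -> header used in the file."""
    with open(path) as fh:
        cmap = yaml.safe_load(fh)
    if not isinstance(cmap, dict):
        raise ValueError("column map must be a mapping")
    return {str(k): str(v) for k, v in cmap.items()}


def read_morphology_csv(path, column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read a morphology table, validating every row's geometric invariants.

    Returns the canonical-schema DataFrame; raises :class:`RowValidationError`
    naming the first offending row and field."""
    df = pd.read_csv(path)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped columns absent from file: {missing}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    absent = [c for c in COLUMNS if c not in df.columns]
    for col in absent:
        if col in ("layer_depth", "animal_id", "hemisphere", "sex", "hippocampus"):
            df[col] = np.nan if col == "layer_depth" else ""
        else:
            raise ValueError(f"missing required column {col!r}")
    df = df[COLUMNS]
    for i in range(len(df)):
        try:
            frame_to_records(df.iloc[[i]])
        except (ValidationError, ValueError) as exc:
            raise RowValidationError(i, exc) from exc
    return df.reset_index(drop=True)


def write_morphology_csv(table, path) -> None:
    """Write records or a canonical-schema table to CSV (lossless round trip)."""
    if not isinstance(table, pd.DataFrame):
        table = records_to_frame(table)
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# provenance

def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance carried alongside every numerical output file."""

    seeds: Dict[str, int] = field(default_factory=dict)
    config: Dict[str, object] = field(default_factory=dict)
    input_digests: Dict[str, str] = field(default_factory=dict)
    timings_s: Dict[str, float] = field(default_factory=dict)
    package_version: str = __version__

    def add_input(self, name: str, path) -> None:
        self.input_digests[name] = _digest(path)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        payload = asdict(self)
        payload["config_hash"] = self.config_hash
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        payload.pop("config_hash", None)
        return cls(**payload)


def write_table(df: pd.DataFrame, path, manifest: RunManifest) -> None:
    """Write a tidy CSV plus its manifest sidecar (``<path>.manifest.json``)."""
    path = Path(path)
    df.to_csv(path, index=False)
    manifest.write(path.with_suffix(path.suffix + ".manifest.json"))


# ---------------------------------------------------------------------------
# fixtures

def make_fixtures(seed: int = 0):
    """Deterministic tiny inputs for the test suite: a 10-cell cohort and a
    small random section tree (≤ 20 compartments)."""
    from .cohort import default_profiles, generate_frame
    from .builder import (Section, CompartmentGraph, default_biophys)

    prof = default_profiles()["ventral-CA1m"]
    cohort = generate_frame(prof, 10, seed, hippocampus="fixture")

    rng = np.random.default_rng(seed + 1)
    bio = default_biophys()
    sections = {"soma": Section("soma", "soma", 15.0, [(0.0, 12.0), (1.0, 12.0)],
                                None, nseg=3)}
    classes = ["apical1", "basal_acd", "ais_prox", "tuft"]
    names = list(sections)
    total = 3
    while total < 17 and len(names) < 6:
        cls = classes[rng.integers(0, len(classes))]
        name = f"sec{len(names)}"
        parent = names[rng.integers(0, len(names))]
        nseg = int(rng.integers(1, 3)) * 2 + 1
        if total + nseg > 20:
            break
        sections[name] = Section(
            name, cls, float(rng.uniform(20, 80)),
            [(0.0, float(rng.uniform(0.8, 2.5))), (1.0, float(rng.uniform(0.5, 2.0)))],
            parent, parent_pos=float(rng.choice([0.0, 0.5, 1.0])), nseg=nseg)
        names.append(name)
        total += nseg
    tree = CompartmentGraph(sections=sections, biophys=bio)
    return cohort, tree
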