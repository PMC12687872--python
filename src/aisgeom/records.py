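"""Proximal-geometry domain model for hippocampal pyramidal neurons.

A :class:`CellRecord` holds one neuron's measured proximal morphology —
soma ellipse diameters, five proximal apical-dendrite diameters, the axon
initial segment (AIS) position/length/diameter profile, and, where the axon
emerges from a basal dendrite, the geometry of the axon-carrying-dendrite
(AcD) stem that separates soma and axon–dendrite bifurcation.

All lengths and diameters are micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Plane",
    "Subregion",
    "AxonOrigin",
    "CellRecord",
    "ValidationError",
    "classify_axon_origin",
    "soma_ellipse_area",
    "soma_spheroid_surface",
    "ais_endpoint",
    "ais_distance_2",
    "mean_apical_diameter",
    "records_to_frame",
    "frame_to_records",
    "annotate_frame",
]

#: distances at which the apical trunk diameters are measured (µm from soma base)
APICAL_OFFSETS = (5.0, 10.0, 15.0, 20.0, 25.0)

#: classification constants: minimum AcD stem length and the distal-origin cut (µm)
ACD_MIN_STEM = 2.0
DISTAL_CUT = 5.0


class Plane(str, Enum):
    """Position along the hippocampal longitudinal (dorso-ventral) axis."""

    dorsal = "dorsal"
    medial = "medial"
    ventral = "ventral"


class Subregion(str, Enum):
    """Subregion along the pyramidal cell band (proximo-distal axis)."""

    hilus = "hilus"
    CA3c = "CA3c"
    CA3b = "CA3b"
    CA3a = "CA3a"
    CA2 = "CA2"
    CA1p = "CA1p"
    CA1m = "CA1m"
    CA1d = "CA1d"
    Sub = "Sub"


class AxonOrigin(str, Enum):
    somatic = "somatic"
    distal = "distal"
    acd = "acd"


class ValidationError(ValueError):
    """Raised when a record violates a geometric invariant; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class CellRecord:
    """One neuron's measured proximal geometry plus anatomical labels."""

    cell_id: str
    plane: Plane
    subregion: Subregion
    soma_major: float
    soma_minor: float
    apical_diams: tuple
    ais_distance: float
    ais_length: float
    ais_d_start: float
    ais_d_max: float
    ais_d_end: float
    ais_max_pos: float
    acd_stem_length: float = 0.0
    acd_stem_diam: Optional[float] = None
    layer_depth: Optional[float] = None
    animal_id: str = ""
    hemisphere: str = ""
    sex: str = ""
    hippocampus: str = ""

    def __post_init__(self):
        object.__setattr__(self, "plane", Plane(self.plane))
        object.__setattr__(self, "subregion", Subregion(self.subregion))
        object.__setattr__(self, "apical_diams", tuple(float(d) for d in self.apical_diams))
        self.validate()

    def validate(self) -> None:
        for name in ("soma_major", "soma_minor", "ais_distance", "ais_length",
                     "ais_d_start", "ais_d_max", "ais_d_end", "ais_max_pos",
                     "acd_stem_length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(name, f"must be finite and >= 0, got {v!r}")
        if len(self.apical_diams) != len(APICAL_OFFSETS):
            raise ValidationError("apical_diams",
                                  f"expected {len(APICAL_OFFSETS)} diameters, got {len(self.apical_diams)}")
        if any((not np.isfinite(d)) or d < 0 for d in self.apical_diams):
            raise ValidationError("apical_diams", "diameters must be finite and >= 0")
        if self.soma_major < self.soma_minor:
            raise ValidationError("soma_major", "soma_major must be >= soma_minor")
        if self.ais_max_pos > self.ais_length:
            raise ValidationError("ais_max_pos", "must lie within the AIS (<= ais_length)")
        if self.acd_stem_length > self.ais_distance:
            raise ValidationError("acd_stem_length",
                                  "stem is part of the soma-to-AIS path (<= ais_distance)")
        if self.acd_stem_length > 0:
            if self.acd_stem_diam is None or not np.isfinite(self.acd_stem_diam) or self.acd_stem_diam <= 0:
                raise ValidationError("acd_stem_diam",
                                      "required and > 0 when acd_stem_length > 0")


def classify_axon_origin(record: CellRecord) -> AxonOrigin:
    """Classify a neuron by where its axon emerges.

    A cell is an AcD cell when the stem separating soma from the
    axon–dendrite bifurcation is at least 2 µm long and strictly longer than
    its mean diameter.  Otherwise the origin is *distal* when the AIS starts
    more than 5 µm from the soma, else *somatic*.
    """
    if record.acd_stem_length >= ACD_MIN_STEM and record.acd_stem_diam is not None \
            and record.acd_stem_length > record.acd_stem_diam:
        return AxonOrigin.acd
    if record.ais_distance > DISTAL_CUT:
        return AxonOrigin.distal
    return AxonOrigin.somatic


def soma_ellipse_area(record: CellRecord) -> float:
    """Soma size simplified as the area of the ellipse spanned by the two
    longest orthogonal diameters (µm²)."""
    return math.pi * (record.soma_major / 2.0) * (record.soma_minor / 2.0)


def soma_spheroid_surface(record: CellRecord) -> float:
    """Soma size as the 3D surface of the prolate spheroid with polar diameter
    ``soma_major`` and equatorial diameter ``soma_minor`` (µm²)."""
    a = record.soma_major / 2.0  # polar semi-axis (long)
    c = record.soma_minor / 2.0  # equatorial semi-axis
    if a <= 0 or c <= 0:
        return 0.0
    if math.isclose(a, c, rel_tol=1e-9):
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - (c * c) / (a * a))
    return 2.0 * math.pi * c * c * (1.0 + (a / (c * e)) * math.asin(e))


def ais_endpoint(record: CellRecord) -> float:
    """Distance from the soma to the distal end of the AIS (µm)."""
    return record.ais_distance + record.ais_length


def ais_distance_2(record: CellRecord) -> float:
    """Distance from the somatodendritic compartment — including the AcD
    stem — to the AIS start (µm).  Equals ``ais_distance`` for non-AcD cells."""
    return max(record.ais_distance - record.acd_stem_length, 0.0)


def mean_apical_diameter(record: CellRecord) -> float:
    """Mean of the five proximal apical-trunk diameters (µm)."""
    return float(np.mean(record.apical_diams))


# ---------------------------------------------------------------------------
# tabular interchange

_APICAL_COLS = [f"apical_d{int(x):02d}" for x in APICAL_OFFSETS]

COLUMNS = [
    "cell_id", "plane", "subregion", "layer_depth", "animal_id", "hemisphere",
    "sex", "hippocampus", "soma_major", "soma_minor", *_APICAL_COLS,
    "ais_distance", "ais_length", "ais_d_start", "ais_d_max", "ais_d_end",
    "ais_max_pos", "acd_stem_length", "acd_stem_diam",
]


def records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id, "plane": r.plane.value, "subregion": r.subregion.value,
            "layer_depth": r.layer_depth, "animal_id": r.animal_id,
            "hemisphere": r.hemisphere, "sex": r.sex, "hippocampus": r.hippocampus,
            "soma_major": r.soma_major, "soma_minor": r.soma_minor,
            "ais_distance": r.ais_distance, "ais_length": r.ais_length,
            "ais_d_start": r.ais_d_start, "ais_d_max": r.ais_d_max,
            "ais_d_end": r.ais_d_end, "ais_max_pos": r.ais_max_pos,
            "acd_stem_length": r.acd_stem_length,
            "acd_stem_diam": np.nan if r.acd_stem_diam is None else r.acd_stem_diam,
        }
        for col, d in zip(_APICAL_COLS, r.apical_diams):
            row[col] = d
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list:
    records = []
    for _, row in df.iterrows():
        stem_d = row.get("acd_stem_diam", np.nan)
        depth = row.get("layer_depth", np.nan)
        records.append(CellRecord(
            cell_id=str(row["cell_id"]), plane=row["plane"], subregion=row["subregion"],
            soma_major=float(row["soma_major"]), soma_minor=float(row["soma_minor"]),
            apical_diams=tuple(float(row[c]) for c in _APICAL_COLS),
            ais_distance=float(row["ais_distance"]), ais_length=float(row["ais_length"]),
            ais_d_start=float(row["ais_d_start"]), ais_d_max=float(row["ais_d_max"]),
            ais_d_end=float(row["ais_d_end"]), ais_max_pos=float(row["ais_max_pos"]),
            acd_stem_length=float(row.get("acd_stem_length", 0.0)),
            acd_stem_diam=None if pd.isna(stem_d) else float(stem_d),
            layer_depth=None if pd.isna(depth) else float(depth),
            animal_id=str(row.get("animal_id", "")), hemisphere=str(row.get("hemisphere", "")),
            sex=str(row.get("sex", "")), hippocampus=str(row.get("hippocampus", "")),
        ))
    return records


def annotate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived geometric columns to a morphology table.

    Adds ``axon_origin``, ``soma_area`` (ellipse, µm²), ``soma_surface``
    (prolate spheroid, µm²), ``apical_diam_mean``, ``ais_endpoint`` and
    ``ais_distance_2``.
    """
    out = df.copy()
    stem_len = out["acd_stem_length"].to_numpy(float)
    stem_d = out["acd_stem_diam"].to_numpy(float)
    is_acd = (stem_len >= ACD_MIN_STEM) & np.isfinite(stem_d) & (stem_len > stem_d)
    origin = np.where(is_acd, AxonOrigin.acd.value,
                      np.where(out["ais_distance"].to_numpy(float) > DISTAL_CUT,
                               AxonOrigin.distal.value, AxonOrigin.somatic.value))
    out["axon_origin"] = origin
    a = out["soma_major"].to_numpy(float) / 2.0
    c = out["soma_minor"].to_numpy(float) / 2.0
    out["soma_area"] = math.pi * a * c
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.sqrt(np.clip(1.0 - (c / a) ** 2, 0.0, 1.0))
        surf = np.where(
            e < 1e-9,
            4.0 * math.pi * a * a,
            2.0 * math.pi * c * c * (1.0 + np.where(e > 0, a / np.where(c * e > 0, c * e, np.inf), 0.0)
                                     * np.arcsin(e)),
        )
    out["soma_surface"] = surf
    out["apical_diam_mean"] = out[_APICAL_COLS].mean(axis=1)
    out["ais_endpoint"] = out["ais_distance"] + out["ais_length"]
    out["ais_distance_2"] = np.maximum(out["ais_distance"] - out["acd_stem_length"], 0.0)
    return out
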