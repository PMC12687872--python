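"""Map a measured cell geometry onto the reduced compartmental CA1 model.

The model topology: a cylindrical soma (lateral surface matched to the
prolate-spheroid soma surface) gives rise to one apical dendrite — three
trunk parts terminating in two tuft branches — and two basal dendrites.
One basal branch carries the axon (the AcD branch); the other is a
canonical basal dendrite.  For AcD cells the axon leaves via the AcD stem;
a balance stub of identical geometry is inserted into the non-AcD branch so
both synaptic zones face an electrotonically equivalent path to the soma.
The AIS is built in two parts, with the sodium activation threshold of the
distal part shifted by −5 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .records import CellRecord, classify_axon_origin, AxonOrigin, soma_spheroid_surface

__all__ = [
    "SECTION_CLASSES",
    "BiophysSpec",
    "Section",
    "CompartmentGraph",
    "default_biophys",
    "default_template",
    "build_cell",
    "balance_branches",
    "segmentize",
    "d_lambda_nseg",
]

SECTION_CLASSES = (
    "soma", "apical1", "apical2", "apical3", "tuft",
    "basal_acd", "basal_nonacd", "acd_stem", "balance_stub",
    "hillock", "ais_prox", "ais_dist", "axon_distal",
)


class ConfigurationError(KeyError):
    pass


@dataclass(frozen=True)
class ChannelDensities:
    """Active/passive conductance densities for one section class (S/cm²)."""

    g_pas: float
    gna: float = 0.0
    gk: float = 0.0

    def __post_init__(self):
        if min(self.g_pas, self.gna, self.gk) < 0:
            raise ValueError("conductance densities must be >= 0")


@dataclass(frozen=True)
class BiophysSpec:
    """Passive and active membrane parameters of the reduced model.

    ``na_shift`` (mV, default −5) offsets the sodium activation threshold of
    the distal AIS only; ``na_shift_mode`` selects whether the shift applies
    to activation gates only (default) or to the full Na kinetics.
    """

    ra: float          # axial resistivity, Ohm*cm
    cm: float          # specific capacitance, uF/cm^2
    v_init: float      # mV
    ena: float         # mV
    ek: float          # mV
    e_pas: float       # mV
    densities: Mapping[str, ChannelDensities]
    na_shift: float = -5.0
    na_shift_mode: str = "activation"

    def __post_init__(self):
        if self.na_shift_mode not in ("activation", "full"):
            raise ValueError("na_shift_mode must be 'activation' or 'full'")
        missing = [c for c in SECTION_CLASSES if c not in self.densities]
        if missing:
            raise ConfigurationError(f"missing channel densities for classes {missing}")

    def for_class(self, cls: str) -> ChannelDensities:
        return self.densities[cls]


@dataclass
class Section:
    """One unbranched cable section.

    ``diam_profile`` is a piecewise-linear diameter profile over normalized
    position [0, 1]; ``parent_pos`` is the attachment point on the parent.
    """

    name: str
    cls: str
    length: float
    diam_profile: List[Tuple[float, float]]
    parent: Optional[str]
    parent_pos: float = 1.0
    nseg: int = 1

    def __post_init__(self):
        if self.cls not in SECTION_CLASSES:
            raise ValueError(f"unknown section class {self.cls!r}")
        if self.length <= 0:
            raise ValueError(f"section {self.name}: length must be > 0")
        xs = [x for x, _ in self.diam_profile]
        if xs != sorted(xs) or xs[0] != 0.0 or xs[-1] != 1.0:
            raise ValueError(f"section {self.name}: diam profile must span [0, 1] in order")
        if self.nseg < 1 or self.nseg % 2 == 0:
            raise ValueError(f"section {self.name}: nseg must be odd and >= 1")

    def diam_at(self, x: float) -> float:
        xs = np.array([p for p, _ in self.diam_profile])
        ds = np.array([d for _, d in self.diam_profile])
        return float(np.interp(x, xs, ds))


@dataclass
class CompartmentGraph:
    """Tree of sections rooted at the soma, with bound biophysics."""

    sections: Dict[str, Section]
    biophys: BiophysSpec
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        roots = [s for s in self.sections.values() if s.parent is None]
        if len(roots) != 1 or roots[0].name != "soma":
            raise ValueError("graph must be a tree rooted at 'soma'")
        for s in self.sections.values():
            if s.parent is not None and s.parent not in self.sections:
                raise ValueError(f"section {s.name}: unknown parent {s.parent}")

    def topological(self) -> List[Section]:
        order, seen = [], set()
        pending = list(self.sections.values())
        while pending:
            progressed = False
            rest = []
            for s in pending:
                if s.parent is None or s.parent in seen:
                    order.append(s)
                    seen.add(s.name)
                    progressed = True
                else:
                    rest.append(s)
            if not progressed:
                raise ValueError("section graph contains a cycle")
            pending = rest
        return order

    def path_to_soma(self, name: str) -> List[str]:
        path = []
        cur = self.sections[name]
        while cur.parent is not None:
            path.append(cur.name)
            cur = self.sections[cur.parent]
        path.append("soma")
        return path

    def path_offset(self, name: str) -> float:
        """Path length (µm) from the soma surface to the 0-end of a section
        (soma itself contributes nothing)."""
        total = 0.0
        cur = self.sections[name]
        while cur.parent is not None and cur.parent != "soma":
            parent = self.sections[cur.parent]
            total += parent.length * cur.parent_pos
            cur = parent
        return total


# ---------------------------------------------------------------------------
# packaged defaults

_DEFAULT_BIOPHYS = {
    # cm of 2 uF/cm^2 and the elevated leak stand in for the membrane area
    # (spines, full arbor) the reduced morphology omits, so the model presents
    # a realistic somatic input impedance and 5-ms charge requirement
    "ra": 150.0, "cm": 2.0, "v_init": -70.0,
    "ena": 55.0, "ek": -90.0, "e_pas": -70.0,
    "na_shift": -5.0, "na_shift_mode": "activation",
    "densities": {
        # S/cm^2; dendrites carry a weak Na/K background, the AIS is the
        # hot zone, its distal half the hottest
        "soma":         {"g_pas": 1.25e-3, "gna": 0.06,  "gk": 0.02},
        "apical1":      {"g_pas": 1.25e-3, "gna": 0.005, "gk": 0.002},
        "apical2":      {"g_pas": 1.25e-3, "gna": 0.005, "gk": 0.002},
        "apical3":      {"g_pas": 1.25e-3, "gna": 0.005, "gk": 0.002},
        "tuft":         {"g_pas": 1.25e-3, "gna": 0.003, "gk": 0.002},
        "basal_acd":    {"g_pas": 1.25e-3, "gna": 0.005, "gk": 0.002},
        "basal_nonacd": {"g_pas": 1.25e-3, "gna": 0.005, "gk": 0.002},
        "acd_stem":     {"g_pas": 1.25e-3, "gna": 0.01,  "gk": 0.004},
        "balance_stub": {"g_pas": 1.25e-3, "gna": 0.005, "gk": 0.002},
        "hillock":      {"g_pas": 1.25e-3, "gna": 0.3,   "gk": 0.06},
        "ais_prox":     {"g_pas": 1.25e-3, "gna": 0.55,  "gk": 0.12},
        "ais_dist":     {"g_pas": 1.25e-3, "gna": 0.65,  "gk": 0.25},
        "axon_distal":  {"g_pas": 1.25e-3, "gna": 0.06,  "gk": 0.03},
    },
}

_DEFAULT_TEMPLATE = {
    # geometry the tracing protocol does not measure, from the reduced model
    "apical1": {"length": 100.0},
    "apical2": {"length": 150.0, "diam": 1.6},
    "apical3": {"length": 150.0, "diam": 1.2},
    "tuft": {"length": 100.0, "diam": 0.8},
    "basal": {"length": 150.0, "diam": 0.9},
    "axon_distal": {"length": 200.0, "diam": 0.5},
    "ais_split_frac": 0.5,
    "soma_nseg": 3,
}


def _packaged(name: str):
    from importlib.resources import files

    path = files("aisgeom.data").joinpath(name)
    return yaml.safe_load(path.read_text())


def default_biophys() -> BiophysSpec:
    """The packaged biophysics configuration (``data/biophys.yaml``)."""
    try:
        return _spec_from_payload(_packaged("biophys.yaml"))
    except FileNotFoundError:
        return _spec_from_payload(_DEFAULT_BIOPHYS)


def default_template() -> Dict[str, object]:
    """The packaged geometry template (``data/template.yaml``)."""
    import copy

    try:
        return dict(_packaged("template.yaml"))
    except FileNotFoundError:
        return copy.deepcopy(_DEFAULT_TEMPLATE)


def _spec_from_payload(payload: Mapping) -> BiophysSpec:
    for key in ("ra", "cm", "v_init", "ena", "ek", "e_pas", "densities"):
        if key not in payload:
            raise ConfigurationError(f"biophysics config missing {key!r}")
    dens = {cls: ChannelDensities(**vals) for cls, vals in payload["densities"].items()}
    return BiophysSpec(
        ra=float(payload["ra"]), cm=float(payload["cm"]),
        v_init=float(payload["v_init"]), ena=float(payload["ena"]),
        ek=float(payload["ek"]), e_pas=float(payload["e_pas"]),
        densities=dens,
        na_shift=float(payload.get("na_shift", -5.0)),
        na_shift_mode=payload.get("na_shift_mode", "activation"),
    )


# ---------------------------------------------------------------------------
# construction

def _ais_taper(record: CellRecord) -> List[Tuple[float, float]]:
    """Piecewise-linear AIS diameter profile over normalized length:
    start diameter, maximum at ``ais_max_pos``, end diameter."""
    L = record.ais_length
    xm = 0.0 if L == 0 else record.ais_max_pos / L
    pts = [(0.0, record.ais_d_start)]
    if 0.0 < xm < 1.0:
        pts.append((xm, record.ais_d_max))
    elif xm == 0.0:
        pts[0] = (0.0, record.ais_d_max)
    pts.append((1.0, record.ais_d_end if xm < 1.0 else record.ais_d_max))
    return pts


def _slice_profile(pts: Sequence[Tuple[float, float]], a: float, b: float) -> List[Tuple[float, float]]:
    """Restrict a [0,1] piecewise profile to [a,b] and renormalize to [0,1]."""
    xs = np.array([x for x, _ in pts])
    ds = np.array([d for _, d in pts])
    inner = [x for x in xs if a < x < b]
    grid = [a] + inner + [b]
    out = [((x - a) / (b - a), float(np.interp(x, xs, ds))) for x in grid]
    return out


def build_cell(record: CellRecord,
               biophys: Optional[BiophysSpec] = None,
               template: Optional[Mapping] = None) -> CompartmentGraph:
    """Construct the reduced compartment model for one measured cell.

    Measured quantities override the template: soma surface, AIS
    distance/length/diameter profile, the five proximal apical diameters and
    — for AcD cells — stem length and diameter.  Everything else (distal
    apical trunk, tuft, basal dendrites, distal axon) comes from the template.
    """
    biophys = biophys or default_biophys()
    template = dict(template or default_template())
    for key in ("apical1", "apical2", "apical3", "tuft", "basal", "axon_distal"):
        if key not in template:
            raise ConfigurationError(f"template missing geometry for {key!r}")

    sections: Dict[str, Section] = {}

    surface = soma_spheroid_surface(record)
    soma_L = record.soma_major
    soma_d = surface / (math.pi * soma_L)
    sections["soma"] = Section("soma", "soma", soma_L, [(0.0, soma_d), (1.0, soma_d)],
                               None, nseg=int(template.get("soma_nseg", 3)))

    # apical trunk: measured diameters at 5..25 µm, then taper to template
    ap1_L = float(template["apical1"]["length"])
    ap2_d = float(template["apical2"]["diam"])
    meas = [(off / ap1_L, d) for off, d in zip((5, 10, 15, 20, 25), record.apical_diams)]
    profile = [(0.0, record.apical_diams[0])] + meas + [(1.0, ap2_d)]
    sections["apical1"] = Section("apical1", "apical1", ap1_L, profile, "soma", 1.0)
    sections["apical2"] = Section("apical2", "apical2", float(template["apical2"]["length"]),
                                  [(0.0, ap2_d), (1.0, float(template["apical3"]["diam"]))],
                                  "apical1", 1.0)
    ap3_d = float(template["apical3"]["diam"])
    sections["apical3"] = Section("apical3", "apical3", float(template["apical3"]["length"]),
                                  [(0.0, ap3_d), (1.0, ap3_d)], "apical2", 1.0)
    tuft_L, tuft_d = float(template["tuft"]["length"]), float(template["tuft"]["diam"])
    for i in (1, 2):
        sections[f"tuft{i}"] = Section(f"tuft{i}", "tuft", tuft_L,
                                       [(0.0, tuft_d), (1.0, tuft_d)], "apical3", 1.0)

    basal_L, basal_d = float(template["basal"]["length"]), float(template["basal"]["diam"])
    is_acd = classify_axon_origin(record) == AxonOrigin.acd and record.acd_stem_length > 0

    if is_acd:
        stem_d = float(record.acd_stem_diam)
        sections["acd_stem"] = Section("acd_stem", "acd_stem", record.acd_stem_length,
                                       [(0.0, stem_d), (1.0, stem_d)], "soma", 0.0)
        axon_parent, axon_pos = "acd_stem", 1.0
        sections["basal_acd"] = Section("basal_acd", "basal_acd", basal_L,
                                        [(0.0, basal_d), (1.0, basal_d)], "acd_stem", 1.0)
    else:
        axon_parent, axon_pos = "soma", 0.0
        sections["basal_acd"] = Section("basal_acd", "basal_acd", basal_L,
                                        [(0.0, basal_d), (1.0, basal_d)], "soma", 0.0)
    sections["basal_nonacd"] = Section("basal_nonacd", "basal_nonacd", basal_L,
                                       [(0.0, basal_d), (1.0, basal_d)], "soma", 0.0)

    hillock_L = record.ais_distance - (record.acd_stem_length if is_acd else 0.0)
    ais_parent, ais_pos = axon_parent, axon_pos
    if hillock_L > 1e-9:
        hd = record.ais_d_start
        sections["hillock"] = Section("hillock", "hillock", hillock_L,
                                      [(0.0, hd), (1.0, hd)], axon_parent, axon_pos)
        ais_parent, ais_pos = "hillock", 1.0

    split = float(template.get("ais_split_frac", 0.5))
    if not 0.0 < split < 1.0:
        raise ConfigurationError("ais_split_frac must lie in (0, 1)")
    taper = _ais_taper(record)
    L = record.ais_length
    sections["ais_prox"] = Section("ais_prox", "ais_prox", split * L,
                                   _slice_profile(taper, 0.0, split), ais_parent, ais_pos)
    sections["ais_dist"] = Section("ais_dist", "ais_dist", (1.0 - split) * L,
                                   _slice_profile(taper, split, 1.0), "ais_prox", 1.0)
    ax_L, ax_d = float(template["axon_distal"]["length"]), float(template["axon_distal"]["diam"])
    sections["axon_distal"] = Section("axon_distal", "axon_distal", ax_L,
                                      [(0.0, ax_d), (1.0, ax_d)], "ais_dist", 1.0)

    graph = CompartmentGraph(sections=sections, biophys=biophys,
                             meta={"cell_id": record.cell_id, "is_acd": is_acd,
                                   "ais_split_frac": split})
    return graph


def balance_branches(graph: CompartmentGraph, record: CellRecord) -> CompartmentGraph:
    """Insert a balance stub mirroring the AcD stem into the non-AcD basal
    path, making the two synaptic zones' passive paths to the soma
    electrotonically equivalent.  Identity for non-AcD cells."""
    if not graph.meta.get("is_acd"):
        return graph
    stem = graph.sections["acd_stem"]
    sections = dict(graph.sections)
    sections["balance_stub"] = Section("balance_stub", "balance_stub", stem.length,
                                       list(stem.diam_profile), "soma", 0.0)
    basal = sections["basal_nonacd"]
    sections["basal_nonacd"] = replace(basal, parent="balance_stub", parent_pos=1.0)
    return CompartmentGraph(sections=sections, biophys=graph.biophys,
                            meta={**graph.meta, "balanced": True})


def d_lambda_nseg(section: Section, ra: float, cm: float,
                  f_hz: float = 100.0, d_lambda: float = 0.1) -> int:
    """Odd segment count from the AC length-constant rule at ``f_hz``."""
    d = np.mean([dd for _, dd in section.diam_profile])
    lam = 1e5 * math.sqrt(d / (4.0 * math.pi * f_hz * ra * cm))
    n = int(section.length / (d_lambda * lam) + 0.9)
    return max(n + (1 - n % 2), 1)


def segmentize(graph: CompartmentGraph,
               injection_sections: Sequence[str] = (),
               resolution: float = 0.5,
               f_hz: float = 100.0,
               d_lambda: float = 0.1) -> CompartmentGraph:
    """Discretize: sections carrying injection or synapse sites at
    ``resolution`` µm per segment, everything else by the d_lambda rule.
    Segment counts are odd."""
    sections = {}
    for name, s in graph.sections.items():
        if name in injection_sections:
            n = int(math.ceil(s.length / resolution))
            n = n + (1 - n % 2)
        else:
            n = d_lambda_nseg(s, graph.biophys.ra, graph.biophys.cm, f_hz, d_lambda)
        sections[name] = replace(s, nseg=max(n, 1))
    return CompartmentGraph(sections=sections, biophys=graph.biophys,
                            meta={**graph.meta, "segmentized": True})


# ---------------------------------------------------------------------------
# YAML I/O (biophysics and template)

def load_biophys(path) -> BiophysSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _spec_from_payload(payload)


def save_biophys(spec: BiophysSpec, path) -> None:
    payload = {
        "ra": spec.ra, "cm": spec.cm, "v_init": spec.v_init,
        "ena": spec.ena, "ek": spec.ek, "e_pas": spec.e_pas,
        "na_shift": spec.na_shift, "na_shift_mode": spec.na_shift_mode,
        "densities": {cls: {"g_pas": d.g_pas, "gna": d.gna, "gk": d.gk}
                      for cls, d in spec.densities.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_template(path) -> Dict[str, object]:
    with open(path) as fh:
        return yaml.safe_load(fh)
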