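"""Excitability experiments on built cells.

Implements the stimulation protocols of the study: conductance-based
synaptic drive of a basal branch (AcD or canonical) and 5-ms current steps
at the soma or AIS, with a rheobase-style search for the minimal stimulus
that elicits an action potential.  An AP is declared when the membrane
potential at the (distal) AIS exceeds 0 mV; the somatic voltage threshold
is the membrane potential at which dV/dt first exceeds 25 mV/ms, and the AP
delay is the time from stimulus onset to that threshold crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import CellRecord, classify_axon_origin, AxonOrigin
from .builder import (BiophysSpec, CompartmentGraph, build_cell, balance_branches,
                      segmentize, default_biophys, default_template)
from .engine import (CompiledCell, CurrentStep, SimulationConfig, SynapseSet,
                     SynapticDrive, compile_cell, place_synapses, simulate)

__all__ = [
    "MODES",
    "ExcitabilityConfig",
    "ExcitabilityResult",
    "detect_ap",
    "ap_voltage_threshold",
    "ap_delay",
    "prepare_cell",
    "find_threshold",
    "branch_comparison",
    "injection_site_comparison",
    "cohort_excitability",
    "median_reference_record",
    "median_reference_sweep",
]

MODES = ("synaptic_acd_branch", "synaptic_nonacd_branch",
         "current_soma", "current_ais_prox", "current_ais_dist")

_CURRENT_SITES = {"current_soma": ("soma", 0.5),
                  "current_ais_prox": ("ais_prox", 0.5),
                  "current_ais_dist": ("ais_dist", 0.5)}
_SYN_BRANCH = {"synaptic_acd_branch": "basal_acd",
               "synaptic_nonacd_branch": "basal_nonacd"}

#: rate-of-rise criterion for the somatic voltage threshold (mV/ms)
DVDT_CRITERION = 25.0


@dataclass(frozen=True)
class ExcitabilityConfig:
    """Protocol settings for threshold experiments."""

    biophys: Optional[BiophysSpec] = None
    template: Optional[Mapping] = None
    dt: float = 0.025
    duration: float = 45.0
    onset: float = 20.0
    step_duration: float = 5.0
    current_range: Tuple[float, float] = (10.0, 1000.0)   # pA
    current_resolution: float = 0.5                       # pA
    syn_range: Tuple[float, float] = (1.0, 100.0)         # nS total
    syn_resolution: float = 0.05                          # nS
    synapse_count: int = 1000
    seed: int = 0

    def resolved_biophys(self) -> BiophysSpec:
        return self.biophys if self.biophys is not None else default_biophys()

    def resolved_template(self) -> Mapping:
        return self.template if self.template is not None else default_template()


@dataclass(frozen=True)
class ExcitabilityResult:
    cell_id: str
    mode: str
    threshold: float           # pA (current modes) or nS total (synaptic)
    unit: str
    v_threshold: float         # mV at soma, NaN when undefined
    ap_delay: float            # ms from onset, NaN when undefined
    converged: bool
    below_range: bool = False
    n_sims: int = 0

    def as_dict(self) -> Dict[str, object]:
        return {"cell_id": self.cell_id, "mode": self.mode, "threshold": self.threshold,
                "unit": self.unit, "v_threshold": self.v_threshold,
                "ap_delay": self.ap_delay, "converged": self.converged,
                "below_range": self.below_range, "n_sims": self.n_sims}


# ---------------------------------------------------------------------------
# AP metrics

def detect_ap(trace: np.ndarray, t: np.ndarray) -> Tuple[bool, float]:
    """AP iff the AIS-site voltage strictly exceeds 0 mV; returns the first
    crossing time (NaN when no AP)."""
    above = trace > 0.0
    if not above.any():
        return False, float("nan")
    return True, float(t[int(np.argmax(above))])


def ap_voltage_threshold(soma_trace: np.ndarray, t: np.ndarray,
                         onset: float = 20.0) -> Tuple[float, float]:
    """Somatic voltage threshold and its crossing time.

    Centered finite-difference dV/dt (one-sided at the boundaries); the
    threshold is the voltage at the first sample after stimulus onset where
    dV/dt exceeds 25 mV/ms.  Returns (NaN, NaN) when the criterion is never
    met."""
    v = np.asarray(soma_trace, float)
    dt = float(t[1] - t[0])
    dvdt = np.empty_like(v)
    dvdt[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    dvdt[0] = (v[1] - v[0]) / dt
    dvdt[-1] = (v[-1] - v[-2]) / dt
    mask = (t >= onset) & (dvdt > DVDT_CRITERION)
    if not mask.any():
        return float("nan"), float("nan")
    i = int(np.argmax(mask))
    # sub-sample interpolation of the criterion crossing between i-1 and i
    # removes most of the discretization jitter of the reported threshold
    if i > 0 and dvdt[i - 1] <= DVDT_CRITERION and t[i - 1] >= onset:
        frac = (DVDT_CRITERION - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
        return (float(v[i - 1] + frac * (v[i] - v[i - 1])),
                float(t[i - 1] + frac * dt))
    return float(v[i]), float(t[i])


def ap_delay(soma_trace: np.ndarray, t: np.ndarray, onset: float = 20.0) -> float:
    """Time between stimulation onset and the somatic threshold crossing."""
    _, t_cross = ap_voltage_threshold(soma_trace, t, onset)
    return float(t_cross - onset) if np.isfinite(t_cross) else float("nan")


# ---------------------------------------------------------------------------
# cell preparation

@dataclass
class PreparedCell:
    """A built, balanced, segmentized and compiled cell ready for one mode."""

    record: CellRecord
    mode: str
    compiled: CompiledCell
    drive: Optional[SynapticDrive]      # unit-strength synaptic drive
    config: ExcitabilityConfig

    def simulate_at(self, strength: float):
        sim = SimulationConfig(dt=self.config.dt, duration=self.config.duration,
                               record_sites=(("soma", 0.5), ("ais_dist", 0.5)))
        if self.drive is not None:
            stimuli = [self.drive.scaled(strength)]
        else:
            sec, pos = _CURRENT_SITES[self.mode]
            stimuli = [CurrentStep(sec, pos, strength, delay=self.config.onset,
                                   duration=self.config.step_duration)]
        return simulate(self.compiled, stimuli, sim)


def prepare_cell(record: CellRecord, mode: str,
                 config: ExcitabilityConfig = ExcitabilityConfig()) -> PreparedCell:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    graph = build_cell(record, config.resolved_biophys(), config.resolved_template())
    graph = balance_branches(graph, record)
    # the AP initiation zone is always finely discretized; injection/synapse
    # sections additionally so, per the 0.5 µm high-resolution rule
    fine = {"hillock", "ais_prox", "ais_dist"} & set(graph.sections)
    if mode in _SYN_BRANCH:
        fine.add(_SYN_BRANCH[mode])
    else:
        fine.add(_CURRENT_SITES[mode][0])
    graph = segmentize(graph, injection_sections=sorted(fine))
    compiled = compile_cell(graph)
    drive = None
    if mode in _SYN_BRANCH:
        syn = SynapseSet(total_g_ns=1.0, count=config.synapse_count,
                         onset=config.onset)
        # times drawn once per (cell, seed) and reused across the search,
        # so the bisection varies only stimulus strength
        drive = place_synapses(graph, _SYN_BRANCH[mode], syn, config.seed)
    return PreparedCell(record=record, mode=mode, compiled=compiled,
                        drive=drive, config=config)


# ---------------------------------------------------------------------------
# threshold search

def _fires(prep: PreparedCell, strength: float) -> Tuple[bool, object]:
    res = prep.simulate_at(strength)
    ok, _ = detect_ap(res.trace("ais_dist", 0.5), res.t)
    return ok, res


def find_threshold(cell, mode: str,
                   config: ExcitabilityConfig = ExcitabilityConfig()) -> ExcitabilityResult:
    """Minimal stimulus (bracket + bisection to the configured resolution)
    that evokes an AP, with the AP metrics measured at that stimulus.

    ``cell`` may be a :class:`CellRecord` or an already prepared cell.
    The search is equivalent to a linear scan at the same resolution: the
    reported value is the smallest grid point on [range min, range max] with
    spacing ``resolution`` at which the cell fires."""
    prep = cell if isinstance(cell, PreparedCell) else prepare_cell(cell, mode, config)
    lo, hi = config.syn_range if prep.drive is not None else config.current_range
    resol = config.syn_resolution if prep.drive is not None else config.current_resolution
    unit = "nS" if prep.drive is not None else "pA"
    n_sims = 0

    fired_lo, res_lo = _fires(prep, lo)
    n_sims += 1
    if fired_lo:
        v_th, _ = ap_voltage_threshold(res_lo.trace("soma", 0.5), res_lo.t, config.onset)
        return ExcitabilityResult(prep.record.cell_id, mode, lo, unit, v_th,
                                  ap_delay(res_lo.trace("soma", 0.5), res_lo.t, config.onset),
                                  converged=True, below_range=True, n_sims=n_sims)
    # geometric bracketing
    a, b = lo, lo
    fired = False
    while b < hi:
        b = min(b * 3.0, hi)
        fired, res_b = _fires(prep, b)
        n_sims += 1
        if fired:
            break
        a = b
    if not fired:
        return ExcitabilityResult(prep.record.cell_id, mode, float("nan"), unit,
                                  float("nan"), float("nan"),
                                  converged=False, n_sims=n_sims)
    # bisection on the resolution grid: a subthreshold, b suprathreshold
    ka, kb = int(math.floor((a - lo) / resol)), int(math.ceil((b - lo) / resol))
    res_at_kb = res_b
    while kb - ka > 1:
        km = (ka + kb) // 2
        fired_m, res_m = _fires(prep, lo + km * resol)
        n_sims += 1
        if fired_m:
            kb, res_at_kb = km, res_m
        else:
            ka = km
    threshold = lo + kb * resol
    soma = res_at_kb.trace("soma", 0.5)
    v_th, _ = ap_voltage_threshold(soma, res_at_kb.t, config.onset)
    return ExcitabilityResult(prep.record.cell_id, mode, threshold, unit, v_th,
                              ap_delay(soma, res_at_kb.t, config.onset),
                              converged=True, n_sims=n_sims)


def branch_comparison(record: CellRecord,
                      config: ExcitabilityConfig = ExcitabilityConfig()) -> Dict[str, ExcitabilityResult]:
    """Paired synaptic thresholds for the AcD branch and the (balanced)
    non-AcD branch of one cell.  Identical synapse placement windows and
    activation times (same seed) are used on both branches."""
    return {mode: find_threshold(record, mode, config)
            for mode in ("synaptic_acd_branch", "synaptic_nonacd_branch")}


def injection_site_comparison(record: CellRecord,
                              config: ExcitabilityConfig = ExcitabilityConfig()) -> pd.DataFrame:
    """5-ms current-step thresholds at the soma, proximal-AIS and distal-AIS
    centers."""
    rows = [find_threshold(record, mode, config).as_dict()
            for mode in ("current_soma", "current_ais_prox", "current_ais_dist")]
    return pd.DataFrame(rows)


def cohort_excitability(records: Iterable[CellRecord],
                        modes: Sequence[str] = ("current_soma",),
                        config: ExcitabilityConfig = ExcitabilityConfig()) -> pd.DataFrame:
    """Build, balance, segmentize and evaluate every record for the
    configured modes; deterministic given the config seed."""
    rows = []
    for rec in records:
        # non-AcD cells passed through the AcD-branch mode reduce to the
        # plain basal branch (stem length 0), so every mode accepts any cell
        for mode in modes:
            rows.append(find_threshold(rec, mode, config).as_dict())
    return pd.DataFrame(rows, columns=["cell_id", "mode", "threshold", "unit",
                                       "v_threshold", "ap_delay", "converged",
                                       "below_range", "n_sims"])


# ---------------------------------------------------------------------------
# median-reference cell and single-parameter sweeps

_SWEEPABLE = ("soma_major", "soma_minor", "ais_distance", "ais_length",
              "ais_d_start", "ais_d_max", "ais_d_end", "ais_max_pos",
              "acd_stem_length", "acd_stem_diam", "apical_scale")

_APICAL_COLS = [f"apical_d{o:02d}" for o in (5, 10, 15, 20, 25)]


def median_reference_record(table: pd.DataFrame, acd: bool = False,
                            cell_id: str = "median-reference") -> CellRecord:
    """Cell with every morphological parameter at the cohort median.

    With ``acd=True`` the stem parameters are medians over AcD cells and the
    cell is built with a dendritic axon origin; otherwise the stem is absent."""
    med = table.median(numeric_only=True)
    stem_len, stem_diam = 0.0, None
    if acd:
        acd_rows = table[table["acd_stem_length"] > 0]
        stem_len = float(acd_rows["acd_stem_length"].median())
        stem_diam = float(acd_rows["acd_stem_diam"].median())
    dist = float(med["ais_distance"])
    return CellRecord(
        cell_id=cell_id, plane="ventral", subregion="CA1m",
        soma_major=float(med["soma_major"]), soma_minor=float(med["soma_minor"]),
        apical_diams=tuple(float(med[c]) for c in _APICAL_COLS),
        ais_distance=max(dist, stem_len), ais_length=float(med["ais_length"]),
        ais_d_start=float(med["ais_d_start"]), ais_d_max=float(med["ais_d_max"]),
        ais_d_end=float(med["ais_d_end"]),
        ais_max_pos=min(float(med["ais_max_pos"]), float(med["ais_length"])),
        acd_stem_length=stem_len, acd_stem_diam=stem_diam,
    )


def _with_parameter(ref: CellRecord, parameter: str, value: float) -> CellRecord:
    kw: Dict[str, object] = {}
    if parameter == "apical_scale":
        base = np.array(ref.apical_diams)
        kw["apical_diams"] = tuple(base * value / base.mean())
    elif parameter == "ais_length":
        kw["ais_length"] = value
        kw["ais_max_pos"] = min(ref.ais_max_pos, value)
    elif parameter == "ais_distance":
        kw["ais_distance"] = max(value, ref.acd_stem_length)
    elif parameter == "acd_stem_length":
        kw["acd_stem_length"] = value
        kw["ais_distance"] = max(ref.ais_distance, value)
        if ref.acd_stem_diam is None:
            kw["acd_stem_diam"] = min(1.3, 0.9 * value) if value > 0 else None
    elif parameter == "ais_d_max":
        kw["ais_d_max"] = max(value, ref.ais_d_start, ref.ais_d_end)
    elif parameter in _SWEEPABLE:
        kw[parameter] = value
    else:
        raise ValueError(f"cannot sweep {parameter!r}")
    return replace(ref, **kw)


def median_reference_sweep(table: pd.DataFrame, parameter: str,
                           mode: str = "current_soma",
                           grid: Optional[Sequence[float]] = None,
                           n_grid: int = 25,
                           config: ExcitabilityConfig = ExcitabilityConfig()) -> pd.DataFrame:
    """Sweep one morphological parameter of the median-reference cell over
    the cohort's 1st–99th percentile range (default 25-point grid), holding
    every other parameter fixed; returns thresholds and voltage thresholds
    per grid point."""
    is_stem = parameter.startswith("acd_stem")
    ref = median_reference_record(table, acd=is_stem)
    if grid is None:
        col = table[parameter] if parameter != "apical_scale" \
            else table[_APICAL_COLS].mean(axis=1)
        vals = col[col > 0] if is_stem else col
        grid = np.linspace(*np.percentile(vals.dropna(), [1, 99]), n_grid)
    rows = []
    for value in grid:
        rec = _with_parameter(ref, parameter, float(value))
        res = find_threshold(rec, mode, config)
        rows.append({"parameter": parameter, "value": float(value),
                     "mode": mode, **{k: v for k, v in res.as_dict().items()
                                      if k not in ("cell_id", "mode")}})
    return pd.DataFrame(rows)
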