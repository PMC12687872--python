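"""Branched cable-equation solver with Hodgkin–Huxley-type conductances.

The spatially discretized cable equation on the section tree is advanced
with an implicit backward-Euler step at a fixed time step (default 25 µs).
Gating variables are advanced by the exponential-integrator update using
rates evaluated at the current voltage; the resulting linear system is
symmetric and tree-structured and is solved exactly in linear time per step
by Hines elimination (leaves-to-root factorization, root-to-leaves back
substitution).  A dense-matrix reference solver with identical physics is
provided for verification.

Units: mV, ms, µm, nA, µS, nF; conductance densities S/cm²; Ra Ω·cm;
cm µF/cm².  Interfaces accept pA and nS where the stimulation protocols are
defined in those units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .builder import CompartmentGraph, Section

__all__ = [
    "SimulationConfig",
    "CurrentStep",
    "SynapseSet",
    "SynapticDrive",
    "CompiledCell",
    "SimResult",
    "simulate",
    "place_synapses",
    "syn_kernel_peak_time",
    "synaptic_conductance",
    "dt_convergence_check",
]


# ---------------------------------------------------------------------------
# configuration and stimuli

@dataclass(frozen=True)
class SimulationConfig:
    """Solver settings; ``record_sites`` are (section, position) pairs."""

    dt: float = 0.025          # ms (25 µs)
    duration: float = 50.0     # ms
    v_init: Optional[float] = None  # default: biophys v_init
    record_sites: tuple = (("soma", 0.5), ("ais_dist", 0.5))
    seed: int = 0
    record_all: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class CurrentStep:
    """Constant current step at one site (amplitude in pA)."""

    section: str
    pos: float
    amplitude_pa: float
    delay: float = 20.0
    duration: float = 5.0


@dataclass(frozen=True)
class SynapseSet:
    """Population of double-exponential conductance synapses.

    ``count`` synapses are evenly distributed over the path window
    ``window`` (µm from the soma) on a named branch; activation times are
    Gaussian around ``onset``; the total peak conductance ``total_g_ns`` is
    divided equally per synapse (kernels are normalized to unit peak)."""

    total_g_ns: float
    count: int = 1000
    window: Tuple[float, float] = (75.0, 100.0)
    e_rev: float = 0.0
    tau_on: float = 0.175
    tau_off: float = 5.0
    onset: float = 20.0
    sigma: float = 4.0

    def __post_init__(self):
        if not (self.tau_off > self.tau_on > 0):
            raise ValueError("need tau_off > tau_on > 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class SynapticDrive:
    """A SynapseSet bound to concrete positions and activation times."""

    branch: str
    positions: np.ndarray      # (count,) position in [0, 1] along the branch
    times: np.ndarray          # (count,) activation times, ms
    g_peak_us: float           # per-synapse peak conductance, µS
    e_rev: float
    tau_on: float
    tau_off: float

    def scaled(self, total_g_ns: float) -> "SynapticDrive":
        """Same placement/times with a different total conductance."""
        return replace(self, g_peak_us=(total_g_ns / len(self.times)) * 1e-3)


def syn_kernel_peak_time(tau_on: float, tau_off: float) -> float:
    """Time to peak of the double-exponential conductance kernel."""
    return tau_on * tau_off / (tau_off - tau_on) * math.log(tau_off / tau_on)


def _kernel_norm(tau_on: float, tau_off: float) -> float:
    tp = syn_kernel_peak_time(tau_on, tau_off)
    return 1.0 / (math.exp(-tp / tau_off) - math.exp(-tp / tau_on))


def synaptic_conductance(t: np.ndarray, g_peak: float, tau_on: float, tau_off: float) -> np.ndarray:
    """Unit-peak-normalized double-exponential conductance kernel scaled to
    ``g_peak``; zero for t < 0."""
    t = np.asarray(t, float)
    g = _kernel_norm(tau_on, tau_off) * (np.exp(-t / tau_off) - np.exp(-t / tau_on))
    return np.where(t >= 0, g_peak * g, 0.0)


def place_synapses(graph: CompartmentGraph, branch: str, synapse_set: SynapseSet,
                   seed: int) -> SynapticDrive:
    """Bind a synapse population to a basal branch.

    Synapse path positions are evenly spaced over the window measured from
    the soma (so on an AcD/balanced branch the stem/stub length counts
    toward the distance); activation times are drawn once per seed."""
    sec = graph.sections[branch]
    offset = graph.path_offset(branch)
    lo, hi = synapse_set.window
    lo_s, hi_s = lo - offset, hi - offset
    if lo_s < -1e-9 or hi_s > sec.length + 1e-9:
        raise ValueError(
            f"window {synapse_set.window} µm from soma does not fit on {branch!r} "
            f"(length {sec.length} µm at path offset {offset} µm)")
    k = np.arange(synapse_set.count)
    path_pos = lo_s + (k + 0.5) / synapse_set.count * (hi_s - lo_s)
    rng = np.random.default_rng(seed)
    times = rng.normal(synapse_set.onset, synapse_set.sigma, synapse_set.count)
    return SynapticDrive(
        branch=branch, positions=path_pos / sec.length, times=times,
        g_peak_us=(synapse_set.total_g_ns / synapse_set.count) * 1e-3,
        e_rev=synapse_set.e_rev, tau_on=synapse_set.tau_on, tau_off=synapse_set.tau_off,
    )


# ---------------------------------------------------------------------------
# compilation: sections -> flat segment arrays

@dataclass
class CompiledCell:
    """Flat per-segment arrays in Hines order (parent index < child index)."""

    graph: CompartmentGraph
    parent: np.ndarray      # (N,) int64, -1 for root
    gax: np.ndarray         # (N,) µS coupling to parent
    cmdt_area: np.ndarray   # (N,) nF  (capacitance; divide by dt at run time)
    gpas: np.ndarray        # (N,) µS
    gnabar: np.ndarray      # (N,) µS at full activation
    gkbar: np.ndarray       # (N,) µS
    na_shift: np.ndarray    # (N,) mV
    seg_of: Dict[str, np.ndarray] = field(default_factory=dict)  # section -> seg indices
    seg_len: Dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.parent)

    def index(self, section: str, pos: float) -> int:
        idx = self.seg_of[section]
        j = min(int(pos * len(idx)), len(idx) - 1)
        return int(idx[j])


def compile_cell(graph: CompartmentGraph) -> CompiledCell:
    bio = graph.biophys
    order = graph.topological()
    parent_list, gax_list, cm_list, gpas_list = [], [], [], []
    gna_list, gk_list, shift_list = [], [], []
    seg_of: Dict[str, np.ndarray] = {}
    seg_len: Dict[str, float] = {}
    # per-segment half axial resistance (MΩ) for connecting neighbours
    half_r: List[float] = []

    def r_per_um(diam: float) -> float:
        # axial resistance per µm of cable, MΩ/µm
        return 0.01 * bio.ra / (math.pi * diam * diam / 4.0)

    for sec in order:
        dens = bio.for_class(sec.cls)
        n = sec.nseg
        l_seg = sec.length / n
        idx = np.zeros(n, dtype=np.int64)
        for j in range(n):
            x_c = (j + 0.5) / n
            d = sec.diam_at(x_c)
            area = math.pi * d * l_seg            # µm², cylinder lateral
            i = len(parent_list)
            idx[j] = i
            if j > 0:
                p = i - 1
                g = 1.0 / (half_r[p] + 0.5 * l_seg * r_per_um(d))
            elif sec.parent is None:
                p, g = -1, 0.0
            else:
                pidx = seg_of[sec.parent]
                psec = graph.sections[sec.parent]
                jp = min(int(sec.parent_pos * len(pidx)), len(pidx) - 1)
                p = int(pidx[jp])
                # resistance from the parent segment's centre to the
                # attachment point, plus the child's first half segment
                x_pc = (jp + 0.5) / len(pidx)
                d_p = psec.diam_at(x_pc)
                r_att = abs(sec.parent_pos - x_pc) * psec.length * r_per_um(d_p)
                g = 1.0 / (r_att + 0.5 * l_seg * r_per_um(d))
            parent_list.append(p)
            gax_list.append(g)
            half_r.append(0.5 * l_seg * r_per_um(d))
            cm_list.append(bio.cm * area * 1e-5)          # nF
            gpas_list.append(dens.g_pas * area * 1e-2)    # µS
            gna_list.append(dens.gna * area * 1e-2)
            gk_list.append(dens.gk * area * 1e-2)
            shift_list.append(bio.na_shift if sec.cls == "ais_dist" else 0.0)
        seg_of[sec.name] = idx
        seg_len[sec.name] = l_seg
    return CompiledCell(
        graph=graph,
        parent=np.array(parent_list, dtype=np.int64),
        gax=np.array(gax_list), cmdt_area=np.array(cm_list),
        gpas=np.array(gpas_list), gnabar=np.array(gna_list),
        gkbar=np.array(gk_list), na_shift=np.array(shift_list),
        seg_of=seg_of, seg_len=seg_len,
    )


# ---------------------------------------------------------------------------
# channel kinetics (transient Na m³h, delayed-rectifier K n)

def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, y + x / 2.0, safe / (1.0 - np.exp(-safe / y)))


def na_m_rates(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = 0.182 * _vtrap(v + 35.0, 9.0)
    b = 0.124 * _vtrap(-(v + 35.0), 9.0)
    return a / (a + b), 1.0 / (a + b)


def na_h_rates(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = 0.024 * _vtrap(v + 50.0, 5.0)
    b = 0.0091 * _vtrap(-(v + 75.0), 5.0)
    hinf = 1.0 / (1.0 + np.exp((v + 65.0) / 6.2))
    return hinf, 1.0 / (a + b)


def k_n_rates(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = 0.02 * _vtrap(v - 25.0, 9.0)
    b = 0.002 * _vtrap(-(v - 25.0), 9.0)
    return a / (a + b), 1.0 / (a + b)


# numba scalar twins (same formulas; keep in sync with the numpy versions)

@njit(cache=True, inline="always")
def _vtrap_s(x, y):
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True, inline="always")
def _na_m_s(v):
    a = 0.182 * _vtrap_s(v + 35.0, 9.0)
    b = 0.124 * _vtrap_s(-(v + 35.0), 9.0)
    return a / (a + b), 1.0 / (a + b)


@njit(cache=True, inline="always")
def _na_h_s(v):
    a = 0.024 * _vtrap_s(v + 50.0, 5.0)
    b = 0.0091 * _vtrap_s(-(v + 75.0), 5.0)
    hinf = 1.0 / (1.0 + math.exp((v + 65.0) / 6.2))
    return hinf, 1.0 / (a + b)


@njit(cache=True, inline="always")
def _k_n_s(v):
    a = 0.02 * _vtrap_s(v - 25.0, 9.0)
    b = 0.002 * _vtrap_s(-(v - 25.0), 9.0)
    return a / (a + b), 1.0 / (a + b)


@njit(cache=True)
def _run(n_steps, dt, parent, gax, cm, gpas, gnabar, gkbar, shift, shift_h,
         epas, ena, ek,
         v, m, h, nk,
         syn_seg, syn_g, e_syn,
         inj_seg, inj_amp, inj_start, inj_end,
         rec_idx, out):
    n = v.shape[0]
    d = np.empty(n)
    rhs = np.empty(n)
    cmdt = cm / dt
    for step in range(n_steps):
        # gating: exponential-integrator update at the current voltage
        for i in range(n):
            vi = v[i]
            if gnabar[i] > 0.0:
                minf, taum = _na_m_s(vi + shift[i])
                hinf, tauh = _na_h_s(vi + shift_h[i])
                m[i] = minf + (m[i] - minf) * math.exp(-dt / taum)
                h[i] = hinf + (h[i] - hinf) * math.exp(-dt / tauh)
            if gkbar[i] > 0.0:
                ninf, taun = _k_n_s(vi)
                nk[i] = ninf + (nk[i] - ninf) * math.exp(-dt / taun)
        # assemble the implicit system
        for i in range(n):
            gna = gnabar[i] * m[i] * m[i] * m[i] * h[i]
            gk = gkbar[i] * nk[i]
            d[i] = cmdt[i] + gpas[i] + gna + gk
            rhs[i] = cmdt[i] * v[i] + gpas[i] * epas + gna * ena + gk * ek
        for k in range(syn_seg.shape[0]):
            i = syn_seg[k]
            g = syn_g[step, k]
            d[i] += g
            rhs[i] += g * e_syn
        for k in range(inj_seg.shape[0]):
            if inj_start[k] <= step < inj_end[k]:
                rhs[inj_seg[k]] += inj_amp[k]
        for i in range(1, n):
            d[i] += gax[i]
            d[parent[i]] += gax[i]
        # Hines elimination (children have larger indices than parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gax[i] / d[i]
            d[p] -= gax[i] * f
            rhs[p] += rhs[i] * f
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + gax[i] * v[parent[i]]) / d[i]
        for r in range(rec_idx.shape[0]):
            out[step, r] = v[rec_idx[r]]
    return v


# ---------------------------------------------------------------------------
# simulation front end

@dataclass
class SimResult:
    t: np.ndarray
    traces: Dict[Tuple[str, float], np.ndarray]
    config: SimulationConfig

    def trace(self, section: str, pos: float) -> np.ndarray:
        for (s, p), tr in self.traces.items():
            if s == section and abs(p - pos) < 1e-9:
                return tr
        raise KeyError((section, pos))

    def to_frame(self):
        """Tidy table of the recorded traces: time_ms, site, v_mv."""
        import pandas as pd

        frames = [pd.DataFrame({"time_ms": self.t, "site": f"{s}({p:g})", "v_mv": tr})
                  for (s, p), tr in self.traces.items()]
        return pd.concat(frames, ignore_index=True)


def _syn_waveforms(drives: Sequence[SynapticDrive], cell: CompiledCell,
                   dt: float, n_steps: int) -> Tuple[np.ndarray, np.ndarray, float]:
    """Aggregate synapse kernels into per-step, per-target-segment
    conductances via the exact two-state exponential recursion."""
    seg_map: Dict[int, int] = {}
    deposits: List[Tuple[int, int, float]] = []  # (step, target, weight µS)
    e_rev = drives[0].e_rev if drives else 0.0
    tau_on = drives[0].tau_on if drives else 0.175
    tau_off = drives[0].tau_off if drives else 5.0
    for drv in drives:
        if (drv.e_rev, drv.tau_on, drv.tau_off) != (e_rev, tau_on, tau_off):
            raise ValueError("all synaptic drives in one run must share kinetics")
        norm = _kernel_norm(drv.tau_on, drv.tau_off)
        for pos, t0 in zip(drv.positions, drv.times):
            seg = cell.index(drv.branch, float(pos))
            tgt = seg_map.setdefault(seg, len(seg_map))
            step = max(int(math.ceil(t0 / dt)), 0)
            if step < n_steps:
                deposits.append((step, tgt, drv.g_peak_us * norm))
    n_tgt = len(seg_map)
    g = np.zeros((n_steps, max(n_tgt, 1)))
    if n_tgt:
        dep = np.zeros((n_steps, n_tgt))
        for step, tgt, w in deposits:
            dep[step, tgt] += w
        decay_on = math.exp(-dt / tau_on)
        decay_off = math.exp(-dt / tau_off)
        a = np.zeros(n_tgt)
        b = np.zeros(n_tgt)
        for s in range(n_steps):
            a = a * decay_on + dep[s]
            b = b * decay_off + dep[s]
            g[s, :n_tgt] = b - a
    seg_idx = np.array(sorted(seg_map, key=seg_map.get), dtype=np.int64) \
        if n_tgt else np.zeros(0, dtype=np.int64)
    return seg_idx, g[:, :n_tgt] if n_tgt else np.zeros((n_steps, 0)), e_rev


def _prepare(cell: CompiledCell, stimuli: Sequence, config: SimulationConfig):
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    steps = [s for s in stimuli if isinstance(s, CurrentStep)]
    drives = [s for s in stimuli if isinstance(s, SynapticDrive)]
    bad = [s for s in stimuli if not isinstance(s, (CurrentStep, SynapticDrive))]
    if bad:
        raise TypeError(f"unsupported stimulus objects: {bad}")
    for s in steps:
        if s.delay + s.duration > config.duration + 1e-9:
            raise ValueError("duration must cover the stimulus window")
    inj_seg = np.array([cell.index(s.section, s.pos) for s in steps], dtype=np.int64)
    inj_amp = np.array([s.amplitude_pa * 1e-3 for s in steps])  # pA -> nA
    inj_start = np.array([int(round(s.delay / dt)) for s in steps], dtype=np.int64)
    inj_end = np.array([int(round((s.delay + s.duration) / dt)) for s in steps], dtype=np.int64)
    syn_seg, syn_g, e_syn = _syn_waveforms(drives, cell, dt, n_steps)
    return n_steps, inj_seg, inj_amp, inj_start, inj_end, syn_seg, syn_g, e_syn


def _init_states(cell: CompiledCell, v0: float):
    n = cell.n
    v = np.full(n, v0)
    shift = cell.na_shift.copy()
    shift_h = shift.copy() if cell.graph.biophys.na_shift_mode == "full" \
        else np.zeros(n)
    # note: the shift convention is "activation threshold shifted by -5 mV",
    # i.e. gates see a voltage offset of -na_shift
    shift = -shift
    shift_h = -shift_h
    m = na_m_rates(v + shift)[0]
    h = na_h_rates(v + shift_h)[0]
    nk = k_n_rates(v)[0]
    return v, m, h, nk, shift, shift_h


def simulate(cell, stimuli: Sequence, config: SimulationConfig) -> SimResult:
    """Run the implicit solver on a compiled cell (or a graph, compiled on
    the fly) and return voltage traces at the configured record sites."""
    if isinstance(cell, CompartmentGraph):
        cell = compile_cell(cell)
    bio = cell.graph.biophys
    v0 = config.v_init if config.v_init is not None else bio.v_init
    n_steps, inj_seg, inj_amp, inj_start, inj_end, syn_seg, syn_g, e_syn = \
        _prepare(cell, stimuli, config)
    v, m, h, nk, shift, shift_h = _init_states(cell, v0)
    sites = list(config.record_sites)
    if config.record_all:
        sites = [(name, (j + 0.5) / len(cell.seg_of[name]))
                 for name in cell.seg_of for j in range(len(cell.seg_of[name]))]
    rec_idx = np.array([cell.index(s, p) for s, p in sites], dtype=np.int64)
    out = np.empty((n_steps, len(sites)))
    _run(n_steps, config.dt, cell.parent, cell.gax, cell.cmdt_area,
         cell.gpas, cell.gnabar, cell.gkbar, shift, shift_h,
         bio.e_pas, bio.ena, bio.ek, v, m, h, nk,
         syn_seg, syn_g, e_syn,
         inj_seg, inj_amp, inj_start, inj_end, rec_idx, out)
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        raise FloatingPointError(
            f"solver diverged at step {bad[0][0]} (t = {bad[0][0] * config.dt:.3f} ms)")
    t = (np.arange(n_steps) + 1) * config.dt
    traces = {site: out[:, k].copy() for k, site in enumerate(sites)}
    return SimResult(t=t, traces=traces, config=config)


def simulate_dense(cell, stimuli: Sequence, config: SimulationConfig) -> SimResult:
    """Reference solver: identical physics, dense-matrix linear solve.

    Used to verify the tree-structured Hines elimination; O(n³) per step,
    only suitable for small test cells."""
    if isinstance(cell, CompartmentGraph):
        cell = compile_cell(cell)
    bio = cell.graph.biophys
    v0 = config.v_init if config.v_init is not None else bio.v_init
    n_steps, inj_seg, inj_amp, inj_start, inj_end, syn_seg, syn_g, e_syn = \
        _prepare(cell, stimuli, config)
    v, m, h, nk, shift, shift_h = _init_states(cell, v0)
    n = cell.n
    cmdt = cell.cmdt_area / config.dt
    # constant axial part of the system matrix
    ax = np.zeros((n, n))
    for i in range(1, n):
        p = cell.parent[i]
        ax[i, i] += cell.gax[i]
        ax[p, p] += cell.gax[i]
        ax[i, p] -= cell.gax[i]
        ax[p, i] -= cell.gax[i]
    sites = list(config.record_sites)
    rec_idx = np.array([cell.index(s, p) for s, p in sites], dtype=np.int64)
    out = np.empty((n_steps, len(sites)))
    for step in range(n_steps):
        minf, taum = na_m_rates(v + shift)
        hinf, tauh = na_h_rates(v + shift_h)
        ninf, taun = k_n_rates(v)
        act = cell.gnabar > 0
        m = np.where(act, minf + (m - minf) * np.exp(-config.dt / taum), m)
        h = np.where(act, hinf + (h - hinf) * np.exp(-config.dt / tauh), h)
        nk = np.where(cell.gkbar > 0, ninf + (nk - ninf) * np.exp(-config.dt / taun), nk)
        gna = cell.gnabar * m ** 3 * h
        gk = cell.gkbar * nk
        diag = cmdt + cell.gpas + gna + gk
        rhs = cmdt * v + cell.gpas * bio.e_pas + gna * bio.ena + gk * bio.ek
        for k, i in enumerate(syn_seg):
            diag[i] += syn_g[step, k]
            rhs[i] += syn_g[step, k] * e_syn
        for k, i in enumerate(inj_seg):
            if inj_start[k] <= step < inj_end[k]:
                rhs[i] += inj_amp[k]
        a = ax + np.diag(diag)
        v = np.linalg.solve(a, rhs)
        out[step] = v[rec_idx]
    t = (np.arange(n_steps) + 1) * config.dt
    traces = {site: out[:, k].copy() for k, site in enumerate(sites)}
    return SimResult(t=t, traces=traces, config=config)


def dt_convergence_check(cell, stimuli: Sequence, config: SimulationConfig,
                         site: Tuple[str, float] = ("soma", 0.5)) -> Dict[str, float]:
    """Rerun at dt/2 and dt/4 and report the maximum trace deviation at one
    site (comparing at the coarse sample times)."""
    base = simulate(cell, stimuli, config).trace(*site)
    report = {}
    for k, frac in (("dt/2", 2), ("dt/4", 4)):
        cfg = replace(config, dt=config.dt / frac)
        fine = simulate(cell, stimuli, cfg).trace(*site)
        report[k] = float(np.max(np.abs(fine[frac - 1::frac] - base)))
    return report
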