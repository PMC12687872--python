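import math

import numpy as np
import pytest
from scipy.stats import kstest

from aisgeom.builder import build_cell, segmentize, Section, CompartmentGraph
from aisgeom.engine import (CompiledCell, CurrentStep, SimulationConfig,
                            SynapseSet, compile_cell, simulate, simulate_dense,
                            place_synapses, syn_kernel_peak_time,
                            synaptic_conductance, dt_convergence_check)
from aisgeom.io import make_fixtures
from conftest import passive_biophys


DT = 0.025


def test_finite_cable_input_resistance(passive_cylinder):
    """Steady-state input resistance of a sealed passive cable matches the
    analytic two-sided coth expression within 0.5%."""
    bio = passive_cylinder.biophys
    sec = passive_cylinder.sections["soma"]
    d_cm = sec.diam_at(0.0) * 1e-4
    r_m = 1.0 / 1e-4                       # Ohm*cm^2
    lam = math.sqrt((r_m / bio.ra) * (d_cm / 4.0))        # cm
    r_axial = 4.0 * bio.ra / (math.pi * d_cm ** 2)        # Ohm/cm
    r_inf = r_axial * lam * 1e-6                          # MOhm
    L_cm = sec.length * 1e-4
    x0 = (sec.length / (2 * sec.nseg)) * 1e-4  # injection at first segment centre
    a, b = x0 / lam, (L_cm - x0) / lam
    coth = lambda x: 1.0 / math.tanh(x)
    rin_analytic = r_inf * (coth(a) * coth(b)) / (coth(a) + coth(b))

    cfg = SimulationConfig(duration=500.0, record_sites=(("soma", 0.0),))
    res = simulate(passive_cylinder, [CurrentStep("soma", 0.0, -50.0, 20.0, 450.0)], cfg)
    tr = res.trace("soma", 0.0)
    rin = (tr[int(460 / DT)] - tr[int(19 / DT)]) / -0.05
    assert rin == pytest.approx(rin_analytic, rel=5e-3)


def test_resting_stability(ca1_record):
    """With no stimulus the membrane settles and stays within 0.5 mV of its
    resting fixed point for 200 ms."""
    g = segmentize(build_cell(ca1_record))
    res = simulate(g, [], SimulationConfig(duration=250.0))
    soma = res.trace("soma", 0.5)
    rest = soma[int(50 / DT):]
    assert rest.max() - rest.min() < 0.5
    assert abs(rest[-1] - rest[0]) < 0.2


def test_tree_solver_matches_dense_reference():
    """Hines elimination reproduces a dense linear solve to 1e-9 mV on small
    random trees with active channels and mixed stimuli."""
    for seed in range(3):
        _, tree = make_fixtures(seed)
        cell = compile_cell(tree)
        assert cell.n <= 20
        sites = tuple((name, 0.5) for name in tree.sections)
        stim = [CurrentStep("soma", 0.5, 150.0, 5.0, 5.0)]
        cfg = SimulationConfig(duration=20.0, record_sites=sites)
        a = simulate(cell, stim, cfg)
        b = simulate_dense(cell, stim, cfg)
        for site in sites:
            np.testing.assert_allclose(a.trace(*site), b.trace(*site), atol=1e-9)


def test_synaptic_kernel_shape():
    tau_on, tau_off = 0.175, 5.0
    tp = syn_kernel_peak_time(tau_on, tau_off)
    assert tp == pytest.approx(tau_on * tau_off / (tau_off - tau_on)
                               * math.log(tau_off / tau_on))
    t = np.linspace(0, 40, 40001)
    g = synaptic_conductance(t, 2.0, tau_on, tau_off)
    assert g[0] == pytest.approx(0.0)
    assert g.max() == pytest.approx(2.0, rel=1e-6)   # unit-peak normalization
    assert abs(t[g.argmax()] - tp) < 2e-3
    assert synaptic_conductance(np.array([-1.0]), 2.0, tau_on, tau_off)[0] == 0.0


def test_place_synapses_positions_and_times(ca1_record):
    g = build_cell(ca1_record)
    one = place_synapses(g, "basal_nonacd", SynapseSet(total_g_ns=10.0, count=1), seed=0)
    # single synapse sits at the window midpoint: 87.5 µm from the soma
    assert one.positions[0] * g.sections["basal_nonacd"].length == pytest.approx(87.5)
    assert one.g_peak_us == pytest.approx(10.0 * 1e-3)

    many = place_synapses(g, "basal_nonacd", SynapseSet(total_g_ns=10.0, count=1000), seed=1)
    d = many.positions * g.sections["basal_nonacd"].length
    assert d.min() >= 75.0 and d.max() <= 100.0
    again = place_synapses(g, "basal_nonacd", SynapseSet(total_g_ns=10.0, count=1000), seed=1)
    np.testing.assert_array_equal(many.times, again.times)

    big = place_synapses(g, "basal_nonacd",
                         SynapseSet(total_g_ns=1.0, count=100000), seed=2)
    assert kstest(big.times, "norm", args=(20.0, 4.0)).pvalue > 0.01


def test_synapse_reversal_zeroes_current(passive_cylinder):
    """Clamped exactly at the reversal potential, synaptic input moves
    nothing (v_init = e_pas = e_rev = 0)."""
    bio = passive_biophys(e_pas=0.0)
    sec = {"soma": Section("soma", "soma", 100.0, [(0.0, 2.0), (1.0, 2.0)], None, nseg=5)}
    g = CompartmentGraph(sections=sec, biophys=bio)
    drv = place_synapses(g, "soma", SynapseSet(total_g_ns=50.0, count=10,
                                               window=(40.0, 60.0)), seed=0)
    res = simulate(g, [drv], SimulationConfig(duration=40.0, record_sites=(("soma", 0.5),)))
    np.testing.assert_allclose(res.trace("soma", 0.5), 0.0, atol=1e-9)


def test_passive_charge_conservation(ca1_record):
    """Injected charge equals capacitive plus leak charge within 0.5%."""
    g = segmentize(build_cell(ca1_record, biophys=passive_biophys()))
    cell = compile_cell(g)
    amp_na, t0, t1 = 0.1, 20.0, 120.0
    cfg = SimulationConfig(duration=200.0, record_all=True)
    res = simulate(cell, [CurrentStep("soma", 0.5, amp_na * 1e3, t0, t1 - t0)], cfg)
    v = np.column_stack([res.traces[s] for s in res.traces])  # (steps, n)
    v0 = np.full(cell.n, g.biophys.v_init)
    vprev = np.vstack([v0, v[:-1]])
    dt = cfg.dt
    q_cap = (cell.cmdt_area * (v - vprev) / dt).sum(axis=1)
    q_leak = (cell.gpas * (v - g.biophys.e_pas)).sum(axis=1)
    injected = amp_na * (t1 - t0)
    absorbed = ((q_cap + q_leak) * dt).sum()
    assert absorbed == pytest.approx(injected, rel=5e-3)


def test_dt_convergence(ca1_record):
    g = segmentize(build_cell(ca1_record, biophys=passive_biophys()))
    rep = dt_convergence_check(g, [CurrentStep("soma", 0.5, 200.0, 5.0, 5.0)],
                               SimulationConfig(duration=25.0))
    # first-order scheme: dev(dt/4)/dev(dt/2) -> 1.5 asymptotically
    assert rep["dt/4"] > rep["dt/2"]
    assert 1.2 < rep["dt/4"] / rep["dt/2"] < 1.9
    same = dt_convergence_check(g, [], SimulationConfig(duration=5.0))
    assert same["dt/2"] < 0.05  # passive resting: nearly dt-independent


def test_spike_time_dt_refinement(ca1_record):
    """Halving the 25 µs step moves the AIS threshold-crossing time by
    less than 0.1 ms at a suprathreshold current step."""
    from aisgeom.excitability import detect_ap

    g = segmentize(build_cell(ca1_record), ["soma", "ais_prox", "ais_dist"])
    cell = compile_cell(g)
    stim = [CurrentStep("soma", 0.5, 400.0, 20.0, 5.0)]
    times = []
    for dt in (0.025, 0.0125):
        res = simulate(cell, stim, SimulationConfig(dt=dt, duration=40.0))
        fired, t_ap = detect_ap(res.trace("ais_dist", 0.5), res.t)
        assert fired
        times.append(t_ap)
    assert abs(times[0] - times[1]) < 0.1


def test_voltage_bounds_under_strong_drive(ca1_record):
    g = segmentize(build_cell(ca1_record), ["soma", "ais_prox", "ais_dist"])
    res = simulate(g, [CurrentStep("soma", 0.5, 1000.0, 20.0, 5.0)],
                   SimulationConfig(duration=45.0))
    for tr in res.traces.values():
        assert tr.min() > -100.0 and tr.max() < 60.0


def test_duration_must_cover_stimulus(ca1_record):
    g = segmentize(build_cell(ca1_record))
    with pytest.raises(ValueError):
        simulate(g, [CurrentStep("soma", 0.5, 100.0, 20.0, 5.0)],
                 SimulationConfig(duration=10.0))
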