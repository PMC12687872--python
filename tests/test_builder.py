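import math

import numpy as np
import pytest

from aisgeom.builder import (build_cell, balance_branches, segmentize,
                             default_biophys, default_template, load_biophys,
                             save_biophys, d_lambda_nseg, ConfigurationError,
                             Section, CompartmentGraph)
from aisgeom.records import soma_spheroid_surface
from aisgeom.engine import compile_cell, simulate, SimulationConfig, CurrentStep
from conftest import passive_biophys


def test_non_acd_topology(ca1_record):
    g = build_cell(ca1_record)
    assert "acd_stem" not in g.sections
    # axon path: soma -> hillock -> ais_prox -> ais_dist -> axon_distal
    assert g.sections["hillock"].parent == "soma"
    assert g.sections["ais_prox"].parent == "hillock"
    assert g.sections["ais_dist"].parent == "ais_prox"
    assert g.sections["axon_distal"].parent == "ais_dist"
    assert g.sections["basal_acd"].parent == "soma"
    assert g.sections["basal_nonacd"].parent == "soma"
    assert g.sections["hillock"].length == pytest.approx(ca1_record.ais_distance)


def test_acd_topology(acd_record):
    g = build_cell(acd_record)
    stem = g.sections["acd_stem"]
    assert stem.parent == "soma"
    assert stem.length == pytest.approx(6.0)
    assert g.sections["basal_acd"].parent == "acd_stem"
    # hillock covers the remaining soma-to-AIS distance beyond the stem
    assert g.sections["hillock"].parent == "acd_stem"
    assert g.sections["hillock"].length == pytest.approx(8.0 - 6.0)


def test_ais_split_conserves_length_and_endpoint(ca1_record):
    g = build_cell(ca1_record)
    total = g.sections["ais_prox"].length + g.sections["ais_dist"].length
    assert total == pytest.approx(ca1_record.ais_length)
    # origin-to-AIS-end path length equals distance + length
    path = g.sections["hillock"].length + total
    assert path == pytest.approx(ca1_record.ais_distance + ca1_record.ais_length)
    # diameters are continuous at the split and hit the taper landmarks
    assert g.sections["ais_prox"].diam_at(1.0) == pytest.approx(
        g.sections["ais_dist"].diam_at(0.0))
    assert g.sections["ais_prox"].diam_at(0.0) == pytest.approx(ca1_record.ais_d_start)
    assert g.sections["ais_dist"].diam_at(1.0) == pytest.approx(ca1_record.ais_d_end)


def test_ais_taper_monotone_when_max_at_start(ca1_record):
    from dataclasses import replace

    rec = replace(ca1_record, ais_max_pos=0.0)
    g = build_cell(rec)
    xs = np.linspace(0, 1, 20)
    prox = [g.sections["ais_prox"].diam_at(x) for x in xs]
    dist = [g.sections["ais_dist"].diam_at(x) for x in xs]
    assert all(np.diff(prox) <= 1e-12) and all(np.diff(dist) <= 1e-12)
    assert prox[0] == pytest.approx(rec.ais_d_max)


def test_soma_cylinder_matches_spheroid_surface(ca1_record):
    g = build_cell(ca1_record)
    soma = g.sections["soma"]
    lateral = math.pi * soma.diam_at(0.5) * soma.length
    assert lateral == pytest.approx(soma_spheroid_surface(ca1_record), rel=1e-3)


def test_template_missing_key_rejected(ca1_record):
    t = default_template()
    del t["basal"]
    with pytest.raises(ConfigurationError):
        build_cell(ca1_record, template=t)


def test_balance_stub_mirrors_stem(ca1_record, acd_record):
    g = balance_branches(build_cell(ca1_record), ca1_record)
    assert "balance_stub" not in g.sections  # identity for non-AcD cells
    g2 = balance_branches(build_cell(acd_record), acd_record)
    stub = g2.sections["balance_stub"]
    stem = g2.sections["acd_stem"]
    assert stub.length == pytest.approx(stem.length)
    assert stub.diam_profile == stem.diam_profile
    assert g2.sections["basal_nonacd"].parent == "balance_stub"


def test_balanced_branches_equal_passive_input_resistance(acd_record):
    """Passive steady-state input resistance at the two synaptic zones
    (87.5 µm path distance) agrees within 1% after balancing."""
    g = balance_branches(build_cell(acd_record, biophys=passive_biophys(g_pas=5e-5)),
                        acd_record)
    g = segmentize(g, ["basal_acd", "basal_nonacd"])
    cell = compile_cell(g)
    rins = []
    for branch in ("basal_acd", "basal_nonacd"):
        off = g.path_offset(branch)
        pos = (87.5 - off) / g.sections[branch].length
        cfg = SimulationConfig(duration=400.0, record_sites=((branch, pos),))
        res = simulate(cell, [CurrentStep(branch, pos, -20.0, delay=20, duration=350)], cfg)
        tr = res.trace(branch, pos)
        rins.append((tr[int(360 / 0.025)] - tr[int(19 / 0.025)]) / -0.02)
    assert abs(rins[0] - rins[1]) / np.mean(rins) < 0.01


def test_segmentize_rules(ca1_record):
    g = build_cell(ca1_record)
    fine = segmentize(g, ["basal_acd"])
    basal = fine.sections["basal_acd"]
    # 150 µm at <= 0.5 µm per segment, odd-adjusted
    assert basal.nseg >= 300 and basal.nseg % 2 == 1
    assert basal.length / basal.nseg <= 0.5
    for s in fine.sections.values():
        assert s.nseg % 2 == 1
    # d_lambda rule elsewhere
    ap = fine.sections["apical2"]
    assert ap.nseg == d_lambda_nseg(g.sections["apical2"], g.biophys.ra, g.biophys.cm)


def test_segmentize_refinement_converges(ca1_record):
    """Refining the spatial grid changes the steady-state somatic voltage
    under a weak current by < 0.1%."""
    vals = []
    for d_lambda in (0.1, 0.033):
        g = segmentize(build_cell(ca1_record, biophys=passive_biophys()),
                       d_lambda=d_lambda)
        cfg = SimulationConfig(duration=300.0, record_sites=(("soma", 0.5),))
        res = simulate(compile_cell(g), [CurrentStep("soma", 0.5, -50.0, 20, 250)], cfg)
        vals.append(res.trace("soma", 0.5)[int(260 / 0.025)])
    assert abs(vals[0] - vals[1]) / abs(vals[1]) < 1e-3


def test_build_is_deterministic(acd_record):
    a = build_cell(acd_record)
    b = build_cell(acd_record)
    assert sorted(a.sections) == sorted(b.sections)
    for name in a.sections:
        assert a.sections[name].diam_profile == b.sections[name].diam_profile


def test_biophys_yaml_round_trip(tmp_path):
    spec = default_biophys()
    path = tmp_path / "bio.yaml"
    save_biophys(spec, path)
    back = load_biophys(path)
    assert back == spec
    # missing required key rejected
    import yaml

    payload = yaml.safe_load(path.read_text())
    del payload["cm"]
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump(payload))
    with pytest.raises(ConfigurationError):
        load_biophys(bad)


def test_graph_requires_soma_root():
    bio = default_biophys()
    with pytest.raises(ValueError):
        CompartmentGraph(sections={"a": Section("a", "soma", 10.0,
                                                [(0.0, 1.0), (1.0, 1.0)], None)},
                         biophys=bio)
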