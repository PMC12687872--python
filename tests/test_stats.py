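import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from aisgeom.stats import (StatsConfig, log_transform, zscore_global,
                           regional_variability, partial_spearman,
                           predictability_ledger, group_compare,
                           acd_fraction_by_region)


def test_log_transform_examples():
    df = pd.DataFrame({"ais_distance": [np.e, 1.0, 4.0],
                       "acd_stem_length": [2.0, 0.0, 3.0],
                       "other": [5.0, 6.0, 7.0]})
    out, excluded = log_transform(df, StatsConfig())
    assert out["ais_distance"].iloc[0] == pytest.approx(1.0)
    assert out["ais_distance"].iloc[1] == pytest.approx(0.0)
    assert np.isnan(out["acd_stem_length"].iloc[1])  # zero stem excluded
    assert excluded["acd_stem_length"] == 1
    pd.testing.assert_series_equal(out["other"], df["other"])  # untouched


def test_zscore_global_convention():
    df = pd.DataFrame({"x": [0.0, 2.0]})
    out = zscore_global(df, ["x"])
    # sample SD (ddof=1): SD = sqrt(2), not 1 — hence ±1/sqrt(2)... the
    # convention check: mean 0 and ddof-1 SD 1
    assert out["x"].mean() == pytest.approx(0.0)
    assert out["x"].std(ddof=1) == pytest.approx(1.0)
    np.testing.assert_allclose(out["x"], [-np.sqrt(0.5), np.sqrt(0.5)])
    with pytest.raises(ValueError):
        zscore_global(pd.DataFrame({"x": [3.0, 3.0, 3.0]}), ["x"])
    again = zscore_global(out, ["x"])  # idempotent once standardized
    np.testing.assert_allclose(again["x"], out["x"], atol=1e-12)


def test_regional_variability_against_resampling():
    rng = np.random.default_rng(0)
    n = 4000
    base = pd.DataFrame({
        "plane": "dorsal", "subregion": "CA1m",
        "hippocampus": rng.choice([f"h{i}" for i in range(8)], n),
        "ais_length": rng.normal(25, 4, n),
        "ais_distance": np.exp(rng.normal(1.5, 0.4, n)),
    })
    out = regional_variability(base, ["ais_length", "ais_distance"])
    # random group assignment = each group is a draw from the global
    # distribution, so within-group SD of global Z-scores ≈ 1
    assert out["ais_length"].mean() == pytest.approx(1.0, abs=0.05)
    assert out["ais_distance"].mean() == pytest.approx(1.0, abs=0.05)
    # permuting rows changes nothing
    perm = base.sample(frac=1.0, random_state=1)
    out2 = regional_variability(perm, ["ais_length", "ais_distance"])
    pd.testing.assert_frame_equal(out.sort_values("hippocampus").reset_index(drop=True),
                                  out2.sort_values("hippocampus").reset_index(drop=True))


def test_regional_variability_flags_small_groups():
    df = pd.DataFrame({
        "plane": "dorsal", "subregion": "CA1m",
        "hippocampus": ["a"] * 10 + ["b"] * 2,
        "ais_length": np.r_[np.random.default_rng(1).normal(25, 4, 10), 20, 30],
        "ais_distance": 5.0,
    })
    out = regional_variability(df, ["ais_length"]).set_index("hippocampus")
    assert np.isfinite(out.loc["a", "ais_length"])
    assert np.isnan(out.loc["b", "ais_length"])


def _partial_rank_oracle(df, x, y, covs):
    """Independent residualization oracle: correlate the residuals of the
    rank-transformed x and y after regressing out rank/dummy covariates."""
    rx = rankdata(df[x])
    ry = rankdata(df[y])
    cols = [np.ones(len(df))]
    for c in covs:
        if df[c].dtype.kind in "fiu":
            cols.append(rankdata(df[c]))
        else:
            d = pd.get_dummies(df[c], drop_first=True, dtype=float)
            cols.extend(d[col].to_numpy() for col in d.columns)
    X = np.column_stack(cols)
    res_x = rx - X @ np.linalg.lstsq(X, rx, rcond=None)[0]
    res_y = ry - X @ np.linalg.lstsq(X, ry, rcond=None)[0]
    return float(np.corrcoef(res_x, res_y)[0, 1])


def test_partial_spearman_monotone_and_oracle():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 10, 20)
    df = pd.DataFrame({"x": x, "y": np.exp(x)})
    r, p, n = partial_spearman(df, "x", "y")
    assert r == pytest.approx(1.0)
    assert n == 20
    # 20-row table with a categorical covariate: matches rank residualization
    df = pd.DataFrame({
        "x": rng.normal(size=20), "y": rng.normal(size=20),
        "g": rng.choice(["a", "b", "c"], 20),
    })
    r, p, n = partial_spearman(df, "x", "y", ["g"])
    assert r == pytest.approx(_partial_rank_oracle(df, "x", "y", ["g"]), abs=1e-6)


def test_partial_spearman_controls_common_cause():
    rng = np.random.default_rng(3)
    n = 4000
    g = rng.choice([0.0, 5.0, 10.0], n)
    x = g + rng.normal(size=n)
    y = 2 * g + rng.normal(size=n)
    r_raw, _, _ = partial_spearman(pd.DataFrame({"x": x, "y": y}), "x", "y")
    df = pd.DataFrame({"x": x, "y": y, "g": pd.Categorical(g.astype(int).astype(str))})
    r_part, _, _ = partial_spearman(df, "x", "y", ["g"])
    assert r_raw > 0.5
    assert abs(r_part) < 0.05


def test_partial_spearman_insufficient_n():
    df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 3.0]})
    with pytest.raises(ValueError):
        partial_spearman(df, "x", "y")


def test_predictability_ledger_properties():
    rng = np.random.default_rng(4)
    n = 300
    indep = pd.DataFrame({f"p{i}": rng.normal(size=n) for i in range(4)})
    led = predictability_ledger(indep, [f"p{i}" for i in range(4)], covariates=())
    assert (led["sum_r2"] < 0.05).all()  # independent columns predict nothing
    # an exact copy contributes r² = 1 to both parameters
    dep = indep.assign(p4=indep["p0"])
    led2 = predictability_ledger(dep, ["p0", "p1", "p2", "p3", "p4"], covariates=())
    led2 = led2.set_index("parameter")["sum_r2"]
    assert led2["p0"] >= 1.0 - 1e-9
    assert led2["p4"] >= 1.0 - 1e-9
    # invariant to parameter order
    led3 = predictability_ledger(dep, ["p4", "p2", "p0", "p3", "p1"], covariates=())
    assert led3.set_index("parameter")["sum_r2"]["p0"] == pytest.approx(led2["p0"])


def test_predictability_ledger_monotone_in_effect_size():
    rng = np.random.default_rng(5)
    n = 1500
    sums = []
    for beta in (0.2, 0.6, 1.2):
        a = rng.normal(size=n)
        b = beta * a + rng.normal(size=n)
        c = beta * b + rng.normal(size=n)
        led = predictability_ledger(pd.DataFrame({"a": a, "b": b, "c": c}),
                                    ["a", "b", "c"], covariates=())
        sums.append(led["sum_r2"].sum())
    assert sums[0] < sums[1] < sums[2]


def test_group_compare_detects_planted_shift():
    rng = np.random.default_rng(6)
    rows = []
    for plane in ("dorsal", "ventral"):
        for sub in ("CA1m", "CA3b", "Sub"):
            mu = 25.0 + (8.0 if sub == "CA3b" else 0.0)
            for v in rng.normal(mu, 2.0, 40):
                rows.append({"plane": plane, "subregion": sub, "ais_length": v})
    df = pd.DataFrame(rows)
    out = group_compare(df, "ais_length", factors=("subregion", "plane"))
    aov = out["anova"].set_index("Source")
    assert aov.loc["subregion", "p_unc"] < 0.001
    assert aov.loc["plane", "p_unc"] > 0.05
    tuk = out["tukey_subregion"]
    ca3_rows = tuk[(tuk["A"] == "CA3b") | (tuk["B"] == "CA3b")]
    assert (ca3_rows["p_tukey"] < 0.01).all()


def test_group_compare_no_false_positives_on_flat_data():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "plane": rng.choice(["dorsal", "ventral"], 200),
        "subregion": rng.choice(["CA1m", "CA3b"], 200),
        "ais_length": rng.normal(25, 0.1, 200),
    })
    out = group_compare(df, "ais_length")
    aov = out["anova"].set_index("Source")
    assert aov.loc["subregion", "p_unc"] > 0.01 or np.isnan(aov.loc["subregion", "p_unc"])


def test_acd_fraction_by_region_toy():
    base = dict(plane="dorsal", subregion="CA1m", hippocampus="h0",
                soma_major=15.0, soma_minor=10.0,
                ais_distance=4.0, ais_length=25.0, ais_d_start=1.0,
                ais_d_max=1.2, ais_d_end=0.5, ais_max_pos=2.0)
    for c in range(5):
        base[f"apical_d{(c + 1) * 5:02d}"] = 2.0
    rows = []
    for i in range(10):
        r = dict(base, cell_id=str(i))
        if i < 5:
            r.update(acd_stem_length=4.0, acd_stem_diam=1.0, ais_distance=5.0)
        else:
            r.update(acd_stem_length=0.0, acd_stem_diam=np.nan)
        rows.append(r)
    df = pd.DataFrame(rows)
    out = acd_fraction_by_region(df)
    assert out["fraction"].iloc[0] == pytest.approx(0.5)
    shuffled = acd_fraction_by_region(df.sample(frac=1.0, random_state=0))
    assert shuffled["fraction"].iloc[0] == pytest.approx(0.5)
    df.loc[:, "acd_stem_length"] = 0.0
    df.loc[:, "acd_stem_diam"] = np.nan
    assert (acd_fraction_by_region(df)["fraction"] == 0).all()
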