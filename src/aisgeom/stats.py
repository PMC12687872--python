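"""Morphometric statistics: transforms, variability, partial correlations,
group comparisons, and the predictability ledger.

Conventions follow common practice in neuro-morphometrics: natural-log
transform of log-normally distributed lengths before parametric tests,
global Z-scoring for cross-parameter comparability, Spearman-based partial
correlations with anatomical location indicator-coded as covariates, and
Bonferroni correction over each tested family.  Sample SD (ddof=1) is used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg

from .records import AxonOrigin, annotate_frame

__all__ = [
    "StatsConfig",
    "log_transform",
    "zscore_global",
    "regional_variability",
    "partial_spearman",
    "predictability_ledger",
    "group_compare",
    "acd_fraction_by_region",
]

#: default location covariates used when partialling out anatomy
LOCATION_COVARIATES = ("plane", "subregion")


@dataclass(frozen=True)
class StatsConfig:
    log_params: tuple = ("ais_distance", "acd_stem_length")
    alpha: float = 0.05
    correlation_method: str = "spearman"
    variability_grouping: tuple = ("hippocampus", "region")

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def log_transform(table: pd.DataFrame, config: StatsConfig = StatsConfig()) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Natural-log transform the configured columns.

    Nonpositive entries (eg zero stem length in non-AcD cells) cannot be
    log-transformed; they become NaN so downstream analyses drop them, and
    the per-column count of such exclusions is returned alongside the table.
    """
    out = table.copy()
    excluded: Dict[str, int] = {}
    for col in config.log_params:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(float)
        bad = ~(vals > 0)
        excluded[col] = int(bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            out[col] = np.where(bad, np.nan, np.log(np.where(bad, 1.0, vals)))
    return out, excluded


def zscore_global(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Z-score each column against the global (whole-table) mean and sample SD."""
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])
    ]
    for col in cols:
        vals = out[col].to_numpy(float)
        ok = np.isfinite(vals)
        sd = np.std(vals[ok], ddof=1) if ok.sum() > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot Z-score")
        out[col] = (vals - np.mean(vals[ok])) / sd
    return out


def regional_variability(table: pd.DataFrame, parameters: Sequence[str],
                         config: StatsConfig = StatsConfig(),
                         min_group_size: int = 3) -> pd.DataFrame:
    """Per-(hippocampus, region) SD of globally Z-scored parameters.

    The table must carry ``hippocampus``, ``plane`` and ``subregion`` labels.
    Log-normal parameters are log-transformed first, then every parameter is
    Z-scored across the entire dataset; variability is the sample SD of those
    Z-scores within each hippocampus x region group.  Groups smaller than
    ``min_group_size`` report NaN.
    """
    logged, _ = log_transform(table, config)
    z = zscore_global(logged, parameters)
    z = z.assign(region=z["plane"].astype(str) + "-" + z["subregion"].astype(str))
    rows = []
    for (hc, region), grp in z.groupby(["hippocampus", "region"], sort=True):
        row = {"hippocampus": hc, "region": region, "n": len(grp)}
        for p in parameters:
            vals = grp[p].dropna().to_numpy(float)
            row[p] = float(np.std(vals, ddof=1)) if len(vals) >= min_group_size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _indicator_code(table: pd.DataFrame, covariates: Sequence[str]) -> Tuple[pd.DataFrame, List[str]]:
    """Dummy-code categorical covariates (drop-first contrasts); numeric ones
    pass through unchanged."""
    frames, names = [], []
    for cov in covariates:
        col = table[cov]
        if pd.api.types.is_numeric_dtype(col):
            frames.append(col.astype(float).rename(cov))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True, dtype=float)
            frames.append(dummies)
            names.extend(dummies.columns)
    if not frames:
        return pd.DataFrame(index=table.index), []
    return pd.concat(frames, axis=1), names


def partial_spearman(table: pd.DataFrame, x: str, y: str,
                     covariates: Sequence[str] = ()) -> Tuple[float, float, int]:
    """Spearman partial correlation of ``x`` and ``y`` given covariates.

    All variables are rank-transformed; categorical covariates are
    indicator-coded.  Returns ``(r, p, n)`` with a two-sided p-value.
    Rows with NaN in any involved column are dropped.
    """
    cov_df, cov_names = _indicator_code(table, covariates)
    data = pd.concat([table[[x, y]].astype(float), cov_df], axis=1).dropna()
    n = len(data)
    if n < len(cov_names) + 3:
        raise ValueError(f"need at least {len(cov_names) + 3} complete rows, got {n}")
    if cov_names:
        res = pg.partial_corr(data=data, x=x, y=y, covar=cov_names, method="spearman")
    else:
        res = pg.corr(data[x], data[y], method="spearman")
    r = float(res["r"].iloc[0])
    pcol = "p_val" if "p_val" in res.columns else "p-val"
    p = float(res[pcol].iloc[0])
    return r, p, n


def predictability_ledger(table: pd.DataFrame, parameters: Sequence[str],
                          covariates: Sequence[str] = LOCATION_COVARIATES,
                          alpha: float = 0.05,
                          gate_significance: bool = True) -> pd.DataFrame:
    """Summed pairwise R² per parameter: how well each morphological parameter
    can be predicted from the others.

    For every unordered pair of parameters a Spearman partial correlation
    (location covariates partialled out) is computed; p-values are Bonferroni
    corrected across all tested pairs, and non-significant pairs contribute 0
    (configurable).  Each parameter's ledger entry is the sum of squared
    coefficients over its pairs; invariant to parameter order.
    """
    params = list(parameters)
    n_pairs = len(params) * (len(params) - 1) // 2
    records = []
    for i, a in enumerate(params):
        for b in params[i + 1:]:
            r, p, n = partial_spearman(table, a, b, covariates)
            records.append({"x": a, "y": b, "r": r, "p": p, "n": n,
                            "p_bonf": min(p * n_pairs, 1.0)})
    pairs = pd.DataFrame(records)
    sums = {p: 0.0 for p in params}
    for _, row in pairs.iterrows():
        contrib = row["r"] ** 2
        if gate_significance and row["p_bonf"] >= alpha:
            contrib = 0.0
        sums[row["x"]] += contrib
        sums[row["y"]] += contrib
    ledger = pd.DataFrame({"parameter": params,
                           "sum_r2": [sums[p] for p in params]})
    ledger.attrs["pairs"] = pairs
    return ledger


def group_compare(table: pd.DataFrame, parameter: str,
                  factors: Sequence[str] = ("subregion", "plane"),
                  level: str = "cell",
                  alpha: float = 0.05) -> Dict[str, pd.DataFrame]:
    """Two-way fixed-effects ANOVA over two anatomical factors, followed by
    Tukey HSD on factors significant at ``alpha``.

    ``level='cell'`` analyses cell-level values (default); ``level='median'``
    first collapses to per-hippocampus medians within each factor cell.
    """
    f1, f2 = factors
    data = table[[f1, f2, parameter] + (["hippocampus"] if level == "median" else [])].dropna()
    if level == "median":
        data = (data.groupby([f1, f2, "hippocampus"], observed=True)[parameter]
                .median().reset_index())
    aov = pg.anova(data=data, dv=parameter, between=[f1, f2], detailed=True)
    aov = aov.rename(columns={"p-unc": "p_unc"})
    out: Dict[str, pd.DataFrame] = {"anova": aov}
    sig = aov.set_index("Source")["p_unc"]
    for f in (f1, f2):
        if f in sig.index and np.isfinite(sig[f]) and sig[f] < alpha:
            tuk = pg.pairwise_tukey(data=data, dv=parameter, between=f)
            out[f"tukey_{f}"] = tuk.rename(columns={"p-tukey": "p_tukey"})
    return out


def acd_fraction_by_region(table: pd.DataFrame) -> pd.DataFrame:
    """AcD share per (plane, subregion): pooled fraction plus the mean over
    per-hippocampus fractions with a normal-approximation 95% CI."""
    df = annotate_frame(table)
    df["is_acd"] = df["axon_origin"] == AxonOrigin.acd.value
    rows = []
    for (plane, sub), grp in df.groupby(["plane", "subregion"], sort=True, observed=True):
        per_hc = grp.groupby("hippocampus", observed=True)["is_acd"].mean()
        m = float(per_hc.mean())
        sd = float(per_hc.std(ddof=1)) if len(per_hc) > 1 else np.nan
        half = 1.96 * sd / np.sqrt(len(per_hc)) if len(per_hc) > 1 else np.nan
        rows.append({
            "plane": plane, "subregion": sub, "n": len(grp),
            "fraction": float(grp["is_acd"].mean()),
            "hc_mean": m, "hc_ci_lo": m - half, "hc_ci_hi": m + half,
            "n_hippocampi": int(per_hc.shape[0]),
        })
    return pd.DataFrame(rows)
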