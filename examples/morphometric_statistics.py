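"""Interdependencies of proximal cell geometry.

Runs the morphometric statistics pipeline on the packaged cohort: the
log-transform of skewed lengths, the partial Spearman correlation of AcD
stem length with AIS distance (controlling for anatomical location), and
the predictability ledger (summed pairwise R² per parameter).
"""

from aisgeom import default_cohort, annotate_frame
from aisgeom.stats import (StatsConfig, log_transform, partial_spearman,
                           predictability_ledger)

ann = annotate_frame(default_cohort(seed=0))
acd = ann[(ann.axon_origin == "acd")
          & ~ann.subregion.isin(["hilus", "CA2"])].copy()
print(f"AcD cells entering the correlation analysis: {len(acd)}")

logged, excluded = log_transform(acd, StatsConfig())
r, p, n = partial_spearman(logged, "acd_stem_length", "ais_distance",
                           ["plane", "subregion"])
print(f"\npartial Spearman(log stem length, log AIS distance | location): "
      f"r = {r:.2f}, p = {p:.2e}, n = {n}")
print(f"  -> r² = {100 * r * r:.0f}% of the stem-length variation is shared "
      "with AIS distance, the two being geometrically linked.")

params = ["soma_area", "apical_diam_mean", "ais_length", "ais_d_max",
          "ais_distance_2", "acd_stem_length", "acd_stem_diam"]
logged2, _ = log_transform(acd, StatsConfig(log_params=("ais_distance_2",
                                                        "acd_stem_length")))
ledger = predictability_ledger(logged2, params)
print("\npredictability ledger (sum of significant pairwise R² per parameter):")
for _, row in ledger.sort_values("sum_r2", ascending=False).iterrows():
    print(f"  {row.parameter:>18s}: {100 * row.sum_r2:5.1f}%")
print("\nCell size is the most predictable parameter; the AcD stem length the "
      "most independent one — its variability is barely echoed by the rest of "
      "the proximal morphology.")
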