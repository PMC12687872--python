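"""Synaptic input thresholds on the AcD vs the canonical basal branch.

Distributes 1000 double-exponential synapses 75-100 µm from the soma on
either basal branch and searches for the minimal total conductance that
triggers an AP.  For an AcD cell, input on the axon-carrying branch has
privileged access to the AIS; the balanced non-AcD branch must drive the
same AIS through the soma.
"""

from aisgeom import CellRecord
from aisgeom.excitability import ExcitabilityConfig, branch_comparison

common = dict(plane="ventral", subregion="CA1m",
              soma_major=17.0, soma_minor=11.0,
              apical_diams=(2.6, 2.4, 2.2, 2.0, 1.8),
              ais_length=25.0, ais_d_start=1.15, ais_d_max=1.25,
              ais_d_end=0.55, ais_max_pos=2.5)
non_acd = CellRecord(cell_id="somatic-origin", ais_distance=5.5,
                     acd_stem_length=0.0, **common)
acd = CellRecord(cell_id="acd-6um-stem", ais_distance=8.0,
                 acd_stem_length=6.0, acd_stem_diam=1.3, **common)

cfg = ExcitabilityConfig()
for rec in (non_acd, acd):
    res = branch_comparison(rec, cfg)
    a = res["synaptic_acd_branch"].threshold
    b = res["synaptic_nonacd_branch"].threshold
    print(f"{rec.cell_id:>15s}: AcD branch {a:6.2f} nS, "
          f"non-AcD branch {b:6.2f} nS  (ratio {a / b:.3f})")

print("\nWith a somatic axon origin both branches are equivalent and fire at "
      "identical thresholds; the 6 µm stem gives the axon-carrying branch a "
      "clearly lower threshold, widening the cell's range of input "
      "efficiencies without changing any channel density.")
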