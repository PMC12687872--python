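# aisgeom

Morphometrics of axon-initial-segment (AIS) geometry in hippocampal
pyramidal neurons, and a reduced conductance-based CA1 model that predicts
what that geometry does to excitability.

Most action potentials start at the AIS, a short Na-channel-rich stretch of
proximal axon whose length and distance from the soma vary widely between
neurons — and in many hippocampal cells the axon does not leave the soma at
all but branches off a basal dendrite (an *axon-carrying dendrite*, AcD).
`aisgeom` is written for computational and cellular neuroscientists who
want to (i) analyse tables of measured proximal geometries — soma ellipse,
proximal apical diameters, AIS position/length/taper, AcD stem — across
anatomical regions, and (ii) ask, cell by cell, what those geometries imply
for input thresholds, voltage thresholds and spike timing.

## What is inside

* **`aisgeom.records`** — validated cell records and the classification
  rule: a cell is an AcD cell iff its stem is ≥ 2 µm long and longer than
  its mean diameter; otherwise *distal* (AIS onset > 5 µm) or *somatic*.
* **`aisgeom.cohort`** — a Gaussian-copula synthetic-cohort generator:
  per-region medians, log-normal marginals for skewed lengths, AcD
  fractions, and planted Spearman rank correlations
  (ρ(log stem, log AIS distance) = 0.80).  The packaged profiles produce a
  3,681-cell cohort over 27 hippocampal regions.
* **`aisgeom.stats`** — log transforms, global Z-scores, per-hippocampus
  variability, partial Spearman correlations with location covariates
  (r, p, n), a predictability ledger (per-parameter Σr² over significant
  pairs), two-way ANOVA + Tukey, AcD fractions per region.
* **`aisgeom.builder`** — maps a record to a reduced compartmental CA1
  model: soma cylinder matched to the spheroid surface, measured apical
  taper, two-part AIS with a −5 mV distal Na activation shift, AcD stem
  and an electrotonic balance stub on the canonical basal branch.
* **`aisgeom.engine`** — branched cable equation with Hodgkin–Huxley-type
  Na/K conductances, backward Euler at 25 µs, Hines linear-time tree
  solve (numba), double-exponential synapse populations, plus a
  dense-matrix reference solver and analytic-cable oracles in the tests.
* **`aisgeom.excitability`** — rheobase-style threshold searches
  (bracket + bisection, equal to a linear scan at the same resolution),
  AP detection (AIS > 0 mV), voltage threshold (somatic dV/dt > 25 mV/ms),
  AP delay, AcD vs non-AcD branch comparisons, soma/AIS injection-site
  comparisons, cohort maps and median-reference single-parameter sweeps.
* **`aisgeom.io`** — morphology CSV with row-addressed validation and
  column-mapping configs, YAML biophysics/template/profiles, run manifests.

The importable API plus the scripts in `examples/` are the interface;
each example builds a small input, runs one capability and prints what the
numbers mean.

## Worked example

```bash
python examples/single_cell_threshold.py
```

```
median-reference CA1 cell: soma 16.8 x 10.5 µm, AIS 23.2 µm starting 4.7 µm from the soma

5-ms current-step thresholds (bracket + bisection to 0.5 pA):
       current_soma:  259.0 pA, voltage threshold -53.76 mV, AP delay 6.82 ms
   current_ais_prox:  197.5 pA, voltage threshold -53.96 mV, AP delay 6.28 ms
   current_ais_dist:  146.5 pA, voltage threshold -54.62 mV, AP delay 5.81 ms
```

The median synthetic CA1 cell needs 259 pA for 5 ms at the soma to fire —
inside the 200–300 pA range expected for these cells — and its somatic
voltage threshold (−53.8 mV) sits in the physiological −58…−50 mV band.
The same current injected at the distal AIS triggers the AP at roughly half
the somatic rheobase: the distal AIS is the most excitable site.

`examples/branch_comparison.py` shows the AcD effect directly:

```
 somatic-origin: AcD branch  53.05 nS, non-AcD branch  53.05 nS  (ratio 1.000)
   acd-6um-stem: AcD branch  40.40 nS, non-AcD branch  52.60 nS  (ratio 0.768)
```

With a somatic axon origin the two balanced basal branches fire at
identical synaptic thresholds; a 6 µm AcD stem gives the axon-carrying
branch privileged access to the AIS and a ~23% lower threshold.

Other examples: `classify_and_map.py` (AcD shares per region — ~50% in
ventral CA1, lowest dorsally), `morphometric_statistics.py` (partial
r = 0.80 between stem length and AIS distance; cell size ~45% predictable
from the rest of the morphology, stem length only ~7%), and
`ais_length_sweep.py` (voltage threshold falls monotonically, ~0.55 mV/µm,
with AIS length).

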