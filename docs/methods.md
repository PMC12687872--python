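# Methods

`aisgeom` analyses the proximal geometry of hippocampal pyramidal neurons —
soma, proximal apical dendrite, axon-carrying-dendrite (AcD) stem, and the
axon initial segment (AIS) — and predicts, with a reduced conductance-based
compartment model, how that geometry shapes input thresholds, somatic
voltage thresholds and spike delay.  This note documents the models, the
conventions, the numerical choices, and what the synthetic data do and do
not establish.

## Morphology model and classification

A `CellRecord` holds one neuron's measured geometry in micrometres: the two
longest orthogonal soma diameters; five apical-trunk diameters at 5, 10,
15, 20 and 25 µm from the soma base; AIS distance (path length from the
somatodendritic origin to the first AIS point), AIS length, diameters at
the AIS start, maximum and end plus the position of the maximum; and, for
cells whose axon leaves via a basal dendrite, the AcD stem length and mean
diameter.  Invariants enforced at construction: nonnegativity,
`soma_major ≥ soma_minor`, `ais_max_pos ≤ ais_length`, and
`acd_stem_length ≤ ais_distance` (the stem is part of the soma-to-AIS
path).

Axon-origin classification is total and deterministic:

* **AcD** — stem at least 2 µm long *and strictly* longer than its mean
  diameter (ties resolve as not-AcD, a conservative reading of
  "longer than");
* otherwise **distal** — AIS starting strictly more than 5 µm from the
  soma (the cut applies to `ais_distance`, not to the stem-subtracted
  variant, so the class definition is uniform across AcD and non-AcD
  cells);
* otherwise **somatic**.

`ais_distance_2 = max(ais_distance − acd_stem_length, 0)` measures the
distance from the somatodendritic compartment *including* the stem; it is
the variant used in the predictability analysis to break the intrinsic
stem/distance link.

Soma size is reported two ways: the ellipse area π·(a/2)(b/2) for
morphometrics, and the exact prolate-spheroid surface (polar diameter =
major axis) for the compartment model.

## Synthetic cohorts (what the generator emulates)

Real measurements are not bundled; the generator produces cohorts with the
statistical structure the analyses assume, so every downstream stage is
testable end to end.  Per region (3 longitudinal planes × 9 subregions) a
`RegionProfile` holds marginal distributions (normal, truncated at a
physical floor, or log-normal parameterized by median and log-SD), an AcD
fraction, and a Spearman rank-correlation target matrix imposed through a
Gaussian copula.  Spearman targets are converted to the copula's Pearson
scale via `2·sin(πρ/6)` before sampling, so planted rank correlations are
recovered directly; the matrix is projected to the nearest PSD correlation
matrix when needed.

Structure the packaged profiles encode (medians anchored to the reported
regional pattern, dispersions the package's own realistic choices):

* AIS length peaks in intermediate CA3 (~35 µm median) and is ~10 µm
  shorter in CA1; the dorsal plane runs ~4 µm shorter throughout; SD 3.2 µm.
* AIS distance is log-normal; the medial CA3 median is set so >80% of AIS
  start more than 5 µm from the soma; dorsal onsets are more proximal.
* AcD fractions: ~0.5 in ventral and medial CA1, lowest in the dorsal
  plane and in the subiculum.
* AcD stems are log-normal and left-truncated at the 2 µm classification
  floor via a median-preserving monotone map (rank structure intact); for
  AcD rows the stem diameter is capped just below the stem length so a
  drawn AcD cell classifies as one.
* For AcD rows the AIS distance is built as `stem + offset`, the hillock
  offset drawn log-normally from the copula's distance axis with a 0.22
  stem–offset rank correlation; the *composite* then reproduces the
  headline Spearman(log stem, log distance) ≈ 0.80 while keeping the
  offset (= `ais_distance_2`) nearly independent of the stem — which is
  what makes stem length the least predictable parameter (~7%) while cell
  size remains the most predictable (~45%).  Inter-parameter targets were
  calibrated once against these dataset-level statistics and then frozen.
* The default cohort is 3,681 cells: 160 per pyramidal region, with
  reduced counts in hilus and CA2, split into per-hippocampus replicates of
  ≤20 cells whose medians carry an independent 5% log-normal jitter (a free
  knob; no reported value constrains it) so replicate-level variability
  statistics are exercised.

What the generator does **not** emulate: measurement error, left-censoring
of thin diameters near the confocal resolution limit, animal/hemisphere
effects (labels are carried but carry no signal), within-region spatial
gradients, and any dependence beyond pairwise rank correlations.  Passing
tests therefore demonstrate that the pipeline recovers the structure it is
pointed at, not that real tissue has that structure.

## Morphometric statistics

Skewed lengths (AIS distance, AcD stem length) are natural-log transformed;
nonpositive entries become missing and are counted.  Z-scores are global
(whole-dataset mean and sample SD, ddof = 1 throughout).  Regional
variability is the within-(hippocampus × region) SD of those global
Z-scores; groups of fewer than 3 cells report missing.

Partial correlations are Spearman: all variables rank-transformed,
categorical location covariates indicator-coded (drop-first), computed with
pingouin and verified in the tests against an independent
rank-residualization oracle.  The predictability ledger computes, for every
unordered parameter pair, the partial Spearman coefficient given location,
Bonferroni-corrects p-values across the tested family, and sums squared
coefficients per parameter (non-significant pairs contribute zero;
configurable).  Because the headline correlation squares to 0.64 while a
regression on other transforms could report differently, the acceptance
output reports both r and 100·r².

Group comparisons are two-way fixed-effects ANOVA over (subregion, plane)
at cell level by default (a per-hippocampus-median switch exists), with
Tukey HSD on factors significant at α = 0.05.

## The reduced compartment model

Topology: cylindrical soma whose lateral surface equals the measured
prolate-spheroid surface (length = soma major axis, diameter solved from
the surface); one apical trunk in three parts (the first 100 µm carries the
five measured diameters as a piecewise profile, tapering to template
values) ending in two tuft branches; two basal dendrites.  The axon leaves
the soma (non-AcD) or the tip of the AcD stem (AcD cells), runs through a
hillock segment covering the remaining AIS distance, then the AIS — built
in two parts with a piecewise-linear taper start → maximum → end and a
default 1:1 proximal/distal split — and a 200 µm distal axon.  For AcD
cells a balance stub with the stem's exact geometry is inserted between
soma and the canonical basal dendrite, making the two synaptic zones'
passive paths to the soma electrotonically equivalent (verified: passive
input resistances at the 87.5 µm synaptic zones agree within 1%).

Biophysics: leak plus transient Na (m³h) and delayed-rectifier K (n), with
Mainen/Hamill-style rate functions; the distal AIS Na activation is shifted
by −5 mV (activation-only by default; a full-kinetics mode exists).  The
original study's channel tables and companion model are not redistributable
here, so the packaged `data/biophys.yaml` is this package's own
parameterization, calibrated once so the median synthetic CA1 cell operates
in the reported physiological range — somatic 5-ms rheobase 200–300 pA and
voltage thresholds −58 to −50 mV — and then frozen.  Two deliberate
effective-parameter choices stand in for membrane area the reduced
morphology omits (spines, full arbor): cm = 2 µF/cm² and a leak of
1.25 mS/cm².  The AIS is the Na hot zone (0.55/0.65 S/cm² proximal/distal)
with an elevated hillock density; dendrites carry a weak background.
With these conditions, ~90% of synthetic CA1 cells fall inside both printed
bands; the residual tails are cells at the extremes of the generator's
dispersion choices.

## Numerics

The cable equation on the section tree is discretized per segment
(odd counts; 0.5 µm resolution on sections carrying stimuli and on the
hillock/AIS initiation zone, a d_lambda = 0.1 rule at 100 Hz elsewhere) and
advanced by backward Euler at dt = 25 µs (40 kHz).  Gating variables use
the exponential-integrator update with rates at the current voltage; the
voltage system — symmetric, tree-structured — is solved exactly each step
by Hines elimination in linear time (numba-compiled).  Verification: the
analytic sealed-cable input resistance is matched within 0.5%; a
dense-matrix reference solver with identical physics agrees to 1e-9 mV on
random ≤20-compartment trees; passive charge is conserved to the implicit
scheme's identity; halving dt moves spike times by <0.1 ms, and the
first-order error ratio is observed under dt refinement.

Synapses are double-exponential conductances (τ_on 0.175 ms, τ_off 5 ms,
reversal 0 mV), kernels normalized to unit peak so "total conductance"
means summed per-synapse peak conductance; 1000 synapses are evenly spaced
over the 75–100 µm path window (stem/stub included in the distance) with
activation times drawn once per (cell, seed) from a Gaussian (mean = onset
20 ms, σ = 4 ms) and reused across a threshold search, so the search varies
only stimulus strength.  Event times are binned to the simulation step and
propagated by the exact two-state recursion.

## Threshold experiments

An AP is a strict 0 mV crossing at the distal-AIS midpoint (the initiation
site).  The somatic voltage threshold is the voltage where dV/dt first
exceeds 25 mV/ms after onset, computed with centered differences and
sub-sample linear interpolation of the criterion crossing (one-sided at
boundaries); AP delay is that crossing time minus the 20 ms onset.
"Incrementally increasing" the stimulus is implemented as geometric
bracketing plus bisection **on the resolution grid** (0.5 pA / 0.05 nS by
default), which provably returns the same grid point as a linear scan at
equal resolution (tested) at a fraction of the cost — about 12 simulations
per threshold.  Current steps (10–1000 pA, 5 ms) are applied at the soma or
the proximal/distal AIS centers; synaptic totals span 1–100 nS.  An AP at
the range minimum flags `below_range`; silence at the maximum flags
non-convergence (a few % of synthetic cells exceed 100 nS on dendritic
drive; they are reported flagged, not clamped).

The median-reference cell fixes every parameter at the cohort median
(stem parameters at AcD-cell medians when a stem sweep requires one) and
sweeps one parameter over the cohort's 1st–99th percentile range
(25 points by default; 9 in the time-boxed tests and examples).

## Problem sizes and determinism

The packaged analyses use the 3,681-cell cohort for statistics and
100-cell CA1 samples for the simulation experiments — the sizes the
packaged conditions define.  Everything is deterministic given the seeds:
cohort generation, synapse placement and times, and the solver itself
(fixed-step implicit integration, no hidden RNG).  All statistics are
deterministic functions of their input table.

## Known limitations

* The biophysics is a two-channel effective model; no HCN, Ca or slow K
  currents, no temperature protocol beyond the rates' built-in scale.
* The branch-connection resistance uses the parent-segment-centre
  convention; section interiors converge with refinement but junction
  voltages are first-order in segment size.
* Voltage thresholds at near-rheobase stimuli retain ~0.3 mV of
  protocol-induced variation (threshold-grid and sampling effects).
* The generator's tails are log-normal by construction; extreme synthetic
  cells (large soma, very short AIS) can leave the reported physiological
  bands — reported as in-band fractions rather than hidden.
* Statistics treat cells as independent replicates within hippocampus ×
  region groups; no mixed-effects model is fitted.
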