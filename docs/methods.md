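# Methods

`vpglu` implements a population-of-models analysis of glutamatergic ventral
pallidum (VP_Glu) neurons: a multicompartment conductance-based cell model,
an affine-invariant ensemble MCMC that assembles populations of parameter
sets reproducing either of two experimentally observed firing phenotypes —
cells that enter depolarization block (DB) under strong current injection
and cells that do not (NDB) — and an in-silico parvalbumin (PV) titration
that asks whether calcium buffering converts one phenotype into the other.

## Cell model

The morphology is a ball-and-stick cell with a myelinated axon: a 10 × 10 µm
soma, a 30 µm × 1 µm axon hillock, a single 1371 µm × 0.3 µm dendrite, and
an axon of 100 nodes of Ranvier alternating with 99 internodes (node first
and node last). Only the hillock is active; it carries eight voltage- and
calcium-gated channels (Nav1.6, delayed-rectifier K, A-type K, SK, BK,
M-type K, L-type Ca, T-type Ca) whose maximal conductances, together with a
common passive leak density for soma/dendrite/hillock, form the
9-dimensional free parameter vector θ. Nodes carry squid-type
Hodgkin–Huxley kinetics to support propagation; soma, dendrite, and
internodes are passive.

Passive constants (not constrained by the calibration targets) default to:
membrane capacitance 1 µF/cm² (0.04 µF/cm² in internodes, representing
myelin), axial resistivity 150 Ω·cm, leak reversal −60 mV, internode leak
10⁻⁵ S/cm². Internodes default to 100 µm × 1 µm. All passive values are
configurable; the leak reversal matches the −60 mV initialization so an
all-passive cell rests at its initial potential.

Integration is backward Euler at dt = 25 µs (12.5 µs available for
convergence checks) at a nominal 23 °C. Gates advance by an exact
exponential update at frozen voltage within each implicit voltage step
(operator splitting); voltage-dependent steady states and `1−exp(−dt/τ)`
factors are tabulated on a 0.05 mV grid and linearly interpolated. Channel
kinetics are taken as defined at the nominal temperature; a Q10 hook exists
and defaults to 1. Every protocol is preceded by 500 ms of unstimulated
equilibration. A membrane potential beyond ±200 mV (or non-finite) is
reported as a simulation failure and scored as infeasible.

Spatial resolution defaults: soma 1 segment, hillock 3, dendrite 41, node
and internode 1 each. A mesh-refinement property test guards this choice
(doubling the resolution moves the passive input resistance by < 0.5%), and
the all-passive cell reproduces the closed-form cascaded-cable input
resistance to better than 1%.

## Channel kinetics

The cited kinetic formulations for the eight hillock channels are not
reproduced in the source material, so each channel ships as an explicit,
overridable parameter table (YAML under `vpglu/data/channels/`):
Boltzmann steady states, bell-shaped voltage-dependent time constants, a
Hill calcium activation for SK (Kd 0.4 µM, n = 4), and a calcium-shifted
Boltzmann for BK whose midpoint sits at +30 mV at 1 µM calcium and moves
−60 mV per decade, so BK opens essentially only on spike-evoked calcium
transients (a calcium-triggered repolarization reserve). The defaults were
designed to satisfy the qualitative structure of the experimental data:

- a fast Nav/Kdr spike generator able to fire repetitively from ~10–30 pA
  with the high somatic input resistances (0.5–1.5 GΩ) of these cells;
- a slow Nav inactivation gate (hundreds of ms, eroding mainly at spike
  voltages) so that sustained high-rate firing collapses into
  depolarization block — the DB mechanism;
- subthreshold SK activation from window-current calcium, so that buffering
  calcium lowers the ramp threshold and removing the SK afterhyperpolarization
  promotes block, which is the mechanistic claim the PV experiment probes.

Calcium enters a 0.1 µm submembrane shell in each hillock compartment
(baseline 50 nM, extrusion time constant 20 ms). Parvalbumin binds free
shell calcium by mass action (k_on = 40 mM⁻¹ms⁻¹, k_off = 2×10⁻⁴ ms⁻¹,
i.e. Kd = 5 nM); at stimulus onset the buffer is equilibrated to baseline
calcium. Magnesium competition for PV sites is not modeled. The coupled
shell/buffer update is backward Euler with an exact solution of the
resulting quadratic, so one step conserves free + bound calcium to
round-off.

## Protocols and metrics

Mirroring the slice-physiology battery: input resistance from a −5 pA,
500 ms step (mean of the final 50 ms against the pre-step baseline); an F-I
curve from 500 ms square pulses at 0–130 pA in 10 pA increments (each sweep
starting from the same equilibrated state); a ramp threshold from a 1 s,
0→150 pA ramp (injected current at the first spike; a no-spike sentinel
otherwise). A spike is a local maximum strictly above 0 mV, debounced by an
upward re-crossing of −20 mV so plateau oscillations during block are not
counted. Peak firing current is the grid argmax (ties to the lowest
amplitude), rheobase the lowest spiking amplitude, and the AHP is measured
on the rheobase sweep as the voltage where dV/dt first exceeds 10 mV/ms
minus the post-spike trough.

Phenotype classification is shape-based on the full-grid F-I curve: NDB if
the rate at the final amplitude stays at ≥ 80% of the peak rate; DB if it
falls below 50% with the peak before the final amplitude; the indeterminate
band in between leans DB. Both thresholds are package constants exposed for
sensitivity analysis; the acceptance checks assert classification
stability, not the threshold values.

## Calibration

Each candidate θ is scored as the mean of four equally weighted normalized
errors against a target bundle: input resistance, ramp threshold (whose
target is the printed rheobase mean), peak firing current, and the summed
absolute F-I error. Scalar terms are normalized by the absolute target
mean (fractional error); the F-I term by the summed target curve (relative
L1 error). Both normalizers are per-target configuration. Normalizing the
scalar terms by the printed dispersions instead is possible, but those
dispersions are standard errors in all likelihood and would make the
published population characteristics unreachable by orders of magnitude;
and a tight fixed per-point F-I normalizer forces fits that reach the steep
experimental peak rates only by decoupling the calcium pathway, which
destroys the parvalbumin sensitivity the experiment probes. Under the
relative normalization the calibrated populations land at SK-engaged peak
rates of roughly 20–30 Hz, which is where the published model populations
sat. Incomplete metrics — a nonspiking cell, a silent ramp, a diverged
simulation — score +∞.

The sampler is an in-package implementation of the Goodman–Weare stretch
move (a = 2), validated against closed-form z-draw moments, analytic
Gaussian targets, a two-point occupancy balance check, and the independent
`emcee` implementation. The log-probability is Boltzmann, −score/T with
T = 0.05 inside the uniform prior box (active conductances 0–1 S/cm², leak
0–10⁻³ S/cm²) and −∞ outside; inside the box an infeasible θ is assigned a
large finite penalty rather than −∞ so that ensembles seeded in dead
regions of parameter space can still diffuse.

A calibration is a schedule of independent restarts (full scale: 10
restarts × 400 walkers × 25 iterations). Restart r initializes walkers at
a per-phenotype base guess plus Gaussian noise growing linearly with r.
Two initialization choices are deliberate deviations from the obvious
defaults, both forced by measurement: the prior-box center (0.5 S/cm² on
every channel) is electrically dead, so the base guess is a modest spiking
regime per phenotype; and the noise is scaled per dimension to the base
guess (floor: 1% of box width) because box-width-scaled noise puts
millisiemens-scale perturbations on channels whose viable densities are a
thousandfold smaller, killing essentially every walker.

Population assembly takes every recorded walker position with score ≤ 0.5,
deduplicates to relative tolerance 10⁻⁹, re-simulates each survivor from
scratch (no caching from proposals), and keeps those whose recomputed score
stays within threshold and whose re-simulated F-I curve classifies to the
target phenotype. An empty population is a warning, not an error.

## Parvalbumin titration

Every population member is re-simulated through the full battery at total
PV concentrations of 1, 2, 5, and 10 mM (0 mM is the stored baseline,
which deterministic re-simulation reproduces bit-identically). Summaries
are arithmetic means and sample SDs per metric plus the pointwise mean F-I
curve; members whose ramp shows no spike at some concentration are excluded
from that concentration's ramp-threshold mean. Populations are compared
with an unpaired two-sided Mann–Whitney U test implemented in-package:
midrank ties, an exact permutation null (dynamic program over doubled
midranks) for combined samples of ≤ 20, and a tie- and continuity-corrected
normal approximation otherwise; both one-sided statistics are reported and
the conventional min(U₁, U₂) is the headline value. Comparisons are
baseline vs each concentration, uncorrected for multiplicity (a correction
flag exists and defaults off, matching the figure-style presentation).

## Target bundles

Printed experimental summary statistics per phenotype (means ± dispersions
of peak firing current, maximum rate, rheobase, input resistance, AHP, and
resting potential) ship as built-in targets. The experimental mean F-I
curves exist only as figures, so the bundled curve is a parametric
surrogate constrained to the printed statistics — zero below rheobase, a
square-root rise to the maximum rate at the peak firing current, and for DB
a linear decay to 20% of peak at 130 pA — and is provenance-tagged
`paper-constrained surrogate` so it cannot be mistaken for printed data.
Fully synthetic surrogate bundles (seeded, reproducible) and ground-truth
fixtures (means = exact simulated metrics of a known θ, SDs = 10% of the
mean with a 1-unit floor) support pipeline testing without external data.

## Problem sizes

The default test and acceptance runs use a reduced configuration chosen as
a deliberate study-size decision: a 10-node axon with a 21-segment dendrite
(somatic metrics are nearly independent of axon length; the full 100-node
axon remains the package default morphology), and calibrations of one
restart × 24 walkers × 25 iterations (~600 model evaluations per target)
against the built-in targets. At this scale populations number in the
tens of members rather than the hundreds produced by the full schedule;
the acceptance outputs report the sizes achieved. The parameter-recovery
harness uses a hidden parameter vector displaced 20–30% per dimension from
the standard starting regime, an SD-normalized fixture score, and three
restarts of 24 walkers × 15 iterations with 15% relative initialization
noise; titrations cap populations at 20–25 members per concentration. The
full-scale presets remain available (`SCALE_PRESETS["full"]`).

## What the synthetic data do and do not show

The surrogate targets and ground-truth fixtures emulate the *structure* of
the experimental constraints (monotone-saturating vs rise-then-fall F-I
curves with realistic means), not the cell-to-cell covariance of real
recordings; passing the recovery tests shows the pipeline can find
parameter sets reproducing a known behavior, not that the recovered
conductances are biologically identified (behavior recovery is asserted at
the metric level only — θ itself is non-identifiable). Likewise the
channel kinetics are explicit, auditable defaults patterned on standard
formulations, not fits to voltage-clamp data from these neurons; the
package's claims about PV are claims about this model family.

## Known limitations

- DB populations under parvalbumin lose their near-rheobase firing: the
  calibrated depolarization-block models pace low-amplitude spiking through
  SK-afterhyperpolarization-dependent recovery of sodium-channel
  inactivation, so buffering the calcium transient leaves them with a
  single onset spike at sub-peak amplitudes and no ramp spike. The
  experimentally reported leftward F-I shift and ramp-threshold drop of the
  DB population under buffering are therefore not reproduced by this model
  family (the corresponding acceptance tests are left failing by design);
  the NDB-population effects — leftward shift, falling ramp threshold, and
  conversion toward block at millimolar PV — are reproduced.
- Single-cylinder dendrite: real VP_Glu arbors would raise input resistance
  and low-amplitude excitability.
- Active conductances confined to the hillock; no synaptic input.
- Ohmic calcium currents with a fixed +120 mV reversal (no GHK flux).
- No magnesium competition for parvalbumin; the effective buffer capacity
  at a given total PV is therefore an upper bound.
- The DB/NDB classification thresholds (80%/50%) are operational choices;
  the acceptance suite tests their stability under re-simulation, not their
  uniqueness.
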