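# Methods

`swrnet` couples three conductance-based spiking networks — a neocortical
network generating the slow oscillation (SO), a CA3 network generating
population bursts, and a CA1 network generating sharp wave-ripples (SWRs) —
and ships the detection and statistical machinery to quantify how the SO
entrains hippocampal events, plus a classification pipeline for sleep
spike-train recordings.

## Cell models

Four cell classes, integrated with fixed-step RK2 (midpoint) at dt = 0.05 ms
(finer steps available for convergence tests):

* **Cortical pyramidal cell** — two compartments (axo-somatic: fast Na,
  delayed-rectifier K, A-type K, non-inactivating slow K; dendritic:
  high-threshold Ca, Ca-dependent K, persistent Na, inward rectifier,
  Na-dependent K), with a dendritic Na pool fed by the persistent and (area
  scaled) transient Na currents and cleared by a pump.  The Na-dependent K
  conductance is 0.5 mS/cm² (reduced from the classic 1.33) which lengthens
  depolarized plateaus.  Leak conductance/reversal and the somato-dendritic
  coupling are heterogeneous across the population (Gaussian, per-cell).
* **Cortical and CA interneurons** — single-compartment Wang–Buzsáki
  fast-spiking cells (the cortical variant carries the heterogeneous leak of
  the cortical network).
* **CA pyramidal cell** — two-compartment Pinsky–Rinzel cell expressed on
  the physiological voltage scale (the original model's scale shifted by
  −60 mV so the +10 mV spike-detection threshold applies uniformly).  The
  faithful parameter set rests marginally close to threshold: at zero input
  the cell is a slow (~0.8 Hz) spontaneous burster.  Default initial
  conditions therefore start cells in the post-burst adapted state (elevated
  AHP gate q = 0.15; cortical cells: elevated Na pool = 12.5 mM), which is a
  stable rest for at least several hundred ms and corresponds to a DOWN-like
  network start.

Spike detection is the upward crossing of +10 mV of the (axo-)somatic
potential, one count per crossing.  All parameter tables are vendored as TSV
files with per-value provenance; any value can be overridden per cell spec.

## Synapses

Every synapse kind uses one aggregate gating variable per (cell, kind):
a presynaptic spike increments s by `multiplicity × α × scaling` (scaling 1/3
for cortical excitatory kinds, 1/2 for cortical inhibitory, 1 elsewhere) and
s decays exponentially with τ.  The cortical NMDA kind uses the same
increment–decay kinetics with τ = 100 ms plus the Jahr–Stevens magnesium
block on the current; this linear-decay reading is the only one consistent
with the aggregate conductance values (an NMDA gate saturating at 1 with
0.225 nS could not sustain UP states).  Currents are
`I = g · s · (V − E)`, excitatory kinds onto the dendritic compartment,
inhibitory onto the (axo-)somatic one.  Cortical GABA reverses at −75 mV.

The cortical per-spike increments α are not published for this scheme; they
are the model's calibration parameters, fixed once so that the isolated
cortex reproduces the SO regime (see "Calibration").  The four
cortico-hippocampal kinds (mossy fiber → CA3 pyramidal cell / interneuron,
temporoammonic → CA1 pyramidal cell / interneuron) have table-specified α
(70, 0.5, 2, 2) and conductances calibrated so one unitary event on the
resting target cell produces the target somatic EPSP (5, 0.25, 0.16, 1 mV);
the calibrated g values are recorded in the synapse registry.

## Wiring

Populations are 1-D equidistant arrays: cortex 1000 PY + 250 IN, CA3 and CA1
1000 PY + 100 IN each.  The CA1 "recording site" is the central 560 µm
(50 PY, 6 IN; pyramidal spacing 11.2 µm).  Within-network wiring uses
Gaussian footprints centred on the homotopic position; the cortical network
fixes the **in-degree** (every cell receives exactly 20 connections of each
type — the convention of the source cortical model), hippocampal wiring
fixes the **out-degree** (CA3 PY: 55 recurrent, 5 onto interneurons, 130
Schaffer; CA3 IN: 68; CA1 PY: 20 onto interneurons; CA1 IN: 400 onto PY,
100 onto IN).  Inhibitory footprints sample targets with replacement; the
repeats become edge multiplicities.  Truncated footprints at array edges are
renormalized (no wrap-around).  Mossy-fiber and temporoammonic projections
sample targets uniformly over the whole array so cortical UP-state wave
propagation is not imprinted on the hippocampus.

Footprint SDs are not published for most projections; they are configuration
defaults calibrated once against the stated connectivity statistics:
CA3 PY→PY σ = 8 mm reproduces the 10.62% unordered-pair connectivity;
CA1 PY→IN σ = 2.4 mm reproduces ~30% connectivity inside the ±2σ cluster;
the Schaffer footprint σ = 1.9 mm covers roughly two thirds of the CA1
array.  Cortical footprints are 250 µm (excitatory) / 125 µm (inhibitory).

Schaffer synapses-per-connection are drawn once per CA1 pyramidal target
from |N(13, 13)| (baseline) or |N(20, 20)| (increased drive), rounded half
away from zero with a floor of 1; interneuron targets get the fixed value
(13 or 20).  Cells above 1.5 × mean (19.5 baseline) form the
"strongly-driven subset".  The strongly-driven flag uses the continuous
sampled value; the integer multiplicity scales the per-spike increment of
every incoming Schaffer edge.

## Scenarios and integration

The projections between networks are strictly feedforward
(cortex → CA3 → CA1 and cortex → CA1), so a scenario is integrated
stage-wise: the cortex first, then CA3 driven by the recorded cortical spike
train, then CA1 driven by the recorded CA3 and cortical trains.  This is
mathematically identical to coupled integration and allows a single cortical
run to be reused across variants of the downstream wiring.  Spikes are
recorded every time step; signals every 1 ms:

* cortical "total synaptic activity" = summed magnitudes of all postsynaptic
  currents network-wide (UP-state detection signal),
* CA1 recording-site conductance = summed synaptic conductances of all
  non-Schaffer synapses onto the 56 site cells (ripple-detection signal),
* mean membrane potential of the site interneurons (ripple-band spectra).

Background drive is Gaussian current noise (per cell, per step, scaled to a
per-√ms SD): cortical PY dendrites 0.25 µA/cm² (seeds UP-state initiation),
CA3 PY 0.2 ± 1.2 µA/cm² (the noisy depolarizing drive that produces
population bursts in the isolated CA3; it stays on in coupled runs, which is
what allows spontaneous DOWN-state bursts), CA1 PY 0 ± 1.3 µA/cm² (sparse
spontaneous DOWN firing).  One master seed spawns named independent streams
(wiring, per-network initial conditions, per-network noise), so wiring can
be held fixed while noise varies; identical (config, seed) gives
bit-identical rasters.

## Event detection

* **UP states**: the activity signal above 0.45 × SD (synaptic-current mode)
  or the 30 ms-binned population rate above 0.2 × SD; SD over the whole
  recording; epochs closer than 100 ms merged.  A zero-variance signal
  yields an empty result with a warning.
* **SO cycles**: end of one UP state to the end of the next (one DOWN then
  one UP); the alignment reference (t = 0) is the signal maximum within the
  cycle.  Incomplete first/last cycles are dropped by construction.
* **CA3 bursts**: 10 ms-binned CA3 pyramidal rate above 1.5 × SD, boundaries
  extended to 1.2 × SD, overlapping extents merged.  Participation is the
  fraction of distinct pyramidal cells spiking inside the boundaries.
* **Ripples**: 150–200 Hz zero-phase 4th-order Butterworth bandpass of the
  site-conductance signal; RMS in 10 ms bins with 50% overlap; onset at
  mean + 3 × SD, boundaries at mean + 2 × SD (the RMS series has a nonzero
  floor, so thresholds are referenced to the mean — the convention of the
  detection literature); events shorter than 20 ms discarded, neighbours
  closer than 10 ms merged; the alignment point is the bandpassed minimum
  inside the event (earliest minimum on ties).  Because zero-phase
  narrowband filtering smears any transient by ±10 ms of supra-boundary
  RMS, the < 20 ms discard rule acts on the RMS support, not the underlying
  transient length.

## Analyses

Per-cell firing is averaged over SO cycles after linearly resampling each
cycle to the mean cycle length (a truncation alternative would weight late
cycle phases unevenly), z-scored per cell, aligned on the cycle reference,
and classified UP- vs DOWN-preferring by whether the peak bin falls inside
the mean-cycle UP region.  Silent cells are excluded with a recorded flag.
Ripple-triggered histograms align spikes of a chosen subset (1 ms bins by
default) on ripple minima together with the average bandpassed waveform.
Ripple phase is the Hilbert (analytic-signal) phase of the average
waveform, linearly interpolated at spike lags and shifted so the trough sits
at −90°; phase locking is tested with the circular V-test against a −90°
mean direction, pooled over the subset's spikes (per-cell testing is the
obvious alternative; pooled matches the histogram-based usage).  Tests with
fewer than 10 spikes are flagged underpowered.

## Sleep classification pipeline

Given spike tables, DOWN-to-UP transition times and ripple times, each cell
gets (i) a state preference from the peri-transition rate curve (±350 ms,
100 ms bins sliding by 10 ms, mean-normalized; maximum before −60 ms →
DOWN-cell, ties broken toward the later bin), (ii) peri-ripple rate curves
(±100 ms, 5 ms bins sliding by 1 ms) whose maximum minus the baseline (bins
more than 40 ms from the peak) is the firing-rate increase, computed
separately over UP- and DOWN-ripples, and (iii) a group 1–4 from the
cross-tabulation of state preference with highly/low ripple firing
(increase above 1.5 × the mean same-state increase; negative increases
enter the mean unclipped).  Ripples are assigned to states via the nearest
transition (before or after); events preceding it by 60–350 ms are
DOWN-ripples.  Cells with no spikes in any window are flagged and excluded,
never silently dropped.

## Synthetic sleep generator

The generator emulates the statistical structure the pipeline assumes:
gamma-distributed UP/DOWN durations alternating at ~0.83 Hz; per-cell
state-modulated Poisson rates (6 Hz preferred state, 0.8 Hz otherwise);
ripples Poisson within UP states (0.9 s⁻¹) plus DOWN-ripples placed in the
window before upcoming transitions so the planted UP share is 90%;
ripple-locked Gaussian rate bumps (σ = 5 ms, 2 ms jitter) of 25 Hz
(highly-firing groups 1/3) or 1.5 Hz (groups 2/4), group 3 attenuated in
UP-ripples.  Reported transition times lag true UP onsets by 70 ms,
emulating threshold-crossing detection of smoothed multiunit activity (this
is also why the pipeline's −60 ms split is meaningful on real data).  The
default epoch is 600 s.  What the generator does *not* emulate: refractory
periods, spike sorting errors, non-stationary rates, theta/spindle
structure, and correlated (non-Poisson) spiking — so passing recovery tests
validates the pipeline's statistical logic, not its robustness to those
real-data features.

## Calibration and the study conditions

Values the source literature fixes (population sizes, connection counts,
multiplicity distributions, α of the cortico-hippocampal synapses, cortical
conductances, thresholds, bin widths, dt) are used verbatim.  Genuinely
unpublished quantities were calibrated **once**, before the analysis runs,
against stated emergent properties, and then frozen:

* cortical per-spike increments α = 5.5 (AMPA PY→PY), 6.0 (NMDA), 4.0
  (AMPA PY→IN), 2.2 (GABA) and PY noise SD 0.25 µA/cm² — tuned so the
  isolated cortex alternates at 0.83–0.95 Hz with ~15 Hz UP-state pyramidal
  rates across seeds;
* hippocampal-internal conductances and the CA3/CA1 noise drives —
  CA3: recurrent AMPA 0.5 nS, PY→IN 5 nS, IN→PY 12 nS (τ 5 ms), noise
  0.2 ± 1.2 µA/cm², giving theta-paced (inter-burst interval ~100–300 ms)
  quasi-synchronized bursts with ~0.8 Hz mean pyramidal rates in isolation,
  ~15–18% burst participation under pyramidal-only cortical drive (with the
  DOWN states largely burst-free, as the pyramidal-only drive regime
  requires) and the monotone UP→DOWN burst-timing shift with growing
  interneuron drive;
  CA1: Schaffer 0.07 nS per synapse, IN→PY 11 nS, IN→IN 2 nS, PY→IN 7 nS
  (all τ 2 ms), noise SD 1.3 µA/cm², giving ripples inside UP states, a
  100–200 Hz interneuron spectral peak, and ~72% UP-preferring pyramidal
  cells with the Schaffer-multiplicity bias toward UP-preferring cells.

Known limitations:

* the calibrated cortical UP states are shorter (~80–150 ms) than the
  ~600 ms plateaus of the full-scale source model: the SO frequency,
  UP-state rates and the UP/DOWN entrainment contrasts are reproduced, but
  statistics that depend on the UP duty cycle run off-scale — in
  particular, ripples nearly tile each short UP state, so the fraction of
  CA1 cells counted as firing "in the average ripple" (~30%) sits well
  above the ~11.5% obtained when ~50 ms ripples are embedded in ~600 ms UP
  states;
* with the feedback inhibition strong enough to truncate UP-state CA3
  bursts at ~18% participation, the spontaneous DOWN-state rebound bursts
  of the strong-interneuron-drive regime stay small (~5% participation
  instead of ~12%);
* the model has no synaptic transmission delays, so the pyramidal→
  interneuron→GABA loop closes within a fraction of a ripple period;
  pyramidal volleys then lock near +45° of the site-conductance oscillation
  rather than the −90° trough, and the V-test against −90° does not reach
  significance even though the locking itself is strong.

## Numerical choices

RK2 (midpoint) with synaptic gating decayed analytically at stage times;
spike-triggered increments applied at the end of the step in which the
presynaptic crossing occurred (no transmission delay — none is stated).
Gaussian noise is held constant within a step and scaled by 1/√dt.
Second-order convergence of spike times was verified (error ratio ≈ 5 per
dt halving); over a second of tonic ~60 Hz firing the accumulated phase
drift between dt = 0.05 and 0.025 ms reaches a few ms, which is inherent to
fixed-step integration of spiking dynamics at these step sizes.

## Problem sizes

Desk-scale runs used throughout the test suite simulate ~12 s per scenario
(≈ 10 SO cycles); the acceptance script uses 10 s for the cortex-only
scenario and 20 s for the cortex-to-CA3 scenarios.  These sizes are the
package's standard quick-analysis configuration; longer runs change the
statistics only through narrower error bars.
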