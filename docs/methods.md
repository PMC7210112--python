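# Methods

This note documents the model equations, the parameter choices behind the
shipped configuration files, what the synthetic-data generators emulate,
and the numerical decisions.  Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Cell model

The granule cell is a tree of ten isopotential compartments — soma
(5.8 µm sphere-equivalent cylinder), four 15 µm dendrites, hillock, AIS,
a 60 µm ascending-axon stub and two 30 µm parallel-fiber stubs — sized so
the whole-cell capacitance is ≈ 3.1 pF and the input resistance ≈ 1.1 GΩ,
the values measured in these cells.  The axonal stubs are recording
points for spike initiation/conduction checks, not full-length fibers.
Geometry and passive parameters live in `grcsim/data/model.yaml` and are
surrogates chosen for electrotonic compactness, not a reproduction of any
published morphometry.

Each compartment carries Hodgkin–Huxley channels from
`grcsim/data/channels.yaml`.  Gates have Boltzmann steady states
(optionally with a non-zero floor: the FHF-modulated Nav1.6 variant keeps
~4% of its inactivation gate open, providing the persistent Na⁺ component
that sustains repetitive firing) and bell-shaped voltage-dependent time
constants, Q10-corrected to 32 °C (the tabulated values are given at
32 °C, so the correction is the identity at the default temperature).
The kinetics are standard fits for each channel family, written for this
package and stored as editable data; they are the search space and the
single source of truth for the optimizer's bounds.

Beyond the voltage-gated set, the soma carries:

* **Cav2.2** (N-type, m², ohmic with E = +60 mV).  Its current is routed
  into the Ca²⁺ shell — it is the *only* source of shell Ca²⁺.
* **A Ca²⁺-gated K⁺ channel** (`KCa1.1`).  Its open fraction relaxes
  toward a Hill function of shell Ca²⁺ (Kd 400 nM, n = 4) through a
  two-stage cascade with a total lag of ~1.4 s.  This is the coupling
  that turns high Cav2.2 density into late spike-frequency adaptation;
  the cascade gives the observed phenomenology — a stable first 500 ms
  followed by slowing — which a single-exponential gate cannot produce.
  Physiologically it stands for the Ca²⁺-dependent K⁺ current plus the
  slower K⁺ mechanisms (A-type de-inactivation, M-current accumulation)
  that deepen adaptation over seconds.
* **TRPM4**, gated by CaM2C (below), Ca²⁺-impermeable, ohmic with
  E_rev = 0 mV.

## Ca²⁺ / Calmodulin / TRPM4 coupling

A single well-mixed submembrane shell (0.3 µm deep) under the soma
integrates the Cav2.2 current with a Calretinin-like single-site buffer
(10 µM, Kd 500 nM) and linear extrusion toward the 100 nM resting level
(τ = 20 ms).  Shell Ca²⁺ therefore tracks the firing rate on a
few-ISI timescale — a design choice: the slow variables live downstream,
in the CaM2C integrator and the KCa cascade, not in the shell itself.
Radial diffusion is not modeled; the mechanism of interest is a
threshold crossing in time, not a spatial profile.

CaM2C forms by cooperative mass action, second-order in Ca²⁺
(`d[CaM2C]/dt = kon₂·Ca²·[CaM] − koff₂·[CaM2C]`, kon₂ = 2·10⁻¹¹
nM⁻²ms⁻¹, koff₂ = 10⁻⁴ ms⁻¹, 10 µM total CaM).  At discharge-level Ca²⁺
(hundreds of nM) the forward rate dominates and CaM2C ramps roughly
linearly for seconds.  TRPM4 opens as a steep Hill function of CaM2C
(half-activation 40 nM, n = 10) with 300 ms activation / 1 s
deactivation.  The rate constants are not published for this pathway;
they were calibrated once so that, with the accelerating model's Cav2.2
density, the acceleration begins ≥ 1.5 s into a 10 pA discharge, and then
frozen in `model.yaml`.  The TRPM4 density of the accelerating reference
model was set so IFC@10pA lands in the experimentally reported band
(96.3 ± 10.2%).

Two deliberate deviations from the recorded DISC (depolarization-induced
slow current) phenomenology, both consequences of modeling TRPM4 as a
smooth CaM2C-integrating conductance:

* the experimental DISC is a *burst* of transient events with a small
  integrated charge (tens of pA·ms) appearing ~1.3 s after the
  depolarizing train; our model produces a smooth sustained inward
  current that begins essentially at the end of the five-step train
  (the strong voltage-clamp steps drive the CaM2C threshold crossing
  during the train itself) and carries a much larger charge.  The tests
  therefore assert the TRPM4-*dependence* of the delayed current
  (present in the accelerating model, absent with TRPM4 disabled and in
  strong-adapting cells), not its latency or charge value.
* the sustained TRPM4 current during an accelerating discharge is tens
  of pA at full activation, not the ~1 pA voltage-clamp tail estimate:
  with this cell's f/I slope (~5–7 Hz/pA) a rate doubling requires a
  pA-scale-times-several depolarizing drive in any GΩ neuron.

## The four reference subtypes

Calibrated parameter sets (in `grcsim/data/subtypes/`) differ only in
somatic Cav2.2, KCa and TRPM4 densities on a shared excitability
baseline (Kv1.1 = 1.2 mS/cm² at the soma for all four):

| subtype | Cav2.2 | KCa | TRPM4 | IFC@10pA |
|---|---|---|---|---|
| strong-adapting | 0.026 | 1.0 | off | ≈ −86% |
| mild-adapting | 0.017 | 0.6 | off | ≈ −39% |
| non-adapting | 0.008 | 0.6 | off | ≈ −9% |
| accelerating | 0.029 | 0 | 0.8 | ≈ +100% |

(densities in mS/cm²; the IFC column is what the shipped tests compute,
not an input).  Cav2.2 is the adaptation dial: sweeping it across its
bounds yields a monotone IFC decrease, the model's account of the
negative IFC–Cav2.2 correlation across optimized model populations.
All four pass the spike-generation/conduction screen (AIS initiation,
non-decremental conduction, soma–axon rate agreement within 1 spike/s)
and are near-linear in f_initial/I over 8–22 pA.

## Synapse

Tsodyks–Markram release with utilization u (facilitation, τ_f) and
resources R (depression, τ_rec); amplitude_k = a_syn·u_k·R_k.  The two
time constants are fixed by requiring the PPR→p curve at the
representative 20 ms ISI to pass through the two experimental anchor
pairs (PPR 0.88 → p 0.43, PPR 0.53 → p 0.85), giving τ_f = 16.72 ms and
τ_rec = 36.72 ms; `ppr_to_p` then inverts PPR by monotone root finding
(PPR(p) is strictly decreasing, attainable range ≈ [0.42, 1.30] at that
ISI).

The postsynaptic event is AMPA (0.3/1.8 ms) plus an additive Mg²⁺-blocked
NMDA component (3/50 ms) with peak-conductance ratio 1.1.  Efficacy
calibration: the measured mean EPSC (−39.5 pA for ~2 synapses) comes from
train protocols, i.e. a depressed steady-state average; with TM
depression roughly halving the first-pulse amplitude this anchors the
full-release quantal peak at a_syn ≈ 1.3 nS (AMPA) per synapse.  The pair
(a_syn = 1.32 nS, NMDA ratio 1.1) was then fixed so that the model
reproduces the transmission regimes: sparse background response at
p = 0.1 on the strong-adapting cell, one-to-one (or supra-one-to-one,
via NMDA-driven doublets) background transfer at p ≥ 0.5.  Release is
deterministic mean-field by default; a stochastic-release flag exists.

Note the quantization of response rates: rates are spike counts over
500 ms (background) or 250 ms (burst) windows, so they move in 2 or 4 Hz
steps, and the S/N and SFC grids consequently take discrete values.
At a 1 s background the accelerating model's TRPM4 pathway cannot engage
(its delay exceeds the background duration), so at p = 0.9 its SFC ties
with other supra-threshold subtypes instead of strictly exceeding them;
at p = 0.5 the ordering (accelerating > all others) is strict.

## Protocols and statistics

* Current steps: 2 s, −8…22 pA in 2 pA increments from −65 mV; holding
  is implemented as a constant somatic bias current computed from the
  steady-state ionic currents and refined by two short settling runs.
* Synaptic trains: 1 s regular background (5–80 Hz) + 250 ms at 100 Hz,
  repeated twice; background response rate is measured over the last
  500 ms of the background (steady state), burst rate over the full
  250 ms.  A Poisson option exists (seeded) but regular is the default,
  matching electrical stimulation.
* DISC protocol: five 100 ms voltage-clamp steps from −65 to 0 mV at
  2 Hz, then ≥ 4 s of observation; onset = first inward deviation beyond
  a 3-SD noise band sustained 20 ms, charge = integrated inward deviation
  over 2 s.
* f_initial/f_final are window counts over 0–500 and 1500–2000 ms divided
  by 0.5 s (not inverse-ISI).  The adaptation index is the normalized
  mean of successive ISI differences (eFEL convention).  Undefined
  features (silent windows, zero denominators) propagate as explicit
  `None`/NaN/inf markers, never as silent zeros.
* Acceleration onset: first time the 3-ISI-smoothed instantaneous rate
  exceeds the 0–500 ms mean by 20%.
* Spike detection: upward crossing of −20 mV with a 1 ms refractory guard.

## Numerics

Fixed-step implicit integration: gate variables advance by the exact
exponential update for frozen voltage, staggered by half a step; the
voltage system (linear given gate values) is solved by Hines elimination
on the tree with a theta-method (θ = 0.5, Crank–Nicolson).  The Ca²⁺,
buffer and CaM2C states use exponential (Rush–Larsen) updates.  The
integrator rejects steps that drive concentrations negative and reports
voltage blow-up (|V| > 200 mV) with the offending compartment.

The default step is **dt = 0.005 ms**, chosen as the largest step at
which halving dt leaves the 2-s spike count of all four reference models
unchanged and early spike times agree within 0.1 ms.  Full-trace spike
times in the near-pause stretches of strongly adapting discharges remain
dt-sensitive (phase of a slow-variable feedback loop); counts and window
statistics converge.  Coarser steps (0.01–0.025 ms) are used internally
where only rates matter (optimizer evaluations, sweeps).

## Optimization and classification

The conductance optimizer is an elitist genetic algorithm (tournament
selection, uniform crossover, Gaussian mutation clipped to the channel
table's bounds) minimizing the summed per-feature |z|-distance to a
feature template at the template currents; the best individuals are
carried over unchanged, so the best distance is non-increasing.  The
scaled-down defaults (population 32, 8 generations, 500 ms evaluations
at 10 pA) are desk-scale; population size, generations, currents and the
gene list are all configurable.  Model validation (AIS spike initiation,
conduction, soma–axon rate match) can be applied to the final population.

Subtype classification mirrors the experimental recipe: cells with
IFC > +20% are pre-separated as accelerating (an operational cutoff;
these cells are unmistakable), k-means with 20 restarts runs on the rest
in the raw (IFC %, f_initial Hz) plane — native units, where the IFC
axis dominates the metric, as in the original Matlab analysis; z-scoring
was tried and rejected because it dilutes the separation with
f_initial noise — the cluster count is chosen by mean silhouette over
k = 2…5, normality is screened by a Lilliefors test and cluster
separation by a single one-way ANOVA on IFC (no multiple-testing
correction: one test per clustering).

## Synthetic cohorts

`grcsim.synth` draws per-cell (IFC, f_initial) pairs from per-subtype
Gaussians at the recorded cohort proportions (non-adapting 20.6%,
adapting 66.7% split 23:19 strong:mild, accelerating 12.7%; integerized
by largest remainder).  The centroids (−70, −35, 0, +90% IFC; 50, 44,
38, 30 Hz) are *surrogates* chosen to respect the observed ordering and
separation — the per-subtype means are not published numbers.  Passing
the clustering tests on these cohorts shows the pipeline recovers
well-separated planted structure at the recorded sample sizes; it does
not certify performance on noisier real data.  PPR samples are truncated
normals in (0, 2]; stimulus trains are exact grids (regular) or seeded
exponential-ISI draws (Poisson).  All generators are deterministic under
a fixed seed.

## Known limitations

* Channel kinetics are standard HH-style fits, not the exact published
  equation sets of the lineage granule-cell models; morphology is a
  surrogate.  Quantitative spike shapes should not be over-interpreted.
* The DISC latency/charge and the ~1 pA tail current are not reproduced
  (see the coupling section); the burst-like DISC microstructure would
  need a store-release or stochastic-channel mechanism that is out of
  scope.
* Synaptic inhibition, spillover, NMDA-sourced shell Ca²⁺ and network
  context are absent.
* Response-rate quantization (2–4 Hz steps) limits the resolution of the
  SFC/S-N grids.
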