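# Methods

This note documents the models, numerical methods and design choices behind
the package; the README gives the usage-level view.

## The I_Kur channel model

The atrial-specific ultra-rapid delayed rectifier current (Kv1.5, gene
*KCNA5*) is described by two Hodgkin–Huxley gates, `I_Kur = g(V)·a·i·(V −
E_K)`:

* steady-state activation `a_inf(V)` — for wild type, the product of two
  Boltzmann factors with (V½, k) = (−17.67, −5.75) and (−8.45, −11.51) mV;
* steady-state availability `i_inf(V) = 0.52/(1+exp((V−15.11)/7.57)) + 0.46`
  — the 0.46 floor is the *minimum availability*, the fraction of channels
  that never inactivate, so full availability saturates at 0.98 rather
  than 1;
* bi-sigmoidal activation and mono-sigmoidal inactivation time constants,
  both divided by the temperature-correction factor KQ10 = 3.52 that maps
  room-temperature kinetics to 37 °C;
* a maximal conductance with explicit voltage dependence,
  `g(V) = 0.64·(4.51 + 1.90/(1+exp(−(V−20.52)/8.27)))`, ranging 2.886 to
  4.102.

Units: the printed conductance expression is read as a whole-cell
conductance in nS; inside a host cell model the current is normalised by a
100 pF reference capacitance to pA/pF, which lands the current at the
magnitude of the host models' native I_Kur.  Standalone channel operations
return the direct product of conductance, gates and driving force.

### Mutant variants

Six *KCNA5* mutants are represented as relative changes to WT: additive V½
shifts, multiplicative slope factors (applied to the signed slope `k` of the
reported Boltzmann forms), an additive minimum-availability change, and a
multiplicative conductance factor.  Because the mutant data were reported as
single Boltzmanns while the WT activation is a two-factor product, mutants
are built on a *WT-equivalent* single Boltzmann obtained by least-squares
fit of the product over the clamp range [−60, +60] mV (V½ = −4.49 mV, k =
−8.46 mV); the WT itself keeps the exact product.  When the minimum
availability shifts, the availability span is adjusted so amplitude + floor
stays at the WT value of 0.98 (the reported normalised form ties the
inactivating span to 1 − MA).  Mutant time constants equal WT.  The variant
named D332H is also accepted under its alternative residue numbering D322H;
the package stores one canonical record with an alias, without judging which
numbering is correct.

Three mutants increase the current (D332H, E48G, A305T: negative activation
shifts and conductance factors > 1) and three reduce it (Y155C, D469E,
P488S; P488S retains only 3.8% of the WT conductance).

## Synthetic voltage-clamp data and fitting

At fixed command voltage the gates relax exponentially, so clamp protocols
are integrated segment-by-segment in closed form.  The generator adds
i.i.d. Gaussian recording noise (reproducible per seed), an optional linear
seal leak, and an optional two-population activation-kinetics mixture
`w·I_fast + (1−w)·I_slow`, emulating the fast and slow activation phenotypes
seen across experimental cells; the default scalings (×0.5 and ×2.0 of the
model time constant, w = 0.5) are explicitly arbitrary because the
underlying per-cell values were never published.

Steady-state point extraction divides measured currents by driving force and
by the *shape* of the voltage-dependent maximal conductance (part of the
channel formulation; its magnitude stays free and is recovered as the
activation fit's amplitude).  Slow-inactivation contamination at the
measurement time and the availability occupied at the holding potential are
divided out using the generator's truth record — a synthetic-recovery
convention that isolates the fitting stage from systematic protocol error.
The availability (two-pulse) arm uses a 30 s conditioning prepulse so the
conditioning genuinely reaches steady state; this is longer than
experimental practice but removes the only remaining systematic error from
the recovery experiment.

Boltzmann fits are bounded nonlinear least squares with deterministic
multi-start over the sigmoid midpoint (5 quantile starts) and an
unconstrained Levenberg–Marquardt polish with analytic Jacobians, which
drives noiseless fits to machine precision.  Flat availability data
degenerate gracefully (floor = mean, amplitude 0, a "V½ unidentifiable"
warning rather than an error).  Activation-phase time constants are fitted
as mono-exponentials on the 5–95% rise window.

The *round-trip* experiment — generate mutant clamp data, fit, difference
against the WT fit — recovers all six relative-change records to < 1e-9
noiseless; at 5% plateau noise the mean absolute errors over 50 seeds are
≈ 0.2 mV on half-voltages, ≈ 2% on slope factors, ≈ 0.002 on minimum
availability and ≈ 0.4% on the conductance factor.

## Cell models

### Courtemanche lineage

A full 21-state reimplementation of the classic human atrial model from its
published equations, in pA/pF units.  Resting potential −81 mV, APD90
≈ 298 ms at 1 Hz, spike–notch–dome morphology.  The I_Kur slot is
switchable: native (cubed activation gate, conductance
0.005 + 0.05/(1+exp(−(V−15)/13)) nS/pF) or the new formulation
("courtemanche_newIKur", standing in for the updated lineage the new current
was developed in).  Mutants enter the native slot by applying the relative
changes directly to the native steady-state Boltzmann parameters (the
activation cube is retained; a negative minimum-availability shift clips at
the native floor of 0).

### Grandi lineage

A reimplementation built from Grandi/Maleckar-style membrane formulations:
ten Tusscher-type I_Na; Maleckar I_Kur (g = 0.045 mS/µF); fast I_to;
I_Kr, I_Ks, I_K1, plateau K⁺; Ca²⁺-activated and background Cl⁻ currents;
GHK-type I_CaL with voltage- and Ca²⁺-dependent inactivation; allosterically
Ca²⁺-activated Na⁺/Ca²⁺ exchange; Na⁺/K⁺ pump; sarcolemmal Ca²⁺ pump;
background currents; intracellular K⁺ fixed at 120 mM.  The published
model's junctional/subsarcolemmal compartment split is consolidated to three
Ca²⁺ pools (cleft, cytosol, SR), with these deliberate departures:

* **Flux-gated Ca²⁺-induced Ca²⁺ release.**  A four-state ryanodine-receptor
  Markov scheme with luminal regulation has a pathological attractor when
  used in one global pool: without spatial spark confinement it settles into
  a permanently leaky state (persistent open fraction, cleft Ca²⁺ pinned at
  10–30 µM).  Release is instead gated by the Ca²⁺-influx trigger (L-type
  plus exchanger flux, plus release feedback) through activation,
  flux-inactivation and voltage-refractory gates — strictly triggered and
  self-terminating by construction.
* **A slow second voltage-inactivation gate on I_CaL** (`f2`, plateau time
  constant 500 ms, recovery ≈ 150 ms near rest).  Without it the
  reimplementation's EADs are an unterminated limit cycle; with it an
  EAD salvo accumulates inactivation and ends after a few oscillations,
  producing the discrete, finitely-prolonged EAD APs the lineage is known
  for.  Slow L-type inactivation components of this order are standard in
  cardiac models.
* I_ClCa senses cytosolic rather than cleft Ca²⁺ (the published model's
  dominant Cl⁻ flux sits outside the junctional cleft).

The free parameters of this reconstruction (I_CaL scale, Na/K-pump scale,
the consolidated-SR constants) were calibrated during model construction
against the lineage's published behaviours: resting potential ≈ −74 mV,
triangular AP, a small Ca²⁺ transient, loss-of-function I_Kur raising the
plateau and APD30, and the native EAD susceptibility under β-adrenergic
stimulation combined with I_Kur loss — including the reported
region-by-mutant EAD pattern (see below).  This is the honest alternative
to copying a reference implementation that is not available; the
reconstruction is labelled as such throughout.

### Variants

Regional, chronic-AF and β-adrenergic variants are multiplicative
conductance scalings (editable tables in `kcna5.cells.variants`):

| variant | scalings |
|---|---|
| CT (crista terminalis) | I_CaL ×1.67, I_to ×0.75 |
| PM (pectinate muscle) | I_CaL ×0.95, I_to ×1.05 |
| chronic AF | I_CaL ×0.35, I_to ×0.35, I_Kur ×0.5, I_K1 ×2 |
| ISO (1 µM) | I_CaL ×2.6, I_Ks ×3, I_Kur ×3 |

The regional factors are provisional literature-style values (the exact
regional sets of the source models are not recoverable); what matters for
the mechanisms studied is the CT's larger I_CaL.  The ISO I_CaL factor was
calibrated within the reported range of β-adrenergic L-type enhancement so
that the Grandi-lineage reconstruction reproduces the published EAD pattern;
the phospholamban (SERCA-affinity) component of ISO is omitted because in
the consolidated SR it drives spontaneous release — delayed-
afterdepolarisation territory, which this package deliberately does not
model (nor does it model spontaneous Ca²⁺ release generally).

## AP metrics and EAD detection

Upstroke = first rising −40 mV crossing after the stimulus; diastolic
reference = voltage immediately before the beat's stimulus (robust under
rate changes); APD_x measured from upstroke to x% repolarisation between
peak and diastolic reference; plateau potential = voltage at 50% of APD90.
An EAD is a local minimum followed by a local maximum with ≥ 2 mV
prominence between the AP peak and the terminal −40 mV crossing, with two
refinements: reversals peaking within 100 ms of the upstroke are excluded
(the spike–notch–dome complex of Courtemanche-type APs is a normal feature,
not an EAD), and a beat window that never repolarised below −40 mV (an
ongoing EAD salvo) counts its prominent reversals, minimum 1.  Under steady
1 Hz pacing EAD-bearing cells alternate 2:1 with recovered beats, so the
steady-state count is the maximum over the final two beats.

With these conventions the Grandi lineage under ISO reproduces the reported
pattern exactly: EADs for Y155C and P488S but not WT or D469E in the RA;
EADs for D469E in the CT (larger I_CaL) but not the PM.

## Tissue

The monodomain equation `∂V/∂t = ∇·(D∇V) − I_ion/C_m` is discretised by
explicit finite differences with harmonic-mean face diffusivities at
heterogeneous interfaces and no-flux (mirrored ghost) boundaries; operator
splitting applies one diffusion update then one reaction step per time
step.  Gates use Rush–Larsen exponential updates, everything else forward
Euler.  Time steps: 0.005 ms single cell, 0.02 ms Courtemanche tissue,
0.015 ms Grandi tissue (its calibrated diffusion coefficient of
≈ 1.5 mm²/ms needs the tighter stability bound).  For speed, all
parameter-independent voltage functions are pre-sampled on a 0.05 mV grid
and linearly interpolated in the hot loop (the I_Kur block stays analytic
because mutants redefine it per node); the direct kernels are retained and
a test pins the two against each other.

* **Conduction velocity** is measured from interpolated upstroke times at
  the 25% and 75% strand positions; the scalar diffusion coefficient is
  bisected until the CV of a 50 mm strand (dx 0.25 mm, single-cell states
  preconditioned 100 beats at 1 Hz) reaches 1.3 m/s ± 0.005 (calibrated
  D = 0.675 mm²/ms for the Courtemanche lineage, 1.51 for the Grandi
  lineage).  Scaling D to 40% of control reduces CV by ≈ 38.6%, matching
  the √D front-speed law (predicted 36.8%).
* **Vulnerability windows** use the 7 × S1 (500 ms) + S2 protocol at the
  CT/PM junction of a half/half strand, stimuli on a 3.3 mm-radius segment
  at twice the measured diastolic capture threshold for 2 ms.  The post-S1
  state is cached once; each S2 continuation classifies whether the wave
  reaches each strand end.  The window is the *range* (min to max) of S2
  values with unidirectional outcome, boundaries bisected to 1 ms; interior
  ordering violations (e.g. an isolated bidirectional-block S2 inside the
  range) are flagged, not dropped.  Where window widths fall below any
  practical scan step (homogeneity too mild), the shift of the junction's
  conduction boundary — the smallest bidirectionally conducted S2 — is the
  ordering observable.
* **Pacemaker surrogate**: a central 3 mm segment driven at 750 ms cycle
  length stands in for the sinoatrial exit (a detailed pacemaker cell model
  is out of scope); per-beat conduction into each flank is classified.
* **2D sheets** (default 50 × 50 mm, dx 0.5 mm) replace the anatomical
  atria.  Re-entry is initiated by the phase-distribution method: ≥ 32
  full-state snapshots at uniform times across one paced cycle, mapped by a
  linear or archimedean (single-rotor) spatial phase layout.  Dominant
  frequency is the peak of the Hann-tapered periodogram above 0.5 Hz;
  "sustained" means an activation within the final 250 ms of the run.

## Problem sizes used

Desk-scale sizes, chosen so the full suite runs on one CPU: strands 200
nodes (50 mm), sheets 100 × 100 (50 mm) for 1.2–2 s, restitution with 15–50
conditioning beats where full 100-beat trains are not needed for the
property under test, EAD scans with 12 conditioning beats.  The analysis
scripts use the same or larger sizes and state them inline.

## Known limitations

* The Grandi lineage is a calibrated reconstruction, not the published
  parameter set; its quantitative outputs (notably the D469E+ISO
  vulnerability window, width 345 ms vs the reported 313 ms, upper boundary
  672 ms vs 689 ms) inherit that uncertainty, which the sensitivity
  analysis over the CT I_CaL factor (analysis/07) quantifies.
* The pacemaker-surrogate experiments reproduce the skipped-beat phenomenon
  but not persistent alternating block, and the one-flank-ISO unidirectional
  block does not occur at the 750 ms surrogate rate because the
  reconstruction's EAD-prolonged CT APD (≈ 650 ms) is shorter than the
  sinus interval.
* No fibre anisotropy, fibrosis, 3D anatomy, spatial DF maps, or
  delayed-afterdepolarisation mechanisms (spontaneous SR release), matching
  the declared scope.
* 2D rotor dominant frequencies (≈ 1–1.5 Hz) are lower than organ-scale
  values: on a 50 mm sheet the rotor meanders with long path length; only
  the orderings across variants are interpreted.
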