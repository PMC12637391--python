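# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `sepsim`, and what the synthetic-circuit results do
and do not say about full-scale, biophysically detailed simulations.

## The decomposition calculus

The EEG of a simulated circuit is linear in the per-compartment
transmembrane currents: `V(t) = Σ_i w_i I_i(t)`, with `w_i` the lead-field
weight of compartment `i`. Three derived quantities follow:

* **Postsynaptic contribution** of a population: the sum of its neurons'
  per-neuron contribution traces. Exact, by linearity of the volume
  conductor.
* **Presynaptic contribution** of population *x*: network EEG minus the
  EEG of a *decoupled replay* in which the recorded spikes of every
  population except *x* drive efferent synapses at their original times,
  while spikes generated inside the replay are recorded but never
  transmitted. This removes exactly the synaptic (and return) currents
  that *x* elicits downstream — up to the caveat below.
* **Pathway contribution** *x→y*: the per-neuron network-minus-decoupled
  difference summed over the neurons of *y*. Per-neuron pairing between
  the two runs is enforced by identical neuron ordering; multi-synaptic
  effects are outside the calculus by construction.

The caveat: in the decoupled run the postsynaptic membranes lack *x*'s
input, so their spike *timing* differs from the connected run even though
their synaptic drive is otherwise identical. The network-minus-decoupled
difference therefore contains, besides the pathway currents, a
spike-timing mismatch term. In an exactly linear circuit (current-based
synapses, passive membranes, spike detectors that do not feed back into
the dynamics) the term vanishes and the contribution sum reproduces the
total to solver precision (residual ~1e-13, tested). With
conductance-based synapses and integrate-and-fire somata the residual is
non-zero and, at the circuit sizes used here, carries a band-power ratio
(>100 Hz vs <100 Hz) above one — the high-frequency replay noise of the
spiking decomposition. All stochastic outcomes (noise path, release
outcomes) are preserved between connected and decoupled runs, so the
residual reflects dynamics, not randomness.

## Circuit model

Neurons are chains: a cylindrical soma (equal-area stand-in for a sphere)
plus, for excitatory cells, a single apical cable pointing toward the pia
— the minimal shape that forms a current dipole. Interneurons are
soma-only; a single isopotential compartment has zero net membrane
current and hence exactly zero direct EEG contribution, consistent with
inhibitory postsynaptic contributions being negligible. Coordinates: z is
depth in µm, 0 at the pia, increasing downward.

Passive membrane: C_m = 1 µF/cm², g_pas = 5·10⁻⁵ S/cm² (τ_m = 20 ms),
E_pas = −65 mV, axial resistivity 150 Ω·cm. Spike mechanism at the soma:
exponential integrate-and-fire (threshold −50 mV, ΔT = 2 mV, detection at
−30 mV, reset −65 mV, refractory 2.5 ms) plus a stereotyped 1 ms biphasic
somatic spike current (peak 1.5 nA, zero net charge) injected as an ionic
current, so action potentials contribute fast dipolar currents — the
source of the replay-timing noise. The exponential drive is capped at
50 mV of depolarisation per step and disabled during the refractory
period; the upstroke is cut by the reset at the detection level. Two
degenerate modes support testing: `detector` (threshold crossings
recorded without influencing the dynamics) and `none`.

Synapses are single-exponential, conductance-based (nS, with reversal
potential) or current-based (nA, for exactly linear test circuits), with
probabilistic release. Placement profiles: `distributed`
(area-proportional over the dendritic membrane) and `perisomatic` (within
50 µm path distance of the soma, area-weighted). The
"Schneider-Mizell-style" variant of the default column differs from the
original only in flipping the L5 PeriTC→L5E profile from distributed to
perisomatic. Thalamocortical delays follow the conduction rule
`delay = base + (distance from the bottom of L6 to the synapse)/velocity`
with base 1 ms and velocity 300 µm/ms (the rule is from the source
circuit; the constants are package defaults, configurable).

Background drive is Ornstein–Uhlenbeck conductance noise at every soma
(τ = 3 ms, excitatory reversal), with sd/mean fixed at 0.4 and negative
excursions clipped at zero. Per-population mean multipliers are
calibrated once so that spontaneous rates sit at ~1–5 Hz — the stand-in
for firing-rate calibration of the full model — and are part of the
default configuration, not free per-experiment knobs.

### The thalamic stimulus

Each stimulus activates exactly `round(0.1 · n_fibers)` of the 100
virtual fibers; spike times are drawn as an inhomogeneous Poisson process
from a piecewise-constant PSTH (1 ms bins): baseline 0.5 Hz plus a
Gaussian bump centred at 5 ms with σ = 2 ms and a 300 Hz peak, i.e. ~1.5
spikes per activated fiber per flick, the single-spike-per-deflection
regime of thalamic relay cells. Each synthetic fiber stands in for many
biological fibers; with only ten active fibers, a bump an order of
magnitude lower would deliver too few spikes to drive a ~240-neuron
column at all. Campaigns simulate two stimuli per trial (inter-stimulus
interval 150 ms) and analyse the response to the second, to include
accommodation; default 10 trials with trial seeds `base_seed + k`.

## Forward models

EEG weights use point-electrode reciprocity in a homogeneous, isotropic
medium (σ = 0.3 S/m): `w = 1/(4πσ)(1/r_rec − 1/r_ref)` V/A per
compartment, the reference term dropping for a reference at infinity. The
recording-minus-reference subtraction is folded into the weight. A
weights-file HDF5 layout (`/electrodes/<name>/scaling_factors`) allows
externally computed (e.g. FEM) weights to be substituted unchanged. LFP
uses the line-source approximation (asinh form, equivalent to the
classical log expression) with somata as point sources, on a vertical
laminar array at 80 µm spacing. Because per-neuron currents sum to zero,
the weights carry a gauge freedom; `gauge_shift` centres the weight range
of a population on zero without changing any signal (tested to 1e-12
relative), and the weights-range statistic (per-neuron 90th−10th
percentile, averaged over a sample, default 100 neurons) summarises how
strongly a population can couple to the electrode.

## CSD and the self-consistency chain

Standard CSD is the second spatial difference `−σ Δ²φ/h²` with Vaknin
duplication of the boundary potentials; step-iCSD builds the analytic
forward matrix of h-thick cylindrical disks (radius ρ, default 500 µm,
closed-form antiderivative rather than quadrature) and solves `C = F⁻¹φ`
per time step, reporting the condition number. The dipole-moment density
is the trapezoidal `∫ z·CSD dz` over the electrode span, evaluated at the
time of peak rectified current density when no time is given. SI units
internally; CSD is reported in nA/mm³ (numerically equal to A/m³) and p
in nAm/mm². The EEG estimate from a cortical patch is `π r² p Ê` with Ê
the dipole-aligned lead field; for the self-consistency experiment Ê is
computed as the z-derivative of the same point-electrode lead field used
for the direct EEG, the patch radius matches the column's lateral extent,
and ρ is set to the column radius. On the synthetic column the two
amplitude estimates agree to ~8% (factor-2 agreement is the tested
bound).

## Waveform features

P1 is the maximum in 8–16 ms, N1 the minimum in 16–40 ms post-stimulus.
The N1 FWHM is measured from the pre-stimulus baseline: half-depth
crossings nearest the trough, linearly interpolated between samples; if
the signal never recovers to half depth the width is undefined and the
trace is flagged. N1 is declared undefined when the trough does not dip
below baseline by more than 1e-9 of the trace scale (guards against
numerical dust on flat traces). Onset detection is the first sample
exceeding baseline mean + 3 baseline SDs. The band-pass (2nd order
Butterworth, 1–500 Hz) is applied zero-phase (forward–backward, reflected
padding) to avoid shifting P1 timing, identically to totals and
per-neuron contributions so the partition invariant survives filtering;
trials are averaged after filtering. FWHM attribution removes one pathway
trace from the total and differences the widths; across two circuit
variants `Δ_{x→y} = ΔFWHM − ΔFWHM_{x→y}`.

## Numerical integration

Fixed-step implicit Euler at dt = 0.025 ms on the cable equation, solved
per neuron by a vectorised Thomas algorithm (chains only); synaptic
conductances enter the matrix implicitly, the EIF exponential and spike
currents explicitly. Currents are reported every 0.1 ms (Nyquist 5 kHz,
safely above the 500 Hz filter corner) as the net axial inflow per
compartment, which equals the total membrane current and sums to zero
per neuron to machine precision by construction. Spike times are recorded
grid-aligned so that replaying them reproduces event delivery steps
exactly; synaptic release outcomes are pure hash functions of
(trial seed, synapse id, event index), and the noise path draws one
normal vector per step regardless of activity — together these make the
replay-all decoupled run reproduce the connected run's currents bitwise.
Voltage divergence beyond ±500 mV aborts with a diagnostic.

## Problem sizes and what the tests show

The default column has ~240 neurons (~1,400 compartments) and 100 fibers;
the linear-exactness circuit ~200 neurons; probe circuits 30–160 neurons.
These sizes make a full campaign run in minutes while preserving the
structural features the analysis depends on: laminar dipole geometry,
pathway-specific placement, stimulus-locked firing over ~1–5 Hz
background. They do not reproduce the population statistics, morphological
diversity, active dendrites or amplitude calibration of a full-scale
model, so passing tests validate the *machinery* (decomposition identities,
replay equivalence, forward-model correctness, feature definitions and
the self-consistency arithmetic), not in vivo waveform shapes. Two known
desk-scale departures: the synthetic N1 is narrower (≈5–10 ms FWHM) than
the tens-of-milliseconds widths of full-scale simulations, and the
perisomatic-targeting variant deepens the N1 (the placement mechanism,
which the package demonstrates with bitwise-frozen presynaptic spiking)
but does not narrow it at this scale. The spectral character of the
spiking decomposition residual is also size-dependent: at the ~130-neuron
scale used in the residual experiment the >100 Hz band dominates, while
at larger stand-in scales coherent slow rate drift can outweigh it.
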