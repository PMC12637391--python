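# sepsim

Synthetic cortical-column simulation and decomposition of the whisker-flick
somatosensory evoked potential (SEP).

A whisker flick evokes a stereotyped EEG waveform over rodent somatosensory
cortex: a positive deflection (P1, ~8–16 ms post-stimulus) followed by a
negative one (N1, early phase 16–40 ms). Which neural populations generate
these components — through their own transmembrane currents, or through the
currents they elicit downstream — cannot be measured in vivo, but it can be
computed in a simulated circuit where every compartment's current and its
coupling to the electrode are known. `sepsim` implements that computational
chain at desk scale, for modellers who want to study, test or extend the
decomposition machinery without a supercomputer:

1. **Synthetic circuit generation** — layered excitatory/inhibitory
   populations (ball-and-stick pyramidal stand-ins, soma-only
   interneurons), virtual thalamic fibers with a stimulus-locked PSTH
   (10% of fibers activated per stimulus), distance-dependent axonal
   delays, Ornstein–Uhlenbeck conductance noise with sd/mean = 0.4, and
   pathway-specific synapse placement (distributed vs perisomatic).
2. **Network simulation** — passive cables with exponential
   integrate-and-fire somata, recording spikes and per-compartment
   transmembrane currents that sum to zero per neuron (charge
   conservation), in *connected* and *decoupled replay* modes with all
   stochastic outcomes preserved between the two.
3. **Forward models** — EEG by the reciprocity (lead-field) approach,
   `w = 1/(4πσ) (1/r_rec − 1/r_ref)` per compartment, with weights-file
   I/O, gauge shifting and the per-neuron weights-range statistic; LFP by
   the line-source approximation on a laminar array (80 µm spacing).
4. **Decomposition** — the presynaptic contribution of population *x* is
   the network EEG minus the decoupled EEG in which every population
   except *x* is replayed; restricting the per-neuron difference to a
   postsynaptic population *y* gives the pathway contribution *x→y*;
   summing per-neuron contributions gives postsynaptic contributions; a
   thalamus-silenced replay isolates the thalamic drive. The sum of all
   contributions is validated against the total signal.
5. **CSD / dipole self-consistency** — standard CSD with Vaknin edge
   correction, step-iCSD (cylindrical disks, ρ = 500 µm), the
   dipole-moment density `p = ∫ z·CSD(z,t) dz`, and the reciprocity
   estimate of the EEG amplitude `π r² p Ê`, cross-checked against the
   directly computed EEG.
6. **Waveform features** — onset (baseline + 3 SD), P1/N1 amplitudes and
   times, N1 full width at half maximum (FWHM), the per-pathway FWHM
   attribution `FWHM_c − FWHM_{c,x→y}`, and the spike-compression
   manipulation.

## Worked example

```python
from sepsim import percent_narrowing, eeg_from_dipole

# N1 widths of 28 ms and 21 ms in two circuit variants:
print(percent_narrowing(28.0, 21.0))          # 25.0  (% narrowing)

# dipole-moment density 0.023 nAm/mm², dipole-aligned lead field
# 4 V/mm/A, column patch radius 0.25 mm, seven columns:
print(eeg_from_dipole(0.023, r=0.25, lead=4.0, n_columns=1))  # 1.8064e-08 V
print(eeg_from_dipole(0.023, r=0.25, lead=4.0, n_columns=7))  # 1.2645e-07 V
```

A full decomposition campaign on the default ~240-neuron column (two
stimuli per trial, response to the second stimulus extracted, 2nd-order
1–500 Hz Butterworth, trial average):

```python
from sepsim import CampaignSpec, run_campaign
from sepsim.configs import default_config

spec = CampaignSpec(config=default_config(), n_trials=5, base_seed=1,
                    targets=["L5I"])
res = run_campaign(spec)
print(res.features.p1_amplitude)   # 6.16886e-08  (V, positive P1 peak)
print(res.features.n1_amplitude)   # -1.34147e-08 (V, N1 trough)
print(res.features.n1_fwhm)        # 8.04639      (ms, N1 width)
```

The P1 here is carried by perisomatically placed thalamocortical
excitation on L2/3 and L5 pyramidal stand-ins (deep current sink,
superficial return source), the N1 by slow thalamic drive to L6 apical
dendrites plus recurrent L5 inhibition; `res.contributions` holds the
per-population presynaptic, pathway and postsynaptic traces that make
that attribution quantitative.

The same stages are scriptable from the shell: `sepsim build`,
`sepsim simulate`, `sepsim campaign`, `sepsim csd`, `sepsim features`
(see `sepsim --help`).

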