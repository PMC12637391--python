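"""Canned experiments exercising the decomposition machinery end to end.

These functions set up the standard validation conditions — an exactly
linear passive circuit for decomposition exactness, the spiking column
for replay-noise characterisation, the replay-all identity, the synapse
placement probe, and the LFP→CSD→dipole→EEG self-consistency chain — and
return the measured quantities.  They are used both by the test suite and
by the reproduction script.
"""

from __future__ import annotations

import copy

import numpy as np

from .circuit import StimulusSpec, build_circuit, generate_thalamic_spikes
from .configs import default_config
from .csd import dipole_lead_field, dipole_moment_density, eeg_from_dipole, step_icsd
from .decomposition import (
    ContributionSet,
    band_power_ratio,
    presynaptic_contribution,
    thalamic_contribution,
    validate_linear_sum,
)
from .leadfield import ElectrodeSpec, circuit_eeg_weights, laminar_lfp_weights
from .netsim import ReplayPlan, SimParams, simulate_connected, simulate_decoupled
from .signals import compute_lfp, compute_signal

__all__ = [
    "linear_chain_config",
    "decomposition_residual",
    "replay_all_deviation",
    "placement_effect",
    "self_consistency",
    "small_spiking_config",
]

_EEG_SPEC = ElectrodeSpec((0.0, 0.0, -2000.0))


def linear_chain_config(n_scale: float = 1.0) -> dict:
    """A fully linear passive circuit (~200 neurons).

    Current-based synapses, threshold detectors that do not perturb the
    dynamics, deterministic release and no background noise: superposition
    holds exactly, so the contribution calculus must be exact.
    """
    n = lambda k: max(2, int(round(k * n_scale)))
    return {
        "layers": {"L23": [100.0, 400.0], "L5": [600.0, 900.0], "L6": [900.0, 1150.0]},
        "column_annulus": [20.0, 200.0],
        "populations": {
            "A": {
                "layer": "L5",
                "syn_class": "EXC",
                "count": n(70),
                "depth": [650.0, 850.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 500.0, "n_dendrite_segments": 6},
            },
            "B": {
                "layer": "L23",
                "syn_class": "EXC",
                "count": n(70),
                "depth": [250.0, 380.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 220.0, "n_dendrite_segments": 5},
            },
            "C": {
                "layer": "L6",
                "syn_class": "INH",
                "count": n(60),
                "depth": [950.0, 1100.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 400.0, "n_dendrite_segments": 5},
            },
            "THAL": {"layer": "THAL", "syn_class": "fiber", "count": 40},
        },
        "connections": [
            {"pre": "THAL", "post": "A", "p": 0.25, "gmax": 0.08, "tau": 2.0, "kind": "current", "placement": "perisomatic"},
            {"pre": "THAL", "post": "C", "p": 0.20, "gmax": 0.06, "tau": 2.0, "kind": "current", "placement": "distributed"},
            {"pre": "A", "post": "B", "p": 0.15, "gmax": 0.05, "tau": 2.0, "kind": "current", "placement": "distributed"},
            {"pre": "A", "post": "A", "p": 0.08, "gmax": 0.04, "tau": 2.0, "kind": "current", "placement": "distributed"},
            {"pre": "C", "post": "A", "p": 0.15, "gmax": -0.05, "tau": 8.0, "kind": "current", "placement": "distributed"},
            {"pre": "B", "post": "C", "p": 0.10, "gmax": 0.04, "tau": 2.0, "kind": "current", "placement": "distributed"},
        ],
        "noise": {"mean": 0.0},
        "spike": {"mode": "detector", "v_thresh": -60.0, "t_ref": 4.0},
        "stimulus": {"n_fibers": 40, "active_fraction": 0.25, "n_stimuli": 1, "isi": 100.0, "baseline": 0.0},
        "stim_start": 20.0,
    }


def small_spiking_config(n_scale: float = 0.6) -> dict:
    """Scaled-down copy of the default spiking column for fast experiments."""
    cfg = copy.deepcopy(default_config())
    for pc in cfg["populations"].values():
        if pc["syn_class"] != "fiber":
            pc["count"] = max(4, int(round(pc["count"] * n_scale)))
    cfg["stimulus"]["n_stimuli"] = 1
    cfg["stimulus"]["isi"] = 110.0
    cfg["stim_start"] = 30.0
    return cfg


def _decompose_once(cfg: dict, seed: int, t_stop: float, filt=None):
    """One-trial full decomposition (all populations + thalamus)."""
    circuit = build_circuit(cfg, seed)
    stim_cfg = cfg["stimulus"]
    stim = StimulusSpec.default(
        baseline=stim_cfg.get("baseline", 0.5),
        n_fibers=stim_cfg["n_fibers"],
        active_fraction=stim_cfg["active_fraction"],
        n_stimuli=stim_cfg["n_stimuli"],
        isi=stim_cfg["isi"],
    )
    stim_start = cfg.get("stim_start", 20.0)
    thal = generate_thalamic_spikes(stim, seed, circuit.fiber_ids, stim_start, t_stop)
    sim = SimParams(t_stop=t_stop)
    weights = circuit_eeg_weights(circuit, _EEG_SPEC)
    spikes, report = simulate_connected(circuit, thal, seed, sim)
    net = compute_signal(report, weights)
    contribs = ContributionSet(total=net)
    for pop in circuit.population_names(spiking_only=True):
        plan = ReplayPlan.excluding(circuit, spikes, pop)
        _, rep = simulate_decoupled(circuit, plan, thal, seed, sim)
        contribs.presynaptic[pop] = presynaptic_contribution(net, compute_signal(rep, weights))
    plan = ReplayPlan.without_thalamus(circuit, spikes)
    _, rep = simulate_decoupled(circuit, plan, thal, seed, sim)
    contribs.thalamic = thalamic_contribution(net, compute_signal(rep, weights))
    return contribs, spikes, circuit


def decomposition_residual(seed: int, linear: bool = True, n_scale: float = 1.0):
    """RMS residual of the contribution sum, and its band-power ratio.

    ``linear=True`` uses the exactly linear circuit (residual should
    vanish); ``linear=False`` uses the spiking column, where spike-timing
    differences between connected and decoupled runs leave a
    high-frequency residual.
    """
    if linear:
        cfg = linear_chain_config(n_scale)
        t_stop = 120.0
    else:
        cfg = small_spiking_config(n_scale)
        t_stop = 140.0
    contribs, _, _ = _decompose_once(cfg, seed, t_stop)
    metric, resid = validate_linear_sum(contribs)
    return metric, band_power_ratio(resid, 100.0)


def replay_all_deviation(seed: int, n_scale: float = 0.5) -> float:
    """Max |current| deviation (nA) between connected and replay-all runs."""
    cfg = small_spiking_config(n_scale)
    circuit = build_circuit(cfg, seed)
    stim_cfg = cfg["stimulus"]
    stim = StimulusSpec.default(
        n_fibers=stim_cfg["n_fibers"],
        active_fraction=stim_cfg["active_fraction"],
        n_stimuli=1,
        isi=stim_cfg["isi"],
    )
    t_stop = 100.0
    thal = generate_thalamic_spikes(stim, seed, circuit.fiber_ids, 30.0, t_stop)
    sim = SimParams(t_stop=t_stop)
    spikes, report = simulate_connected(circuit, thal, seed, sim)
    plan = ReplayPlan.all(circuit, spikes)
    _, report_d = simulate_decoupled(circuit, plan, thal, seed, sim)
    return float(np.abs(report.currents - report_d.currents).max())


def _placement_config(placement: str) -> dict:
    """Thalamus → PeriTC → pyramidal probe with no feedback onto PeriTC."""
    return {
        "layers": {"L5": [600.0, 900.0]},
        "column_annulus": [20.0, 150.0],
        "populations": {
            "PTC": {"layer": "L5", "syn_class": "PeriTC", "count": 10, "depth": [650.0, 850.0]},
            "PC": {
                "layer": "L5",
                "syn_class": "EXC",
                "count": 25,
                "depth": [650.0, 850.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 550.0, "n_dendrite_segments": 7},
            },
            "THAL": {"layer": "THAL", "syn_class": "fiber", "count": 30},
        },
        "connections": [
            {"pre": "THAL", "post": "PTC", "p": 0.4, "gmax": 2.0, "tau": 2.0, "p_release": 1.0},
            {"pre": "THAL", "post": "PC", "p": 0.2, "gmax": 1.0, "tau": 2.0, "placement": "perisomatic", "p_release": 1.0},
            {"pre": "PTC", "post": "PC", "p": 0.5, "gmax": 4.0, "e_rev": -80.0, "tau": 9.0, "placement": placement, "p_release": 1.0},
        ],
        "noise": {"mean": 0.0},
        "spike": {"mode": "eif"},
        "stimulus": {"n_fibers": 30, "active_fraction": 0.5, "n_stimuli": 1, "isi": 80.0, "baseline": 0.0},
        "stim_start": 20.0,
    }


def placement_effect(seed: int):
    """Perisomatic vs distributed inhibition with identical presynaptic spikes.

    Returns ``(percent_change, spikes_identical)``: the relative change in
    the peak magnitude of the PeriTC presynaptic EEG contribution between
    the two placement profiles, and whether the PeriTC spike trains of the
    two connected simulations are bitwise equal (they must be — the
    inhibitory cells receive no feedback, so only synapse location
    differs).
    """
    peaks, trains = [], []
    for placement in ("distributed", "perisomatic"):
        cfg = _placement_config(placement)
        circuit = build_circuit(cfg, seed)
        stim = StimulusSpec.default(
            n_fibers=30, active_fraction=0.5, n_stimuli=1, isi=80.0, baseline=0.0
        )
        t_stop = 90.0
        thal = generate_thalamic_spikes(stim, seed, circuit.fiber_ids, 20.0, t_stop)
        sim = SimParams(t_stop=t_stop)
        weights = circuit_eeg_weights(circuit, _EEG_SPEC)
        spikes, report = simulate_connected(circuit, thal, seed, sim)
        net = compute_signal(report, weights)
        plan = ReplayPlan.excluding(circuit, spikes, "PTC")
        _, rep = simulate_decoupled(circuit, plan, thal, seed, sim)
        contrib = presynaptic_contribution(net, compute_signal(rep, weights))
        peaks.append(np.abs(contrib.values).max())
        ptc = spikes.select(circuit.population("PTC").ids)
        trains.append((ptc.ids.copy(), ptc.times.copy()))
    identical = np.array_equal(trains[0][0], trains[1][0]) and np.array_equal(
        trains[0][1], trains[1][1]
    )
    change = 100.0 * abs(peaks[1] - peaks[0]) / max(peaks[0], 1e-300)
    return change, identical


def self_consistency(seed: int, n_scale: float = 0.6) -> dict:
    """EEG amplitude two ways: direct reciprocity vs LFP→iCSD→dipole chain.

    Returns a dict with the directly computed reciprocity EEG peak
    (``eeg_direct_v``), the ``pi r^2 p E_hat`` estimate (``eeg_estimate_v``,
    patch radius matching the column lateral extent, E_hat the
    dipole-aligned lead field of the same electrode), their ratio, the
    peak laminar LFP (mV) and the dipole-moment density (nAm/mm²).
    """
    cfg = small_spiking_config(n_scale)
    circuit = build_circuit(cfg, seed)
    stim_cfg = cfg["stimulus"]
    stim = StimulusSpec.default(
        n_fibers=stim_cfg["n_fibers"],
        active_fraction=stim_cfg["active_fraction"],
        n_stimuli=1,
        isi=stim_cfg["isi"],
    )
    t_stop = 120.0
    thal = generate_thalamic_spikes(stim, seed, circuit.fiber_ids, 30.0, t_stop)
    sim = SimParams(t_stop=t_stop)
    _, report = simulate_connected(circuit, thal, seed, sim)

    eeg_spec = ElectrodeSpec((0.0, 0.0, -5000.0))
    eeg = compute_signal(report, circuit_eeg_weights(circuit, eeg_spec))
    mask = eeg.time > 30.0
    eeg_peak = float(np.abs(eeg.values[mask]).max())
    t_peak = float(eeg.time[mask][np.argmax(np.abs(eeg.values[mask]))])

    depths = np.asarray(cfg["recording"]["lfp_depths"])
    lfp = compute_lfp(report, laminar_lfp_weights(circuit, depths))
    r_col_um = cfg["column_annulus"][1]
    csd = step_icsd(lfp, h=80.0, rho=r_col_um, sigma=0.3)
    p = dipole_moment_density(csd, t=t_peak)
    lead = dipole_lead_field(eeg_spec, (depths[0], depths[-1]))
    est = abs(eeg_from_dipole(p, r=r_col_um * 1e-3, lead=lead, n_columns=1))
    return {
        "eeg_direct_v": eeg_peak,
        "eeg_estimate_v": est,
        "ratio": est / eeg_peak,
        "lfp_peak_mv": float(np.abs(lfp.values).max()),
        "dipole_density_nam_per_mm2": p,
        "lead_v_per_mm_a": lead,
    }
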