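"""Contribution calculus: partition identities and superposition oracles."""

import numpy as np
import pytest

from sepsim import (
    ContributionSet,
    ElectrodeSpec,
    SignalTrace,
    StimulusSpec,
    band_power_ratio,
    build_circuit,
    circuit_eeg_weights,
    compute_signal,
    generate_thalamic_spikes,
    pathway_contribution,
    postsynaptic_contribution,
    presynaptic_contribution,
    simulate_connected,
    simulate_decoupled,
    thalamic_contribution,
    validate_linear_sum,
)
from sepsim.netsim import ReplayPlan, SimParams

EEG = ElectrodeSpec((0.0, 0.0, -2000.0))


def linear_toy_config():
    """THAL -> A -> B feed-forward chain with current-based synapses,
    passive membranes and threshold detectors: exactly linear."""
    return {
        "layers": {"L23": [100.0, 400.0], "L5": [600.0, 900.0]},
        "column_annulus": [20.0, 100.0],
        "populations": {
            "A": {
                "layer": "L5",
                "syn_class": "EXC",
                "count": 8,
                "depth": [650.0, 800.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 400.0, "n_dendrite_segments": 5},
            },
            "B": {
                "layer": "L23",
                "syn_class": "EXC",
                "count": 8,
                "depth": [250.0, 350.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 200.0, "n_dendrite_segments": 4},
            },
            "THAL": {"layer": "THAL", "syn_class": "fiber", "count": 10},
        },
        "connections": [
            {"pre": "THAL", "post": "A", "p": 0.5, "gmax": 0.15, "tau": 2.0, "kind": "current", "placement": "perisomatic"},
            {"pre": "A", "post": "B", "p": 0.4, "gmax": 0.08, "tau": 2.0, "kind": "current", "placement": "distributed"},
        ],
        "noise": {"mean": 0.0},
        "spike": {"mode": "detector", "v_thresh": -64.0, "t_ref": 5.0},
        "stimulus": {"n_fibers": 10, "active_fraction": 0.5, "n_stimuli": 1, "isi": 60.0, "baseline": 0.0},
        "stim_start": 10.0,
    }


@pytest.fixture(scope="module")
def linear_toy():
    cfg = linear_toy_config()
    c = build_circuit(cfg, seed=2)
    stim = StimulusSpec.default(
        n_fibers=10, active_fraction=0.5, n_stimuli=1, isi=60.0, baseline=0.0
    )
    thal = generate_thalamic_spikes(stim, 2, c.fiber_ids, 10.0, 80.0)
    sim = SimParams(t_stop=80.0)
    w = circuit_eeg_weights(c, EEG)
    spikes, rep = simulate_connected(c, thal, 2, sim)
    net = compute_signal(rep, w)
    return {"circuit": c, "thal": thal, "sim": sim, "weights": w, "spikes": spikes, "net": net}


def _decoupled_trace(toy, plan):
    _, rep = simulate_decoupled(
        toy["circuit"], plan, toy["thal"], 2, toy["sim"]
    )
    return compute_signal(rep, toy["weights"])


class TestPresynaptic:
    def test_identical_traces_give_zero(self, linear_toy):
        net = linear_toy["net"]
        out = presynaptic_contribution(net, net)
        assert np.abs(out.values).max() == 0.0
        assert np.abs(out.contributions).max() == 0.0

    def test_population_without_efferents_contributes_nothing(self, linear_toy):
        toy = linear_toy
        plan = ReplayPlan.excluding(toy["circuit"], toy["spikes"], "B")
        contrib = presynaptic_contribution(toy["net"], _decoupled_trace(toy, plan))
        assert np.abs(contrib.values).max() < 1e-15

    def test_feed_forward_superposition_oracle(self, linear_toy):
        """Presynaptic contribution of A == EEG of a run where only A's
        recorded spikes are played into the circuit (direct superposition)."""
        toy = linear_toy
        plan = ReplayPlan.excluding(toy["circuit"], toy["spikes"], "A")
        contrib = presynaptic_contribution(toy["net"], _decoupled_trace(toy, plan))
        only_a = ReplayPlan(
            toy["spikes"].select(toy["circuit"].population("A").ids),
            None,
            include_thalamic=False,
        )
        direct = _decoupled_trace(toy, only_a)
        scale = np.abs(direct.values).max()
        assert scale > 0  # A must actually fire and drive B
        assert np.abs(contrib.values - direct.values).max() / scale < 1e-9

    def test_grid_mismatch_rejected(self, linear_toy):
        net = linear_toy["net"]
        other = SignalTrace(net.time[:-1], net.values[:-1])
        with pytest.raises(ValueError):
            presynaptic_contribution(net, other)


class TestPathwayAndPostsynaptic:
    def test_pathways_partition_presynaptic(self, linear_toy):
        toy = linear_toy
        c = toy["circuit"]
        plan = ReplayPlan.excluding(c, toy["spikes"], "A")
        dec = _decoupled_trace(toy, plan)
        pre = presynaptic_contribution(toy["net"], dec)
        total = np.zeros_like(pre.values)
        for pop in ("A", "B"):
            total += pathway_contribution(toy["net"], dec, c.population(pop).ids).values
        scale = max(np.abs(pre.values).max(), 1e-30)
        assert np.abs(total - pre.values).max() / scale < 1e-12

    def test_pathway_to_unconnected_population_is_zero(self, linear_toy):
        # A projects only to B; the A->A pathway reflects only A's own
        # (absent) afferent currents from A
        toy = linear_toy
        c = toy["circuit"]
        plan = ReplayPlan.excluding(c, toy["spikes"], "B")
        dec = _decoupled_trace(toy, plan)
        pw = pathway_contribution(toy["net"], dec, c.population("A").ids)
        assert np.abs(pw.values).max() < 1e-15

    def test_postsynaptic_union_equals_total(self, linear_toy):
        net = linear_toy["net"]
        c = linear_toy["circuit"]
        s = np.zeros_like(net.values)
        for pop in ("A", "B"):
            s += postsynaptic_contribution(net, c.population(pop).ids).values
        scale = max(np.abs(net.values).max(), 1e-30)
        assert np.abs(s - net.values).max() / scale < 1e-12

    def test_postsynaptic_matches_brute_force_sum(self, linear_toy):
        net = linear_toy["net"]
        c = linear_toy["circuit"]
        ids = c.population("B").ids
        brute = net.contributions[:, np.isin(net.neuron_ids, ids)].sum(axis=1)
        tr = postsynaptic_contribution(net, ids)
        assert np.allclose(tr.values, brute, rtol=0, atol=0)

    def test_unknown_population_rejected(self, linear_toy):
        with pytest.raises(KeyError):
            linear_toy["circuit"].population("NOPE")


class TestThalamic:
    def test_pure_thalamocortical_circuit_thalamic_equals_total(self):
        cfg = linear_toy_config()
        cfg["connections"] = [r for r in cfg["connections"] if r["pre"] == "THAL"]
        c = build_circuit(cfg, seed=4)
        stim = StimulusSpec.default(
            n_fibers=10, active_fraction=0.5, n_stimuli=1, isi=60.0, baseline=0.0
        )
        thal = generate_thalamic_spikes(stim, 4, c.fiber_ids, 10.0, 80.0)
        sim = SimParams(t_stop=80.0)
        w = circuit_eeg_weights(c, EEG)
        spikes, rep = simulate_connected(c, thal, 4, sim)
        net = compute_signal(rep, w)
        plan = ReplayPlan.without_thalamus(c, spikes)
        _, rep_nt = simulate_decoupled(c, plan, thal, 4, sim)
        contrib = thalamic_contribution(net, compute_signal(rep_nt, w))
        scale = np.abs(net.values).max()
        assert scale > 0
        assert np.abs(contrib.values - net.values).max() / scale < 1e-12


class TestLinearSum:
    def _full_set(self, linear_toy):
        toy = linear_toy
        c = toy["circuit"]
        cs = ContributionSet(total=toy["net"])
        for pop in ("A", "B"):
            plan = ReplayPlan.excluding(c, toy["spikes"], pop)
            cs.presynaptic[pop] = presynaptic_contribution(
                toy["net"], _decoupled_trace(toy, plan)
            )
        plan = ReplayPlan.without_thalamus(c, toy["spikes"])
        cs.thalamic = thalamic_contribution(toy["net"], _decoupled_trace(toy, plan))
        return cs

    def test_exact_on_linear_circuit(self, linear_toy):
        metric, resid = validate_linear_sum(self._full_set(linear_toy))
        assert metric < 1e-6

    def test_white_noise_residual_closed_form(self, linear_toy):
        cs = self._full_set(linear_toy)
        rng = np.random.default_rng(0)
        eps = 0.05
        rms = np.sqrt(np.mean(cs.total.values**2))
        noise = rng.standard_normal(len(cs.total.values))
        noise *= eps * rms / np.sqrt(np.mean(noise**2))
        cs.thalamic = cs.thalamic.copy_with(values=cs.thalamic.values - noise)
        metric, _ = validate_linear_sum(cs)
        assert abs(metric - eps) / eps < 1e-6

    def test_sum_equals_total_by_construction(self):
        t = 0.1 * np.arange(100)
        a = SignalTrace(t, np.sin(t))
        b = SignalTrace(t, np.cos(t))
        total = SignalTrace(t, a.values + b.values)
        cs = ContributionSet(total=total, presynaptic={"A": a}, thalamic=b)
        metric, _ = validate_linear_sum(cs)
        assert metric < 1e-15


class TestBandPower:
    def test_high_frequency_residual_detected(self):
        t = 0.1 * np.arange(2048)  # fs = 10 kHz
        slow = SignalTrace(t, np.sin(2 * np.pi * 20 * t * 1e-3))
        fast = SignalTrace(t, np.sin(2 * np.pi * 800 * t * 1e-3))
        assert band_power_ratio(slow, 100.0) < 0.1
        assert band_power_ratio(fast, 100.0) > 10.0
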