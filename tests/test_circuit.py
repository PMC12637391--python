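"""Synthetic circuit generation: determinism, placement laws, stimulus."""

import numpy as np
import pytest
from scipy import stats

from sepsim import (
    StimulusSpec,
    assign_axonal_delays,
    ball_and_stick,
    build_circuit,
    generate_thalamic_spikes,
    place_synapses,
    soma_only,
)
from sepsim.circuit import CircuitModel, Morphology

from conftest import tiny_spiking_config


def two_pop_config(n=10, p=0.0):
    return {
        "layers": {"L5": [600.0, 900.0]},
        "populations": {
            "A": {
                "layer": "L5",
                "syn_class": "EXC",
                "count": n,
                "depth": [650.0, 850.0],
                "morphology": {"type": "ball_and_stick", "dendrite_length": 300.0},
            },
            "B": {"layer": "L5", "syn_class": "INH", "count": n, "depth": [650.0, 850.0]},
        },
        "connections": [{"pre": "A", "post": "B", "p": p, "gmax": 1.0}],
        "noise": {"mean": 0.0},
    }


class TestMorphology:
    def test_ball_and_stick_is_a_rooted_chain(self):
        m = ball_and_stick(dendrite_length=500.0, n_dendrite_segments=5)
        assert m.n_segments == 6
        comp = m.compartments()
        assert np.array_equal(comp["parent"], np.arange(-1, 5))
        assert comp["is_soma"][0] and not comp["is_soma"][1:].any()
        assert np.all(comp["length"] > 0) and np.all(comp["radius"] > 0)

    def test_path_distance_increases_along_dendrite(self):
        m = ball_and_stick(dendrite_length=500.0, n_dendrite_segments=5)
        d = m.path_distance()
        assert d[0] == 0.0
        assert np.all(np.diff(d[1:]) > 0)

    def test_invalid_trees_rejected(self):
        with pytest.raises(ValueError):
            Morphology(
                np.zeros((2, 3)),
                np.ones((2, 3)),
                np.array([1.0, 1.0]),
                np.array([-1, -1]),  # two roots
            )
        with pytest.raises(ValueError):
            Morphology(
                np.zeros((1, 3)), np.zeros((1, 3)), np.array([1.0]), np.array([-1])
            )  # zero length


class TestBuildCircuit:
    def test_zero_probability_gives_no_synapses(self):
        c = build_circuit(two_pop_config(p=0.0), seed=0)
        assert len(c.synapses) == 0
        assert c.n_neurons == 20

    def test_determinism_bitwise(self):
        cfg = tiny_spiking_config()
        a = build_circuit(cfg, seed=3)
        b = build_circuit(cfg, seed=3)
        for f in ("pre", "post", "segment", "offset", "gmax", "delay"):
            assert np.array_equal(getattr(a.synapses, f), getattr(b.synapses, f))
        assert np.array_equal(a.soma_position, b.soma_position, equal_nan=True)

    def test_synapse_count_matches_bernoulli_law(self):
        cfg = two_pop_config(n=50, p=0.1)
        c = build_circuit(cfg, seed=7)
        mean, sd = 250.0, np.sqrt(2500 * 0.1 * 0.9)
        assert abs(len(c.synapses) - mean) < 4 * sd

    def test_population_counts_and_errors(self):
        cfg = two_pop_config()
        cfg["populations"]["A"]["count"] = 0
        with pytest.raises(ValueError):
            build_circuit(cfg, seed=0)
        cfg = two_pop_config()
        cfg["connections"] = [{"pre": "A", "post": "B", "p": 0.5, "placement": "nope"}]
        with pytest.raises(ValueError):
            build_circuit(cfg, seed=0)

    def test_hdf5_round_trip(self, tmp_path, tiny_circuit):
        path = tmp_path / "circuit.h5"
        tiny_circuit.to_hdf5(path)
        back = CircuitModel.from_hdf5(path)
        assert back.n_neurons == tiny_circuit.n_neurons
        assert np.array_equal(back.synapses.pre, tiny_circuit.synapses.pre)
        assert np.array_equal(back.synapses.delay, tiny_circuit.synapses.delay)
        assert np.array_equal(
            back.soma_position, tiny_circuit.soma_position, equal_nan=True
        )
        assert back.noise.scale == tiny_circuit.noise.scale


class TestPlacement:
    def test_zero_count_empty(self):
        assert place_synapses(ball_and_stick(), 0, "distributed", seed=0) == []

    def test_perisomatic_respects_distance_bound(self):
        m = ball_and_stick(dendrite_length=500.0, n_dendrite_segments=10)
        dist = m.path_distance()
        placements = place_synapses(m, 200, "perisomatic", seed=1)
        for seg, _ in placements:
            comp_idx = m.compartments()["first_comp"][seg]
            assert dist[comp_idx] <= 50.0

    def test_perisomatic_unreachable_raises(self):
        # the soma sits at path distance zero, so only a negative bound can
        # exclude every compartment — the degenerate error branch
        m = ball_and_stick(soma_radius=8.0, dendrite_length=500.0, n_dendrite_segments=2)
        with pytest.raises(ValueError):
            place_synapses(m, 1, "perisomatic", seed=0, perisomatic_radius=-1.0)

    def test_distributed_follows_area_law(self):
        # two equal-area dendrite compartments: counts ~ Binomial(n, share)
        m = ball_and_stick(dendrite_length=200.0, n_dendrite_segments=2)
        comp = m.compartments()
        share = comp["area"] / comp["area"].sum()
        n = 10_000
        placements = place_synapses(m, n, "distributed", seed=5)
        segs = np.array([s for s, _ in placements])
        counts = np.bincount(segs, minlength=3)
        d1, d2 = counts[1], counts[2]
        n_dend = d1 + d2
        sd = np.sqrt(n_dend * 0.25)
        assert abs(d1 - d2) < 4 * sd
        # goodness of fit across all three compartments at alpha = 0.001
        chi2 = stats.chisquare(counts, share * n).pvalue
        assert chi2 > 0.001


class TestThalamicSpikes:
    def test_active_fiber_count_exact(self):
        spec = StimulusSpec.default(n_fibers=100, active_fraction=0.1, n_stimuli=1, baseline=0.0)
        rec = generate_thalamic_spikes(spec, seed=2, t_stop=100.0)
        assert len(np.unique(rec.ids)) <= 10  # at most the 10 chosen fibers fire
        # with a strong PSTH every chosen fiber fires with high probability
        spec = StimulusSpec(
            np.array([0.0, 50.0]), np.array([200.0]), n_fibers=100,
            active_fraction=0.1, n_stimuli=1, baseline_rate=0.0,
        )
        rec = generate_thalamic_spikes(spec, seed=2, t_stop=100.0)
        assert len(np.unique(rec.ids)) == 10

    def test_all_zero_psth_empty(self):
        spec = StimulusSpec(
            np.array([0.0, 10.0]), np.array([0.0]), n_fibers=10,
            active_fraction=0.5, n_stimuli=1, baseline_rate=0.0,
        )
        assert len(generate_thalamic_spikes(spec, seed=0, t_stop=50.0)) == 0

    def test_empty_psth_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(np.array([0.0]), np.array([]))

    def test_poisson_mean_count(self):
        # 100 Hz for 50 ms on 10 active fibers -> 50 expected spikes
        spec = StimulusSpec(
            np.array([0.0, 50.0]), np.array([100.0]), n_fibers=20,
            active_fraction=0.5, n_stimuli=1, baseline_rate=0.0,
        )
        counts = [
            len(generate_thalamic_spikes(spec, seed=s, stim_start=0.0, t_stop=60.0))
            for s in range(200)
        ]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 50.0) < 3 * max(se, 1e-9)

    def test_spikes_sorted_and_repeat_per_stimulus(self):
        spec = StimulusSpec.default(n_fibers=50, active_fraction=0.2, n_stimuli=2, isi=100.0)
        rec = generate_thalamic_spikes(spec, seed=4, stim_start=10.0, t_stop=230.0)
        assert np.all(np.diff(rec.times) >= 0)
        in_first = ((rec.times > 10) & (rec.times < 40)).sum()
        in_second = ((rec.times > 110) & (rec.times < 140)).sum()
        assert in_first > 0 and in_second > 0

    def test_text_round_trip(self, tmp_path):
        spec = StimulusSpec.default(n_fibers=20, active_fraction=0.5, n_stimuli=1)
        rec = generate_thalamic_spikes(spec, seed=1, t_stop=80.0)
        path = tmp_path / "spikes.txt"
        rec.to_text(path)
        back = type(rec).from_text(path)
        assert np.array_equal(back.ids, rec.ids)
        assert np.allclose(back.times, rec.times, atol=1e-6)


class TestAxonalDelays:
    def test_closed_form_and_base_delay(self, tiny_circuit):
        # synthetic check: distance 900 µm at 300 µm/ms plus 1 ms base -> 4 ms
        assert 1.0 + 900.0 / 300.0 == 4.0
        c = assign_axonal_delays(tiny_circuit, base_delay=1.0, velocity=300.0)
        syn = c.synapses
        thal_mask = np.isin(syn.pre, c.fiber_ids)
        from sepsim.circuit import synapse_positions

        z = synapse_positions(c)[:, 2]
        expected = 1.0 + (c.l6_bottom - z[thal_mask]) / 300.0
        assert np.allclose(syn.delay[thal_mask], expected)
        # synapse exactly at the L6 bottom would get exactly the base delay
        assert np.all(syn.delay[thal_mask] >= 1.0)

    def test_monotone_in_depth(self, tiny_circuit):
        c = assign_axonal_delays(tiny_circuit, base_delay=1.0, velocity=300.0)
        syn = c.synapses
        thal = np.isin(syn.pre, c.fiber_ids)
        from sepsim.circuit import synapse_positions

        z = synapse_positions(c)[:, 2][thal]
        d = syn.delay[thal]
        order = np.argsort(z)
        # deeper synapse (larger z) never has a larger delay
        assert np.all(np.diff(d[order]) <= 1e-12)

    def test_velocity_validation(self, tiny_circuit):
        with pytest.raises(ValueError):
            assign_axonal_delays(tiny_circuit, velocity=0.0)
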