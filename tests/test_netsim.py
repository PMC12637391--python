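"""Engine properties: conservation, reproducibility, replay identity, noise."""

import numpy as np
import pytest

from sepsim import SimParams, ou_noise_stream, simulate_connected, simulate_decoupled
from sepsim.circuit import SpikeRecord, build_circuit
from sepsim.netsim import ReplayPlan

from conftest import tiny_spiking_config


class TestQuietCircuit:
    def test_no_input_means_no_spikes_and_zero_currents(self):
        cfg = tiny_spiking_config()
        cfg["noise"]["mean"] = 0.0
        cfg["spike"] = {"mode": "none"}
        c = build_circuit(cfg, seed=1)
        spikes, rep = simulate_connected(c, SpikeRecord.empty(), 1, SimParams(t_stop=30.0))
        assert len(spikes) == 0
        # uniform rest potential: axial currents identically zero from the start
        assert np.abs(rep.currents).max() < 1e-12

    def test_quiet_eif_circuit_stays_silent(self):
        # the subthreshold exponential leaves a sub-µA standing dipole but
        # must not fire without input
        cfg = tiny_spiking_config()
        cfg["noise"]["mean"] = 0.0
        c = build_circuit(cfg, seed=1)
        spikes, rep = simulate_connected(c, SpikeRecord.empty(), 1, SimParams(t_stop=30.0))
        assert len(spikes) == 0
        assert np.abs(rep.currents).max() < 1e-5


class TestChargeConservation:
    def test_per_neuron_sum_below_tolerance(self, tiny_run):
        rep = tiny_run["report"]
        n_comp = rep.currents.shape[1]
        tol = 1e-9 * n_comp
        assert np.abs(rep.neuron_sum()).max() < tol


class TestReproducibility:
    def test_same_seed_bitwise_identical(self, tiny_circuit, tiny_run):
        spikes2, rep2 = simulate_connected(
            tiny_circuit, tiny_run["thalamic"], 11, tiny_run["sim"]
        )
        assert np.array_equal(spikes2.ids, tiny_run["spikes"].ids)
        assert np.array_equal(spikes2.times, tiny_run["spikes"].times)
        assert np.array_equal(rep2.currents, tiny_run["report"].currents)

    def test_different_seed_differs(self, tiny_circuit, tiny_run):
        spikes2, _ = simulate_connected(
            tiny_circuit, tiny_run["thalamic"], 12, tiny_run["sim"]
        )
        assert not (
            len(spikes2) == len(tiny_run["spikes"])
            and np.array_equal(spikes2.times, tiny_run["spikes"].times)
        )


class TestSingleNeuronOracle:
    def test_synaptic_onset_and_depolarisation_match_reference(self):
        """One ball-and-stick cell, one synapse at t=10 ms with 2 ms delay:
        conductance turns on at 12 ms and the somatic response matches an
        independent stiff-ODE integration of the same cable equation."""
        cfg = {
            "layers": {"L5": [600.0, 900.0]},
            "populations": {
                "P": {
                    "layer": "L5",
                    "syn_class": "EXC",
                    "count": 1,
                    "depth": [700.0, 700.0001],
                    "morphology": {
                        "type": "ball_and_stick",
                        "dendrite_length": 200.0,
                        "n_dendrite_segments": 2,
                    },
                },
                "THAL": {"layer": "THAL", "syn_class": "fiber", "count": 1},
            },
            "connections": [
                {"pre": "THAL", "post": "P", "p": 1.0, "gmax": 2.0, "e_rev": 0.0,
                 "tau": 2.0, "delay": 2.0, "p_release": 1.0, "placement": "perisomatic"}
            ],
            "noise": {"mean": 0.0},
            "spike": {"mode": "none"},
            "delays": {"base": 2.0, "velocity": 1e12},  # effectively constant 2 ms
        }
        c = build_circuit(cfg, seed=0)
        thal = SpikeRecord(np.array([1]), np.array([10.0]))
        sim = SimParams(t_stop=40.0, record_v=True)
        spikes, rep = simulate_connected(c, thal, 0, sim)
        v = rep.voltages[:, 0]
        t = rep.time
        # quiescent before onset at 12 ms (one step of delivery lag allowed)
        assert np.all(np.abs(v[t <= 12.0] - (-65.0)) < 1e-9)
        assert v[t >= 13.0].max() > -64.0

        # independent reference: dense ODE integration of the same cable
        from scipy.integrate import solve_ivp
        from sepsim.netsim import compartment_frame

        frame = compartment_frame(c, sim.ra)
        M = frame.n_comp
        gl, cm, ga = frame.gl_uS, frame.cm_nF, frame.ga_uS
        syn = c.synapses
        comp_syn = 0  # perisomatic placement on a 200 µm cable: the soma
        gmax, tau, e_rev = syn.gmax[0] * 1e-3, syn.tau[0], syn.e_rev[0]
        onset = 10.0 + syn.delay[0]

        A = np.zeros((M, M))
        for i in range(1, M):
            A[i, i - 1] += ga[i]
            A[i - 1, i] += ga[i]
            A[i, i] -= ga[i]
            A[i - 1, i - 1] -= ga[i]

        def rhs(tt, vv):
            g_syn = gmax * np.exp(-(tt - onset) / tau) if tt >= onset else 0.0
            i_ion = gl * (vv - (-65.0))
            i_ion[comp_syn] += g_syn * (vv[comp_syn] - e_rev)
            return (-i_ion + A @ vv) / cm

        ref = solve_ivp(
            rhs, (0.0, 40.0), np.full(M, -65.0), t_eval=t, rtol=1e-9, atol=1e-10,
            max_step=0.25,
        )
        v_ref = ref.y[0]
        peak = v.max() - (-65.0)
        peak_ref = v_ref.max() - (-65.0)
        assert peak_ref > 0.5  # the stimulus is not trivial
        assert abs(peak - peak_ref) / peak_ref < 0.02
        assert abs(t[np.argmax(v)] - ref.t[np.argmax(v_ref)]) < 0.5


class TestDecoupledReplay:
    def test_replay_all_reproduces_connected_currents(self, tiny_circuit, tiny_run):
        plan = ReplayPlan.all(tiny_circuit, tiny_run["spikes"])
        _, rep_d = simulate_decoupled(
            tiny_circuit, plan, tiny_run["thalamic"], 11, tiny_run["sim"]
        )
        dev = np.abs(rep_d.currents - tiny_run["report"].currents).max()
        assert dev < 1e-6

    def test_excluded_population_without_efferents_changes_nothing(self):
        cfg = tiny_spiking_config()
        # make L5E a sink: remove its efferent synapses
        cfg["connections"] = [r for r in cfg["connections"] if r["pre"] != "L5E"]
        c = build_circuit(cfg, seed=5)
        from sepsim import StimulusSpec, generate_thalamic_spikes

        stim = StimulusSpec.default(n_fibers=20, active_fraction=0.2, n_stimuli=1, isi=60.0)
        thal = generate_thalamic_spikes(stim, 5, c.fiber_ids, 15.0, 60.0)
        sim = SimParams(t_stop=60.0)
        spikes, rep = simulate_connected(c, thal, 5, sim)
        plan = ReplayPlan.excluding(c, spikes, "L5E")
        _, rep_d = simulate_decoupled(c, plan, thal, 5, sim)
        assert np.abs(rep_d.currents - rep.currents).max() < 1e-9

    def test_intrinsic_spikes_recorded_but_not_transmitted(self, tiny_circuit, tiny_run):
        # replaying only thalamus: cortical cells still fire (recorded), but
        # removing e.g. the inhibitory population's replay must not silence them
        plan = ReplayPlan.excluding(tiny_circuit, tiny_run["spikes"], "L5I")
        spikes_d, _ = simulate_decoupled(
            tiny_circuit, plan, tiny_run["thalamic"], 11, tiny_run["sim"]
        )
        assert len(spikes_d) > 0

    def test_replay_validation_errors(self, tiny_circuit, tiny_run):
        bad = ReplayPlan(SpikeRecord(np.array([10_000]), np.array([1.0])))
        with pytest.raises(ValueError):
            simulate_decoupled(
                tiny_circuit, bad, tiny_run["thalamic"], 11, tiny_run["sim"]
            )
        late = ReplayPlan(SpikeRecord(np.array([0]), np.array([1e6])))
        with pytest.raises(ValueError):
            simulate_decoupled(
                tiny_circuit, late, tiny_run["thalamic"], 11, tiny_run["sim"]
            )
        with pytest.raises(KeyError):
            ReplayPlan.excluding(tiny_circuit, tiny_run["spikes"], "NOPE")


class TestOUNoise:
    def test_zero_ratio_constant(self):
        x = ou_noise_stream(10.0, 0.0, 3.0, 0.1, 1000, (1, 2))
        assert np.all(x == 10.0)

    def test_sd_over_mean_near_configured_ratio(self):
        x = ou_noise_stream(10.0, 0.4, 3.0, 0.1, 1_000_000, (7, 0))
        ratio = x.std() / x.mean()
        assert 0.38 < ratio < 0.42

    def test_lag_tau_autocorrelation(self):
        tau, dt = 3.0, 0.1
        x = ou_noise_stream(100.0, 0.1, tau, dt, 500_000, (3, 1))  # mild ratio: no clipping
        lag = int(tau / dt)
        xc = x - x.mean()
        r = (xc[:-lag] * xc[lag:]).mean() / xc.var()
        assert abs(r - np.exp(-1)) < 0.02

    def test_same_key_identical_and_validation(self):
        a = ou_noise_stream(5.0, 0.4, 3.0, 0.1, 1000, (9, 9))
        b = ou_noise_stream(5.0, 0.4, 3.0, 0.1, 1000, (9, 9))
        assert np.array_equal(a, b)
        assert a.min() >= 0.0
        with pytest.raises(ValueError):
            ou_noise_stream(5.0, 0.4, 3.0, 5.0, 10, (0, 0))  # dt >= tau


class TestReportIO:
    def test_currents_report_round_trip(self, tmp_path, tiny_run):
        rep = tiny_run["report"]
        path = tmp_path / "currents.h5"
        rep.to_hdf5(path)
        back = type(rep).from_hdf5(path)
        assert np.array_equal(back.currents, rep.currents)
        assert np.array_equal(back.offsets, rep.offsets)
        assert np.array_equal(back.comp_neuron, rep.comp_neuron)
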