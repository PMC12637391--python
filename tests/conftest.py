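"""Shared fixtures: tiny circuits that exercise every stage quickly."""

from __future__ import annotations

import numpy as np
import pytest

from sepsim import StimulusSpec, build_circuit, generate_thalamic_spikes
from sepsim.netsim import SimParams, simulate_connected


def tiny_spiking_config(n_e: int = 12, n_i: int = 4, n_fibers: int = 20) -> dict:
    """Two-layer spiking circuit: thalamus -> L5E (+ L5I -> L5E inhibition)."""
    return {
        "layers": {"L23": [100.0, 400.0], "L5": [600.0, 900.0], "L6": [900.0, 1150.0]},
        "column_annulus": [20.0, 120.0],
        "populations": {
            "L5E": {
                "layer": "L5",
                "syn_class": "EXC",
                "count": n_e,
                "depth": [650.0, 850.0],
                "morphology": {
                    "type": "ball_and_stick",
                    "dendrite_length": 500.0,
                    "n_dendrite_segments": 6,
                },
            },
            "L5I": {"layer": "L5", "syn_class": "PeriTC", "count": n_i, "depth": [650.0, 850.0]},
            "THAL": {"layer": "THAL", "syn_class": "fiber", "count": n_fibers},
        },
        "connections": [
            {"pre": "THAL", "post": "L5E", "p": 0.4, "gmax": 1.5, "tau": 2.0, "placement": "perisomatic", "p_release": 0.9},
            {"pre": "THAL", "post": "L5I", "p": 0.5, "gmax": 1.8, "tau": 2.0, "p_release": 0.9},
            {"pre": "L5I", "post": "L5E", "p": 0.5, "gmax": 3.0, "e_rev": -80.0, "tau": 8.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "L5E", "post": "L5I", "p": 0.3, "gmax": 1.0, "tau": 2.0, "p_release": 0.9},
        ],
        "noise": {"mean": 1.2, "ratio": 0.4, "tau": 3.0, "scale": {"L5E": 0.7, "L5I": 0.085}},
        "delays": {"base": 1.0, "velocity": 300.0},
        "spike": {"mode": "eif"},
        "stimulus": {"n_fibers": n_fibers, "active_fraction": 0.1, "n_stimuli": 1, "isi": 60.0},
        "stim_start": 15.0,
    }


@pytest.fixture(scope="session")
def tiny_circuit():
    return build_circuit(tiny_spiking_config(), seed=11)


@pytest.fixture(scope="session")
def tiny_run(tiny_circuit):
    """One connected trial of the tiny circuit (spikes, currents report)."""
    stim = StimulusSpec.default(
        n_fibers=20, active_fraction=0.1, n_stimuli=1, isi=60.0
    )
    thal = generate_thalamic_spikes(stim, 11, tiny_circuit.fiber_ids, 15.0, 70.0)
    sim = SimParams(t_stop=70.0)
    spikes, report = simulate_connected(tiny_circuit, thal, 11, sim)
    return {"stim": stim, "thalamic": thal, "sim": sim, "spikes": spikes, "report": report}
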