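"""Default desk-scale circuit configurations.

The default circuit is a ~240-neuron stand-in for a cortical column:
layered excitatory populations with ball-and-stick morphologies (apical
cable toward the pia), soma-only interneurons, and 100 virtual thalamic
fibers.  Thalamocortical excitation onto L2/3 and L5 pyramidal stand-ins
is placed perisomatically (deep current sink, superficial return source —
a positive surface deflection), while thalamic synapses onto L6 cells are
distributed over the apical cable (negative, slow deflection); recurrent
L5 inhibition carries the bulk of the N1.  The Schneider-Mizell-style
variant differs only in the placement profile of the L5 perisomatic
targeting cells' synapses onto L5 pyramidal cells.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["default_config", "sm_variant", "load_config", "dump_config"]


def default_config() -> dict:
    """Desk-scale spiking column emulating the study conditions."""
    return {
        "layers": {
            "L1": [0.0, 100.0],
            "L23": [100.0, 400.0],
            "L4": [400.0, 600.0],
            "L5": [600.0, 900.0],
            "L6": [900.0, 1150.0],
        },
        "column_annulus": [20.0, 250.0],
        "populations": {
            "L23E": {
                "layer": "L23",
                "syn_class": "EXC",
                "count": 50,
                "depth": [250.0, 380.0],
                "morphology": {
                    "type": "ball_and_stick",
                    "dendrite_length": 220.0,
                    "n_dendrite_segments": 5,
                },
            },
            "L23I": {"layer": "L23", "syn_class": "INH", "count": 10, "depth": [150.0, 380.0]},
            "L4E": {
                "layer": "L4",
                "syn_class": "EXC",
                "count": 35,
                "depth": [420.0, 580.0],
                "morphology": {
                    "type": "ball_and_stick",
                    "dendrite_length": 250.0,
                    "n_dendrite_segments": 5,
                },
            },
            "L4I": {"layer": "L4", "syn_class": "INH", "count": 8, "depth": [420.0, 580.0]},
            "L5E": {
                "layer": "L5",
                "syn_class": "EXC",
                "count": 50,
                "depth": [650.0, 850.0],
                "morphology": {
                    "type": "ball_and_stick",
                    "dendrite_length": 550.0,
                    "n_dendrite_segments": 7,
                },
            },
            "L5I": {"layer": "L5", "syn_class": "PeriTC", "count": 12, "depth": [620.0, 880.0]},
            "L6E": {
                "layer": "L6",
                "syn_class": "EXC",
                "count": 35,
                "depth": [950.0, 1100.0],
                "morphology": {
                    "type": "ball_and_stick",
                    "dendrite_length": 500.0,
                    "n_dendrite_segments": 6,
                },
            },
            "L6I": {"layer": "L6", "syn_class": "INH", "count": 8, "depth": [950.0, 1100.0]},
            "THAL": {"layer": "THAL", "syn_class": "fiber", "count": 100},
        },
        "connections": [
            # thalamocortical excitation (10 active fibers per stimulus;
            # convergence chosen so target cells receive ~4-8 evoked events)
            {"pre": "THAL", "post": "L23E", "p": 0.35, "gmax": 1.3, "e_rev": 0.0, "tau": 2.0, "placement": "perisomatic", "p_release": 0.9},
            {"pre": "THAL", "post": "L4E", "p": 0.40, "gmax": 1.2, "e_rev": 0.0, "tau": 2.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "THAL", "post": "L5E", "p": 0.50, "gmax": 1.5, "e_rev": 0.0, "tau": 2.0, "placement": "perisomatic", "p_release": 0.9},
            {"pre": "THAL", "post": "L6E", "p": 0.45, "gmax": 1.6, "e_rev": 0.0, "tau": 6.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "THAL", "post": "L5I", "p": 0.50, "gmax": 1.4, "e_rev": 0.0, "tau": 2.0, "p_release": 0.9},
            {"pre": "THAL", "post": "L4I", "p": 0.35, "gmax": 1.2, "e_rev": 0.0, "tau": 2.0, "p_release": 0.9},
            {"pre": "THAL", "post": "L23I", "p": 0.30, "gmax": 1.2, "e_rev": 0.0, "tau": 2.0, "p_release": 0.9},
            {"pre": "THAL", "post": "L6I", "p": 0.35, "gmax": 1.2, "e_rev": 0.0, "tau": 2.0, "p_release": 0.9},
            # recurrent excitation
            {"pre": "L4E", "post": "L23E", "p": 0.05, "gmax": 0.9, "e_rev": 0.0, "tau": 2.0, "placement": "distributed", "p_release": 0.8},
            {"pre": "L23E", "post": "L5E", "p": 0.05, "gmax": 0.9, "e_rev": 0.0, "tau": 2.0, "placement": "distributed", "p_release": 0.8},
            {"pre": "L5E", "post": "L5E", "p": 0.06, "gmax": 0.9, "e_rev": 0.0, "tau": 2.0, "placement": "distributed", "p_release": 0.8},
            {"pre": "L4E", "post": "L4E", "p": 0.05, "gmax": 0.8, "e_rev": 0.0, "tau": 2.0, "placement": "distributed", "p_release": 0.8},
            {"pre": "L6E", "post": "L6E", "p": 0.04, "gmax": 0.8, "e_rev": 0.0, "tau": 2.0, "placement": "distributed", "p_release": 0.8},
            # excitation of interneurons
            {"pre": "L5E", "post": "L5I", "p": 0.10, "gmax": 1.0, "e_rev": 0.0, "tau": 2.0, "p_release": 0.8},
            {"pre": "L23E", "post": "L23I", "p": 0.08, "gmax": 1.0, "e_rev": 0.0, "tau": 2.0, "p_release": 0.8},
            {"pre": "L6E", "post": "L6I", "p": 0.08, "gmax": 1.0, "e_rev": 0.0, "tau": 2.0, "p_release": 0.8},
            # inhibition (slow decay sustains the N1)
            {"pre": "L5I", "post": "L5E", "p": 0.30, "gmax": 5.0, "e_rev": -80.0, "tau": 9.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "L6I", "post": "L5E", "p": 0.10, "gmax": 2.5, "e_rev": -80.0, "tau": 9.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "L6I", "post": "L6E", "p": 0.20, "gmax": 3.0, "e_rev": -80.0, "tau": 8.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "L23I", "post": "L23E", "p": 0.20, "gmax": 3.0, "e_rev": -80.0, "tau": 8.0, "placement": "distributed", "p_release": 0.9},
            {"pre": "L4I", "post": "L4E", "p": 0.20, "gmax": 3.0, "e_rev": -80.0, "tau": 8.0, "placement": "distributed", "p_release": 0.9},
        ],
        "noise": {
            "mean": 1.2,  # nS; sd/mean fixed at 0.4
            "ratio": 0.4,
            "tau": 3.0,
            "e_rev": 0.0,
            # per-population multipliers calibrated for low spontaneous
            # rates (~1-5 Hz) so the response is stimulus-locked
            "scale": {
                "L23E": 0.33,
                "L4E": 0.38,
                "L5E": 0.72,
                "L6E": 0.68,
                "L23I": 0.085,
                "L4I": 0.085,
                "L5I": 0.085,
                "L6I": 0.085,
            },
        },
        "delays": {"base": 1.0, "velocity": 300.0},
        "spike": {"mode": "eif"},
        "stimulus": {
            "peak_rate": 300.0,
            "center": 5.0,
            "sigma": 2.0,
            "baseline": 0.5,
            "n_fibers": 100,
            "active_fraction": 0.1,
            "n_stimuli": 2,
            "isi": 150.0,
        },
        "recording": {
            "eeg_position": [0.0, 0.0, -2000.0],
            "eeg_reference": None,
            "sigma": 0.3,
            "lfp_depths": [40.0 + 80.0 * k for k in range(15)],
        },
        "stim_start": 40.0,
        "post_window": 100.0,
    }


def sm_variant(config: dict | None = None) -> dict:
    """Perisomatic-targeting rewiring of the L5 PeriTC -> L5E pathway."""
    cfg = copy.deepcopy(config if config is not None else default_config())
    for rule in cfg["connections"]:
        if rule["pre"] == "L5I" and rule["post"] == "L5E":
            rule["placement"] = "perisomatic"
    return cfg


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
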