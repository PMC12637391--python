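"""Simulation campaigns: trials, decoupled-run scheduling and reports.

A campaign runs ``n_trials`` trials.  Each trial simulates the connected
circuit with a fresh thalamic stimulus and noise seed, then one decoupled
replay per decomposition target plus a thalamus-silenced replay; traces
are post-processed (second-stimulus extraction, band-pass, trial average)
and combined into a :class:`~sepsim.decomposition.ContributionSet` with
SEP features and summary reports.  Trial seeds are ``base_seed + trial``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuit import CircuitModel, SpikeRecord, StimulusSpec, build_circuit, generate_thalamic_spikes
from .decomposition import (
    ContributionSet,
    pathway_contribution,
    postsynaptic_contribution,
    presynaptic_contribution,
    thalamic_contribution,
    validate_linear_sum,
)
from .features import SEPFeatures, sep_features
from .leadfield import ElectrodeSpec, circuit_eeg_weights
from .netsim import ReplayPlan, SimParams, simulate_connected, simulate_decoupled
from .signals import SignalTrace, average_traces, compute_signal, postprocess_sep

__all__ = ["CampaignSpec", "CampaignResult", "run_campaign", "export_reports"]


@dataclass
class CampaignSpec:
    """Everything needed to reproduce a campaign."""

    config: dict
    n_trials: int = 10  # trials per campaign, each with its own seed
    base_seed: int = 0
    targets: list[str] = field(default_factory=list)  # populations to decouple
    filter: tuple[int, float, float] | None = (2, 1.0, 500.0)
    pre_ms: float = 10.0
    post_ms: float = 100.0
    postsyn_populations: list[str] | None = None

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class CampaignResult:
    contributions: ContributionSet
    features: SEPFeatures
    residual_metric: float
    residual: SignalTrace
    manifest: dict
    circuit: CircuitModel
    spikes: list[SpikeRecord]
    n_simulations: int
    trial_totals: list[SignalTrace] = field(default_factory=list)


def _stimulus_from_config(cfg: dict) -> StimulusSpec:
    sc = dict(cfg.get("stimulus", {}))
    return StimulusSpec.default(
        peak_rate=sc.get("peak_rate", 300.0),
        center=sc.get("center", 5.0),
        sigma=sc.get("sigma", 2.0),
        baseline=sc.get("baseline", 0.5),
        n_fibers=sc.get("n_fibers", 100),
        active_fraction=sc.get("active_fraction", 0.1),
        n_stimuli=sc.get("n_stimuli", 2),
        isi=sc.get("isi", 150.0),
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_campaign(spec: CampaignSpec) -> CampaignResult:
    """Run a full decomposition campaign; deterministic given the spec."""
    cfg = spec.config
    circuit = build_circuit(cfg, seed=spec.base_seed)
    for target in spec.targets:
        circuit.population(target)  # raise early for unknown targets

    stim = _stimulus_from_config(cfg)
    stim_start = float(cfg.get("stim_start", 40.0))
    t_stop = stim_start + stim.n_stimuli * stim.isi + 10.0
    sim = SimParams(t_stop=t_stop)
    rec = cfg.get("recording", {})
    espec = ElectrodeSpec(
        tuple(rec.get("eeg_position", (0.0, 0.0, -2000.0))),
        None if rec.get("eeg_reference") is None else tuple(rec["eeg_reference"]),
        rec.get("sigma", 0.3),
    )
    weights = circuit_eeg_weights(circuit, espec)
    stim_times = stim_start + np.arange(stim.n_stimuli) * stim.isi

    def post(trace):
        return postprocess_sep(
            trace, stim_times, spec.filter, which_stimulus=min(2, stim.n_stimuli),
            pre_ms=spec.pre_ms, post_ms=spec.post_ms,
        )

    nets, decs, nothal, all_spikes = [], {t: [] for t in spec.targets}, [], []
    n_sims = 0
    for trial in range(spec.n_trials):
        trial_seed = spec.base_seed + trial
        thal = generate_thalamic_spikes(
            stim, trial_seed, circuit.fiber_ids, stim_start=stim_start, t_stop=t_stop
        )
        spikes, report = simulate_connected(circuit, thal, trial_seed, sim)
        n_sims += 1
        all_spikes.append(spikes)
        nets.append(post(compute_signal(report, weights)))
        for target in spec.targets:
            plan = ReplayPlan.excluding(circuit, spikes, target)
            _, rep_d = simulate_decoupled(circuit, plan, thal, trial_seed, sim)
            n_sims += 1
            decs[target].append(post(compute_signal(rep_d, weights)))
        plan = ReplayPlan.without_thalamus(circuit, spikes)
        _, rep_nt = simulate_decoupled(circuit, plan, thal, trial_seed, sim)
        n_sims += 1
        nothal.append(post(compute_signal(rep_nt, weights)))

    total = average_traces(nets)
    members = circuit.membership()
    post_pops = spec.postsyn_populations or circuit.population_names(spiking_only=True)

    contribs = ContributionSet(total=total)
    for target in spec.targets:
        per_trial = [presynaptic_contribution(n, d) for n, d in zip(nets, decs[target])]
        contribs.presynaptic[target] = average_traces(per_trial)
        for post_pop in post_pops:
            per_trial_pw = [
                pathway_contribution(n, d, members[post_pop])
                for n, d in zip(nets, decs[target])
            ]
            contribs.pathway[(target, post_pop)] = average_traces(per_trial_pw)
    contribs.thalamic = average_traces(
        [thalamic_contribution(n, d) for n, d in zip(nets, nothal)]
    )
    for post_pop in post_pops:
        contribs.postsynaptic[post_pop] = postsynaptic_contribution(total, members[post_pop])

    feats = sep_features(total)
    if set(spec.targets) >= set(circuit.population_names(spiking_only=True)):
        residual_metric, residual = validate_linear_sum(contribs)
    else:  # partial target list: residual against the decomposed subset only
        residual_metric, residual = float("nan"), SignalTrace(
            total.time, np.zeros_like(total.values), meta={"kind": "residual"}
        )

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "base_seed": spec.base_seed,
        "trial_seeds": [spec.base_seed + k for k in range(spec.n_trials)],
        "n_trials": spec.n_trials,
        "targets": list(spec.targets),
        "filter": list(spec.filter) if spec.filter else None,
        "n_simulations": n_sims,
        "stimulus_times_ms": [float(t) for t in stim_times],
    }
    return CampaignResult(
        contribs, feats, residual_metric, residual, manifest, circuit, all_spikes,
        n_sims, nets,
    )


def export_reports(result: CampaignResult, out_dir, formats=("hdf5", "csv")) -> list[Path]:
    """Write trace containers, summary CSVs and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    c = result.contributions

    if "hdf5" in formats:
        import h5py

        path = out / "contributions.h5"
        if path.exists():
            path.unlink()
        with h5py.File(path, "w") as f:

            def put(group, name, tr):
                g = f.require_group(group).create_group(name)
                g.create_dataset("time", data=tr.time, track_times=False)
                g.create_dataset("data", data=tr.values, track_times=False)

            put("contributions", "total", c.total)
            for pop, tr in c.presynaptic.items():
                put("contributions/pre", pop, tr)
            for (pre, post_pop), tr in c.pathway.items():
                put("contributions/pathway", f"{pre}__{post_pop}", tr)
            for pop, tr in c.postsynaptic.items():
                put("contributions/post", pop, tr)
            if c.thalamic is not None:
                put("contributions", "thalamic", c.thalamic)
        written.append(path)

    if "csv" in formats:
        rows = []

        def summarise(kind, name, tr):
            rows.append(
                {
                    "kind": kind,
                    "population": name,
                    "peak": tr.values.max(),
                    "trough": tr.values.min(),
                    "peak_to_peak": tr.values.max() - tr.values.min(),
                }
            )

        summarise("total", "ALL", c.total)
        for pop, tr in c.presynaptic.items():
            summarise("presynaptic", pop, tr)
        for (pre, post_pop), tr in c.pathway.items():
            summarise("pathway", f"{pre}->{post_pop}", tr)
        for pop, tr in c.postsynaptic.items():
            summarise("postsynaptic", pop, tr)
        if c.thalamic is not None:
            summarise("thalamic", "THAL", c.thalamic)
        path = out / "contributions_summary.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10e")
        written.append(path)

        f = result.features
        path = out / "features.csv"
        pd.DataFrame([vars(f)]).to_csv(path, index=False, float_format="%.10e")
        written.append(path)

    path = out / "manifest.json"
    path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
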