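"""Network simulation: membrane dynamics and transmembrane-current reports.

The engine integrates passive multicompartment cables (chains: soma plus a
single apical cable, or soma only) with an exponential integrate-and-fire
spike mechanism at the soma, single-exponential synapses (conductance- or
current-based), and Ornstein-Uhlenbeck conductance noise.  A fixed-step
implicit-Euler update (default 0.025 ms) solves the cable equation per
neuron via a vectorised Thomas algorithm; transmembrane currents are
reported on a coarser grid (default 0.1 ms).

Reported transmembrane currents are the net axial inflow per compartment,
which by Kirchhoff's law equals the total (capacitive + ionic) membrane
current and sums to exactly zero over each neuron — the charge-conservation
property that makes the EEG gauge freedom exact.

Two modes are supported:

* **connected** — spikes generated during the run are transmitted through
  efferent synapses after their axonal delay;
* **decoupled replay** — efferent synapses are driven only by a recorded
  spike train played back at the original times; spikes generated during
  the run are recorded but never transmitted.  All stochastic outcomes
  (noise path, release outcomes) are preserved between the two modes for
  the same trial seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .circuit import CircuitModel, SpikeRecord, SYN_CONDUCTANCE
from .streams import counter_uniform, philox_generator, sequential_indices

__all__ = [
    "SimParams",
    "CurrentsReport",
    "ReplayPlan",
    "simulate_connected",
    "simulate_decoupled",
    "ou_noise_stream",
]

_OU_TAG = 0xA0


@dataclass(frozen=True)
class SimParams:
    t_stop: float  # ms
    dt: float = 0.025  # ms, integration step
    report_dt: float = 0.1  # ms, current-report step
    ra: float = 150.0  # Ohm cm, axial resistivity
    record_v: bool = False

    def __post_init__(self):
        k = self.report_dt / self.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError("report_dt must be an integer multiple of dt")


@dataclass
class CurrentsReport:
    """Per-compartment transmembrane currents (nA) on a fixed time grid."""

    time: np.ndarray  # (T,) ms
    currents: np.ndarray  # (T, M) nA
    neuron_ids: np.ndarray  # (N,) global ids of reported neurons
    offsets: np.ndarray  # (N+1,) compartment ranges per neuron
    voltages: np.ndarray | None = None  # (T, N) somatic potentials, optional

    @property
    def comp_neuron(self) -> np.ndarray:
        """Global neuron id owning each compartment column."""
        counts = np.diff(self.offsets)
        return np.repeat(self.neuron_ids, counts)

    def neuron_sum(self) -> np.ndarray:
        """Per-neuron sum of compartment currents at every step (≈ 0)."""
        return np.add.reduceat(self.currents, self.offsets[:-1], axis=1)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("report")
            g.create_dataset("time", data=self.time, track_times=False)
            g.create_dataset("currents", data=self.currents, track_times=False)
            g.create_dataset("node_ids", data=self.neuron_ids, track_times=False)
            g.create_dataset("index_pointers", data=self.offsets, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "CurrentsReport":
        with h5py.File(path, "r") as f:
            g = f["report"]
            return cls(g["time"][()], g["currents"][()], g["node_ids"][()], g["index_pointers"][()])


@dataclass
class ReplayPlan:
    """What to play into a decoupled simulation.

    ``replay`` holds the recorded spikes to be re-injected through efferent
    synapses; ``excluded`` names the population whose efferents stay silent
    (its spikes must not appear in ``replay``); ``include_thalamic``
    controls whether the thalamic stimulus drives its synapses.  Intrinsic
    spikes are never transmitted in a decoupled run.
    """

    replay: SpikeRecord
    excluded: str | None = None
    include_thalamic: bool = True

    @classmethod
    def all(cls, circuit: CircuitModel, spikes: SpikeRecord) -> "ReplayPlan":
        return cls(spikes.select(circuit.cortical_ids), None, True)

    @classmethod
    def excluding(cls, circuit: CircuitModel, spikes: SpikeRecord, population: str) -> "ReplayPlan":
        pop = circuit.population(population)  # raises for unknown names
        keep = spikes.select(circuit.cortical_ids).drop(pop.ids)
        return cls(keep, population, True)

    @classmethod
    def without_thalamus(cls, circuit: CircuitModel, spikes: SpikeRecord) -> "ReplayPlan":
        return cls(spikes.select(circuit.cortical_ids), None, False)

    def validate(self, circuit: CircuitModel, t_stop: float) -> None:
        if self.excluded is not None:
            circuit.population(self.excluded)
        known = np.concatenate([p.ids for p in circuit.populations])
        if len(self.replay) and not np.isin(self.replay.ids, known).all():
            raise ValueError("replay spike references unknown neuron")
        if len(self.replay) and (
            self.replay.times.min() < 0 or self.replay.times.max() > t_stop
        ):
            raise ValueError("replay time outside simulation window")


def ou_noise_stream(
    mean: float,
    ratio: float,
    tau: float,
    dt: float,
    n_steps: int,
    stream_key: tuple,
) -> np.ndarray:
    """Exact-discretisation Ornstein-Uhlenbeck conductance series (nS).

    Stationary mean ``mean`` and standard deviation ``ratio * mean``;
    negative excursions are clipped at zero.  The same ``stream_key``
    always reproduces the same series.
    """
    if mean < 0 or ratio < 0:
        raise ValueError("mean and ratio must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt >= tau:
        raise ValueError("dt must be smaller than the correlation time")
    if ratio == 0:
        return np.full(n_steps, float(mean))
    from scipy.signal import lfilter

    rng = np.random.Generator(np.random.Philox(key=np.asarray(stream_key, dtype=np.uint64)))
    alpha = np.exp(-dt / tau)
    sigma = ratio * mean
    eps = rng.standard_normal(n_steps) * (sigma * np.sqrt(1 - alpha**2))
    x = lfilter([1.0], [1.0, -alpha], eps) + mean
    return np.clip(x, 0.0, None)


# ---------------------------------------------------------------------------
# compartment frame


@dataclass
class _Frame:
    neuron_ids: np.ndarray  # cortical ids, ascending
    offsets: np.ndarray  # (N+1,)
    center: np.ndarray  # (M, 3) µm
    start: np.ndarray
    end: np.ndarray
    radius: np.ndarray
    length: np.ndarray
    is_soma: np.ndarray
    neuron_of: np.ndarray  # (M,) position in neuron_ids
    cm_nF: np.ndarray
    gl_uS: np.ndarray
    ga_uS: np.ndarray  # coupling to previous compartment (0 at roots)
    groups: dict  # n_comp -> (neuron_rows, comp index matrix)
    soma_comp: np.ndarray  # (N,) soma compartment per neuron
    seg_first_comp: list  # per neuron, segment -> first compartment (global)

    @property
    def n_comp(self) -> int:
        return len(self.center)


_FRAMES: dict[int, _Frame] = {}


def compartment_frame(circuit: CircuitModel, ra: float = 150.0) -> _Frame:
    key = (id(circuit), ra)
    if key in _FRAMES:
        return _FRAMES[key]
    ids = circuit.cortical_ids
    p = circuit.passive
    centers, starts, ends, radii, lengths, soma_mask = [], [], [], [], [], []
    cm, gl, ga, neuron_of = [], [], [], []
    offsets = [0]
    soma_comp = []
    seg_first = []
    for row, nid in enumerate(ids):
        m = circuit.morphology_of(int(nid))
        comp = m.compartments()
        pos = circuit.soma_position[nid]
        n = len(comp["length"])
        if np.any(comp["parent"] != np.arange(-1, n - 1)):
            raise ValueError("engine requires chain morphologies (soma + single cable)")
        centers.append(comp["center"] + pos)
        starts.append(comp["start"] + pos)
        ends.append(comp["end"] + pos)
        radii.append(comp["radius"])
        lengths.append(comp["length"])
        soma_mask.append(comp["is_soma"])
        area_cm2 = comp["area"] * 1e-8  # µm² -> cm²
        cm.append(p.cm * area_cm2 * 1e3)  # µF -> nF
        gl.append(p.g_pas * area_cm2 * 1e6)  # S -> µS
        # half-cylinder series resistance to the parent compartment
        r_half = ra * (comp["length"] * 1e-4 / 2) / (np.pi * (comp["radius"] * 1e-4) ** 2)
        g = np.zeros(n)
        g[1:] = 1.0 / (r_half[1:] + r_half[:-1]) * 1e6  # S -> µS
        ga.append(g)
        neuron_of.append(np.full(n, row))
        soma_comp.append(offsets[-1] + int(np.flatnonzero(comp["is_soma"])[0]))
        seg_first.append(offsets[-1] + comp["first_comp"])
        offsets.append(offsets[-1] + n)
    offsets = np.asarray(offsets)
    counts = np.diff(offsets)
    groups = {}
    for c in np.unique(counts):
        rows = np.flatnonzero(counts == c)
        cidx = offsets[rows][:, None] + np.arange(c)[None, :]
        groups[int(c)] = (rows, cidx)
    frame = _Frame(
        ids,
        offsets,
        np.vstack(centers),
        np.vstack(starts),
        np.vstack(ends),
        np.concatenate(radii),
        np.concatenate(lengths),
        np.concatenate(soma_mask),
        np.concatenate(neuron_of),
        np.concatenate(cm),
        np.concatenate(gl),
        np.concatenate(ga),
        groups,
        np.asarray(soma_comp),
        seg_first,
    )
    if len(_FRAMES) > 16:
        _FRAMES.clear()
    _FRAMES[key] = frame
    return frame


# ---------------------------------------------------------------------------
# engine


def _spike_waveform(amp: float, duration: float, dt: float) -> np.ndarray:
    """Biphasic somatic spike current: fast inward peak, slower outward tail."""
    t = np.arange(0.0, duration, dt)
    wave = np.sin(np.pi * t / duration) * np.sin(2 * np.pi * t / duration)
    return -amp * wave  # first lobe inward (depolarising upstroke)


def _events_from_spikes(
    spikes: SpikeRecord,
    syn_by_pre: tuple[np.ndarray, np.ndarray, np.ndarray],
    delay_steps: np.ndarray,
    dt: float,
    n_steps: int,
):
    """Expand a spike record into (event_step, synapse) arrays."""
    uniq, indptr, syn_sorted = syn_by_pre
    if len(uniq) == 0 or len(spikes) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    pos = np.searchsorted(uniq, spikes.ids)
    valid = (pos < len(uniq)) & (uniq[np.minimum(pos, len(uniq) - 1)] == spikes.ids)
    pos, times = pos[valid], spikes.times[valid]
    counts = indptr[pos + 1] - indptr[pos]
    starts = np.repeat(indptr[pos], counts)
    within = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    syns = syn_sorted[starts + within]
    steps = np.repeat(np.round(times / dt).astype(np.int64), counts) + delay_steps[syns]
    keep = steps < n_steps
    return steps[keep], syns[keep]


def _bucket(steps: np.ndarray, syns: np.ndarray) -> dict[int, list[np.ndarray]]:
    sched: dict[int, list[np.ndarray]] = {}
    if len(steps) == 0:
        return sched
    order = np.argsort(steps, kind="stable")
    steps, syns = steps[order], syns[order]
    bounds = np.flatnonzero(np.r_[True, steps[1:] != steps[:-1]])
    for b, e in zip(bounds, np.r_[bounds[1:], len(steps)]):
        sched.setdefault(int(steps[b]), []).append(syns[b:e])
    return sched


def _simulate(
    circuit: CircuitModel,
    sim: SimParams,
    trial_seed: int,
    thalamic: SpikeRecord | None,
    replay: SpikeRecord | None,
    transmit: bool,
    include_thalamic: bool = True,
) -> tuple[SpikeRecord, CurrentsReport]:
    frame = compartment_frame(circuit, sim.ra)
    dt = sim.dt
    n_steps = int(round(sim.t_stop / dt))
    report_every = int(round(sim.report_dt / dt))
    n_rep = n_steps // report_every
    M = frame.n_comp
    N = len(frame.neuron_ids)
    p = circuit.passive
    spk = circuit.spike

    # synapse arrays -> global compartment index of each synapse
    syn = circuit.synapses
    n_syn = len(syn)
    id_to_row = {int(g): r for r, g in enumerate(frame.neuron_ids)}
    syn_comp = np.zeros(n_syn, dtype=np.int64)
    for j in range(n_syn):
        row = id_to_row[int(syn.post[j])]
        syn_comp[j] = frame.seg_first_comp[row][syn.segment[j]]
    decay = np.exp(-dt / syn.tau) if n_syn else np.zeros(0)
    delay_steps = np.round(syn.delay / dt).astype(np.int64) if n_syn else np.zeros(0, dtype=np.int64)
    cond_mask = syn.kind == SYN_CONDUCTANCE
    g_state = np.zeros(n_syn)  # nS -> stored in µS via 1e-3 at add time
    i_state = np.zeros(n_syn)  # nA

    # efferent CSR over synapses sorted by presynaptic id
    if n_syn:
        order = np.argsort(syn.pre, kind="stable")
        uniq, first = np.unique(syn.pre[order], return_index=True)
        indptr = np.r_[first, n_syn]
        syn_by_pre = (uniq, indptr, order)
    else:
        syn_by_pre = (np.zeros(0, dtype=np.int64), np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64))

    # static event schedule: thalamic stimulus and/or replayed spikes
    static_steps, static_syns = [], []
    if thalamic is not None and include_thalamic and len(thalamic):
        s, y = _events_from_spikes(thalamic, syn_by_pre, delay_steps, dt, n_steps)
        static_steps.append(s)
        static_syns.append(y)
    if replay is not None and len(replay):
        s, y = _events_from_spikes(replay, syn_by_pre, delay_steps, dt, n_steps)
        static_steps.append(s)
        static_syns.append(y)
    schedule = _bucket(
        np.concatenate(static_steps) if static_steps else np.zeros(0, dtype=np.int64),
        np.concatenate(static_syns) if static_syns else np.zeros(0, dtype=np.int64),
    )

    # noise: one standard-normal vector per step regardless of activity,
    # so the path is identical between connected and decoupled runs
    noise = circuit.noise
    pop_of = circuit.population_of()
    noise_mean = np.array(
        [noise.mean * noise.scale.get(pop_of[int(g)], 1.0) for g in frame.neuron_ids]
    )
    use_noise = noise_mean.max(initial=0.0) > 0
    if use_noise:
        if noise.ratio > 0 and dt >= noise.tau:
            raise ValueError("dt must be smaller than the noise correlation time")
        rng_ou = philox_generator(trial_seed, _OU_TAG)
        alpha = np.exp(-dt / noise.tau)
        beta = np.sqrt(1 - alpha**2)
        sigma = noise.ratio * noise_mean
        x_ou = noise_mean.copy()

    # spike bookkeeping
    wave = _spike_waveform(spk.spike_current, spk.spike_duration, dt)
    spike_phase = np.full(N, -1, dtype=np.int64)
    refract_until = np.full(N, -1.0)
    prev_above = np.zeros(N, dtype=bool)
    ev_counter = np.zeros(n_syn, dtype=np.int64)

    V = np.full(M, p.e_pas)
    a_coef = dt / frame.cm_nF
    gl = frame.gl_uS
    ga = frame.ga_uS
    soma = frame.soma_comp
    gl_soma = gl[soma]
    currents = np.empty((n_rep, M))
    volt = np.empty((n_rep, N)) if sim.record_v else None
    rep_time = np.empty(n_rep)
    spikes_out_id, spikes_out_t = [], []

    # per-group views for the tridiagonal solve
    groups = []
    for c, (rows, cidx) in frame.groups.items():
        gam = ga[cidx]
        up = np.zeros_like(gam)
        up[:, :-1] = gam[:, 1:]
        groups.append((c, rows, cidx, gam, up))

    parent_idx = np.arange(M) - 1
    roots = frame.offsets[:-1]
    parent_idx[roots] = -1
    has_parent = parent_idx >= 0

    rep_i = 0
    for step in range(n_steps):
        t = (step + 1) * dt
        # --- synaptic state decay and event delivery
        if n_syn:
            g_state *= decay
            i_state *= decay
            batch = schedule.pop(step, None)
            if batch is not None:
                syns = np.concatenate(batch)
                k = sequential_indices(syns, ev_counter)
                u = counter_uniform(trial_seed, syns, k)
                released = u < syn.p_release[syns]
                hits = syns[released]
                np.add.at(g_state, hits[cond_mask[hits]], syn.gmax[hits[cond_mask[hits]]])
                np.add.at(i_state, hits[~cond_mask[hits]], syn.gmax[hits[~cond_mask[hits]]])
            g_comp = np.bincount(syn_comp, weights=g_state, minlength=M) * 1e-3  # nS->µS
            ge_comp = np.bincount(syn_comp, weights=g_state * syn.e_rev, minlength=M) * 1e-3
            i_comp = np.bincount(syn_comp, weights=i_state, minlength=M)
        else:
            g_comp = ge_comp = i_comp = 0.0

        g_extra = np.zeros(M)
        rhs_extra = np.zeros(M)
        if n_syn:
            g_extra += g_comp
            rhs_extra += ge_comp + i_comp
        # --- OU noise at the soma
        if use_noise:
            x_ou = noise_mean + (x_ou - noise_mean) * alpha + sigma * beta * rng_ou.standard_normal(N)
            g_ou = np.clip(x_ou, 0.0, None) * 1e-3  # nS -> µS
            g_extra[soma] += g_ou
            rhs_extra[soma] += g_ou * noise.e_rev
        # --- somatic spike mechanism currents (treated as ionic)
        if spk.mode == "eif":
            vs = V[soma]
            i_exp = gl_soma * spk.delta_t * np.exp(
                np.clip((vs - spk.v_thresh) / spk.delta_t, -50.0, 20.0)
            )
            # cap the explicit exponential drive at 50 mV of depolarisation
            # per step; the upstroke is cut at v_cut by the reset anyway
            np.minimum(i_exp, 50.0 * frame.cm_nF[soma] / dt, out=i_exp)
            i_exp[t < refract_until] = 0.0  # no regenerative drive while refractory
            rhs_extra[soma] += i_exp
            active = spike_phase >= 0
            if active.any():
                rhs_extra[soma[active]] -= wave[spike_phase[active]]
                spike_phase[active] += 1
                spike_phase[spike_phase >= len(wave)] = -1

        # --- implicit Euler cable solve (Thomas, vectorised per group)
        for c, rows, cidx, gam, up in groups:
            a = a_coef[cidx]
            diag = 1.0 + a * (gl[cidx] + g_extra[cidx] + gam + up)
            b = V[cidx] + a * (gl[cidx] * p.e_pas + rhs_extra[cidx])
            if c == 1:
                V[cidx[:, 0]] = b[:, 0] / diag[:, 0]
                continue
            lower = -a * gam
            upper = -a * up
            d = diag.copy()
            for i in range(1, c):
                w = lower[:, i] / d[:, i - 1]
                d[:, i] -= w * upper[:, i - 1]
                b[:, i] -= w * b[:, i - 1]
            x_last = b[:, c - 1] / d[:, c - 1]
            V[cidx[:, c - 1]] = x_last
            prev = x_last
            for i in range(c - 2, -1, -1):
                prev = (b[:, i] - upper[:, i] * prev) / d[:, i]
                V[cidx[:, i]] = prev

        # --- spike detection
        fired = np.zeros(N, dtype=bool)
        if spk.mode == "eif":
            fired = (V[soma] > spk.v_cut) & (t >= refract_until)
            if fired.any():
                rows_f = np.flatnonzero(fired)
                V[soma[rows_f]] = spk.v_reset
                spike_phase[rows_f] = 0
                refract_until[rows_f] = t + spk.t_ref
        elif spk.mode == "detector":
            above = V[soma] > spk.v_thresh
            fired = above & ~prev_above & (t >= refract_until)
            refract_until[fired] = t + spk.t_ref
            prev_above = above
        if fired.any():
            rows_f = np.flatnonzero(fired)
            gids = frame.neuron_ids[rows_f]
            t_spk = step * dt  # grid-aligned so replay reproduces delivery steps
            spikes_out_id.append(gids)
            spikes_out_t.append(np.full(len(gids), t_spk))
            if transmit:
                if len(gids):
                    rec = SpikeRecord(gids, np.full(len(gids), t_spk))
                    s, y = _events_from_spikes(rec, syn_by_pre, delay_steps, dt, n_steps)
                    for st, sy in _bucket(s, y).items():
                        schedule.setdefault(st, []).extend(sy)

        if not np.all(np.abs(V) < 500.0):
            raise RuntimeError(f"unstable integration: |V| diverged at t={t:.3f} ms")

        # --- report
        if (step + 1) % report_every == 0:
            flow = np.zeros(M)
            flow[has_parent] = ga[has_parent] * (
                V[parent_idx[has_parent]] - V[has_parent]
            )
            im = flow.copy()
            np.subtract.at(im, parent_idx[has_parent], flow[has_parent])
            currents[rep_i] = im
            rep_time[rep_i] = t
            if volt is not None:
                volt[rep_i] = V[soma]
            rep_i += 1

    spikes = (
        SpikeRecord(np.concatenate(spikes_out_id), np.concatenate(spikes_out_t))
        if spikes_out_id
        else SpikeRecord.empty()
    )
    report = CurrentsReport(rep_time, currents, frame.neuron_ids, frame.offsets, volt)
    return spikes, report


def simulate_connected(
    circuit: CircuitModel,
    thalamic: SpikeRecord | None,
    trial_seed: int,
    sim: SimParams,
) -> tuple[SpikeRecord, CurrentsReport]:
    """Run the fully connected circuit driven by a thalamic spike record."""
    return _simulate(circuit, sim, trial_seed, thalamic, None, transmit=True)


def simulate_decoupled(
    circuit: CircuitModel,
    plan: ReplayPlan,
    thalamic: SpikeRecord | None,
    trial_seed: int,
    sim: SimParams,
) -> tuple[SpikeRecord, CurrentsReport]:
    """Run the decoupled circuit: recorded spikes drive efferent synapses at
    their original times, intrinsic spikes are recorded but not transmitted."""
    plan.validate(circuit, sim.t_stop)
    return _simulate(
        circuit,
        sim,
        trial_seed,
        thalamic,
        plan.replay,
        transmit=False,
        include_thalamic=plan.include_thalamic,
    )
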