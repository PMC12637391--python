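"""Synthetic cortical-column circuits.

Generates small, statistically controlled stand-in circuits with the
structure the downstream analysis assumes: layered excitatory/inhibitory
populations (L1..L6) plus virtual thalamic fibers, simplified morphologies
(ball-and-stick pyramidal stand-ins, soma-only interneurons), pathway
specific synapse placement (distributed over the dendritic membrane versus
perisomatic), distance-dependent axonal delays for thalamocortical
synapses, and a stimulus-locked thalamic spike generator.

Coordinate frame: ``z`` is depth in micrometres, 0 at the pia, increasing
downward.  Ball-and-stick apical dendrites therefore extend in ``-z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import h5py
import numpy as np

from .streams import substream

__all__ = [
    "Morphology",
    "ball_and_stick",
    "soma_only",
    "Population",
    "SynapseTable",
    "PassiveParams",
    "SpikeParams",
    "NoiseParams",
    "StimulusSpec",
    "SpikeRecord",
    "CircuitModel",
    "build_circuit",
    "place_synapses",
    "generate_thalamic_spikes",
    "assign_axonal_delays",
]

SYN_CONDUCTANCE = 0
SYN_CURRENT = 1


# ---------------------------------------------------------------------------
# morphologies


@dataclass(frozen=True)
class Morphology:
    """Piecewise-cylindrical neuron shape in a soma-centred local frame.

    ``proximal``/``distal`` are (S, 3) endpoint arrays in micrometres,
    ``radius`` the cylinder radii, ``parent`` the index of each segment's
    parent (-1 for the soma root).  ``n_compartments`` allows segments to be
    subdivided into equal electrical compartments; the builders in this
    module emit one compartment per segment.
    """

    proximal: np.ndarray
    distal: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    soma_index: int = 0
    n_compartments: np.ndarray | None = None

    def __post_init__(self):
        prox = np.atleast_2d(np.asarray(self.proximal, dtype=float))
        dist = np.atleast_2d(np.asarray(self.distal, dtype=float))
        rad = np.asarray(self.radius, dtype=float)
        par = np.asarray(self.parent, dtype=np.int64)
        ncomp = (
            np.ones(len(rad), dtype=np.int64)
            if self.n_compartments is None
            else np.asarray(self.n_compartments, dtype=np.int64)
        )
        object.__setattr__(self, "proximal", prox)
        object.__setattr__(self, "distal", dist)
        object.__setattr__(self, "radius", rad)
        object.__setattr__(self, "parent", par)
        object.__setattr__(self, "n_compartments", ncomp)
        if np.count_nonzero(par < 0) != 1 or par[self.soma_index] != -1:
            raise ValueError("morphology must have exactly one root at the soma")
        if np.any(par >= np.arange(len(par))):
            raise ValueError("parents must precede children (tree order)")
        if np.any(self.segment_length <= 0) or np.any(rad <= 0):
            raise ValueError("segment lengths and radii must be positive")
        if np.any(ncomp < 1):
            raise ValueError("n_compartments must be >= 1")

    @property
    def n_segments(self) -> int:
        return len(self.radius)

    @property
    def segment_length(self) -> np.ndarray:
        return np.linalg.norm(self.distal - self.proximal, axis=1)

    def compartments(self):
        """Flatten segments into compartments.

        Returns a dict with ``center`` (C, 3), ``start``/``end`` (C, 3),
        ``length``, ``radius``, ``parent`` (compartment index, -1 at root),
        ``segment`` (owning segment), ``is_soma`` and lateral membrane
        ``area`` in µm² (the spherical soma is represented as an
        equal-area cylinder).
        """
        centers, starts, ends, lengths, radii = [], [], [], [], []
        parents, segment_of, is_soma = [], [], []
        first_comp = np.zeros(self.n_segments, dtype=np.int64)
        last_comp = np.zeros(self.n_segments, dtype=np.int64)
        idx = 0
        for s in range(self.n_segments):
            n = int(self.n_compartments[s])
            first_comp[s] = idx
            p, d = self.proximal[s], self.distal[s]
            for k in range(n):
                a = p + (d - p) * (k / n)
                b = p + (d - p) * ((k + 1) / n)
                starts.append(a)
                ends.append(b)
                centers.append(0.5 * (a + b))
                lengths.append(np.linalg.norm(b - a))
                radii.append(self.radius[s])
                segment_of.append(s)
                is_soma.append(s == self.soma_index)
                if k == 0:
                    par_seg = self.parent[s]
                    parents.append(-1 if par_seg < 0 else int(last_comp[par_seg]))
                else:
                    parents.append(idx - 1)
                idx += 1
            last_comp[s] = idx - 1
        out = {
            "center": np.array(centers),
            "start": np.array(starts),
            "end": np.array(ends),
            "length": np.array(lengths),
            "radius": np.array(radii),
            "parent": np.array(parents, dtype=np.int64),
            "segment": np.array(segment_of, dtype=np.int64),
            "is_soma": np.array(is_soma, dtype=bool),
            "first_comp": first_comp,
        }
        out["area"] = 2.0 * np.pi * out["radius"] * out["length"]
        return out

    def path_distance(self) -> np.ndarray:
        """Path distance (µm) from the soma centre to each compartment centre."""
        comp = self.compartments()
        dist = np.zeros(len(comp["length"]))
        for i in range(len(dist)):
            p = comp["parent"][i]
            if p < 0:
                dist[i] = 0.0
            else:
                dist[i] = dist[p] + 0.5 * comp["length"][p] + 0.5 * comp["length"][i]
        return dist


def ball_and_stick(
    soma_radius: float = 8.0,
    dendrite_length: float = 400.0,
    dendrite_radius: float = 1.5,
    n_dendrite_segments: int = 5,
    direction: Sequence[float] = (0.0, 0.0, -1.0),
) -> Morphology:
    """Soma plus a single apical cable, the minimal dipole-forming shape."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    prox = [(0.0, 0.0, -soma_radius)]
    dist = [(0.0, 0.0, soma_radius)]
    radius = [soma_radius]
    parent = [-1]
    step = dendrite_length / n_dendrite_segments
    for k in range(n_dendrite_segments):
        prox.append(tuple(u * (k * step)))
        dist.append(tuple(u * ((k + 1) * step)))
        radius.append(dendrite_radius)
        parent.append(k)  # segment 0 is the soma
    return Morphology(np.array(prox), np.array(dist), np.array(radius), np.array(parent))


def soma_only(radius: float = 8.0) -> Morphology:
    return Morphology(
        np.array([[0.0, 0.0, -radius]]),
        np.array([[0.0, 0.0, radius]]),
        np.array([radius]),
        np.array([-1]),
    )


# ---------------------------------------------------------------------------
# circuit containers


@dataclass(frozen=True)
class Population:
    name: str
    layer: str  # L1..L6 or THAL
    syn_class: str  # EXC | INH | PeriTC | fiber
    ids: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=np.int64))


@dataclass
class SynapseTable:
    """Struct-of-arrays synapse list."""

    pre: np.ndarray
    post: np.ndarray
    segment: np.ndarray
    offset: np.ndarray
    gmax: np.ndarray  # nS (conductance kind) or nA (current kind)
    e_rev: np.ndarray  # mV (unused for current kind)
    tau: np.ndarray  # ms
    delay: np.ndarray  # ms
    p_release: np.ndarray
    kind: np.ndarray  # SYN_CONDUCTANCE | SYN_CURRENT

    def __len__(self):
        return len(self.pre)

    @classmethod
    def empty(cls) -> "SynapseTable":
        z = np.zeros(0)
        zi = np.zeros(0, dtype=np.int64)
        return cls(zi, zi, zi, z, z, z, z, z, z, np.zeros(0, dtype=np.int8))

    @classmethod
    def concatenate(cls, tables: Sequence["SynapseTable"]) -> "SynapseTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls.empty()
        return cls(*[np.concatenate([getattr(t, f) for t in tables]) for f in _SYN_FIELDS])


_SYN_FIELDS = (
    "pre",
    "post",
    "segment",
    "offset",
    "gmax",
    "e_rev",
    "tau",
    "delay",
    "p_release",
    "kind",
)


@dataclass(frozen=True)
class PassiveParams:
    cm: float = 1.0  # µF/cm²
    g_pas: float = 5e-5  # S/cm²  (membrane time constant 20 ms)
    e_pas: float = -65.0  # mV


@dataclass(frozen=True)
class SpikeParams:
    """Spike mechanism at the soma.

    ``mode``: 'eif' (exponential integrate-and-fire with reset and a
    stereotyped 1 ms somatic spike-current waveform), 'detector' (threshold
    crossings are recorded but do not alter the passive dynamics — used for
    exactly linear test circuits), or 'none'.
    """

    mode: str = "eif"
    v_thresh: float = -50.0  # mV, EIF rheobase threshold / detector level
    delta_t: float = 2.0  # mV, EIF spike sharpness
    v_cut: float = -30.0  # mV, detection level for the EIF upstroke
    v_reset: float = -65.0
    t_ref: float = 2.5  # ms
    spike_current: float = 1.5  # nA, peak of the somatic spike waveform
    spike_duration: float = 1.0  # ms


@dataclass(frozen=True)
class NoiseParams:
    """Ornstein-Uhlenbeck conductance noise injected at every soma."""

    mean: float = 0.0  # nS
    ratio: float = 0.4  # sd / mean
    tau: float = 3.0  # ms
    e_rev: float = 0.0  # mV
    scale: Mapping[str, float] = field(default_factory=dict)  # per-population multiplier


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus-locked thalamic firing description.

    The PSTH is piecewise constant on ``bin_edges`` (ms, relative to each
    stimulus onset) with ``rates`` in Hz.  Each stimulus activates exactly
    ``round(active_fraction * n_fibers)`` fibers; all fibers additionally
    fire at ``baseline_rate`` throughout the simulation.
    """

    bin_edges: np.ndarray
    rates: np.ndarray
    n_fibers: int = 100
    active_fraction: float = 0.1
    n_stimuli: int = 2
    isi: float = 150.0  # ms between stimulus onsets
    baseline_rate: float = 0.5  # Hz

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "rates", rates)
        if len(rates) == 0:
            raise ValueError("empty PSTH")
        if len(edges) != len(rates) + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must bracket rates and increase")
        if np.any(rates < 0):
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active fraction must be in [0, 1]")

    @staticmethod
    def default(
        peak_rate: float = 300.0,
        center: float = 5.0,
        sigma: float = 2.0,
        baseline: float = 0.5,
        **kwargs,
    ) -> "StimulusSpec":
        """Baseline + Gaussian-bump PSTH on 1 ms bins over 0..25 ms."""
        edges = np.arange(0.0, 26.0, 1.0)
        mid = 0.5 * (edges[:-1] + edges[1:])
        rates = baseline + peak_rate * np.exp(-0.5 * ((mid - center) / sigma) ** 2)
        return StimulusSpec(edges, rates, baseline_rate=baseline, **kwargs)


@dataclass
class SpikeRecord:
    """Spike times (ms) with their emitting neuron/fiber ids, time-sorted."""

    ids: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        order = np.argsort(self.times, kind="stable")
        self.ids = self.ids[order]
        self.times = self.times[order]

    def __len__(self):
        return len(self.ids)

    @classmethod
    def empty(cls) -> "SpikeRecord":
        return cls(np.zeros(0, dtype=np.int64), np.zeros(0))

    def select(self, ids: np.ndarray) -> "SpikeRecord":
        mask = np.isin(self.ids, np.asarray(ids))
        return SpikeRecord(self.ids[mask], self.times[mask])

    def drop(self, ids: np.ndarray) -> "SpikeRecord":
        mask = ~np.isin(self.ids, np.asarray(ids))
        return SpikeRecord(self.ids[mask], self.times[mask])

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.ids, self.times]), fmt="%d %.6f")

    @classmethod
    def from_text(cls, path) -> "SpikeRecord":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            return cls.empty()
        return cls(data[:, 0].astype(np.int64), data[:, 1])

    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset("ids", data=self.ids, track_times=False)
        group.create_dataset("times", data=self.times, track_times=False)

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "SpikeRecord":
        return cls(group["ids"][()], group["times"][()])


@dataclass
class CircuitModel:
    """Populations, morphologies, synapses and simulation parameters."""

    populations: list[Population]
    morphology_index: np.ndarray  # per neuron, -1 for fibers
    morphologies: list[Morphology]
    soma_position: np.ndarray  # (N, 3) µm; NaN rows for fibers
    synapses: SynapseTable
    passive: PassiveParams = PassiveParams()
    spike: SpikeParams = SpikeParams()
    noise: NoiseParams = NoiseParams()
    layer_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    # -- structure queries ---------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.morphology_index)

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"unknown population {name!r}")

    def population_names(self, spiking_only: bool = False) -> list[str]:
        return [
            p.name
            for p in self.populations
            if not (spiking_only and p.syn_class == "fiber")
        ]

    @property
    def fiber_ids(self) -> np.ndarray:
        ids = [p.ids for p in self.populations if p.syn_class == "fiber"]
        return np.concatenate(ids) if ids else np.zeros(0, dtype=np.int64)

    @property
    def cortical_ids(self) -> np.ndarray:
        ids = [p.ids for p in self.populations if p.syn_class != "fiber"]
        return np.sort(np.concatenate(ids)) if ids else np.zeros(0, dtype=np.int64)

    def population_of(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for p in self.populations:
            for i in p.ids:
                out[int(i)] = p.name
        return out

    def membership(self) -> dict[str, np.ndarray]:
        return {p.name: p.ids for p in self.populations}

    @property
    def l6_bottom(self) -> float:
        return max(b for _, b in self.layer_bounds.values()) if self.layer_bounds else 0.0

    def morphology_of(self, neuron_id: int) -> Morphology | None:
        idx = self.morphology_index[neuron_id]
        return None if idx < 0 else self.morphologies[idx]

    def validate(self) -> None:
        all_ids = np.concatenate([p.ids for p in self.populations])
        if len(np.unique(all_ids)) != len(all_ids):
            raise ValueError("neuron ids overlap across populations")
        syn = self.synapses
        if len(syn):
            if syn.post.max(initial=-1) >= self.n_neurons:
                raise ValueError("synapse references unknown neuron")
            for j in range(len(syn)):
                m = self.morphology_of(int(syn.post[j]))
                if m is None or syn.segment[j] >= m.n_segments:
                    raise ValueError("synapse references unknown segment")
        bounds = sorted(self.layer_bounds.values())
        for (t0, b0), (t1, b1) in zip(bounds[:-1], bounds[1:]):
            if t1 < b0:
                raise ValueError("layer boundaries overlap")

    # -- serialisation -------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            gp = f.create_group("populations")
            for p in self.populations:
                g = gp.create_group(p.name)
                g.attrs["layer"] = p.layer
                g.attrs["syn_class"] = p.syn_class
                g.create_dataset("ids", data=p.ids, track_times=False)
            gm = f.create_group("morphologies")
            for k, m in enumerate(self.morphologies):
                g = gm.create_group(str(k))
                for name in ("proximal", "distal", "radius", "parent", "n_compartments"):
                    g.create_dataset(name, data=getattr(m, name), track_times=False)
                g.attrs["soma_index"] = m.soma_index
            f.create_dataset("morphology_index", data=self.morphology_index, track_times=False)
            f.create_dataset("soma_position", data=self.soma_position, track_times=False)
            gs = f.create_group("synapses")
            for name in _SYN_FIELDS:
                gs.create_dataset(name, data=getattr(self.synapses, name), track_times=False)
            gl = f.create_group("layers")
            for name, (top, bottom) in self.layer_bounds.items():
                gl.create_dataset(name, data=np.array([top, bottom]), track_times=False)
            for grp, obj in (("passive", self.passive), ("spike", self.spike)):
                g = f.create_group(grp)
                for key, val in vars(obj).items():
                    g.attrs[key] = val
            g = f.create_group("noise")
            for key, val in vars(self.noise).items():
                if key == "scale":
                    for pop, s in val.items():
                        g.attrs[f"scale_{pop}"] = s
                else:
                    g.attrs[key] = val

    @classmethod
    def from_hdf5(cls, path) -> "CircuitModel":
        with h5py.File(path, "r") as f:
            pops = [
                Population(name, g.attrs["layer"], g.attrs["syn_class"], g["ids"][()])
                for name, g in f["populations"].items()
            ]
            morphs = [
                Morphology(
                    g["proximal"][()],
                    g["distal"][()],
                    g["radius"][()],
                    g["parent"][()],
                    int(g.attrs["soma_index"]),
                    g["n_compartments"][()],
                )
                for _, g in sorted(f["morphologies"].items(), key=lambda kv: int(kv[0]))
            ]
            syn = SynapseTable(*[f["synapses"][name][()] for name in _SYN_FIELDS])
            layers = {name: tuple(ds[()]) for name, ds in f["layers"].items()}
            passive = PassiveParams(**{k: float(v) for k, v in f["passive"].attrs.items()})
            spk = {k: v for k, v in f["spike"].attrs.items()}
            spk["mode"] = str(spk["mode"])
            spike = SpikeParams(**spk)
            nz, scale = {}, {}
            for k, v in f["noise"].attrs.items():
                if k.startswith("scale_"):
                    scale[k[6:]] = float(v)
                else:
                    nz[k] = float(v)
            noise = NoiseParams(scale=scale, **nz)
            return cls(
                pops,
                f["morphology_index"][()],
                morphs,
                f["soma_position"][()],
                syn,
                passive,
                spike,
                noise,
                layers,
            )


# ---------------------------------------------------------------------------
# operations


def place_synapses(
    post_morphology: Morphology,
    n: int,
    profile: str,
    seed: int,
    perisomatic_radius: float = 50.0,
) -> list[tuple[int, float]]:
    """Sample ``n`` synapse locations on a morphology.

    ``distributed`` places synapses with probability proportional to
    compartment membrane area; ``perisomatic`` restricts placement to
    compartments within ``perisomatic_radius`` µm path distance of the soma
    (area-weighted within that set).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    comp = post_morphology.compartments()
    if profile == "distributed":
        weights = comp["area"].astype(float)
    elif profile == "perisomatic":
        dist = post_morphology.path_distance()
        mask = dist <= perisomatic_radius
        if not mask.any():
            raise ValueError("no compartment within the perisomatic distance bound")
        weights = np.where(mask, comp["area"], 0.0)
    else:
        raise ValueError(f"unknown placement profile {profile!r}")
    if n == 0:
        return []
    rng = substream(seed, 0x51)
    p = weights / weights.sum()
    comps = rng.choice(len(p), size=n, p=p)
    offsets = rng.random(n)
    segs = comp["segment"][comps]
    return [(int(s), float(o)) for s, o in zip(segs, offsets)]


def generate_thalamic_spikes(
    spec: StimulusSpec,
    seed: int,
    fiber_ids: np.ndarray | None = None,
    stim_start: float = 50.0,
    t_stop: float | None = None,
) -> SpikeRecord:
    """Draw thalamic fiber spikes for a trial.

    For each of ``spec.n_stimuli`` stimuli (onsets ``stim_start + k*isi``)
    exactly ``round(active_fraction * n_fibers)`` fibers are chosen and fire
    as an inhomogeneous Poisson process following the PSTH.  All fibers fire
    at the baseline rate over ``[0, t_stop]``.
    """
    if fiber_ids is None:
        fiber_ids = np.arange(spec.n_fibers, dtype=np.int64)
    fiber_ids = np.asarray(fiber_ids, dtype=np.int64)
    if len(fiber_ids) != spec.n_fibers:
        raise ValueError("fiber_ids length must equal spec.n_fibers")
    if t_stop is None:
        t_stop = stim_start + spec.n_stimuli * spec.isi
    rng = substream(seed, 0x7A)
    n_active = int(round(spec.active_fraction * spec.n_fibers))
    ids_out, times_out = [], []

    widths = np.diff(spec.bin_edges)
    bump = np.clip(spec.rates - spec.baseline_rate, 0.0, None)  # baseline handled globally
    for k in range(spec.n_stimuli):
        onset = stim_start + k * spec.isi
        active = rng.choice(fiber_ids, size=n_active, replace=False)
        for fid in active:
            counts = rng.poisson(bump * widths * 1e-3)
            for b in np.flatnonzero(counts):
                t = spec.bin_edges[b] + widths[b] * rng.random(counts[b])
                times_out.append(onset + t)
                ids_out.append(np.full(counts[b], fid, dtype=np.int64))
    # homogeneous baseline firing on every fiber
    if spec.baseline_rate > 0 and t_stop > 0:
        lam = spec.baseline_rate * t_stop * 1e-3
        counts = rng.poisson(lam, size=spec.n_fibers)
        for i in np.flatnonzero(counts):
            times_out.append(rng.random(counts[i]) * t_stop)
            ids_out.append(np.full(counts[i], fiber_ids[i], dtype=np.int64))
    if not ids_out:
        return SpikeRecord.empty()
    ids = np.concatenate(ids_out)
    times = np.concatenate(times_out)
    keep = times <= t_stop
    return SpikeRecord(ids[keep], times[keep])


def synapse_positions(circuit: CircuitModel) -> np.ndarray:
    """Absolute (x, y, z) positions (µm) of every synapse."""
    pos = np.zeros((len(circuit.synapses), 3))
    syn = circuit.synapses
    for j in range(len(syn)):
        m = circuit.morphology_of(int(syn.post[j]))
        s = int(syn.segment[j])
        local = m.proximal[s] + (m.distal[s] - m.proximal[s]) * syn.offset[j]
        pos[j] = circuit.soma_position[syn.post[j]] + local
    return pos


def assign_axonal_delays(
    circuit: CircuitModel,
    base_delay: float = 1.0,
    velocity: float = 300.0,
    pre_ids: np.ndarray | None = None,
) -> CircuitModel:
    """Set distance-dependent delays: base + (distance from L6 bottom)/velocity.

    Distance is measured from the bottom of L6 up to the synapse location,
    emulating thalamocortical conduction along the ascending fiber.  By
    default the rule is applied to synapses whose presynaptic element is a
    thalamic fiber.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if not circuit.layer_bounds:
        raise ValueError("layer boundaries undefined")
    if pre_ids is None:
        pre_ids = circuit.fiber_ids
    syn = circuit.synapses
    if len(syn) == 0:
        return circuit
    mask = np.isin(syn.pre, pre_ids)
    if not mask.any():
        return circuit
    z = synapse_positions(circuit)[:, 2]
    distance = circuit.l6_bottom - z
    if np.any(distance[mask] < 0):
        raise ValueError("synapse below the bottom of L6 (negative distance)")
    delay = syn.delay.copy()
    delay[mask] = base_delay + distance[mask] / velocity
    new_syn = replace(syn, delay=delay)
    return replace(circuit, synapses=new_syn)


# ---------------------------------------------------------------------------
# builder


_MORPH_BUILDERS = {"ball_and_stick": ball_and_stick, "soma_only": soma_only}


def build_circuit(config: Mapping, seed: int) -> CircuitModel:
    """Build a deterministic synthetic circuit from a structured config.

    See :func:`sepsim.configs.default_config` for the expected schema.
    Identical ``(config, seed)`` yields a bit-identical circuit.  Each
    connection rule draws from its own child random stream, so editing one
    rule (e.g. flipping a placement profile) does not perturb any other
    rule's realisation.
    """
    layers = {k: tuple(v) for k, v in config["layers"].items()}
    pops: list[Population] = []
    morphologies: list[Morphology] = []
    morph_index_parts: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    next_id = 0
    annulus = config.get("column_annulus", (20.0, 250.0))

    pop_cfgs = config["populations"]
    for pi, (name, pc) in enumerate(pop_cfgs.items()):
        count = int(pc["count"])
        if count <= 0:
            raise ValueError(f"population {name!r} has zero count")
        ids = np.arange(next_id, next_id + count, dtype=np.int64)
        next_id += count
        pops.append(Population(name, pc["layer"], pc["syn_class"], ids))
        rng = substream(seed, 0x10, pi)
        if pc["syn_class"] == "fiber":
            morph_index_parts.append(np.full(count, -1, dtype=np.int64))
            positions.append(np.full((count, 3), np.nan))
            continue
        mc = dict(pc.get("morphology", {"type": "soma_only"}))
        mtype = mc.pop("type")
        if mtype not in _MORPH_BUILDERS:
            raise ValueError(f"unknown morphology type {mtype!r}")
        morph = _MORPH_BUILDERS[mtype](**mc)
        morphologies.append(morph)
        morph_index_parts.append(np.full(count, len(morphologies) - 1, dtype=np.int64))
        lo, hi = pc.get("depth", layers[pc["layer"]])
        r = np.sqrt(rng.uniform(annulus[0] ** 2, annulus[1] ** 2, count))
        theta = rng.uniform(0, 2 * np.pi, count)
        z = rng.uniform(lo, hi, count)
        positions.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), z]))

    morph_index = np.concatenate(morph_index_parts)
    soma_position = np.vstack(positions)
    by_name = {p.name: p for p in pops}

    tables = []
    for ri, rule in enumerate(config.get("connections", [])):
        pre = by_name[rule["pre"]]
        post = by_name[rule["post"]]
        p_conn = float(rule["p"])
        rng = substream(seed, 0x20, ri)
        pairs = np.argwhere(rng.random((len(pre.ids), len(post.ids))) < p_conn)
        if rule["pre"] == rule["post"]:
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]  # no autapses
        if len(pairs) == 0:
            continue
        pre_ids = pre.ids[pairs[:, 0]]
        post_ids = post.ids[pairs[:, 1]]
        profile = rule.get("placement", "distributed")
        # all members of a population share a morphology template, so one
        # placement call covers the whole rule (draws are i.i.d. per synapse)
        m = morphologies[morph_index[post_ids[0]]]
        placements = place_synapses(
            m,
            len(pairs),
            profile,
            seed=int(substream(seed, 0x30, ri).integers(0, 2**31)),
            perisomatic_radius=rule.get("perisomatic_radius", 50.0),
        )
        seg = np.array([s for s, _ in placements], dtype=np.int64)
        off = np.array([o for _, o in placements])
        n = len(pairs)
        tables.append(
            SynapseTable(
                pre_ids,
                post_ids,
                seg,
                off,
                np.full(n, float(rule.get("gmax", 1.0))),
                np.full(n, float(rule.get("e_rev", 0.0))),
                np.full(n, float(rule.get("tau", 2.0))),
                np.full(n, float(rule.get("delay", 1.0))),
                np.full(n, float(rule.get("p_release", 1.0))),
                np.full(n, SYN_CURRENT if rule.get("kind", "conductance") == "current" else SYN_CONDUCTANCE, dtype=np.int8),
            )
        )
    synapses = SynapseTable.concatenate(tables)

    noise_cfg = dict(config.get("noise", {}))
    noise = NoiseParams(
        mean=float(noise_cfg.get("mean", 0.0)),
        ratio=float(noise_cfg.get("ratio", 0.4)),
        tau=float(noise_cfg.get("tau", 3.0)),
        e_rev=float(noise_cfg.get("e_rev", 0.0)),
        scale=dict(noise_cfg.get("scale", {})),
    )
    spike_cfg = dict(config.get("spike", {}))
    passive_cfg = dict(config.get("passive", {}))
    circuit = CircuitModel(
        pops,
        morph_index,
        morphologies,
        soma_position,
        synapses,
        PassiveParams(**passive_cfg),
        SpikeParams(**spike_cfg),
        noise,
        layers,
    )
    delays = config.get("delays", {})
    circuit = assign_axonal_delays(
        circuit,
        base_delay=float(delays.get("base", 1.0)),
        velocity=float(delays.get("velocity", 300.0)),
    )
    circuit.validate()
    return circuit
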