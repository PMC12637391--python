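"""Reproducible random streams.

Two kinds of stochasticity need to be *identical* between a connected
simulation and its decoupled replays:

* the Ornstein-Uhlenbeck background-noise path, which is drawn from a
  counter-based Philox generator keyed by the trial seed, with a fixed
  number of draws per time step (the draw sequence therefore does not
  depend on network activity); and
* per-synapse release outcomes, which are pure hash functions of
  ``(trial_seed, synapse id, event index)`` so that the k-th activation of
  a synapse releases identically no matter which simulation triggers it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["philox_generator", "substream", "counter_uniform", "sequential_indices"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)


def philox_generator(seed: int, tag: int) -> np.random.Generator:
    """Counter-based generator for a (seed, tag) stream."""
    return np.random.Generator(np.random.Philox(key=[np.uint64(seed), np.uint64(tag)]))


def substream(seed: int, *tags: int) -> np.random.Generator:
    """Independent child generator of ``seed`` identified by integer tags."""
    return np.random.default_rng([int(seed)] + [int(t) for t in tags])


def _mix(z: np.ndarray) -> np.ndarray:
    # splitmix64 finaliser; uint64 wrap-around is intentional
    z = (z ^ (z >> np.uint64(30))) * _C1
    z = (z ^ (z >> np.uint64(27))) * _C2
    return z ^ (z >> np.uint64(31))


def counter_uniform(key: int, ids, counters) -> np.ndarray:
    """Uniform(0, 1) deviates addressed by ``(key, id, counter)``.

    Stateless: the same triple always yields the same deviate, which is what
    makes synaptic-release outcomes reproducible across replay simulations.
    """
    ids = np.asarray(ids, dtype=np.uint64)
    counters = np.asarray(counters, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = (np.uint64(key) + _GOLDEN) * _C2
        h = _mix(_mix(x ^ (ids * _GOLDEN)) ^ (counters * _C1))
    return (h >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))


def sequential_indices(ids: np.ndarray, counter: np.ndarray) -> np.ndarray:
    """Per-id event indices for a batch of events, advancing ``counter``.

    Duplicate ids within the batch receive consecutive indices in their
    batch order. ``counter`` is updated in place.
    """
    ids = np.asarray(ids)
    out = np.empty(ids.shape, dtype=np.int64)
    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    # offset of each event within its run of equal ids
    boundaries = np.flatnonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])
    run_start = np.repeat(boundaries, np.diff(np.r_[boundaries, sorted_ids.size]))
    within = np.arange(sorted_ids.size) - run_start
    out[order] = counter[sorted_ids] + within
    np.add.at(counter, ids, 1)
    return out
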