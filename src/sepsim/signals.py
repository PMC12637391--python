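"""Signal assembly and post-processing.

EEG/LFP traces are the dot product of the transmembrane-current report
with the lead-field weights; per-neuron contribution matrices are retained
so that population contributions can be isolated in post-processing.
Post-processing follows the evoked-potential protocol: extract the window
around the second stimulus (to account for accommodation), band-pass
filter (2nd-order Butterworth, 1-500 Hz, applied zero-phase), average over
trials, and normalise to the P1 peak of a reference trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "SignalTrace",
    "compute_signal",
    "compute_lfp",
    "postprocess_sep",
    "average_traces",
    "normalize_to_p1",
]


@dataclass
class SignalTrace:
    """A time-stamped signal with optional per-neuron contributions.

    ``values`` is (T,) for a single electrode or (T, E) for an array.
    When ``contributions`` (T, N) is present its row-sum equals ``values``
    at every sample (to 1e-12 relative).
    """

    time: np.ndarray  # ms
    values: np.ndarray
    contributions: np.ndarray | None = None
    neuron_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def copy_with(self, **kwargs) -> "SignalTrace":
        out = dict(
            time=self.time,
            values=self.values,
            contributions=self.contributions,
            neuron_ids=self.neuron_ids,
            meta=dict(self.meta),
        )
        out.update(kwargs)
        return SignalTrace(**out)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def check_partition(self, rtol: float = 1e-9) -> float:
        """Max relative deviation of sum(contributions) from the total."""
        if self.contributions is None:
            raise ValueError("no contribution matrix")
        s = self.contributions.sum(axis=1)
        scale = max(np.abs(self.values).max(), 1e-30)
        return float(np.abs(s - self.values).max() / scale)

    def population_trace(self, ids: np.ndarray) -> "SignalTrace":
        """Sum of per-neuron contributions over a set of neuron ids."""
        if self.contributions is None or self.neuron_ids is None:
            raise ValueError("no contribution matrix")
        cols = np.isin(self.neuron_ids, np.asarray(ids))
        return SignalTrace(
            self.time,
            self.contributions[:, cols].sum(axis=1),
            self.contributions[:, cols],
            self.neuron_ids[cols],
            dict(self.meta),
        )

    # -- I/O ---------------------------------------------------------------

    def to_hdf5(self, path, name: str = "trace") -> None:
        with h5py.File(path, "a") as f:
            if f"traces/{name}" in f:
                del f[f"traces/{name}"]
            g = f.require_group("traces").create_group(name)
            g.create_dataset("time", data=self.time, track_times=False)
            g.create_dataset("data", data=self.values, track_times=False)
            if self.contributions is not None:
                g.create_dataset("contributions", data=self.contributions, track_times=False)
                g.create_dataset("neuron_ids", data=self.neuron_ids, track_times=False)

    @classmethod
    def from_hdf5(cls, path, name: str = "trace") -> "SignalTrace":
        with h5py.File(path, "r") as f:
            g = f[f"traces/{name}"]
            return cls(
                g["time"][()],
                g["data"][()],
                g["contributions"][()] if "contributions" in g else None,
                g["neuron_ids"][()] if "neuron_ids" in g else None,
            )

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({"time_ms": self.time})
        vals = self.values if self.values.ndim > 1 else self.values[:, None]
        for i in range(vals.shape[1]):
            df[f"value_{i}" if vals.shape[1] > 1 else "value"] = vals[:, i]
        df.to_csv(path, index=False)


def compute_signal(currents, weights, electrode: int | str = 0) -> SignalTrace:
    """EEG trace (V) from a currents report and a weights table.

    Retains the per-neuron contribution matrix (compartment currents
    weighted and summed within each neuron).
    """
    w = weights.single(electrode)
    if w.shape[0] != currents.currents.shape[1]:
        raise ValueError("compartment ordering mismatch between currents and weights")
    weighted = currents.currents * w[None, :]
    contrib = np.add.reduceat(weighted, currents.offsets[:-1], axis=1)
    total = contrib.sum(axis=1)
    return SignalTrace(currents.time, total, contrib, currents.neuron_ids, {"unit": "V"})


def compute_lfp(currents, weights) -> SignalTrace:
    """Laminar LFP (mV, one column per electrode) from a currents report."""
    w = weights.weights
    if w.shape[1] != currents.currents.shape[1]:
        raise ValueError("compartment ordering mismatch between currents and weights")
    vals = currents.currents @ w.T * 1e3  # V -> mV
    meta = {"unit": "mV"}
    if "depths_um" in weights.meta:
        meta["depths_um"] = weights.meta["depths_um"]
    return SignalTrace(currents.time, vals, None, None, meta)


def _bandpass_sos(order: int, low: float, high: float, fs: float):
    nyq = fs / 2
    if not 0 < low < high < nyq:
        raise ValueError("invalid filter band (need 0 < low < high < Nyquist)")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def postprocess_sep(
    raw: SignalTrace,
    stimulus_times,
    filt: tuple[int, float, float] | None = (2, 1.0, 500.0),
    which_stimulus: int = 2,
    pre_ms: float = 10.0,
    post_ms: float = 100.0,
) -> SignalTrace:
    """Extract the response to one stimulus, re-zeroed and band-passed.

    The time axis of the output runs from ``-pre_ms`` to ``post_ms``
    relative to the selected stimulus onset (default: the second stimulus).
    Filtering is zero-phase (forward-backward) with reflection padding and
    is applied identically to the total and the per-neuron contributions,
    preserving the partition invariant.
    """
    stimulus_times = np.atleast_1d(np.asarray(stimulus_times, dtype=float))
    if which_stimulus > len(stimulus_times):
        raise ValueError(
            f"requested stimulus {which_stimulus} but only {len(stimulus_times)} given"
        )
    onset = stimulus_times[which_stimulus - 1]
    dt = raw.dt
    fs = 1000.0 / dt

    def _filter(x):
        if filt is None:
            return x
        sos = _bandpass_sos(filt[0], filt[1], filt[2], fs)
        return sps.sosfiltfilt(sos, x, axis=0, padtype="even")

    values = _filter(raw.values)
    contrib = _filter(raw.contributions) if raw.contributions is not None else None
    i0 = int(np.searchsorted(raw.time, onset - pre_ms))
    i1 = int(np.searchsorted(raw.time, onset + post_ms, side="right"))
    meta = dict(raw.meta)
    meta.update({"stimulus_onset_ms": float(onset), "filter": filt})
    return SignalTrace(
        raw.time[i0:i1] - onset,
        values[i0:i1],
        None if contrib is None else contrib[i0:i1],
        raw.neuron_ids,
        meta,
    )


def average_traces(traces) -> SignalTrace:
    """Sample-wise mean of traces on identical time grids."""
    traces = list(traces)
    t0 = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != t0.shape or not np.allclose(tr.time, t0):
            raise ValueError("time grid mismatch")
    values = np.mean([tr.values for tr in traces], axis=0)
    contrib = None
    if all(tr.contributions is not None for tr in traces):
        contrib = np.mean([tr.contributions for tr in traces], axis=0)
    return SignalTrace(t0, values, contrib, traces[0].neuron_ids, dict(traces[0].meta))


def p1_peak(trace: SignalTrace, window: tuple[float, float] = (8.0, 16.0)) -> float:
    mask = (trace.time >= window[0]) & (trace.time <= window[1])
    if not mask.any():
        raise ValueError("P1 window outside trace span")
    return float(trace.values[mask].max())


def normalize_to_p1(
    trace: SignalTrace,
    reference: SignalTrace,
    window: tuple[float, float] = (8.0, 16.0),
) -> SignalTrace:
    """Divide a trace by the reference's P1 peak (positive by convention)."""
    peak = p1_peak(reference, window)
    if peak <= 0:
        raise ValueError("reference P1 peak must be positive")
    return trace.copy_with(
        values=trace.values / peak,
        contributions=None if trace.contributions is None else trace.contributions / peak,
        meta={**trace.meta, "normalized_to": peak, "unit": "P1 units"},
    )
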