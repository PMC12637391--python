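"""SEP waveform features and pathway attribution of the N1 width.

Feature conventions (matching the trace polarity used throughout, P1
positive upward): P1 is the maximum in the 8-16 ms post-stimulus window,
N1 the minimum in the 16-40 ms window, and the N1 full width at half
maximum (FWHM) is measured between the half-depth crossings relative to
the pre-stimulus baseline, linearly interpolated between samples.

The pathway-attribution statistic removes one presynaptic-to-postsynaptic
pathway trace from the total and asks how much the N1 FWHM changes:
``FWHM_c - FWHM_{c,x->y}`` is the contribution of pathway x->y to the N1
width of circuit c (positive = the pathway widens N1).  Between two
circuit variants, ``Delta_{x->y} = DeltaFWHM - DeltaFWHM_{x->y}``
attributes the cross-circuit width difference to the pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import SpikeRecord
from .decomposition import ContributionSet
from .signals import SignalTrace

__all__ = [
    "SEPFeatures",
    "FWHMAttribution",
    "detect_onset",
    "sep_features",
    "fwhm_attribution",
    "percent_narrowing",
    "compress_spikes",
]

P1_WINDOW = (8.0, 16.0)
N1_WINDOW = (16.0, 40.0)


@dataclass
class SEPFeatures:
    baseline_mean: float
    baseline_sd: float
    onset: float | None
    p1_amplitude: float | None
    p1_time: float | None
    n1_amplitude: float | None
    n1_time: float | None
    peak_to_peak: float | None
    n1_fwhm: float | None


def detect_onset(
    values: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float],
    n_sd: float = 3.0,
) -> float | None:
    """First time the signal exceeds baseline mean + ``n_sd`` baseline SDs.

    Returns ``None`` when the signal never crosses (including the
    degenerate zero-variance, zero-signal case).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window outside trace")
    mu = values[mask].mean()
    sd = values[mask].std()
    after = times > baseline_window[1]
    crossed = after & (values > mu + n_sd * sd)
    if sd == 0:
        crossed &= values > mu  # flat baseline: any strict exceedance
    idx = np.flatnonzero(crossed)
    return None if idx.size == 0 else float(times[idx[0]])


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _fwhm(time, values, baseline, trough_idx) -> float | None:
    """Width between the half-depth crossings nearest the trough."""
    depth = baseline - values[trough_idx]
    half = baseline - 0.5 * depth
    # walk left from the trough to the last sample above the half level
    left = None
    for i in range(trough_idx, 0, -1):
        if values[i - 1] >= half > values[i]:
            left = _interp_crossing(time[i - 1], time[i], values[i - 1], values[i], half)
            break
    right = None
    for i in range(trough_idx, len(values) - 1):
        if values[i] < half <= values[i + 1]:
            right = _interp_crossing(time[i], time[i + 1], values[i], values[i + 1], half)
            break
    if left is None or right is None:
        return None
    return float(right - left)


def sep_features(
    trace: SignalTrace,
    p1_window: tuple[float, float] = P1_WINDOW,
    n1_window: tuple[float, float] = N1_WINDOW,
    baseline_window: tuple[float, float] | None = None,
) -> SEPFeatures:
    """Extract baseline, onset, P1, N1 and N1-FWHM features from a trace.

    The trace's time axis is relative to stimulus onset; the baseline is
    the pre-stimulus part (default: everything before 0).
    """
    t, v = trace.time, np.asarray(trace.values, dtype=float)
    if v.ndim != 1:
        raise ValueError("sep_features expects a single-channel trace")
    if t[0] > p1_window[0] or t[-1] < n1_window[1]:
        raise ValueError("trace does not span the P1/N1 windows")
    if baseline_window is None:
        baseline_window = (float(t[0]), 0.0)
    bmask = (t >= baseline_window[0]) & (t <= baseline_window[1])
    baseline_mean = float(v[bmask].mean()) if bmask.any() else 0.0
    baseline_sd = float(v[bmask].std()) if bmask.any() else 0.0
    onset = detect_onset(v, t, baseline_window) if bmask.any() else None

    p1_mask = (t >= p1_window[0]) & (t <= p1_window[1])
    p1_idx = np.flatnonzero(p1_mask)[np.argmax(v[p1_mask])]
    p1_amp, p1_time = float(v[p1_idx]), float(t[p1_idx])

    n1_mask = (t >= n1_window[0]) & (t <= n1_window[1])
    n1_idx = np.flatnonzero(n1_mask)[np.argmin(v[n1_mask])]
    depth = baseline_mean - v[n1_idx]
    scale = np.abs(v - baseline_mean).max()
    if depth <= 1e-9 * scale:  # no genuine deflection below baseline: N1 undefined
        return SEPFeatures(
            baseline_mean, baseline_sd, onset, p1_amp, p1_time, None, None, None, None
        )
    n1_amp, n1_time = float(v[n1_idx]), float(t[n1_idx])
    fwhm = _fwhm(t, v, baseline_mean, int(n1_idx))
    return SEPFeatures(
        baseline_mean,
        baseline_sd,
        onset,
        p1_amp,
        p1_time,
        n1_amp,
        n1_time,
        p1_amp - n1_amp,
        fwhm,
    )


@dataclass
class FWHMAttribution:
    """Per-pathway N1-width attribution.

    ``fwhm_total`` is the N1 FWHM of the full signal; ``fwhm_removed``
    maps each pathway to the FWHM of the signal with that pathway's trace
    subtracted; ``contribution = fwhm_total - fwhm_removed`` (ms, positive
    = pathway widens N1).  With two circuits, ``delta`` maps pathways to
    ``DeltaFWHM - DeltaFWHM_{x->y}``.  Pathways whose removed signal has
    no defined N1 are listed in ``flagged`` and excluded from the tables.
    """

    fwhm_total: float
    fwhm_removed: dict[tuple[str, str], float]
    contribution: dict[tuple[str, str], float]
    delta: dict[tuple[str, str], float] | None = None
    flagged: set | None = None

    def to_frame(self):
        """Attribution table: one row per pathway."""
        import pandas as pd

        rows = []
        for (pre, post), fwhm in self.fwhm_removed.items():
            rows.append(
                {
                    "pathway": f"{pre}->{post}",
                    "fwhm_removed_ms": fwhm,
                    "contribution_ms": self.contribution[(pre, post)],
                    "delta_ms": None if self.delta is None else self.delta.get((pre, post)),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pathway_fwhms(contribs: ContributionSet, **kw):
    total = contribs.total
    f_total = sep_features(total, **kw).n1_fwhm
    if f_total is None:
        raise ValueError("total signal has no defined N1")
    removed, flagged = {}, set()
    for key, tr in contribs.pathway.items():
        s = total.copy_with(values=total.values - tr.values, contributions=None)
        f = sep_features(s, **kw).n1_fwhm
        if f is None:
            flagged.add(key)
        else:
            removed[key] = f
    return f_total, removed, flagged


def fwhm_attribution(
    contribs_a: ContributionSet,
    contribs_b: ContributionSet | None = None,
    **feature_kwargs,
) -> FWHMAttribution:
    """N1-width attribution for one circuit, or across two variants."""
    f_a, removed_a, flagged = _pathway_fwhms(contribs_a, **feature_kwargs)
    contribution = {k: f_a - v for k, v in removed_a.items()}
    delta = None
    if contribs_b is not None:
        f_b, removed_b, flagged_b = _pathway_fwhms(contribs_b, **feature_kwargs)
        flagged |= flagged_b
        dfwhm = f_a - f_b
        delta = {}
        for k in removed_a:
            if k in removed_b:
                delta[k] = dfwhm - (removed_a[k] - removed_b[k])
    return FWHMAttribution(f_a, removed_a, contribution, delta, flagged)


def percent_narrowing(fwhm_a: float, fwhm_b: float) -> float:
    """Relative narrowing 100 * (a - b) / a in percent."""
    if fwhm_a <= 0:
        raise ValueError("reference FWHM must be positive")
    return 100.0 * (fwhm_a - fwhm_b) / fwhm_a


def compress_spikes(
    spikes: SpikeRecord,
    window: tuple[float, float] = (10.0, 40.0),
    target: float = 15.0,
    stimulus_time: float = 0.0,
    ids: np.ndarray | None = None,
) -> SpikeRecord:
    """Shift all (selected) spikes inside a post-stimulus window to one time.

    Spike count is preserved; spikes outside the window, or from neurons
    not in ``ids``, are unchanged.
    """
    if window[0] >= window[1]:
        raise ValueError("invalid window")
    t = spikes.times - stimulus_time
    mask = (t >= window[0]) & (t <= window[1])
    if ids is not None:
        mask &= np.isin(spikes.ids, np.asarray(ids))
    times = spikes.times.copy()
    times[mask] = stimulus_time + target
    return SpikeRecord(spikes.ids.copy(), times)
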