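"""Lead fields: compartment sensitivity weights for EEG and LFP.

EEG weights follow the reciprocity theorem for a homogeneous, isotropic
volume conductor: the sensitivity of an electrode pair to a unit current at
a point equals the potential a unit current injected through that pair
would create there,

    w(x) = 1 / (4 pi sigma) * (1/r_rec - 1/r_ref)   [V/A],

reported in V/nA.  The recording-minus-reference subtraction is folded
into the weight, one scalar per compartment.  LFP coefficients use the
line-source approximation: each cylindrical compartment is a uniform line
of current, somata are point sources.

Because each neuron's transmembrane currents sum to zero, the weights have
a gauge freedom — adding a constant to all weights of a neuron leaves the
signal unchanged.  :func:`gauge_shift` exploits this to centre the range
of weights over a population on zero for visualisation and the
weights-range statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "ElectrodeSpec",
    "WeightsTable",
    "point_electrode_weights",
    "line_source_weights",
    "circuit_eeg_weights",
    "laminar_lfp_weights",
    "gauge_shift",
    "weights_range_stat",
]

_UM = 1e-6  # µm -> m
_PER_NA = 1e-9  # V/A -> V/nA


@dataclass(frozen=True)
class ElectrodeSpec:
    """A recording/reference electrode pair in a homogeneous medium.

    ``reference=None`` places the reference at infinity.  ``sigma`` is the
    medium conductivity in S/m (0.3 S/m, the gray-matter convention).
    """

    position: tuple[float, float, float]
    reference: tuple[float, float, float] | None = None
    sigma: float = 0.3
    name: str = "EEG"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("conductivity must be positive")
        if self.reference is not None and np.allclose(self.position, self.reference):
            raise ValueError("recording and reference positions must differ")


@dataclass
class WeightsTable:
    """Per-compartment, per-electrode sensitivity weights (V/nA)."""

    weights: np.ndarray  # (E, M)
    electrode_names: list[str]
    positions: np.ndarray  # (E, 3) µm
    sigma: float
    comp_neuron: np.ndarray | None = None  # (M,) owning neuron id
    meta: dict = field(default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return self.weights.shape[1]

    def single(self, name: str | int = 0) -> np.ndarray:
        if isinstance(name, int):
            return self.weights[name]
        return self.weights[self.electrode_names.index(name)]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            ge = f.create_group("electrodes")
            for i, name in enumerate(self.electrode_names):
                g = ge.create_group(name)
                g.create_dataset("scaling_factors", data=self.weights[i], track_times=False)
                g.create_dataset("position", data=self.positions[i], track_times=False)
            f.attrs["sigma"] = self.sigma
            if self.comp_neuron is not None:
                f.create_dataset("compartment_node_ids", data=self.comp_neuron, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "WeightsTable":
        with h5py.File(path, "r") as f:
            names = list(f["electrodes"].keys())
            weights = np.vstack([f["electrodes"][n]["scaling_factors"][()] for n in names])
            positions = np.vstack([f["electrodes"][n]["position"][()] for n in names])
            comp_neuron = (
                f["compartment_node_ids"][()] if "compartment_node_ids" in f else None
            )
            return cls(weights, names, positions, float(f.attrs["sigma"]), comp_neuron)


def point_electrode_weights(
    compartment_centers: np.ndarray,
    spec: ElectrodeSpec,
    comp_neuron: np.ndarray | None = None,
) -> WeightsTable:
    """Reciprocity weights of a point electrode pair (V/nA)."""
    centers = np.atleast_2d(np.asarray(compartment_centers, dtype=float))
    r_rec = np.linalg.norm((centers - np.asarray(spec.position)) * _UM, axis=1)
    if np.any(r_rec == 0):
        raise ValueError("compartment coincides with the recording electrode")
    w = 1.0 / (4 * np.pi * spec.sigma * r_rec)
    if spec.reference is not None:
        r_ref = np.linalg.norm((centers - np.asarray(spec.reference)) * _UM, axis=1)
        if np.any(r_ref == 0):
            raise ValueError("compartment coincides with the reference electrode")
        w = w - 1.0 / (4 * np.pi * spec.sigma * r_ref)
    return WeightsTable(
        (w * _PER_NA)[None, :],
        [spec.name],
        np.asarray(spec.position, dtype=float)[None, :],
        spec.sigma,
        comp_neuron,
    )


def line_source_weights(
    starts: np.ndarray,
    ends: np.ndarray,
    is_point: np.ndarray,
    electrode_position,
    sigma: float = 0.3,
    comp_neuron: np.ndarray | None = None,
    name: str = "LFP",
) -> WeightsTable:
    """Line-source coefficients (V/nA) of one extracellular electrode.

    Each compartment from ``starts[i]`` to ``ends[i]`` is treated as a
    uniform line of current; entries flagged in ``is_point`` (somata) use
    the point-source formula at the midpoint.  With rho the perpendicular
    distance of the electrode from the line and t its axial projection
    measured from the start,

        phi = I/(4 pi sigma L) * [asinh((L - t)/rho) + asinh(t/rho)],

    which is the log form of the classical line-source potential.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float)) * _UM
    ends = np.atleast_2d(np.asarray(ends, dtype=float)) * _UM
    e = np.asarray(electrode_position, dtype=float) * _UM
    is_point = np.asarray(is_point, dtype=bool)
    d = ends - starts
    L = np.linalg.norm(d, axis=1)
    u = d / L[:, None]
    t = np.einsum("ij,ij->i", e - starts, u)
    rho = np.linalg.norm(e - starts - t[:, None] * u, axis=1)
    w = np.empty(len(L))

    on_axis = (rho < 1e-12) & (t > 0) & (t < L) & ~is_point
    if np.any(on_axis):
        raise ValueError("electrode lies on a segment axis within its span")
    line = ~is_point
    rho_safe = np.maximum(rho, 1e-15)
    w[line] = (
        1.0
        / (4 * np.pi * sigma * L[line])
        * (np.arcsinh((L[line] - t[line]) / rho_safe[line]) + np.arcsinh(t[line] / rho_safe[line]))
    )
    mid = 0.5 * (starts + ends)
    r = np.linalg.norm(e - mid, axis=1)
    if np.any(r[is_point] == 0):
        raise ValueError("electrode coincides with a point source")
    w[is_point] = 1.0 / (4 * np.pi * sigma * r[is_point])
    return WeightsTable(
        (w * _PER_NA)[None, :],
        [name],
        (np.asarray(electrode_position, dtype=float))[None, :],
        sigma,
        comp_neuron,
    )


def circuit_eeg_weights(circuit, spec: ElectrodeSpec, ra: float = 150.0) -> WeightsTable:
    """EEG reciprocity weights for every compartment of a circuit."""
    from .netsim import compartment_frame

    frame = compartment_frame(circuit, ra)
    return point_electrode_weights(
        frame.center, spec, comp_neuron=frame.neuron_ids[frame.neuron_of]
    )


def laminar_lfp_weights(
    circuit,
    depths: np.ndarray,
    xy: tuple[float, float] = (0.0, 0.0),
    sigma: float = 0.3,
    ra: float = 150.0,
) -> WeightsTable:
    """Line-source LFP weights for a vertical laminar electrode array."""
    from .netsim import compartment_frame

    frame = compartment_frame(circuit, ra)
    tables = []
    for z in depths:
        tables.append(
            line_source_weights(
                frame.start,
                frame.end,
                frame.is_soma,
                (xy[0], xy[1], z),
                sigma=sigma,
                name=f"ch{z:.0f}",
            )
        )
    return WeightsTable(
        np.vstack([t.weights for t in tables]),
        [t.electrode_names[0] for t in tables],
        np.vstack([t.positions for t in tables]),
        sigma,
        frame.neuron_ids[frame.neuron_of],
        meta={"depths_um": np.asarray(depths, dtype=float)},
    )


def gauge_shift(weights: WeightsTable, scope: np.ndarray | None = None) -> WeightsTable:
    """Shift weights so max+min over the scope is zero (per electrode).

    ``scope`` is a boolean mask or index array over compartments (default:
    all).  Because per-neuron currents sum to zero, the EEG computed from
    shifted weights is unchanged.
    """
    w = weights.weights.copy()
    idx = np.arange(w.shape[1]) if scope is None else np.asarray(scope)
    sel = w[:, idx]
    if sel.shape[1] == 0:
        raise ValueError("scope is empty")
    shift = 0.5 * (sel.max(axis=1) + sel.min(axis=1))
    w = w - shift[:, None]
    return WeightsTable(
        w,
        list(weights.electrode_names),
        weights.positions,
        weights.sigma,
        weights.comp_neuron,
        dict(weights.meta),
    )


def weights_range_stat(
    weights: WeightsTable,
    neuron_sample: np.ndarray,
    electrode: int | str = 0,
) -> float:
    """Mean per-neuron 90th-minus-10th-percentile compartment weight (V/nA).

    A larger range implies a larger possible per-cell signal contribution;
    neurons with fewer than two compartments contribute a range of zero.
    """
    if weights.comp_neuron is None:
        raise ValueError("weights table lacks a compartment-to-neuron map")
    sample = np.asarray(neuron_sample)
    if sample.size == 0:
        raise ValueError("neuron sample is empty")
    w = weights.single(electrode)
    out = np.empty(sample.size)
    for i, nid in enumerate(sample):
        wc = w[weights.comp_neuron == nid]
        out[i] = 0.0 if wc.size < 2 else np.percentile(wc, 90) - np.percentile(wc, 10)
    return float(out.mean())
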