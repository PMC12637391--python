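"""Current source density and dipole-moment analysis of laminar LFP.

Two CSD estimators are provided for an evenly spaced laminar electrode
array:

* **standard CSD with Vaknin correction** — the discrete second spatial
  derivative ``-sigma * (phi[j+1] - 2 phi[j] + phi[j-1]) / h**2``, with the
  boundary potentials duplicated so the edge channels can be estimated;
* **step-iCSD** — assumes the CSD is homogeneous within cylindrical disks
  of radius ``rho`` (default 500 µm) and thickness ``h`` centred on the
  electrodes, builds the analytic disk forward matrix F and solves
  ``C = F^-1 phi`` per time step.

From a CSD profile the dipole-moment density per unit cortical surface,
``p = integral z * CSD(z, t) dz``, is evaluated at the time of peak
current density, and the peak EEG from a cortical patch of radius r is
estimated by reciprocity as ``pi r^2 * p * E_hat`` with ``E_hat`` the
dipole-aligned lead field.  Internally SI units are used; CSD is reported
in nA/mm³ (numerically equal to A/m³) and p in nAm/mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import SignalTrace

__all__ = [
    "CSDProfile",
    "standard_csd_vaknin",
    "step_icsd",
    "dipole_moment_density",
    "eeg_from_dipole",
    "dipole_lead_field",
]

_MM = 1e-3  # mm -> m
_UM = 1e-6  # µm -> m


@dataclass
class CSDProfile:
    """CSD (nA/mm³ = A/m³) on a depth x time grid."""

    depths: np.ndarray  # µm, electrode positions
    time: np.ndarray  # ms
    values: np.ndarray  # (T, K) nA/mm³
    method: str = "standard_vaknin"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.depths) <= 0) or (
            len(self.time) > 1 and np.any(np.diff(self.time) <= 0)
        ):
            raise ValueError("grids must be strictly increasing")
        if self.method not in ("standard_vaknin", "step_icsd"):
            raise ValueError(f"unknown CSD method {self.method!r}")

    def peak_time_index(self) -> int:
        """Sample with the largest total rectified current density."""
        return int(np.argmax(np.abs(self.values).sum(axis=1)))


def _lfp_to_volts(lfp: SignalTrace) -> tuple[np.ndarray, np.ndarray]:
    phi = np.atleast_2d(lfp.values)
    if phi.shape[0] != len(lfp.time):
        phi = phi.T
    unit = lfp.meta.get("unit", "mV")
    scale = 1e-3 if unit == "mV" else 1.0
    depths = np.asarray(lfp.meta.get("depths_um"))
    if depths is None or depths.ndim == 0:
        raise ValueError("laminar LFP requires electrode depths in meta['depths_um']")
    return phi * scale, depths


def _check_spacing(depths: np.ndarray, h: float) -> None:
    if len(depths) < 3:
        raise ValueError("need at least 3 electrodes")
    spacing = np.diff(depths)
    if not np.allclose(spacing, h, rtol=1e-6):
        raise ValueError("electrode spacing is not uniform at the stated h")


def standard_csd_vaknin(lfp: SignalTrace, h: float = 80.0, sigma: float = 0.3) -> CSDProfile:
    """Second-spatial-derivative CSD with duplicated boundary potentials."""
    phi, depths = _lfp_to_volts(lfp)
    _check_spacing(depths, h)
    padded = np.concatenate([phi[:, :1], phi, phi[:, -1:]], axis=1)  # Vaknin
    h_m = h * _UM
    csd = -sigma * (padded[:, 2:] - 2 * padded[:, 1:-1] + padded[:, :-2]) / h_m**2
    return CSDProfile(depths, lfp.time, csd, "standard_vaknin", {"h_um": h, "sigma": sigma})


def step_icsd_forward_matrix(depths_um: np.ndarray, h: float, rho: float, sigma: float) -> np.ndarray:
    """Analytic forward matrix of the step-iCSD disk model.

    ``F[j, k]`` is the potential at electrode j per unit CSD in disk k
    (thickness h, radius rho, centred on electrode k).  The on-axis
    potential of a uniform disk of current density C is
    ``C/(2 sigma) * (sqrt(d^2 + rho^2) - |d|)`` integrated over the disk
    thickness; the integral has a closed-form antiderivative.
    """
    z = np.asarray(depths_um, dtype=float) * _UM
    h_m, rho_m = h * _UM, rho * _UM

    def G(u):
        # antiderivative of sqrt(u^2 + rho^2) - |u|  (u = z_j - z)
        return 0.5 * (u * np.sqrt(u**2 + rho_m**2) + rho_m**2 * np.arcsinh(u / rho_m) - u * np.abs(u))

    zj = z[:, None]
    zk = z[None, :]
    u1 = zj - (zk - h_m / 2)
    u2 = zj - (zk + h_m / 2)
    return (G(u1) - G(u2)) / (2 * sigma)


def step_icsd(
    lfp: SignalTrace, h: float = 80.0, rho: float = 500.0, sigma: float = 0.3
) -> CSDProfile:
    """Inverse CSD assuming piecewise-constant sources in cylindrical disks."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    phi, depths = _lfp_to_volts(lfp)
    _check_spacing(depths, h)
    F = step_icsd_forward_matrix(depths, h, rho, sigma)
    cond = np.linalg.cond(F)
    if cond > 1e12:
        raise np.linalg.LinAlgError(f"forward matrix ill-conditioned (cond={cond:.3g})")
    csd = np.linalg.solve(F, phi.T).T  # A/m³ == nA/mm³
    return CSDProfile(
        depths, lfp.time, csd, "step_icsd", {"h_um": h, "rho_um": rho, "sigma": sigma, "cond": cond}
    )


def dipole_moment_density(csd: CSDProfile, t: float | None = None) -> float:
    """Depth integral ``p = ∫ z · CSD(z, t) dz`` in nAm/mm².

    Trapezoidal over the electrode span; ``t`` (ms) picks the nearest
    sample, defaulting to the time of peak rectified current density.
    """
    if csd.values.size == 0:
        raise ValueError("empty CSD profile")
    if t is None:
        ti = csd.peak_time_index()
    else:
        ti = int(np.argmin(np.abs(csd.time - t)))
    z_m = csd.depths * _UM
    p_si = np.trapezoid(z_m * csd.values[ti], z_m)  # A/m = A·m/m²
    return float(p_si * 1e3)  # -> nAm/mm²


def monopole_fraction(csd: CSDProfile, t: float | None = None) -> float:
    """|∫ CSD dz| relative to ∫ |CSD| dz — near zero for dipolar sources."""
    ti = csd.peak_time_index() if t is None else int(np.argmin(np.abs(csd.time - t)))
    z_m = csd.depths * _UM
    net = np.trapezoid(csd.values[ti], z_m)
    gross = np.trapezoid(np.abs(csd.values[ti]), z_m)
    return float(abs(net) / max(gross, 1e-300))


def eeg_from_dipole(
    p: float, r: float = 0.25, lead: float = 4.0, n_columns: int = 1
) -> float:
    """Reciprocity EEG estimate ``pi r^2 * p * E_hat`` (V).

    ``p`` in nAm/mm², patch radius ``r`` in mm, dipole-aligned lead field
    ``lead`` in V/mm/A.  The circuit-level estimate multiplies the
    per-column patch estimate by ``n_columns``.
    """
    p_si = p * 1e-3  # nAm/mm² -> (A·m)/m²
    area = np.pi * (r * _MM) ** 2  # m²
    lead_si = lead / _MM  # V/mm/A -> V/m/A
    return float(area * p_si * lead_si * n_columns)


def dipole_lead_field(spec, depth_range_um: tuple[float, float], n: int = 50) -> float:
    """Average dipole-aligned lead field E_hat (V/mm/A) along the column axis.

    Numerical z-derivative of the point-electrode reciprocity potential,
    averaged over the given depth range on the column axis (x = y = 0).
    """
    from .leadfield import point_electrode_weights

    z = np.linspace(depth_range_um[0], depth_range_um[1], n)
    pts = np.column_stack([np.zeros(n), np.zeros(n), z])
    w = point_electrode_weights(pts, spec).weights[0] / 1e-9  # V/A
    dwdz = np.gradient(w, z * _UM)  # V/A per m
    return float(np.abs(dwdz).mean() * _MM)  # V/mm/A
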