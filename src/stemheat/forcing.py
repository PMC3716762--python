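"""Time- and wedge-resolved boundary heat-flux forcing.

A :class:`ForcingSeries` holds the prescribed fire heat flux (radiant +
convective) per circumferential wedge as a function of time, together with
the ambient air temperature used for the net radiant exchange at the bark
surface.  Generators cover the synthetic laboratory pulse, fire-temperature
derived fluxes, exponential height scaling and the five circumferential
redistribution cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STEFAN_BOLTZMANN = 5.67e-8  # W/(m^2 K^4)
EMISSIVITY = 1.0            # black-body surfaces throughout

#: default shape parameter of the exponential flux-vs-height profile (1/m)
DEFAULT_HEIGHT_SHAPE = -0.0155


@dataclass
class ForcingSeries:
    """Prescribed fire heat flux per wedge plus ambient temperature.

    ``flux`` has shape (n_times, n_cols) with n_cols either 1 (broadcast to
    every wedge) or the wedge count of the target grid.  ``ambient``
    is a scalar temperature or a series of length n_times.
    """

    times: np.ndarray
    flux: np.ndarray
    ambient: float | np.ndarray = 300.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flux = np.atleast_2d(np.asarray(self.flux, dtype=float))
        if self.flux.shape[0] != self.times.size and self.flux.shape[1] == self.times.size:
            self.flux = self.flux.T
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D array with at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.flux.shape[0] != self.times.size:
            raise ValueError("flux rows must match times")
        if np.any(self.flux < 0):
            raise ValueError("fire heat flux must be non-negative")
        if np.ndim(self.ambient):
            self.ambient = np.asarray(self.ambient, dtype=float)
            if self.ambient.size != self.times.size:
                raise ValueError("ambient series must match times")

    @property
    def n_columns(self) -> int:
        return self.flux.shape[1]

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def flux_at(self, t: float, n_wedges: int) -> np.ndarray:
        """Linearly interpolated flux per wedge at time ``t`` (W/m^2)."""
        if self.n_columns not in (1, n_wedges):
            raise ValueError(
                f"forcing has {self.n_columns} flux columns; expected 1 or {n_wedges}")
        q = np.array([np.interp(t, self.times, self.flux[:, c])
                      for c in range(self.n_columns)])
        if self.n_columns == 1:
            q = np.full(n_wedges, q[0])
        return q

    def ambient_at(self, t: float) -> float:
        if np.ndim(self.ambient):
            return float(np.interp(t, self.times, self.ambient))
        return float(self.ambient)

    def total_dose(self, n_wedges: int, wedge_arc_area: float = 1.0) -> float:
        """Time- and circumference-integrated delivered energy (J per unit
        height when ``wedge_arc_area`` is the per-wedge surface arc area)."""
        per_col = np.trapezoid(self.flux, self.times, axis=0)
        if self.n_columns == 1:
            return float(per_col[0] * n_wedges * wedge_arc_area)
        return float(per_col.sum() * wedge_arc_area)

    def scaled(self, factor) -> "ForcingSeries":
        """Return a copy with the flux multiplied by a scalar or per-wedge vector."""
        factor = np.asarray(factor, dtype=float)
        if factor.ndim == 0:
            flux = self.flux * float(factor)
        else:
            if self.n_columns == 1:
                flux = self.flux * factor[np.newaxis, :]
            elif factor.size == self.n_columns:
                flux = self.flux * factor[np.newaxis, :]
            else:
                raise ValueError("multiplier length does not match flux columns")
        return ForcingSeries(self.times.copy(), flux, self.ambient)


@dataclass(frozen=True)
class HeightProfile:
    """Exponential scaling of peak fire forcing with height above ground."""

    ground_fire_temperature: float       # T_f(0), K
    top_fire_temperature: float          # T_f(z_top), K
    top_height: float                    # z_top, m
    shape: float = DEFAULT_HEIGHT_SHAPE  # c, 1/m

    def __post_init__(self) -> None:
        if self.top_height <= 0:
            raise ValueError("top_height must be positive")
        if self.ground_fire_temperature < 0 or self.top_fire_temperature < 0:
            raise ValueError("temperatures must be non-negative (K)")

    def scale(self, z: float) -> float:
        """Flux multiplier exp(c z) relative to ground level."""
        if not 0.0 <= z <= self.top_height:
            raise ValueError(f"height {z} outside [0, {self.top_height}]")
        return float(np.exp(self.shape * z))


def radiant_exchange(T_s, T_o):
    """Net black-body radiant exchange with ambient air, W/m^2.

    Positive when the ambient is hotter than the surface (net gain),
    negative when the surface radiates to cooler surroundings.
    """
    T_s = np.asarray(T_s, dtype=float)
    T_o = np.asarray(T_o, dtype=float)
    if np.any(T_s <= 0) or np.any(T_o <= 0):
        raise ValueError("temperatures must be positive (K)")
    out = EMISSIVITY * STEFAN_BOLTZMANN * (T_o ** 4 - T_s ** 4)
    return out if out.ndim else float(out)


def fire_flux_from_temperature(T_f, T_o):
    """Radiant fire heat flux implied by a fire air temperature, W/m^2.

    Black-body exchange between the fire environment at ``T_f`` and the
    pre-fire ambient ``T_o``; clamped at zero (and logged) when T_f < T_o.
    """
    T_f = np.asarray(T_f, dtype=float)
    T_o = np.asarray(T_o, dtype=float)
    if np.any(T_o <= 0) or np.any(T_f <= 0):
        raise ValueError("temperatures must be positive (K)")
    raw = EMISSIVITY * STEFAN_BOLTZMANN * (T_f ** 4 - T_o ** 4)
    if np.any(raw < 0):
        log.info("fire temperature below ambient; clamping flux at zero")
    out = np.maximum(raw, 0.0)
    return out if out.ndim else float(out)


def height_interpolated_flux(profile: HeightProfile, z: float,
                             times, normalized_series,
                             ambient: float) -> ForcingSeries:
    """Forcing at height ``z`` from a normalized temporal shape.

    The peak flux at ground level is the black-body flux implied by the
    profile's ground fire temperature; at height z it is scaled by
    exp(c z).  The temporal shape follows ``normalized_series`` (values in
    [0, 1]).
    """
    s = np.asarray(normalized_series, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("normalized series must lie in [0, 1]")
    peak0 = fire_flux_from_temperature(profile.ground_fire_temperature, ambient)
    flux = peak0 * profile.scale(z) * s
    return ForcingSeries(np.asarray(times, dtype=float), flux[:, np.newaxis], ambient)


def circumferential_distribution(case_id: int, n_wedges: int) -> np.ndarray:
    """Per-wedge heat-flux multipliers for the five redistribution cases.

    Quadrants (bearings clockwise from north): front = upper-right
    [0, 90); right = lower-right [90, 180); lee = lower-left [180, 270);
    left = upper-left [270, 360).  Fractions of the total delivered dose
    per quadrant:

    ========  ======  =====  ====  =====
    case      front   right  lee   left
    ========  ======  =====  ====  =====
    1         1/2     0      1/2   0
    2         1/4     1/4    1/4   1/4
    3         3/8     1/8    3/8   1/8
    4         1/3     0      2/3   0
    5         2/8     1/8    4/8   1/8
    ========  ======  =====  ====  =====

    The mean multiplier over wedges is 1, so the total dose is
    case-invariant.
    """
    if n_wedges % 8 != 0:
        raise ValueError("n_wedges must be divisible by 8")
    fractions = {
        1: (0.5, 0.0, 0.5, 0.0),
        2: (0.25, 0.25, 0.25, 0.25),
        3: (3 / 8, 1 / 8, 3 / 8, 1 / 8),
        4: (1 / 3, 0.0, 2 / 3, 0.0),
        5: (2 / 8, 1 / 8, 4 / 8, 1 / 8),
    }
    if case_id not in fractions:
        raise ValueError(f"unknown circumferential case {case_id!r}; expected 1..5")
    front, right, lee, left = fractions[case_id]
    per_quadrant = np.array([front, right, lee, left]) * 4.0  # 4 quadrants
    quarter = n_wedges // 4
    return np.repeat(per_quadrant, quarter)


def synthetic_lab_pulse(peak_flux: float, ramp_s: float, hold_s: float,
                        cool_s: float, ambient: float = 300.0,
                        dt: float = 1.0, decay_tau: float | None = None) -> ForcingSeries:
    """Deterministic bench-style heating pulse.

    Linear ramp to ``peak_flux`` over ``ramp_s``, hold for ``hold_s``, then
    exponential decay with time constant ``decay_tau`` (default cool_s/4)
    over ``cool_s``.
    """
    if peak_flux < 0:
        raise ValueError("peak_flux must be non-negative")
    if hold_s <= 0 or cool_s <= 0 or ramp_s < 0:
        raise ValueError("durations must be positive (ramp may be zero)")
    tau = cool_s / 4.0 if decay_tau is None else decay_tau
    t_end = ramp_s + hold_s + cool_s
    times = np.unique(np.concatenate([
        np.arange(0.0, t_end + dt / 2, dt), [ramp_s, ramp_s + hold_s, t_end]]))
    q = np.empty_like(times)
    for n, t in enumerate(times):
        if t <= ramp_s:
            q[n] = peak_flux * (t / ramp_s if ramp_s > 0 else 1.0)
        elif t <= ramp_s + hold_s:
            q[n] = peak_flux
        else:
            q[n] = peak_flux * np.exp(-(t - ramp_s - hold_s) / tau)
    if ramp_s == 0:
        q[0] = peak_flux  # step onset
    return ForcingSeries(times, q[:, np.newaxis], ambient)


def pulse_integral(peak_flux, ramp_s, hold_s, cool_s, decay_tau=None) -> float:
    """Closed-form time integral of :func:`synthetic_lab_pulse` (J/m^2)."""
    tau = cool_s / 4.0 if decay_tau is None else decay_tau
    return peak_flux * (ramp_s / 2.0 + hold_s + tau * (1.0 - np.exp(-cool_s / tau)))


# ---------------------------------------------------------------------------
# CSV and spreadsheet I/O
# ---------------------------------------------------------------------------

def write_forcing_csv(series: ForcingSeries, path) -> None:
    df = pd.DataFrame({"time_s": series.times})
    amb = series.ambient
    df["T_ambient_K"] = amb if np.ndim(amb) else float(amb)
    for c in range(series.n_columns):
        name = "flux_W_m2" if series.n_columns == 1 else f"flux_W_m2_{c + 1}"
        df[name] = series.flux[:, c]
    df.to_csv(path, index=False)


def read_forcing_csv(path) -> ForcingSeries:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    if "T_ambient_K" not in df.columns:
        raise ValueError(f"{path}: missing required column 'T_ambient_K'")
    flux_cols = [c for c in df.columns if c.startswith("flux")]
    if not flux_cols:
        raise ValueError(f"{path}: no flux columns found")
    times = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}: non-monotone time at row {bad[0] + 2}")
    flux = df[flux_cols].to_numpy(dtype=float)
    neg = np.nonzero((flux < 0).any(axis=1))[0]
    if neg.size:
        raise ValueError(f"{path}: negative flux at row {neg[0] + 2}")
    amb = df["T_ambient_K"].to_numpy(dtype=float)
    ambient = float(amb[0]) if np.allclose(amb, amb[0]) else amb
    return ForcingSeries(times, flux, ambient)


def read_height_spreadsheet(path, sheet=0) -> dict:
    """Import a per-height temperature/heat-flux spreadsheet (XLSX).

    Expects columns time_s, height_m, and at least one of T_fire_K and
    flux_W_m2 (flux computed from temperature via the black-body relation
    when absent), plus T_ambient_K.  Returns {height: ForcingSeries}.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    required = {"time_s", "height_m", "T_ambient_K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for z, sub in df.groupby("height_m"):
        sub = sub.sort_values("time_s")
        amb = sub["T_ambient_K"].to_numpy(dtype=float)
        if "flux_W_m2" in sub.columns:
            flux = sub["flux_W_m2"].to_numpy(dtype=float)
        elif "T_fire_K" in sub.columns:
            flux = fire_flux_from_temperature(
                sub["T_fire_K"].to_numpy(dtype=float), amb)
        else:
            raise ValueError(f"{path}: need either flux_W_m2 or T_fire_K")
        ambient = float(amb[0]) if np.allclose(amb, amb[0]) else amb
        out[float(z)] = ForcingSeries(
            sub["time_s"].to_numpy(dtype=float), flux[:, np.newaxis], ambient)
    return out
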