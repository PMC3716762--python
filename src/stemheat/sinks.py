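"""Desiccation and charring energy sinks.

Water loss follows a first-order Arrhenius drying law with a T^(-1/2)
prefactor; the evaporated mass removes latent heat from its control volume.
Charring is an Arrhenius pyrolysis of dry mass down to a char-fraction
floor, constrained so the char front advances at most one node per wedge
per time step, from the surface inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# drying kinetics
WATER_LOSS_PREFACTOR = 6.05e5      # k_w, K^0.5 / s
WATER_LOSS_ACTIVATION = 5956.0     # E_w/R, K
DEFAULT_LATENT_HEAT = 2.26e6       # J/kg, latent heat of vaporization

# pyrolysis kinetics
CHAR_DENSITY_FRACTION = 0.30       # c_f, residual fraction of dry density
PYROLYSIS_PREFACTOR = 7.0e7        # A_p, 1/s
PYROLYSIS_ACTIVATION = 15610.0     # E_p/R, K
#: pyrolysis proceeds only in nodes hotter than this (K); keeps the
#: one-node-per-step front rule from crawling at negligible rates
CHAR_ONSET_TEMPERATURE = 500.0
#: mass-rate floor (kg/s) below which a node is not considered charring
CHAR_RATE_FLOOR = 1e-12

# properties of charred material (the source gives none; configurable)
DEFAULT_CHAR_CONDUCTIVITY = 0.10   # W/(m K)
DEFAULT_CHAR_HEAT_CAPACITY = 1.0   # kJ/(kg K)


def water_loss_rate(M, T, rho, V, W_m):
    """Water mass-loss rate of a control volume, kg/s (non-negative).

    dm_w/dt = W_m k_w T^(-1/2) exp(-E_w/(R T)) m_w with the control
    volume's water mass m_w = M/(1+M) rho V (rho is the moist density).
    """
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    rho = np.asarray(rho, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(M < 0) or np.any(T <= 0) or np.any(rho < 0) or np.any(V < 0):
        raise ValueError("inputs must be non-negative (T strictly positive)")
    if not 0.01 <= float(np.min(W_m)) <= 1.0 or not 0.01 <= float(np.max(W_m)) <= 1.0:
        raise ValueError("W_m must lie in [0.01, 1]")
    water_mass = M / (1.0 + M) * rho * V
    rate = W_m * WATER_LOSS_PREFACTOR * T ** -0.5 * np.exp(-WATER_LOSS_ACTIVATION / T)
    out = rate * water_mass
    return out if out.ndim else float(out)


def desiccation_flux(mass_rate, V, latent_heat: float = DEFAULT_LATENT_HEAT):
    """Volumetric energy sink from evaporation, W/m^3 (always >= 0 as a sink)."""
    mass_rate = np.asarray(mass_rate, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(mass_rate < 0):
        raise ValueError("mass_rate must be non-negative")
    out = latent_heat * mass_rate / V
    return out if out.ndim else float(out)


def charring_rate(rho, T, P_m, rho_dry=None):
    """Pyrolysis mass-conversion rate per unit volume, kg/(m^3 s).

    dm_char/dt = P_m A_p exp(-E_p/(R T)) (rho - c_f rho_dry), floored at
    zero once the density has fallen to the char fraction.  ``rho_dry``
    defaults to ``rho`` (fully desiccated material).
    """
    rho = np.asarray(rho, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(rho < 0) or np.any(T <= 0) or np.any(np.asarray(P_m) < 0):
        raise ValueError("inputs must be non-negative (T strictly positive)")
    rho_d = rho if rho_dry is None else np.asarray(rho_dry, dtype=float)
    charrable = np.maximum(rho - CHAR_DENSITY_FRACTION * rho_d, 0.0)
    out = P_m * PYROLYSIS_PREFACTOR * np.exp(-PYROLYSIS_ACTIVATION / T) * charrable
    return out if out.ndim else float(out)


@dataclass
class CharState:
    """Per-node char flags with a contiguous surface-inward front per wedge.

    ``front`` holds, per wedge, the number of charred nodes counted from
    the surface (0 = none).
    """

    n_radial: int
    n_wedges: int
    front: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.front is None:
            self.front = np.zeros(self.n_wedges, dtype=int)
        self.front = np.asarray(self.front, dtype=int)
        if np.any(self.front < 0) or np.any(self.front > self.n_radial):
            raise ValueError("char front out of range")

    @property
    def flags(self) -> np.ndarray:
        """(n_radial, n_wedges) boolean char flags, contiguous from surface."""
        return np.arange(self.n_radial)[:, np.newaxis] < self.front[np.newaxis, :]

    def copy(self) -> "CharState":
        return CharState(self.n_radial, self.n_wedges, self.front.copy())


def advance_char_front(state: CharState, rates: np.ndarray, dt: float,
                       threshold: float = CHAR_RATE_FLOOR) -> CharState:
    """Advance the char front by at most one node per wedge per step.

    ``rates`` is the (n_radial, n_wedges) charring mass rate field; the
    candidate node of each wedge is the one immediately deeper than the
    current front, and it chars only when its rate exceeds ``threshold``.
    Char flags never revert.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (state.n_radial, state.n_wedges):
        raise ValueError("rates shape does not match the char state")
    new = state.copy()
    candidate = new.front  # next un-charred node index per wedge
    can_advance = candidate < state.n_radial
    idx = np.where(can_advance, np.minimum(candidate, state.n_radial - 1), 0)
    rate_at_candidate = rates[idx, np.arange(state.n_wedges)]
    advance = can_advance & (rate_at_candidate * dt > threshold)
    new.front = new.front + advance.astype(int)
    return new
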