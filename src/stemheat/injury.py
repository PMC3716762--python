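"""Rate-process tissue viability and necrotic-depth statistics.

Viability N of each node decays at a temperature-dependent Eyring-type rate
with a compensation law linking activation entropy to enthalpy.  A node is
dead once N falls below a threshold (default 0.001, a 3-log reduction).
Viability is tracked in log space to avoid underflow over long
integrations; the public contract is on N itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAS_CONSTANT = 8.31          # R, J/(mol K)
FREQUENCY_RATIO = 2.08e10    # k_B/h, 1/(s K)

#: log-viability floor: nodes never decay below exp(LOG_N_FLOOR)
LOG_N_FLOOR = -745.0


@dataclass(frozen=True)
class ViabilityParams:
    """Thermal-tolerance kinetics parameters.

    Defaults follow the rate-process thermal-death literature for plant
    tissue: activation enthalpy 582 kJ/mol with a compensation law
    dS = dH/T_crit - b_comp (T_crit = 327.8 K, b_comp = 271.5 J/(mol K),
    i.e. 64.9 cal/(mol K)).
    """

    activation_enthalpy: float = 582.0   # dH, kJ/mol
    t_crit: float = 327.8                # K
    b_comp: float = 271.5                # J/(mol K)
    death_threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.activation_enthalpy <= 0 or self.t_crit <= 0 or self.b_comp <= 0:
            raise ValueError("kinetic parameters must be positive")
        if not 0.0 < self.death_threshold < 1.0:
            raise ValueError("death_threshold must lie in (0, 1)")

    @property
    def activation_entropy(self) -> float:
        """dS from the compensation law, J/(mol K)."""
        return self.activation_enthalpy * 1e3 / self.t_crit - self.b_comp


def viability_rate(T, params: ViabilityParams = ViabilityParams()):
    """Viability progression rate f(T), 1/s.

    f = (k_B/h) T exp(dS/R - dH/(R T)), strictly increasing in T.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    dh = params.activation_enthalpy * 1e3
    exponent = params.activation_entropy / GAS_CONSTANT - dh / (GAS_CONSTANT * T)
    out = FREQUENCY_RATIO * T * np.exp(exponent)
    return out if out.ndim else float(out)


def constant_T_viability(N0, f, t_tot):
    """Closed-form viability after constant-temperature exposure: N0 exp(-f t)."""
    N0 = np.asarray(N0, dtype=float)
    if np.any(N0 <= 0) or np.any(N0 > 1):
        raise ValueError("N0 must lie in (0, 1]")
    if np.any(np.asarray(f) < 0) or np.any(np.asarray(t_tot) < 0):
        raise ValueError("f and t_tot must be non-negative")
    out = N0 * np.exp(-np.asarray(f, dtype=float) * np.asarray(t_tot, dtype=float))
    return out if out.ndim else float(out)


def update_log_viability(log_N: np.ndarray, T: np.ndarray, dt: float,
                         params: ViabilityParams = ViabilityParams()) -> np.ndarray:
    """One discrete viability step in log space: log N -= f(T) dt."""
    out = log_N - viability_rate(T, params) * dt
    return np.maximum(out, LOG_N_FLOOR)


@dataclass(frozen=True)
class InjuryResult:
    """Necrosis summary of a completed (cooled-down) run."""

    necrotic_depth: np.ndarray       # per wedge, m
    live_area_fraction: float
    time_to_max_depth: float | None = None   # s, None if nothing died
    wedge_bearings: np.ndarray | None = None  # rad CW from north

    @property
    def max_depth(self) -> float:
        return float(self.necrotic_depth.max())

    @property
    def girdled(self) -> bool:
        """True when every wedge shows some necrosis."""
        return bool(np.all(self.necrotic_depth > 0))

    def to_frame(self):
        import pandas as pd

        bearings = (self.wedge_bearings if self.wedge_bearings is not None
                    else np.full(self.necrotic_depth.size, np.nan))
        return pd.DataFrame({
            "wedge": np.arange(1, self.necrotic_depth.size + 1),
            "bearing_deg": np.degrees(bearings),
            "necrotic_depth_mm": self.necrotic_depth * 1e3,
        })


def necrotic_depth(log_N: np.ndarray, grid, params: ViabilityParams = ViabilityParams(),
                   time_to_max_depth: float | None = None) -> InjuryResult:
    """Per-wedge necrotic depth and live-area fraction from final viability.

    Depth in a wedge is the surface radius minus the radius of the deepest
    node with N below the death threshold (zero when none died).  The live
    area fraction weights surviving nodes by their control-volume areas.
    """
    log_thresh = np.log(params.death_threshold)
    dead = log_N < log_thresh
    n_radial, n_wedges = dead.shape
    depth = np.zeros(n_wedges)
    for j in range(n_wedges):
        idx = np.nonzero(dead[:, j])[0]
        if idx.size:
            depth[j] = grid.surface_radius - grid.node_radii[idx[-1]]
    live_area = float((grid.cv_volumes[:, np.newaxis] * ~dead).sum())
    total_area = grid.cv_volumes.sum() * n_wedges
    return InjuryResult(
        necrotic_depth=depth,
        live_area_fraction=live_area / total_area,
        time_to_max_depth=time_to_max_depth,
        wedge_bearings=grid.wedge_angles.copy(),
    )
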