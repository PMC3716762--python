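"""Independent reference solutions for solver verification.

Contains a deliberately simple forward-Euler finite-volume integrator
(assembled from neighbor differences, sharing only the grid geometry and
property functions with the implicit solver) and two closed-form conduction
benchmarks: the steady logarithmic annulus profile and the Bessel-series
transient response of a cylinder to a step surface temperature.
"""

from __future__ import annotations

import numpy as np
from scipy.special import j0, j1, jn_zeros

from .forcing import STEFAN_BOLTZMANN, ForcingSeries
from .grid import PolarGrid
from .solver import RunConfig, SimulationState


def explicit_reference_run(grid: PolarGrid, property_model, config: RunConfig,
                           forcing: ForcingSeries, state: SimulationState,
                           dt: float, total_time: float) -> np.ndarray:
    """Forward-Euler oracle: returns the temperature field at ``total_time``.

    Sinks, charring and viability are not modelled; the surface carries the
    prescribed fire flux plus explicit black-body exchange with ambient.
    """
    g = grid
    nr, nw = g.shape
    T = state.T.copy()
    st = state.copy()
    dr = g.geometry.radial_spacing
    dtheta = g.dtheta
    area_r = g.face_radii[1:-1] * dtheta            # radial faces
    area_t = (g.face_radii[:-1] - g.face_radii[1:])  # circumferential faces
    dist_t = g.node_radii * dtheta
    surf_area = g.surface_radius * dtheta
    V = g.cv_volumes[:, np.newaxis]

    n_steps = int(round(total_time / dt))
    t = state.time
    for _ in range(n_steps):
        st.T = T
        rho, k, cp = property_model.evaluate(g, st)
        heat = np.zeros_like(T)  # W per node

        kf = 2.0 * k[:-1, :] * k[1:, :] / (k[:-1, :] + k[1:, :])
        flux = kf * area_r[:, np.newaxis] * (T[1:, :] - T[:-1, :]) / dr
        heat[:-1, :] += flux
        heat[1:, :] -= flux

        k_east = np.roll(k, -1, axis=1)
        kf_t = 2.0 * k * k_east / (k + k_east)
        flux_t = kf_t * area_t[:, np.newaxis] * \
            (np.roll(T, -1, axis=1) - T) / dist_t[:, np.newaxis]
        heat += flux_t - np.roll(flux_t, 1, axis=1)

        q_fire = forcing.flux_at(t, nw)
        T_o = forcing.ambient_at(t)
        q_rad = STEFAN_BOLTZMANN * (T_o ** 4 - T[0, :] ** 4)
        heat[0, :] += (q_fire + q_rad) * surf_area

        T = T + dt * heat / (rho * cp * V)
        t += dt
    return T


def log_annulus_profile(r, r_a, r_b, T_a, T_b):
    """Steady conduction profile between fixed temperatures at r_a and r_b."""
    r = np.asarray(r, dtype=float)
    return T_a + (T_b - T_a) * np.log(r / r_a) / np.log(r_b / r_a)


def cylinder_step_response(r, t, radius, diffusivity, T_init, T_surface,
                           n_terms: int = 60):
    """Transient temperature in a solid cylinder after a surface step.

    Series solution T = T_s + (T_i - T_s) * sum 2/(l_n J1(l_n)) J0(l_n r/R)
    exp(-l_n^2 Fo) with l_n the roots of J0 and Fo = alpha t / R^2.
    """
    if np.ndim(r) != 0:
        raise ValueError("r must be a scalar (evaluate one radius at a time)")
    lam = jn_zeros(0, n_terms)
    fo = np.atleast_1d(np.asarray(t, dtype=float)) * diffusivity / radius ** 2
    coeff = 2.0 / (lam * j1(lam)) * j0(lam * (r / radius))
    theta = (coeff[:, np.newaxis] * np.exp(-np.outer(lam ** 2, fo))).sum(axis=0)
    out = T_surface + (T_init - T_surface) * theta
    return float(out[0]) if out.size == 1 else out
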