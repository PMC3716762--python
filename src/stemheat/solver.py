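"""Crank-Nicolson time integration of 2-D polar heat conduction in a stem.

The semi-discrete finite-volume system couples every node radially (face
areas r*dtheta, harmonic-mean face conductivity) and circumferentially
(periodic in the wedge index), with a prescribed-flux boundary at the bark
surface and a no-flux center.  Each step performs, in order:

1. implicit conduction (theta-weighted, 0.5 = Crank-Nicolson), with the
   surface radiant exchange linearized about the old surface temperature
   and treated implicitly for stability,
2. explicit water loss and its latent-heat sink (applied within the same
   linear system as a constant source term),
3. char-front advancement (at most one node per wedge per step),
4. property refresh from the updated water mass and char flags,
5. viability decay at the new temperatures.

Material properties entering the matrix are evaluated at the old time
level (linearized Crank-Nicolson).  The discrete energy budget closes
exactly by construction (flux-form stencil); the residual is tracked and
reported for every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import injury as injury_mod
from . import properties as props
from . import sinks as sinks_mod
from .forcing import STEFAN_BOLTZMANN, ForcingSeries
from .grid import PolarGrid, WOOD
from .injury import InjuryResult, ViabilityParams
from .properties import SpeciesParams


@dataclass
class RunConfig:
    """Numerical and physical run configuration."""

    dt: float = 1.0
    total_time: float = 600.0
    theta: float = 0.5                   # time-weighting; 0.5 = Crank-Nicolson
    output_every: float = 10.0           # snapshot cadence, s
    initial_temperature: float = 300.0   # K
    enable_sinks: bool = True
    enable_viability: bool = True
    latent_heat: float = sinks_mod.DEFAULT_LATENT_HEAT        # J/kg
    # the printed drying kinetics are slow but non-zero at room temperature;
    # evaporation is gated above this onset so an unforced stem does not
    # evaporatively cool on long horizons
    desiccation_onset_temperature: float = 310.0              # K
    char_heat: float = 4.0e5                                  # J/kg pyrolyzed
    char_conductivity: float = sinks_mod.DEFAULT_CHAR_CONDUCTIVITY
    char_heat_capacity: float = sinks_mod.DEFAULT_CHAR_HEAT_CAPACITY  # kJ/(kg K)
    viability: ViabilityParams = field(default_factory=ViabilityParams)
    # verification hooks: pin the surface / an interior ring temperature
    fixed_surface_temperature: float | None = None
    fixed_inner_temperature: float | None = None
    fixed_inner_index: int = -1          # radial ring carrying the inner pin

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.total_time < 0:
            raise ValueError("total_time must be non-negative")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1]")


@dataclass
class SimulationState:
    """Full model state at one time instant (arrays are (n_radial, n_wedges))."""

    time: float
    T: np.ndarray
    water_mass: np.ndarray      # kg per control volume (per unit height)
    dry_mass: np.ndarray        # kg per control volume (per unit height)
    char: sinks_mod.CharState
    log_N: np.ndarray           # log viability

    @property
    def moisture(self) -> np.ndarray:
        return self.water_mass / self.dry_mass

    @property
    def viability(self) -> np.ndarray:
        return np.exp(self.log_N)

    def copy(self) -> "SimulationState":
        return SimulationState(self.time, self.T.copy(), self.water_mass.copy(),
                               self.dry_mass.copy(), self.char.copy(),
                               self.log_N.copy())


class ConstantPropertyModel:
    """Uniform constant properties (solver verification)."""

    def __init__(self, rho: float, k: float, cp: float):
        self.rho, self.k, self.cp = rho, k, cp  # kg/m^3, W/(m K), J/(kg K)

    def evaluate(self, grid: PolarGrid, state: SimulationState):
        shape = state.T.shape
        return (np.full(shape, self.rho), np.full(shape, self.k),
                np.full(shape, self.cp))


class StemPropertyModel:
    """Zone-, moisture-, char- and temperature-dependent stem properties."""

    def __init__(self, grid: PolarGrid, species: SpeciesParams, config: RunConfig):
        self.species = species
        self.config = config
        labels = np.array(grid.zone_labels)
        self.wood_mask = (labels == WOOD)[:, np.newaxis]

    def evaluate(self, grid: PolarGrid, state: SimulationState):
        V = grid.cv_volumes[:, np.newaxis]
        rho = (state.dry_mass + state.water_mass) / V
        rho_dry = state.dry_mass / V
        M = state.moisture
        T = state.T

        k = np.where(
            self.wood_mask,
            props.wood_conductivity(rho, self.species.dry_wood_density, M),
            props.bark_conductivity(np.maximum(rho_dry, 1.0), M, T),
        )
        cp = np.where(
            self.wood_mask,
            props.wood_heat_capacity(T, M),
            props.bark_heat_capacity(T, M),
        ) * 1e3  # kJ -> J

        charred = state.char.flags
        if charred.any():
            k = np.where(charred, self.config.char_conductivity, k)
            cp = np.where(charred, self.config.char_heat_capacity * 1e3, cp)
        return rho, k, cp


def initial_state(grid: PolarGrid, species: SpeciesParams,
                  config: RunConfig) -> SimulationState:
    """Uniform-temperature initial state with the radial moisture profile."""
    nr, nw = grid.shape
    V = grid.cv_volumes
    labels = np.array(grid.zone_labels)
    dry_density = np.where(labels == WOOD, species.dry_wood_density,
                           species.dry_bark_density)
    moisture = np.empty(nr)
    r_d = grid.cambium_radius
    for i in range(nr):
        if labels[i] == WOOD:
            r = min(grid.node_radii[i], r_d)
            moisture[i] = props.initial_moisture_profile(r, r_d, species)
        elif labels[i] == "inner_bark":
            moisture[i] = species.inner_bark_m
        else:
            moisture[i] = species.outer_bark_m

    dry_mass = np.tile((dry_density * V)[:, np.newaxis], (1, nw))
    water_mass = np.tile((dry_density * V * moisture)[:, np.newaxis], (1, nw))
    return SimulationState(
        time=0.0,
        T=np.full((nr, nw), float(config.initial_temperature)),
        water_mass=water_mass,
        dry_mass=dry_mass,
        char=sinks_mod.CharState(nr, nw),
        log_N=np.zeros((nr, nw)),
    )


def uniform_state(grid: PolarGrid, temperature: float,
                  dry_density: float = 500.0) -> SimulationState:
    """Dry, uniform-temperature state (constant-property verification runs)."""
    nr, nw = grid.shape
    V = grid.cv_volumes[:, np.newaxis]
    return SimulationState(
        time=0.0,
        T=np.full((nr, nw), float(temperature)),
        water_mass=np.zeros((nr, nw)),
        dry_mass=np.tile(dry_density * V, (1, nw)),
        char=sinks_mod.CharState(nr, nw),
        log_N=np.zeros((nr, nw)),
    )


@dataclass
class RunResult:
    """Trajectory, probe series, injury summary and energy budget."""

    grid: PolarGrid
    config: RunConfig
    snapshot_times: list
    snapshots: list                    # SimulationState at output cadence
    probe_times: np.ndarray
    probes: dict                       # name -> (n_steps, n_wedges) arrays
    final_state: SimulationState
    injury: InjuryResult
    energy: dict                       # input/sink/stored/residual, J per unit height

    def probe_frame(self, wedge: int = 1) -> pd.DataFrame:
        j = wedge - 1
        return pd.DataFrame({
            "time_s": self.probe_times,
            **{name: arr[:, j] for name, arr in self.probes.items()},
        })

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for t, st in zip(self.snapshot_times, self.snapshots):
            nr, nw = st.T.shape
            ii, jj = np.meshgrid(np.arange(nr), np.arange(nw), indexing="ij")
            rows.append(pd.DataFrame({
                "time_s": t,
                "radial_index": ii.ravel(),
                "wedge": jj.ravel() + 1,
                "r_m": self.grid.node_radii[ii.ravel()],
                "theta_rad": self.grid.wedge_angles[jj.ravel()],
                "T_K": st.T.ravel(),
                "moisture": st.moisture.ravel(),
                "viability": st.viability.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


class Simulator:
    """Stateful stepping engine for one grid / species / config / forcing."""

    def __init__(self, grid: PolarGrid, species: SpeciesParams | None,
                 config: RunConfig, forcing: ForcingSeries,
                 property_model=None):
        self.grid = grid
        self.species = species
        self.config = config
        self.forcing = forcing
        if property_model is None:
            if species is None:
                raise ValueError("need a species or an explicit property model")
            property_model = StemPropertyModel(grid, species, config)
        self.property_model = property_model
        self._build_topology()
        # cumulative energy bookkeeping (J per unit height)
        self.energy_in = 0.0
        self.energy_sunk = 0.0
        self.energy_stored = 0.0

    # -- geometry-only precomputation ------------------------------------
    def _build_topology(self) -> None:
        g = self.grid
        nr, nw = g.shape
        self.n_unknowns = nr * nw
        idx = np.arange(self.n_unknowns).reshape(nr, nw)
        self._idx = idx
        dr = g.geometry.radial_spacing
        dtheta = g.dtheta
        # radial faces between node i and i+1 (per wedge)
        self._rad_area = g.face_radii[1:-1] * dtheta       # (nr-1,)
        self._rad_dist = dr
        # circumferential faces between wedge j and j+1 (per ring)
        self._circ_area = g.face_radii[:-1] - g.face_radii[1:]  # (nr,)
        self._circ_dist = g.node_radii * dtheta
        # surface face arc length per wedge (area per unit height)
        self.surface_area = g.surface_radius * dtheta

    # -- operator assembly ------------------------------------------------
    def assemble_system(self, state: SimulationState, dt: float):
        """Build the theta-weighted linear system for one conduction step.

        Returns (A, b, aux) with aux carrying the pieces needed for the
        boundary application and energy bookkeeping.
        """
        g = self.grid
        nr, nw = g.shape
        rho, k, cp = self.property_model.evaluate(g, state)
        for name, arr in (("density", rho), ("conductivity", k), ("heat capacity", cp)):
            if not np.all(np.isfinite(arr)):
                i, j = np.unravel_index(int(np.argmin(np.isfinite(arr))), arr.shape)
                raise ValueError(f"non-finite {name} at node (i={i}, j={j})")

        V = g.cv_volumes[:, np.newaxis]
        C = (rho * cp * V / dt).ravel()  # W/K mass term

        def harmonic(a, b):
            s = a + b
            out = np.zeros_like(a)
            nz = s > 0
            out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
            return out

        rows, cols, vals = [], [], []

        def add_conductance(p, q, gcond):
            rows.extend([p, q, p, q])
            cols.extend([q, p, p, q])
            vals.extend([gcond, gcond, -gcond, -gcond])

        # radial coupling
        k_face_r = harmonic(k[:-1, :], k[1:, :])
        g_r = k_face_r * self._rad_area[:, np.newaxis] / self._rad_dist
        p = self._idx[:-1, :].ravel()
        q = self._idx[1:, :].ravel()
        add_conductance(p, q, g_r.ravel())

        # circumferential (periodic) coupling
        k_face_t = harmonic(k, np.roll(k, -1, axis=1))
        g_t = k_face_t * self._circ_area[:, np.newaxis] / self._circ_dist[:, np.newaxis]
        p = self._idx.ravel()
        q = np.roll(self._idx, -1, axis=1).ravel()
        add_conductance(p, q, g_t.ravel())

        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_unknowns, self.n_unknowns)).tocsr()

        theta = self.config.theta
        A = sp.diags(C).tocsr() - theta * K
        b = C * state.T.ravel() + (1.0 - theta) * (K @ state.T.ravel())
        aux = {"C": C, "rho": rho, "k": k, "cp": cp, "K": K}
        return A, b, aux

    def apply_boundary(self, A, b, aux, state: SimulationState, dt: float,
                       sink_power: np.ndarray):
        """Add surface forcing, linearized radiant exchange and sink terms."""
        g = self.grid
        nr, nw = g.shape
        t = state.time
        surf = self._idx[0, :]

        # fire flux averaged over the step (trapezoid in t)
        q_fire = 0.5 * (self.forcing.flux_at(t, nw)
                        + self.forcing.flux_at(t + dt, nw))
        T_o = self.forcing.ambient_at(t + 0.5 * dt)
        T_s = state.T[0, :]

        # radiant exchange linearized about the old surface temperature and
        # treated implicitly: q = sigma T_o^4 + 3 sigma T_s^4 - 4 sigma T_s^3 T_new
        sig = STEFAN_BOLTZMANN
        rad_const = sig * T_o ** 4 + 3.0 * sig * T_s ** 4
        rad_slope = 4.0 * sig * T_s ** 3

        A = A + sp.coo_matrix(
            (rad_slope * self.surface_area, (surf, surf)),
            shape=A.shape).tocsr()
        b = b.copy()
        b[surf] += (q_fire + rad_const) * self.surface_area
        b -= sink_power.ravel()

        # verification hooks: Dirichlet rows
        fixed = []
        if self.config.fixed_surface_temperature is not None:
            fixed.append((self._idx[0, :], self.config.fixed_surface_temperature))
        if self.config.fixed_inner_temperature is not None:
            fixed.append((self._idx[self.config.fixed_inner_index, :],
                          self.config.fixed_inner_temperature))
        if fixed:
            A = A.tolil()
            for idx_row, value in fixed:
                A[idx_row, :] = 0.0
                A[idx_row, idx_row] = 1.0
                b[idx_row] = value
            A = A.tocsr()

        bc = {"q_fire": q_fire, "rad_const": rad_const, "rad_slope": rad_slope,
              "dirichlet": bool(fixed)}
        return A, b, bc

    # -- one full step ----------------------------------------------------
    def step(self, state: SimulationState) -> SimulationState:
        cfg = self.config
        dt = cfg.dt
        g = self.grid
        nr, nw = g.shape
        V = g.cv_volumes[:, np.newaxis]

        # (2-prep) explicit sinks evaluated at the old state
        sink_power = np.zeros((nr, nw))
        water_rate = np.zeros((nr, nw))
        if cfg.enable_sinks:
            rho_old, _, _ = self.property_model.evaluate(g, state)
            water_rate = sinks_mod.water_loss_rate(
                state.moisture, state.T, rho_old, V,
                self.species.water_loss_rate if self.species else 0.5)
            water_rate = np.where(
                state.T > cfg.desiccation_onset_temperature, water_rate, 0.0)
            # a node cannot lose more water than it holds in one step
            water_rate = np.minimum(water_rate, state.water_mass / dt)
            sink_power += cfg.latent_heat * water_rate

        # (1) implicit conduction
        A, b, aux = self.assemble_system(state, dt)
        A, b, bc = self.apply_boundary(A, b, aux, state, dt, sink_power)
        T_flat = spla.spsolve(A.tocsc(), b)
        residual = np.linalg.norm(A @ T_flat - b)
        scale = np.linalg.norm(b) or 1.0
        if not np.isfinite(residual) or residual / scale > 1e-8:
            raise RuntimeError(
                f"linear solve failed: relative residual {residual / scale:.3e}")
        T_new = T_flat.reshape(nr, nw)

        new = state.copy()
        new.time = state.time + dt
        new.T = T_new

        # (2) water mass update
        if cfg.enable_sinks:
            new.water_mass = np.maximum(state.water_mass - water_rate * dt, 0.0)

        # (3) charring: bark only, desiccated and hot nodes, one node/step
        char_energy = 0.0
        pm = self.species.pyrolysis_multiplier if self.species else 0.0
        if cfg.enable_sinks and pm > 0:
            rho_dry = new.dry_mass / V
            rates = sinks_mod.charring_rate(rho_dry, new.T, pm) * V
            bark = ~np.array([z == WOOD for z in g.zone_labels])[:, np.newaxis]
            eligible = bark & (new.moisture < 0.02) & \
                (new.T > sinks_mod.CHAR_ONSET_TEMPERATURE)
            rates = np.where(eligible, rates, 0.0)
            prev_front = new.char.front.copy()
            new.char = sinks_mod.advance_char_front(new.char, rates, dt)
            flipped = new.char.front > prev_front
            if flipped.any():
                for j in np.nonzero(flipped)[0]:
                    i = prev_front[j]
                    converted = new.dry_mass[i, j] * (1.0 - sinks_mod.CHAR_DENSITY_FRACTION)
                    new.dry_mass[i, j] -= converted
                    new.water_mass[i, j] = 0.0
                    char_energy += cfg.char_heat * converted

        # (5) viability at the new temperatures
        if cfg.enable_viability:
            new.log_N = injury_mod.update_log_viability(
                new.log_N, new.T, dt, cfg.viability)

        # energy bookkeeping (exact for the applied discrete operators)
        if not bc["dirichlet"]:
            q_rad = bc["rad_const"] - bc["rad_slope"] * T_new[0, :]
            self.energy_in += float(
                ((bc["q_fire"] + q_rad) * self.surface_area).sum() * dt)
            self.energy_sunk += float(sink_power.sum() * dt) + char_energy
            self.energy_stored += float((aux["C"] * (T_flat - state.T.ravel())).sum() * dt)
        return new

    # -- full run ---------------------------------------------------------
    def run(self, state: SimulationState | None = None) -> RunResult:
        cfg = self.config
        g = self.grid
        if state is None:
            if self.species is None:
                raise ValueError("initial state required for constant-property runs")
            state = initial_state(g, self.species, cfg)
        if cfg.total_time > self.forcing.t_end + 1e-9:
            raise ValueError("forcing series does not cover the run horizon")

        n_steps = int(round(cfg.total_time / cfg.dt))
        every = max(1, int(round(cfg.output_every / cfg.dt)))
        i_sub = min(1, g.n_radial - 1)
        i_cam = min(g.cambium_index, g.n_radial - 1)

        snapshot_times = [state.time]
        snapshots = [state.copy()]
        probe_t = [state.time]
        probe = {"T_surface_K": [state.T[0, :].copy()],
                 "T_subsurface_K": [state.T[i_sub, :].copy()],
                 "T_cambium_K": [state.T[i_cam, :].copy()]}
        log_thresh = np.log(cfg.viability.death_threshold)
        max_dead = 0
        time_to_max = None

        for n in range(n_steps):
            state = self.step(state)
            probe_t.append(state.time)
            probe["T_surface_K"].append(state.T[0, :].copy())
            probe["T_subsurface_K"].append(state.T[i_sub, :].copy())
            probe["T_cambium_K"].append(state.T[i_cam, :].copy())
            if cfg.enable_viability:
                dead_count = int((state.log_N < log_thresh).sum())
                if dead_count > max_dead:
                    max_dead = dead_count
                    time_to_max = state.time
            if (n + 1) % every == 0 or n == n_steps - 1:
                snapshot_times.append(state.time)
                snapshots.append(state.copy())

        inj = injury_mod.necrotic_depth(state.log_N, g, cfg.viability,
                                        time_to_max_depth=time_to_max)
        denom = max(abs(self.energy_in), abs(self.energy_stored), 1.0)
        energy = {
            "input_J": self.energy_in,
            "sinks_J": self.energy_sunk,
            "stored_J": self.energy_stored,
            "residual": abs(self.energy_stored + self.energy_sunk - self.energy_in) / denom,
        }
        return RunResult(
            grid=g, config=cfg,
            snapshot_times=snapshot_times, snapshots=snapshots,
            probe_times=np.asarray(probe_t),
            probes={k: np.asarray(v) for k, v in probe.items()},
            final_state=state, injury=inj, energy=energy,
        )


def run(grid: PolarGrid, species: SpeciesParams | None, config: RunConfig,
        forcing: ForcingSeries, property_model=None,
        state: SimulationState | None = None) -> RunResult:
    """Convenience wrapper: build a :class:`Simulator` and run it."""
    sim = Simulator(grid, species, config, forcing, property_model)
    return sim.run(state)
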