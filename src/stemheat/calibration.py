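"""Species-level water-loss-rate calibration.

The objective combines, over all sections of a species, a cambium
temperature-series term (both series resampled onto a common 200-second
grid) and a necrotic-depth term, each entering quadratically.  The search
over the water-loss-rate parameter is an exhaustive grid at step 0.05
followed by golden-section refinement; every evaluation is a full model
run, so the search is deterministic and derivative-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: resampling interval for the temperature error term, seconds
RESAMPLE_INTERVAL = 200.0

WM_BOUNDS = (0.01, 1.0)
GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ReferenceObservation:
    """One observed section: a probe temperature series and a necrotic depth."""

    times: np.ndarray              # s
    temperatures: np.ndarray       # K
    probe_depth_mm: float
    necrotic_depth_mm: float
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.temperatures.size:
            raise ValueError("times and temperatures must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.necrotic_depth_mm < 0:
            raise ValueError("necrotic depth must be non-negative")


@dataclass
class SimulatedSample:
    """Model output matched to one observation."""

    times: np.ndarray
    temperatures: np.ndarray
    necrotic_depth_mm: float


def _resampled(times, values, grid):
    return np.interp(grid, np.asarray(times, float), np.asarray(values, float))


def species_error(simulations, observations,
                  resample_interval: float = RESAMPLE_INTERVAL) -> float:
    """Combined temperature + necrotic-depth error over a species' sections.

    E = sum_is [ mean_t (T_sim - T_obs)^2 + (D_sim - D_obs)^2 ] with the
    temperature series compared on a shared grid at ``resample_interval``
    and depths in mm.  Zero iff every simulation reproduces its observation.
    """
    if len(simulations) != len(observations):
        raise ValueError(
            f"{len(simulations)} simulations vs {len(observations)} observations")
    err = 0.0
    for sim, obs in zip(simulations, observations):
        t_end = min(sim.times[-1], obs.times[-1])
        grid = np.arange(0.0, t_end + 1e-9, resample_interval)
        if grid.size < 2:
            grid = np.array([0.0, t_end])
        dT = _resampled(sim.times, sim.temperatures, grid) \
            - _resampled(obs.times, obs.temperatures, grid)
        err += float(np.mean(dT ** 2))
        err += float((sim.necrotic_depth_mm - obs.necrotic_depth_mm) ** 2)
    return err


@dataclass
class WmFit:
    """Result of the water-loss-rate search."""

    wm: float
    error: float
    profile: pd.DataFrame       # columns wm, error (grid stage)
    n_evaluations: int

    def to_json(self, species: str | None = None) -> str:
        return json.dumps({
            "species": species,
            "wm": self.wm,
            "error": self.error,
            "n_evaluations": self.n_evaluations,
            "profile": {
                "wm": self.profile["wm"].tolist(),
                "error": self.profile["error"].tolist(),
            },
        }, indent=2)


def fit_wm(observations, simulate, grid_step: float = 0.05,
           bounds: tuple = WM_BOUNDS, refine_tol: float = 0.01,
           resample_interval: float = RESAMPLE_INTERVAL) -> WmFit:
    """Fit the water-loss-rate parameter against reference observations.

    ``simulate`` is a callable mapping a candidate value to a list of
    :class:`SimulatedSample` (one per observation, same order).  The error
    profile over the initial grid is returned alongside the refined argmin.
    """
    if not observations:
        raise ValueError("need at least one observation")
    evals = {"n": 0}

    def objective(wm: float) -> float:
        evals["n"] += 1
        sims = simulate(wm)
        if sims is None or len(sims) == 0:
            raise RuntimeError(f"all simulations failed at wm={wm}")
        return species_error(sims, observations, resample_interval)

    lo, hi = bounds
    # grid aligned on multiples of the step (clipped into the bounds) so
    # round candidate values are sampled exactly
    grid = np.round(np.arange(0.0, hi + grid_step / 2, grid_step), 10)
    grid = np.unique(np.clip(grid, lo, hi))
    errors = np.array([objective(w) for w in grid])
    profile = pd.DataFrame({"wm": grid, "error": errors})
    k = int(np.argmin(errors))

    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    best_w, best_e = float(grid[k]), float(errors[k])
    if refine_tol and b > a:
        x1 = b - GOLDEN * (b - a)
        x2 = a + GOLDEN * (b - a)
        f1, f2 = objective(x1), objective(x2)
        while (b - a) > refine_tol:
            if f1 <= f2:
                b, x2, f2 = x2, x1, f1
                x1 = b - GOLDEN * (b - a)
                f1 = objective(x1)
            else:
                a, x1, f1 = x1, x2, f2
                x2 = a + GOLDEN * (b - a)
                f2 = objective(x2)
        for w, e in ((x1, f1), (x2, f2)):
            if e < best_e:
                best_w, best_e = float(w), float(e)
    return WmFit(wm=best_w, error=best_e, profile=profile,
                 n_evaluations=evals["n"])


# ---------------------------------------------------------------------------
# observation I/O
# ---------------------------------------------------------------------------

def read_observations(csv_path, metadata_path=None):
    """Read probe observations from CSV (+ optional JSON sidecar).

    The CSV needs columns time_s, T_K, probe_depth_mm and may carry several
    sections distinguished by a 'section' column; the sidecar maps section
    labels to {"necrotic_depth_mm": ..., ...metadata}.
    """
    df = pd.read_csv(csv_path)
    required = {"time_s", "T_K", "probe_depth_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{csv_path}: no observation rows")
    meta = {}
    if metadata_path is not None:
        with open(metadata_path) as fh:
            meta = json.load(fh)
    out = []
    groups = df.groupby("section") if "section" in df.columns else [("0", df)]
    for label, sub in groups:
        label = str(label)
        m = meta.get(label, {})
        out.append(ReferenceObservation(
            times=sub["time_s"].to_numpy(),
            temperatures=sub["T_K"].to_numpy(),
            probe_depth_mm=float(sub["probe_depth_mm"].iloc[0]),
            necrotic_depth_mm=float(m.get("necrotic_depth_mm", 0.0)),
            label=label,
            metadata=m,
        ))
    return out
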