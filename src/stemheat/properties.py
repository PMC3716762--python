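"""Moisture-, density- and temperature-dependent thermophysics of wood and bark.

All functions are pure and accept scalars or numpy arrays.  Units are SI
throughout (kg, m, s, K) except heat capacities, which follow the source
parameterizations and return kJ/(kg K); callers that need J/(kg K) scale by
1000.  The bark relations are published in calorie/gram/centimeter form and
are converted here once, with 1 cal = 4.184 J.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

CAL_TO_J = 4.184
WATER_DENSITY = 1000.0  # kg/m^3
#: conversion cal/(cm s K) -> W/(m K)
_CAL_CM_S_K = CAL_TO_J * 100.0

#: default radial breakpoints of the moisture profile, as fractions of the
#: cambium radius r_d: the profile fraction is P1 at the cambium, P2 halfway
#: in, P3 at the center, with linear interpolation between.
DEFAULT_MOISTURE_BREAKPOINTS = (1.0, 0.5, 0.0)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species thermophysical and calibration constants."""

    name: str
    dry_wood_density: float            # rho_w, kg/m^3
    dry_bark_density: float            # rho_b, kg/m^3
    max_moisture: float                # M, water mass / dry mass near the cambium
    p1: float = 1.0                    # moisture-profile fraction at the cambium
    p2: float = 0.5                    # ... halfway to the center
    p3: float = 0.2                    # ... at the center
    water_loss_rate: float = 0.5       # W_m, dimensionless, in [0.01, 1]
    pyrolysis_multiplier: float = 0.0  # P_m; 0 disables charring
    inner_bark_moisture: float | None = None   # defaults to max_moisture
    outer_bark_moisture: float | None = None   # defaults to 0.3 * max_moisture
    moisture_breakpoints: tuple = DEFAULT_MOISTURE_BREAKPOINTS

    def __post_init__(self) -> None:
        if self.dry_wood_density <= 0 or self.dry_bark_density <= 0:
            raise ValueError("dry densities must be positive")
        if self.max_moisture < 0:
            raise ValueError("max_moisture must be non-negative")
        for p in (self.p1, self.p2, self.p3):
            if not 0.0 <= p <= 1.0:
                raise ValueError("moisture profile fractions must lie in [0, 1]")
        if not 0.01 <= self.water_loss_rate <= 1.0:
            raise ValueError("water_loss_rate must lie in [0.01, 1]")

    @property
    def inner_bark_m(self) -> float:
        return self.max_moisture if self.inner_bark_moisture is None else self.inner_bark_moisture

    @property
    def outer_bark_m(self) -> float:
        return 0.3 * self.max_moisture if self.outer_bark_moisture is None else self.outer_bark_moisture

    def with_water_loss_rate(self, wm: float) -> "SpeciesParams":
        return replace(self, water_loss_rate=wm)


# ---------------------------------------------------------------------------
# wood
# ---------------------------------------------------------------------------

def initial_moisture_profile(r, r_d, params: SpeciesParams):
    """Initial wood moisture content at radius ``r`` (dry-basis, dimensionless).

    The maximum inner-bark moisture ``M`` is scaled by a piecewise-linear
    fraction anchored at the configured breakpoints: P1 at the cambium
    radius ``r_d``, P2 and P3 at the interior breakpoints.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > r_d * (1 + 1e-12)):
        raise ValueError("r must lie in [0, r_d]")
    b1, b2, b3 = params.moisture_breakpoints
    xp = np.array([b3, b2, b1]) * r_d
    fp = np.array([params.p3, params.p2, params.p1])
    frac = np.interp(r, xp, fp)
    out = params.max_moisture * frac
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def wood_moist_density(r, r_d, params: SpeciesParams):
    """Initial moist wood density rho_w * (1 + M(r)) in kg/m^3."""
    return params.dry_wood_density * (1.0 + initial_moisture_profile(r, r_d, params))


def wood_conductivity(rho, rho_w, moisture):
    """Thermal conductivity of moist wood, W/(m K).

    k = G_M (0.1941 + 0.4064 M) + 0.01864, with the specific gravity G_M
    computed from oven-dry mass per unit volume at moisture content M,
    relative to water: G_M = rho / ((1 + M) rho_water).
    """
    rho = np.asarray(rho, dtype=float)
    rho_w = np.asarray(rho_w, dtype=float)
    m = np.asarray(moisture, dtype=float)
    if np.any(rho < 0) or np.any(rho_w <= 0) or np.any(m < 0):
        raise ValueError("densities must be positive and moisture non-negative")
    g_m = rho / ((1.0 + m) * WATER_DENSITY)
    k = g_m * (0.1941 + 0.4064 * m) + 0.01864
    return k if k.ndim else float(k)


def wood_conductivity_from_gravity(g_m, moisture):
    """Conductivity from specific gravity directly (verification helper)."""
    return np.asarray(g_m) * (0.1941 + 0.4064 * np.asarray(moisture)) + 0.01864


def water_heat_capacity(T):
    """Heat capacity of wood-bound water, kJ/(kg K).

    c_pw = 3.8 + 130/(645 - T) for T <= 630 K, and 15 above; the lower
    branch is used at exactly 630 K.
    """
    T = np.asarray(T, dtype=float)
    low = 3.8 + 130.0 / (645.0 - np.minimum(T, 630.0))
    out = np.where(T <= 630.0, low, 15.0)
    return out if out.ndim else float(out)


def dry_wood_heat_capacity(T):
    """Heat capacity of dry wood c_p0 = 0.1031 + 0.00386 T, kJ/(kg K)."""
    T = np.asarray(T, dtype=float)
    out = 0.1031 + 0.00386 * T
    return out if out.ndim else float(out)


def wood_heat_capacity(T, moisture):
    """Heat capacity of moist wood, kJ/(kg K).

    Mass-weighted mixture of dry wood and water plus the wood-water bond
    correction A_c = M_pct (-0.06191 + 2.36e-4 T - 1.33e-4 M_pct) with
    M_pct the moisture content in percent.  (The bond term is transcribed
    from the wood-handbook form; the final coefficient multiplies M_pct.)
    """
    T = np.asarray(T, dtype=float)
    m = np.asarray(moisture, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    c_p0 = dry_wood_heat_capacity(T)
    c_pw = water_heat_capacity(T)
    m_pct = 100.0 * m
    a_c = m_pct * (-0.06191 + 2.36e-4 * T - 1.33e-4 * m_pct)
    out = (c_p0 + m * c_pw) / (1.0 + m) + a_c
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# bark
# ---------------------------------------------------------------------------

def bark_moist_density(rho_b, bark_moisture):
    """Moist bark density rho_b * (1 + M_bark), kg/m^3."""
    rho_b = np.asarray(rho_b, dtype=float)
    m = np.asarray(bark_moisture, dtype=float)
    if np.any(rho_b <= 0) or np.any(m < 0):
        raise ValueError("rho_b must be positive and bark moisture non-negative")
    out = rho_b * (1.0 + m)
    return out if out.ndim else float(out)


def bark_conductivity(rho_b, bark_moisture, T):
    """Thermal conductivity of bark, W/(m K).

    Three-term empirical sum in dry density (g/cm^3), moisture fraction and
    temperature (K), published in units of 1e-4 cal/(cm s K):

        k = (2.104 rho_g + 5.544 M + 3.266e-3 T - 0.166) * 1e-4 cal/(cm s K)

    converted to SI here.
    """
    rho_b = np.asarray(rho_b, dtype=float)
    m = np.asarray(bark_moisture, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    if np.any(rho_b <= 0) or np.any(m < 0):
        raise ValueError("rho_b must be positive and moisture non-negative")
    rho_g = rho_b / 1000.0  # kg/m^3 -> g/cm^3
    k_cal = (2.104 * rho_g + 5.544 * m + 3.266e-3 * T - 0.166) * 1e-4
    out = k_cal * _CAL_CM_S_K
    return out if out.ndim else float(out)


def bark_heat_capacity(T, bark_moisture):
    """Heat capacity of moist bark, kJ/(kg K).

    Dry-bark line c_dry = 0.2646 + 1.17e-3 (T - 273.15) cal/(g K), mixed
    with water by mass, plus the empirical moisture correction
    delta_c = M (1.82e-4 T - 2.02e-2) cal/(g K), which vanishes when dry.
    """
    T = np.asarray(T, dtype=float)
    m = np.asarray(bark_moisture, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    c_dry = 0.2646 + 1.17e-3 * (T - 273.15)
    c_w = 1.0  # cal/(g K)
    delta_c = m * (1.82e-4 * T - 2.02e-2)
    out = ((c_dry + m * c_w) / (1.0 + m) + delta_c) * CAL_TO_J
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# species fixture table
# ---------------------------------------------------------------------------

def load_species_table() -> pd.DataFrame:
    """Load the bundled per-section species parameter table."""
    with resources.files("stemheat.data").joinpath("species_params.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def species_from_table(species: str, table: pd.DataFrame | None = None,
                       tree: int | None = None, section: int | None = None,
                       **overrides) -> SpeciesParams:
    """Build :class:`SpeciesParams` for one species (optionally one section).

    Without ``tree``/``section`` the species-mean moisture and density are
    used; with them, the matching section row is used.
    """
    df = load_species_table() if table is None else table
    rows = df[df["species"].str.lower() == species.lower()]
    if rows.empty:
        raise KeyError(f"species {species!r} not found in the parameter table")
    if tree is not None:
        rows = rows[rows["tree"] == tree]
        if section is not None:
            rows = rows[rows["section"] == section]
        if rows.empty:
            raise KeyError(f"no row for {species!r} tree={tree} section={section}")
    first = rows.iloc[0]
    kwargs = dict(
        name=first["species"],
        dry_wood_density=float(rows["density_g_cm3"].mean()) * 1000.0,
        # bark density is not measured separately in the fixture; use wood density
        dry_bark_density=float(rows["density_g_cm3"].mean()) * 1000.0,
        max_moisture=float(rows["moisture_pct"].mean()) / 100.0,
        p1=float(first["p1"]),
        p2=float(first["p2"]),
        p3=float(first["p3"]),
        water_loss_rate=float(first["wm"]),
    )
    kwargs.update(overrides)
    return SpeciesParams(**kwargs)


def section_geometry(species: str, tree: int, section: int,
                     n_wedges: int = 16, radial_spacing: float = 1e-3,
                     outer_bark_fraction: float = 0.33):
    """Stem geometry for one measured section.

    The fixture records total bark thickness only; it is split between
    outer and inner bark by ``outer_bark_fraction``.
    """
    from .grid import StemGeometry

    df = load_species_table()
    rows = df[(df["species"].str.lower() == species.lower())
              & (df["tree"] == tree) & (df["section"] == section)]
    if rows.empty:
        raise KeyError(f"no section {species!r} {tree}-{section}")
    row = rows.iloc[0]
    bark = float(row["bark_thickness_mm"]) / 1000.0
    return StemGeometry(
        diameter=float(row["diameter_mm"]) / 1000.0,
        outer_bark_thickness=outer_bark_fraction * bark,
        inner_bark_thickness=(1.0 - outer_bark_fraction) * bark,
        n_wedges=n_wedges,
        radial_spacing=radial_spacing,
    )
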