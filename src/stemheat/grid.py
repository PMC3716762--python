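"""Polar finite-volume discretization of a horizontal stem slice.

The slice is divided into ``n_wedges`` uniform angular wedges; each wedge
carries the same column of radial nodes.  Node 0 sits at the bark surface
(its outer control-volume face coincides with the stem surface so the flux
boundary condition applies at a node); nodes proceed inward with uniform
spacing.  The geometric center is not a node: the innermost ring's inner
face is collapsed to r = 0, which absorbs the small central disc and makes
the control volumes tile the full cross-section exactly.  Heat crosses the
center only by diffusing circumferentially around the innermost ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

OUTER_BARK = "outer_bark"
INNER_BARK = "inner_bark"
WOOD = "wood"


@dataclass(frozen=True)
class StemGeometry:
    """Stem cross-section geometry.

    Parameters
    ----------
    diameter : float
        Stem diameter in meters.
    outer_bark_thickness, inner_bark_thickness : float
        Bark layer thicknesses in meters (may be zero).
    n_wedges : int
        Number of uniform angular wedges (>= 4).
    radial_spacing : float
        Distance between adjacent radial nodes in meters.
    """

    diameter: float
    outer_bark_thickness: float = 0.0
    inner_bark_thickness: float = 0.0
    n_wedges: int = 16
    radial_spacing: float = 1e-3

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.outer_bark_thickness < 0 or self.inner_bark_thickness < 0:
            raise ValueError("bark thicknesses must be non-negative")
        if self.outer_bark_thickness + self.inner_bark_thickness >= self.diameter / 2:
            raise ValueError("total bark thickness must be less than the stem radius")
        if self.n_wedges < 4:
            raise ValueError("n_wedges must be at least 4")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be positive")
        if self.radial_spacing > self.diameter / 2:
            raise ValueError("radial_spacing exceeds the stem radius")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def bark_thickness(self) -> float:
        return self.outer_bark_thickness + self.inner_bark_thickness


@dataclass(frozen=True)
class PolarGrid:
    """Discretized stem slice.

    Radial index ``i`` runs 0 (surface) .. n_radial-1 (innermost ring);
    wedge index ``j`` runs 0 .. n_wedges-1 and maps to the 1-based wedge
    numbering via ``j + 1``.  All face areas and volumes are per unit stem
    height.
    """

    geometry: StemGeometry
    node_radii: np.ndarray          # (n_radial,), strictly decreasing, [0] = surface
    face_radii: np.ndarray          # (n_radial+1,), outer face of node i at [i]
    wedge_angles: np.ndarray        # (n_wedges,), wedge-center bearings, rad CW from north
    cv_volumes: np.ndarray          # (n_radial,), volume per unit height per wedge, m^3/m
    zone_labels: tuple              # (n_radial,), one of {outer_bark, inner_bark, wood}
    _wedge_width: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_wedge_width", 2.0 * np.pi / self.n_wedges)

    @property
    def n_radial(self) -> int:
        return self.node_radii.size

    @property
    def n_wedges(self) -> int:
        return self.geometry.n_wedges

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.n_wedges

    @property
    def shape(self) -> tuple:
        return (self.n_radial, self.n_wedges)

    @property
    def n_nodes(self) -> int:
        return self.n_radial * self.n_wedges

    @property
    def surface_radius(self) -> float:
        return float(self.face_radii[0])

    @property
    def n_bark(self) -> int:
        """Number of bark nodes (outer + inner) per wedge."""
        return sum(1 for z in self.zone_labels if z != WOOD)

    @property
    def cambium_index(self) -> int:
        """Radial index of the first wood node (bark/wood interface)."""
        return self.n_bark

    @property
    def cambium_radius(self) -> float:
        """Radial distance from the center to the vascular cambium."""
        return float(self.face_radii[self.n_bark])

    def total_volume(self) -> float:
        return float(self.cv_volumes.sum() * self.n_wedges)

    def node_depth(self, i) -> np.ndarray:
        """Depth of node i below the bark surface (m)."""
        return self.surface_radius - self.node_radii[i]


def build_grid(geometry: StemGeometry) -> PolarGrid:
    """Build the polar finite-volume grid for a stem cross-section.

    Bark thicknesses are rounded to the nearest whole number of radial
    nodes (at least one node for a non-zero thickness).  Warns when the
    spacing cannot resolve a non-zero bark layer.
    """
    R = geometry.radius
    dr = geometry.radial_spacing
    n_radial = int(round(R / dr))
    if n_radial < 2:
        raise ValueError("grid needs at least two radial nodes; reduce radial_spacing")

    node_radii = R - dr * np.arange(n_radial)

    # faces midway between nodes; outer face on the surface; innermost face
    # collapsed to the center so the volumes tile the full disc
    face_radii = np.empty(n_radial + 1)
    face_radii[0] = R
    face_radii[1:-1] = 0.5 * (node_radii[:-1] + node_radii[1:])
    face_radii[-1] = 0.0

    dtheta = 2.0 * np.pi / geometry.n_wedges
    cv_volumes = 0.5 * dtheta * (face_radii[:-1] ** 2 - face_radii[1:] ** 2)
    wedge_angles = dtheta * (np.arange(geometry.n_wedges) + 0.5)

    labels = _zone_labels(geometry, n_radial, dr)

    grid = PolarGrid(
        geometry=geometry,
        node_radii=node_radii,
        face_radii=face_radii,
        wedge_angles=wedge_angles,
        cv_volumes=cv_volumes,
        zone_labels=labels,
    )
    return grid


def _zone_labels(geometry: StemGeometry, n_radial: int, dr: float) -> tuple:
    def n_nodes_for(thickness: float, name: str) -> int:
        if thickness <= 0:
            return 0
        n = int(round(thickness / dr))
        if n == 0:
            warnings.warn(
                f"radial_spacing {dr:g} m under-resolves the {name} "
                f"({thickness:g} m); using a single node",
                stacklevel=3,
            )
            n = 1
        return n

    n_outer = n_nodes_for(geometry.outer_bark_thickness, "outer bark")
    n_inner = n_nodes_for(geometry.inner_bark_thickness, "inner bark")
    if n_outer + n_inner >= n_radial:
        raise ValueError("bark occupies the whole grid; refine radial_spacing")
    labels = [OUTER_BARK] * n_outer + [INNER_BARK] * n_inner
    labels += [WOOD] * (n_radial - len(labels))
    return tuple(labels)


def wedge_of_angle(grid: PolarGrid, bearing: float) -> int:
    """Map a bearing (radians clockwise from north) to a 1-based wedge index.

    Wedge 1 spans [0, dtheta) from north; indices increase clockwise.
    Angles are wrapped mod 2*pi.
    """
    b = float(bearing) % (2.0 * np.pi)
    j = int(b // grid.dtheta) + 1
    # guard against b // dtheta == n_wedges from roundoff at the wrap point
    return min(j, grid.n_wedges)
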