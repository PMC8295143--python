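"""Simulation domain and electrode placement on a structured grid.

The model plane is the 2D longitudinal plane containing both needle axes:
x runs rightwards across the tissue, y runs downwards from the tissue
surface.  Two parallel needles enter from the surface; each carries an
insulated shaft and a conductive active segment of length L ending at the
tip.  Only this plane can represent all five protocol factors (active
length varies along the needles, so a transverse cross-section could not
express it).

Geometry is discretised on a uniform node lattice.  Nodes are labelled
tissue, left/right active electrode, or inactive shaft; the solvers treat
active-electrode nodes as Dirichlet conductors and shaft nodes as excluded
from conduction (electrically and thermally insulating).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Region",
    "ElectrodeConfig",
    "DomainSpec",
    "Grid",
    "GeometryError",
    "build_grid",
    "outer_probe_point",
]

MM = 1.0e-3


class GeometryError(ValueError):
    """Raised when a requested geometry cannot be laid out on the domain."""


class Region(IntEnum):
    TISSUE = 0
    LEFT_ACTIVE = 1
    RIGHT_ACTIVE = 2
    SHAFT = 3


@dataclass
class ElectrodeConfig:
    """Two parallel needle electrodes.

    Lengths in mm (clinician units); ``distance_mm`` is centre-to-centre.
    The applied voltage is the potential difference between the two active
    segments (left at +V, right at 0).
    """

    active_length_mm: float
    distance_mm: float
    voltage: float
    diameter_mm: float = 1.0
    insertion_depth_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.active_length_mm <= 0:
            raise GeometryError("active length must be positive")
        if self.distance_mm <= self.diameter_mm:
            raise GeometryError("electrode distance must exceed the diameter")
        if self.voltage < 0:
            raise GeometryError("voltage must be non-negative")
        if self.active_length_mm > self.insertion_depth_mm:
            raise GeometryError("active length cannot exceed insertion depth")


@dataclass
class DomainSpec:
    """Rectangular tissue domain, insulated (zero-flux) on all outer borders."""

    width_mm: float = 60.0
    height_mm: float = 60.0
    spacing_mm: float = 0.25
    margin_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0 or self.width_mm <= 0 or self.height_mm <= 0:
            raise GeometryError("domain dimensions and spacing must be positive")
        for name in ("width_mm", "height_mm"):
            extent = getattr(self, name)
            n = extent / self.spacing_mm
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise GeometryError(f"spacing must divide {name} evenly")


@dataclass
class Grid:
    """Node lattice with region labels and measurement points.

    Attributes
    ----------
    x, y : 1D arrays of node coordinates in metres (y downward from surface).
    region : 2D int array indexed ``[y, x]`` with :class:`Region` codes.
    """

    x: np.ndarray
    y: np.ndarray
    region: np.ndarray
    spacing: float
    electrodes: ElectrodeConfig
    domain: DomainSpec
    center_index: tuple[int, int] = field(default=(0, 0))  # (iy, ix)

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape

    @property
    def cell_area(self) -> float:
        """Nodal control-volume area, m²."""
        return self.spacing**2

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.region == Region.TISSUE

    @property
    def electrode_mask(self) -> np.ndarray:
        return self.region != Region.TISSUE

    @property
    def center_point(self) -> tuple[float, float]:
        """(x, y) of the inter-electrode centre point in metres."""
        iy, ix = self.center_index
        return float(self.x[ix]), float(self.y[iy])

    def nearest_index(self, x_m: float, y_m: float) -> tuple[int, int]:
        """Snap a physical point to the nearest node; raise if outside."""
        if not (self.x[0] - 1e-12 <= x_m <= self.x[-1] + 1e-12) or not (
            self.y[0] - 1e-12 <= y_m <= self.y[-1] + 1e-12
        ):
            raise GeometryError(f"point ({x_m:.4g}, {y_m:.4g}) m lies outside the domain")
        ix = int(np.argmin(np.abs(self.x - x_m)))
        iy = int(np.argmin(np.abs(self.y - y_m)))
        return iy, ix


def build_grid(domain: DomainSpec, electrodes: ElectrodeConfig) -> Grid:
    """Lay out both electrodes on the lattice and label every node.

    The active segment of each electrode covers the rectangle
    diameter × active_length ending at the tip (y = insertion depth); the
    shaft covers the same width from the surface down to the active segment.
    The centre measurement point is the node nearest the midpoint between
    the electrode axes at half the active length above the tips.
    """
    h = domain.spacing_mm * MM
    if domain.spacing_mm > electrodes.diameter_mm:
        raise GeometryError("grid spacing is coarser than the electrode diameter")
    nx = int(round(domain.width_mm / domain.spacing_mm)) + 1
    ny = int(round(domain.height_mm / domain.spacing_mm)) + 1
    x = np.arange(nx) * h
    y = np.arange(ny) * h

    width = domain.width_mm * MM
    xc = width / 2.0
    half_d = electrodes.distance_mm * MM / 2.0
    rad = electrodes.diameter_mm * MM / 2.0
    depth = electrodes.insertion_depth_mm * MM
    active_top = depth - electrodes.active_length_mm * MM

    margin = domain.margin_mm * MM
    if xc - half_d - rad < margin or xc + half_d + rad > width - margin:
        raise GeometryError("electrodes (plus margin) do not fit in the domain width")
    if depth + margin > domain.height_mm * MM:
        raise GeometryError("electrode tips (plus margin) do not fit in the domain height")

    region = np.full((ny, nx), int(Region.TISSUE), dtype=np.int8)
    eps = 1e-9
    for code, axis in ((Region.LEFT_ACTIVE, xc - half_d), (Region.RIGHT_ACTIVE, xc + half_d)):
        col = np.abs(x - axis) <= rad + eps
        if not col.any():
            raise GeometryError("electrode column missed every grid node")
        act = (y >= active_top - eps) & (y <= depth + eps)
        shaft = y < active_top - eps
        region[np.ix_(act, col)] = int(code)
        region[np.ix_(shaft, col)] = int(Region.SHAFT)

    grid = Grid(x=x, y=y, region=region, spacing=h, electrodes=electrodes, domain=domain)
    grid.center_index = grid.nearest_index(xc, depth - electrodes.active_length_mm * MM / 2.0)
    return grid


def outer_probe_point(grid: Grid) -> tuple[int, int]:
    """Node index (iy, ix) 3 mm lateral of the right electrode surface at tip depth.

    Mirrors the placement of the outer fibre-optic temperature probe in the
    validation experiments.
    """
    e = grid.electrodes
    xc = grid.domain.width_mm * MM / 2.0
    x_probe = xc + (e.distance_mm / 2.0 + e.diameter_mm / 2.0 + 3.0) * MM
    y_probe = e.insertion_depth_mm * MM
    return grid.nearest_index(x_probe, y_probe)
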