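"""Octagonal arena geometry.

The arena is a regular octagon divided into eight peripheral chambers by
radial dividers, with an open central region. Each chamber has a nosepoke
port (below a speaker) at the midpoint of its outer wall. Chambers are
numbered 0-7 counterclockwise starting from east; the ring adjacency maps
each chamber to its two neighbors.

All geometry lives in a planar cm frame with the origin at the arena
center. Conversion to camera pixels is an affine transform owned by the
synthetic-data generator / pose readers, not by this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

# Nominal dimensions of the physical arena (cm). The octagon is built from
# the longest diagonal; the resulting side (15.3 cm) is within machining
# slack of the nominal 15 cm.
N_PORTS = 8
SIDE_LENGTH_CM = 15.0
LONGEST_DIAGONAL_CM = 40.0
ENTRYWAY_WIDTH_CM = 5.5

_SECTOR = 2.0 * math.pi / N_PORTS  # 45 degrees


def _corner_angles() -> np.ndarray:
    # Corners sit between the wall-facing directions k*45deg.
    return np.arange(N_PORTS) * _SECTOR + _SECTOR / 2.0


@dataclass(frozen=True)
class ArenaGeometry:
    """Planar layout of the eight-chamber octagonal arena.

    Attributes
    ----------
    n_ports : int
        Number of chambers/ports on the ring (8).
    side_length, longest_diagonal, entryway_width : float
        Nominal dimensions in cm.
    chamber_polygons : list of (4, 2) arrays
        Quadrilateral per chamber, from the inner entry edge to the outer
        wall, in cm.
    divider_segments : list of ((x0, y0), (x1, y1))
        Radial dividers between adjacent chambers.
    port_positions : (8, 2) array
        Port location at the midpoint of each outer wall.
    adjacency : dict
        chamber -> (counterclockwise neighbor, clockwise neighbor).
    """

    n_ports: int = N_PORTS
    side_length: float = SIDE_LENGTH_CM
    longest_diagonal: float = LONGEST_DIAGONAL_CM
    entryway_width: float = ENTRYWAY_WIDTH_CM
    chamber_polygons: list = field(default_factory=list)
    divider_segments: list = field(default_factory=list)
    port_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    adjacency: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ArenaGeometry":
        """Build the standard arena from the nominal dimensions."""
        R = LONGEST_DIAGONAL_CM / 2.0
        # Inner octagon sized so each chamber's entry edge is one entryway.
        r_in = ENTRYWAY_WIDTH_CM / (2.0 * math.sin(_SECTOR / 2.0))
        ang = _corner_angles()
        outer = np.column_stack([R * np.cos(ang), R * np.sin(ang)])
        inner = np.column_stack([r_in * np.cos(ang), r_in * np.sin(ang)])

        polys = []
        dividers = []
        for k in range(N_PORTS):
            lo, hi = k - 1, k  # corner indices flanking wall k
            polys.append(
                np.array([inner[lo], outer[lo], outer[hi], inner[hi]])
            )
            dividers.append((tuple(inner[hi]), tuple(outer[hi])))

        apothem = R * math.cos(_SECTOR / 2.0)
        theta = np.arange(N_PORTS) * _SECTOR
        ports = np.column_stack([apothem * np.cos(theta), apothem * np.sin(theta)])
        adjacency = {
            k: ((k + 1) % N_PORTS, (k - 1) % N_PORTS) for k in range(N_PORTS)
        }
        return cls(
            chamber_polygons=polys,
            divider_segments=dividers,
            port_positions=ports,
            adjacency=adjacency,
        )

    @property
    def inner_radius(self) -> float:
        """Circumradius (cm) of the central open region."""
        return self.entryway_width / (2.0 * math.sin(_SECTOR / 2.0))

    def entry_point(self, chamber: int) -> np.ndarray:
        """Midpoint (cm) of the chamber's entryway edge."""
        poly = self.chamber_polygons[chamber]
        return (poly[0] + poly[3]) / 2.0

    def locate(self, xy) -> np.ndarray:
        """Classify points as chamber id 0-7, -1 for center, -2 outside.

        Both octagons (outer wall and inner entry ring) are regular, so
        containment reduces to projections onto the eight wall normals;
        the chamber id then follows from the angular sector. Boundary
        points count as the more central region.

        Parameters
        ----------
        xy : (n, 2) array of planar positions in cm (NaN rows -> -3).
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        nanrow = np.isnan(xy).any(axis=1)
        xy = np.where(nanrow[:, None], 0.0, xy)
        theta = np.arange(self.n_ports) * _SECTOR
        normals = np.column_stack([np.cos(theta), np.sin(theta)])  # (8, 2)
        proj = xy @ normals.T  # (n, 8)
        support = proj.max(axis=1)
        cos_half = math.cos(_SECTOR / 2.0)
        inner_apothem = self.inner_radius * cos_half
        outer_apothem = (self.longest_diagonal / 2.0) * cos_half

        out = np.full(len(xy), -2, dtype=int)
        angle = np.arctan2(xy[:, 1], xy[:, 0])
        sector = np.floor((angle + _SECTOR / 2.0) / _SECTOR).astype(int) % self.n_ports
        in_outer = support <= outer_apothem + 1e-12
        in_inner = support <= inner_apothem + 1e-12
        out[in_outer & ~in_inner] = sector[in_outer & ~in_inner]
        out[in_inner] = -1
        out[nanrow] = -3
        return out

    def is_adjacent(self, a: int, b: int) -> bool:
        return b in self.adjacency[a]

    def chamber_shapes(self) -> list[Polygon]:
        """Chamber polygons as shapely geometries (plotting/GIS export)."""
        return [Polygon(p) for p in self.chamber_polygons]

    def center_shape(self) -> Polygon:
        """Central open region as a shapely polygon."""
        r = self.inner_radius
        return Polygon(
            [(r * math.cos(a), r * math.sin(a)) for a in _corner_angles()]
        )
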