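"""Microscale computational domain: nine oriented nanochains in a square.

The domain is a ``domain_size`` square centred at the origin.  Nine rigid
rectangular nanochains sit on a 3x3 grid with pitch ``spacing`` (grid nodes
at every combination of -spacing, 0, +spacing); each rectangle may be
rotated to model the random in-plane orientations nanochains adopt in
suspension.  Chain walls move with the rigid-rotation velocity field

    u = -omega*(y - y_ci),   v = omega*(x - x_ci)

about the chain's grid node (x_ci, y_ci), which is how the rotating chains
stir the surrounding fluid while the geometry itself stays fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

#: Default seed for the seeded_random orientation mode.
DEFAULT_ORIENTATION_SEED = 20260305


@dataclass(frozen=True)
class ChainPlacement:
    """One nanochain rectangle: grid node, orientation and dimensions.

    ``ref_x, ref_y`` is the Table-position grid node about which the wall
    velocity rotates.  With the default centre pivot the rectangle's
    geometric centre coincides with the grid node; with the ``corner`` pivot
    (the behaviour of drawing tools that rotate a corner-based rectangle
    about its base point) the geometric centre moves off the node.
    """

    index: int            # 1..9
    ref_x: float          # rotation-centre x (m)
    ref_y: float          # rotation-centre y (m)
    angle: float          # in-plane rotation (rad)
    length: float         # rectangle long side (m)
    width: float          # rectangle short side (m)
    pivot: str = "center"  # 'center' | 'corner'

    def corners(self) -> np.ndarray:
        """(4, 2) array of rectangle corner coordinates after rotation."""
        L, W = self.length, self.width
        local = np.array([[-L / 2, -W / 2], [L / 2, -W / 2],
                          [L / 2, W / 2], [-L / 2, W / 2]])
        c, s = math.cos(self.angle), math.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        if self.pivot == "center":
            pts = local @ R.T
            pts[:, 0] += self.ref_x
            pts[:, 1] += self.ref_y
        elif self.pivot == "corner":
            # rotate about the lower-left corner at (ref - (L/2, W/2))
            base = np.array([self.ref_x - L / 2, self.ref_y - W / 2])
            pts = (local + np.array([L / 2, W / 2])) @ R.T + base
        else:
            raise ValueError(f"unknown pivot {self.pivot!r}")
        return pts

    def polygon(self) -> Polygon:
        return Polygon(self.corners())

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.length + self.width)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-rotated-rectangle test."""
        pts = self.corners()
        # local frame axes from the first edge
        origin = pts[0]
        ex = pts[1] - pts[0]
        ey = pts[3] - pts[0]
        lx = ((x - origin[0]) * ex[0] + (y - origin[1]) * ex[1]) / (ex @ ex)
        ly = ((x - origin[0]) * ey[0] + (y - origin[1]) * ey[1]) / (ey @ ey)
        return (lx >= 0) & (lx <= 1) & (ly >= 0) & (ly <= 1)

    def wall_velocity(self, omega: float, x, y):
        """Rigid-rotation velocity (u, v) at point(s) (x, y) for given omega."""
        return -omega * (np.asarray(y) - self.ref_y), omega * (np.asarray(x) - self.ref_x)

    def tangential_wall_velocity(self, omega: float, x, y):
        """Rigid-rotation velocity with its component normal to the nearest
        rectangle side removed (the 'tangential' wall convention)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        u, v = self.wall_velocity(omega, x, y)
        pts = self.corners()
        origin = pts[0]
        ex = pts[1] - pts[0]   # along length
        ey = pts[3] - pts[0]   # along width
        lx = ((x - origin[0]) * ex[0] + (y - origin[1]) * ex[1]) / (ex @ ex)
        ly = ((x - origin[0]) * ey[0] + (y - origin[1]) * ey[1]) / (ey @ ey)
        # distance (in metres) to the nearest side of each family
        d_len_sides = np.minimum(np.abs(ly), np.abs(1 - ly)) * self.width
        d_wid_sides = np.minimum(np.abs(lx), np.abs(1 - lx)) * self.length
        ex_hat = ex / np.linalg.norm(ex)
        ey_hat = ey / np.linalg.norm(ey)
        # nearest side runs along ex (long side) -> normal is ey_hat
        near_long = d_len_sides <= d_wid_sides
        nxs = np.where(near_long, ey_hat[0], ex_hat[0])
        nys = np.where(near_long, ey_hat[1], ex_hat[1])
        un = u * nxs + v * nys
        return u - un * nxs, v - un * nys


def wall_velocity(placement: ChainPlacement, omega: float, point):
    """Rigid-rotation wall velocity at ``point`` = (x, y) in metres."""
    u, v = placement.wall_velocity(omega, point[0], point[1])
    return float(u), float(v)


@dataclass(frozen=True)
class MicroGeometry:
    """The fluid domain: origin-centred square minus nine chain rectangles."""

    half_width: float                      # domain_size/2 (m)
    placements: tuple[ChainPlacement, ...]  # ordered, index 1..9

    @property
    def domain_size(self) -> float:
        return 2.0 * self.half_width

    @property
    def fluid_area(self) -> float:
        """Exact fluid area (chains are disjoint and inside the square)."""
        return self.domain_size**2 - sum(p.length * p.width for p in self.placements)

    def domain_polygon(self) -> Polygon:
        h = self.half_width
        return box(-h, -h, h, h)

    def polygons(self) -> dict:
        """Exportable polygon list: outer square plus one entry per chain."""
        return {
            "outer": list(map(list, self.domain_polygon().exterior.coords)),
            "chains": {p.index: p.corners().tolist() for p in self.placements},
        }

    def placement_report(self) -> list[dict]:
        """JSON-serializable placement summary."""
        return [
            {"index": p.index, "x": p.ref_x, "y": p.ref_y, "angle": p.angle,
             "length": p.length, "width": p.width, "pivot": p.pivot}
            for p in self.placements
        ]


class GeometryError(ValueError):
    """Chain placement violates the domain constraints."""


def build_chain_grid(params, orientation_mode: str = "seeded_random",
                     seed: int = DEFAULT_ORIENTATION_SEED,
                     pivot: str = "center") -> MicroGeometry:
    """Construct the 3x3 nanochain grid geometry.

    Parameters
    ----------
    params : MicroModelParams
        Supplies domain_size, spacing and chain dimensions.
    orientation_mode : {'aligned', 'seeded_random'}
        ``aligned`` sets every rotation angle to zero (useful for analytic
        oracles); ``seeded_random`` draws the nine angles uniformly on
        [0, pi) from ``seed`` (rectangles are pi-periodic).
    seed : int
        Seed for the random orientations; identical seeds give identical
        geometries.
    pivot : {'center', 'corner'}
        Point about which each rectangle is rotated when placed.

    Raises
    ------
    GeometryError
        If any rotated rectangle leaves the domain or two chains overlap.
    """
    s = params.spacing
    if orientation_mode == "aligned":
        angles = np.zeros(9)
    elif orientation_mode == "seeded_random":
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0.0, math.pi, size=9)
    else:
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")

    # Table ordering: chains 1-3 bottom row, 4-6 middle row, 7-9 top row.
    nodes = [(-s, -s), (0.0, -s), (s, -s),
             (-s, 0.0), (0.0, 0.0), (s, 0.0),
             (-s, s), (0.0, s), (s, s)]
    placements = tuple(
        ChainPlacement(index=i + 1, ref_x=x, ref_y=y, angle=float(angles[i]),
                       length=params.L_chain, width=params.W_chain, pivot=pivot)
        for i, (x, y) in enumerate(nodes)
    )
    geom = MicroGeometry(half_width=params.domain_size / 2.0, placements=placements)
    _validate_geometry(geom)
    return geom


def _validate_geometry(geom: MicroGeometry) -> None:
    domain = geom.domain_polygon()
    polys = [p.polygon() for p in geom.placements]
    for placement, poly in zip(geom.placements, polys):
        if not domain.contains(poly):
            raise GeometryError(
                f"chain {placement.index} leaves the domain after rotation "
                f"by {placement.angle:.3f} rad"
            )
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersects(polys[j]):
                raise GeometryError(
                    f"chains {geom.placements[i].index} and "
                    f"{geom.placements[j].index} overlap"
                )
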