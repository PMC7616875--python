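"""Hexagonal analysis grids over a study region.

Analyses are run at the nodes of a regular hexagonal lattice clipped to the
study-region polygon. A pointy-top offset-row layout is used: rows are
``spacing * sqrt(3)/2`` apart vertically, nodes within a row are ``spacing``
apart, and every other row is shifted by half a spacing, so nearest
neighbours are always exactly one spacing apart and interior nodes have six
neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box, shape

from pgsmap.errors import EmptyGridError, InvalidRegionError

ROW_PITCH = math.sqrt(3.0) / 2.0  # vertical pitch per unit spacing

__all__ = ["AnalysisGrid", "build_hex_grid", "hex_adjacency", "as_polygon"]


def as_polygon(region) -> Polygon:
    """Coerce a region given as a shapely Polygon, a GeoJSON-style mapping,
    or an ``(xmin, ymin, xmax, ymax)`` rectangle into a shapely Polygon."""
    if isinstance(region, Polygon):
        poly = region
    elif isinstance(region, dict):
        poly = shape(region)
        if not isinstance(poly, Polygon):
            raise InvalidRegionError(f"region geometry is {poly.geom_type}, expected Polygon")
    else:
        xmin, ymin, xmax, ymax = region
        poly = box(xmin, ymin, xmax, ymax)
    if poly.is_empty or poly.area <= 0 or not poly.is_valid:
        raise InvalidRegionError("region polygon is degenerate (zero area or invalid)")
    return poly


@dataclass
class AnalysisGrid:
    """Hexagonal lattice of analysis locations.

    Attributes
    ----------
    nodes : (n, 2) array of planar node coordinates (metres).
    spacing : centre-to-centre distance between adjacent nodes.
    region : study-region polygon the lattice was clipped to.
    adjacency : per-node lists of neighbouring node indices (shared hex edge).
    """

    nodes: np.ndarray
    spacing: float
    region: Polygon
    adjacency: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if not self.adjacency:
            self.adjacency = hex_adjacency(self)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


def _lattice_points(poly: Polygon, spacing: float) -> np.ndarray:
    """Offset-row hexagonal lattice over the region bounding box, clipped to
    the polygon (nodes within half a spacing of the boundary are kept so the
    lattice covers the region edge)."""
    xmin, ymin, xmax, ymax = poly.bounds
    vpitch = spacing * ROW_PITCH
    n_rows = int(math.floor((ymax - ymin) / vpitch)) + 1
    pts = []
    for r in range(n_rows + 1):
        y = ymin + r * vpitch
        x0 = xmin + (spacing / 2.0 if r % 2 else 0.0)
        n_cols = int(math.floor((xmax - x0) / spacing)) + 1
        for c in range(n_cols + 1):
            pts.append((x0 + c * spacing, y))
    pts = np.asarray(pts)
    # polygon distance is 0 for interior points, so one rule covers both
    # retention cases: inside, or within half a spacing of the boundary
    dists = shapely.distance(poly, shapely.points(pts))
    return pts[dists <= spacing / 2.0]


def build_hex_grid(region, spacing: float | None = None, target_n: int | None = None) -> AnalysisGrid:
    """Build the hexagonal analysis grid over ``region``.

    Exactly one of ``spacing`` (metres between adjacent nodes) or ``target_n``
    (desired clipped node count; spacing is then solved by bisection so the
    count lands within 5% of the target) must be given.
    """
    poly = as_polygon(region)
    if (spacing is None) == (target_n is None):
        raise ValueError("give exactly one of spacing or target_n")

    if spacing is not None:
        xmin, ymin, xmax, ymax = poly.bounds
        if spacing > max(xmax - xmin, ymax - ymin):
            raise EmptyGridError(
                f"spacing {spacing} exceeds the region extent; no lattice fits"
            )
        nodes = _lattice_points(poly, float(spacing))
        if len(nodes) == 0:
            raise EmptyGridError(f"spacing {spacing} exceeds the region extent; no nodes placed")
        return AnalysisGrid(nodes=nodes, spacing=float(spacing), region=poly)

    if target_n < 1:
        raise ValueError("target_n must be positive")
    # density heuristic: n ~ area / (s^2 * sqrt(3)/2)
    s0 = math.sqrt(poly.area / (target_n * ROW_PITCH))
    lo, hi = s0 / 4.0, s0 * 4.0
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        n = len(_lattice_points(poly, mid))
        if best is None or abs(n - target_n) < abs(best[1] - target_n):
            best = (mid, n)
        if abs(n - target_n) <= 0.05 * target_n:
            best = (mid, n)
            break
        if n > target_n:
            lo = mid  # too dense -> widen spacing
        else:
            hi = mid
    s, n = best
    if n == 0:
        raise EmptyGridError("could not place any node in region")
    if abs(n - target_n) > 0.05 * target_n:
        raise EmptyGridError(
            f"bisection stalled at {n} nodes for target {target_n}; check region geometry"
        )
    return AnalysisGrid(nodes=_lattice_points(poly, s), spacing=s, region=poly)


def hex_adjacency(grid: AnalysisGrid) -> list[list[int]]:
    """Neighbour lists: node pairs at distance <= 1.01 * spacing share a hex
    edge. Symmetric, no self-loops, at most six neighbours per node."""
    tree = cKDTree(grid.nodes)
    pairs = tree.query_pairs(r=1.01 * grid.spacing)
    adj: list[list[int]] = [[] for _ in range(len(grid.nodes))]
    for i, j in sorted(pairs):
        adj[i].append(j)
        adj[j].append(i)
    return [sorted(a) for a in adj]
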