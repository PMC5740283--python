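"""Thiessen polygons, surface interpolation, contours and transects.

Two-dimensional sampling is collapsed onto a one-dimensional transect in
four steps: build the Thiessen (Voronoi) map of localities and its
adjacency graph; interpolate the locality hybrid indices piecewise-
linearly on the Delaunay triangulation; extract the h = 0.5 isoline by
marching squares; and give every locality a signed minimum distance to
that contour, positive on the focal-species side.  All coordinates are
planar km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LineString, MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree
from skimage import measure

from .core import LocalityTable
from .markers import HybridIndexTable

__all__ = [
    "ThiessenMap",
    "GriddedField",
    "ContourSet",
    "TransectPoint",
    "build_thiessen",
    "interpolate_surface",
    "extract_half_contour",
    "signed_transect",
    "thiessen_to_geojson",
    "contours_to_geojson",
]

_EDGE_TOL = 1e-9


@dataclass
class ThiessenMap:
    """Clipped Voronoi cells per locality plus the shared-edge adjacency
    graph (symmetric; an edge requires positive shared boundary length)."""

    polygons: dict[str, Polygon]
    bounding_region: Polygon
    adjacency: dict[str, tuple[str, ...]]

    def neighbours(self, locality_id: str) -> tuple[str, ...]:
        return self.adjacency[locality_id]

    def area(self) -> float:
        return sum(p.area for p in self.polygons.values())


@dataclass
class GriddedField:
    """Regular grid of interpolated values; NaN outside the convex hull."""

    xs: np.ndarray          # (nx,)
    ys: np.ndarray          # (ny,)
    values: np.ndarray      # (ny, nx)


@dataclass
class ContourSet:
    polylines: tuple[LineString, ...]
    level: float = 0.5
    grid_shape: tuple[int, int] = (0, 0)

    @property
    def empty(self) -> bool:
        return not self.polylines

    def min_distance(self, x: float, y: float) -> float:
        if self.empty:
            raise ValueError("empty contour set")
        p = Point(x, y)
        return min(line.distance(p) for line in self.polylines)


@dataclass(frozen=True)
class TransectPoint:
    locality_id: str
    distance: float         # signed km; positive on the focal-species side
    h: Optional[float] = None
    n_genotypes: Optional[int] = None


# ---------------------------------------------------------------------------
# Thiessen polygons
# ---------------------------------------------------------------------------

def build_thiessen(localities: LocalityTable, margin: float = 0.10) -> ThiessenMap:
    """Voronoi cells clipped to the bounding box expanded by ``margin``.

    Two cells are adjacent when their clipped polygons share a boundary of
    positive length.  Duplicate coordinates are an error.
    """
    coords = localities.coords()
    if len(coords) < 2:
        raise ValueError("need at least 2 localities")
    seen: dict[tuple[float, float], str] = {}
    for loc, (x, y) in zip(localities.locality_ids, coords):
        key = (float(x), float(y))
        if key in seen:
            raise ValueError(f"duplicate coordinates for localities {seen[key]!r} and {loc!r}")
        seen[key] = loc

    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    span_x, span_y = xmax - xmin, ymax - ymin
    fallback = max(span_x, span_y, 1.0)
    pad_x = margin * (span_x if span_x > 0 else fallback)
    pad_y = margin * (span_y if span_y > 0 else fallback)
    region = box(xmin - pad_x, ymin - pad_y, xmax + pad_x, ymax + pad_y)

    raw = voronoi_diagram(MultiPoint([tuple(c) for c in coords]), envelope=region)
    cells = [g for g in raw.geoms]
    tree = STRtree(cells)
    polygons: dict[str, Polygon] = {}
    for loc, (x, y) in zip(localities.locality_ids, coords):
        pt = Point(x, y)
        idx = tree.query(pt, predicate="intersects")
        best = None
        for i in idx:
            if cells[i].buffer(1e-9).covers(pt):
                best = cells[i]
                break
        if best is None:  # numeric edge case: fall back to nearest cell
            best = min(cells, key=lambda c: c.distance(pt))
        polygons[loc] = best.intersection(region)

    ids = list(localities.locality_ids)
    polys = [polygons[l] for l in ids]
    ptree = STRtree(polys)
    adj: dict[str, set[str]] = {l: set() for l in ids}
    for i, l in enumerate(ids):
        for j in ptree.query(polys[i], predicate="intersects"):
            j = int(j)
            if j == i:
                continue
            shared = polys[i].intersection(polys[j])
            if shared.length > _EDGE_TOL:
                adj[l].add(ids[j])
                adj[ids[j]].add(l)
    return ThiessenMap(
        polygons, region, {l: tuple(sorted(adj[l])) for l in ids}
    )


# ---------------------------------------------------------------------------
# interpolation and contouring
# ---------------------------------------------------------------------------

def interpolate_surface(
    localities: LocalityTable,
    values: Mapping[str, float],
    resolution: int = 200,
    max_triangle_edge: Optional[float] = None,
) -> GriddedField:
    """Piecewise-linear interpolation of per-locality values on the
    Delaunay triangulation, evaluated on a regular grid over the bounding
    box; NaN outside the convex hull.

    Sliver triangles along the hull boundary connect distant localities
    and would smear values across unsampled space, so grid nodes falling
    in triangles with an edge longer than ``max_triangle_edge`` are
    masked (default: 6x the median nearest-neighbour distance; pass
    ``numpy.inf`` to disable).
    """
    locs = [l for l in localities.locality_ids if l in values]
    if len(locs) < 3:
        raise ValueError("need at least 3 localities with values")
    pts = np.array([localities.position(l) for l in locs])
    vals = np.array([values[l] for l in locs], dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError("localities are collinear; cannot triangulate") from e
    interp = LinearNDInterpolator(tri, vals)
    xs = np.linspace(pts[:, 0].min(), pts[:, 0].max(), resolution)
    ys = np.linspace(pts[:, 1].min(), pts[:, 1].max(), resolution)
    XX, YY = np.meshgrid(xs, ys)
    grid_vals = interp(XX, YY)

    if max_triangle_edge is None:
        from scipy.spatial import cKDTree

        nn = cKDTree(pts).query(pts, k=2)[0][:, 1]
        max_triangle_edge = 6.0 * float(np.median(nn))
    if np.isfinite(max_triangle_edge):
        corners = pts[tri.simplices]  # (n_tri, 3, 2)
        edge_len = np.linalg.norm(
            corners - np.roll(corners, 1, axis=1), axis=2
        ).max(axis=1)
        simplex = tri.find_simplex(np.column_stack([XX.ravel(), YY.ravel()]))
        bad = (simplex >= 0) & (edge_len[simplex] > max_triangle_edge)
        grid_vals = grid_vals.copy()
        grid_vals.ravel()[bad] = np.nan
    return GriddedField(xs, ys, grid_vals)


def extract_half_contour(field: GriddedField, level: float = 0.5) -> ContourSet:
    """Marching-squares isolines of the field at ``level`` (default 0.5),
    as polylines in map coordinates.  A field entirely above or below the
    level yields an empty contour set."""
    finite = field.values[np.isfinite(field.values)]
    polylines = []
    if finite.size and finite.min() < level < finite.max():
        raw = measure.find_contours(field.values, level)
        dx = field.xs[1] - field.xs[0] if len(field.xs) > 1 else 1.0
        dy = field.ys[1] - field.ys[0] if len(field.ys) > 1 else 1.0
        seen = set()
        for path in raw:
            if len(path) < 2:
                continue
            pts = [(field.xs[0] + c * dx, field.ys[0] + r * dy) for r, c in path]
            key = tuple(np.round(pts[0], 9)) + tuple(np.round(pts[-1], 9)) + (len(pts),)
            if key in seen:
                continue
            seen.add(key)
            polylines.append(LineString(pts))
    return ContourSet(tuple(polylines), level, field.values.shape)


def thiessen_to_geojson(tmap: ThiessenMap, path) -> None:
    """Write the clipped Thiessen polygons as a GeoJSON FeatureCollection
    (planar km coordinates; locality id and neighbours as properties)."""
    import json

    features = [
        {
            "type": "Feature",
            "geometry": poly.__geo_interface__,
            "properties": {"locality_id": loc,
                           "neighbours": list(tmap.adjacency.get(loc, ()))},
        }
        for loc, poly in tmap.polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def contours_to_geojson(contour: ContourSet, path) -> None:
    """Write the contour polylines as a GeoJSON FeatureCollection."""
    import json

    features = [
        {
            "type": "Feature",
            "geometry": line.__geo_interface__,
            "properties": {"level": contour.level, "index": i},
        }
        for i, line in enumerate(contour.polylines)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def signed_transect(
    localities: LocalityTable,
    contour: ContourSet,
    dominant: Mapping[str, str],
    focal_species: str,
    hybrid: Optional[HybridIndexTable] = None,
    locality_ids: Optional[Sequence[str]] = None,
) -> list[TransectPoint]:
    """Signed minimum straight-line distance of each locality to the 0.5
    contour: positive where the focal species is genetically dominant,
    negative elsewhere.  ``hybrid`` fills in h and the genotype counts."""
    if contour.empty:
        raise ValueError("empty contour set")
    ids = list(locality_ids) if locality_ids is not None else list(localities.locality_ids)
    out = []
    for loc in ids:
        if loc not in dominant:
            raise ValueError(f"locality {loc!r} has no dominant-species label")
        x, y = localities.position(loc)
        d = contour.min_distance(x, y)
        signed = d if dominant[loc] == focal_species else -d
        h = n = None
        if hybrid is not None:
            h = hybrid.h.get(loc)
            n = hybrid.n_genotypes.get(loc)
        out.append(TransectPoint(loc, signed, h, n))
    return out
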