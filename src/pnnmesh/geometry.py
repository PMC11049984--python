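"""Single-mesh contour geometry.

A perineuronal-net (PNN) mesh unit is the polygonal extracellular-matrix
border around one synaptic bouton.  This module quantifies one traced mesh
contour with the standard 2-D shape descriptors used in PNN morphometry:
area, perimeter, circularity (4*pi*A/P**2, 1 for a circle) and solidity
(A divided by convex-hull area), plus a vertex-count shape class
(triangle ... polygon with 7+ vertices).

Contours are closed polygons given as ordered pixel-coordinate vertices
(x rightward, y downward, 0-based, pixel-centered); the closing edge from
the last vertex back to the first is implicit.  Polygons are canonicalised
to counter-clockwise orientation in this coordinate frame.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from shapely.geometry import Polygon as _ShPolygon


class Provenance(str, enum.Enum):
    """Where a contour came from: exact simulation truth, the radial
    semi-automated tracer, or the learned image-to-image model."""

    GROUND_TRUTH = "ground_truth"
    CLASSICAL = "classical"
    MODEL = "model"


class ShapeClass(str, enum.Enum):
    TRIANGLE = "triangle"
    QUADRILATERAL = "quadrilateral"
    PENTAGON = "pentagon"
    HEXAGON = "hexagon"
    POLYGON_7PLUS = "polygon_7plus"


_SHAPE_BY_COUNT = {
    3: ShapeClass.TRIANGLE,
    4: ShapeClass.QUADRILATERAL,
    5: ShapeClass.PENTAGON,
    6: ShapeClass.HEXAGON,
}


class ContourError(ValueError):
    """Raised for degenerate or invalid mesh contours."""


@dataclass(frozen=True)
class MeshContour:
    """Closed ordered-vertex polygon outlining one PNN mesh.

    Parameters
    ----------
    vertices
        (n, 2) array of (x, y) pixel coordinates; n >= 3.  The polygon is
        implicitly closed (last vertex != first).
    z_plane
        Index of the confocal z-plane the contour was traced in, or None
        for single-plane data.
    pixel_size
        Lateral pixel size in micrometres per pixel; converts pixel
        measurements to physical units.
    provenance
        One of :class:`Provenance`.
    mesh_id
        Identifier, unique within an annotation set.
    """

    vertices: np.ndarray
    z_plane: Optional[int] = None
    pixel_size: float = 1.0
    provenance: Provenance = Provenance.GROUND_TRUTH
    mesh_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourError("vertices must be an (n, 2) array of (x, y)")
        if v.shape[0] < 3:
            raise ContourError(f"a contour needs >= 3 vertices, got {v.shape[0]}")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
            if v.shape[0] < 3:
                raise ContourError("contour collapses below 3 vertices")
        # canonical counter-clockwise orientation: shoelace signed area > 0
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        if self.pixel_size <= 0:
            raise ContourError("pixel_size must be positive")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def to_polygon(self) -> _ShPolygon:
        return _ShPolygon(self.vertices)

    @property
    def is_simple(self) -> bool:
        return self.to_polygon().is_valid

    def centroid(self) -> np.ndarray:
        return np.asarray(self.to_polygon().centroid.coords[0])

    def with_vertices(self, vertices: np.ndarray) -> "MeshContour":
        return replace(self, vertices=np.asarray(vertices, dtype=float))


@dataclass(frozen=True)
class MeshGeometry:
    """Shape descriptors for one mesh contour.

    ``area_um2``/``perimeter_um`` are in physical units, ``area_px2``/
    ``perimeter_px`` in pixels.  ``circularity`` and ``solidity`` are
    dimensionless in (0, 1].
    """

    area_um2: float
    perimeter_um: float
    area_px2: float
    perimeter_px: float
    circularity: float
    solidity: float
    vertex_count: int
    shape_class: ShapeClass
    mesh_id: str = ""
    provenance: Provenance = Provenance.GROUND_TRUTH


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise order in an
    (x right, y down) frame with the CCW convention applied to coordinates
    as stored."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _perimeter(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def compute_geometry(contour: MeshContour) -> MeshGeometry:
    """Compute area, perimeter, circularity, solidity and shape class.

    Area is the shoelace polygon area scaled by ``pixel_size**2``;
    perimeter is the closed polyline length scaled by ``pixel_size``;
    circularity = 4*pi*A/P**2; solidity = A / convex-hull area.

    Raises
    ------
    ContourError
        If the polygon is degenerate (zero area) or self-intersecting.
    """
    v = contour.vertices
    area_px2 = abs(_signed_area(v))
    if area_px2 <= 0.0:
        raise ContourError(f"mesh {contour.mesh_id!r}: zero-area contour")
    poly = contour.to_polygon()
    if not poly.is_valid:
        raise ContourError(f"mesh {contour.mesh_id!r}: self-intersecting contour")
    perim_px = _perimeter(v)
    hull_area = poly.convex_hull.area
    circ = 4.0 * math.pi * area_px2 / perim_px**2
    sol = area_px2 / hull_area
    s = contour.pixel_size
    cls = shape_class(contour)
    return MeshGeometry(
        area_um2=area_px2 * s * s,
        perimeter_um=perim_px * s,
        area_px2=area_px2,
        perimeter_px=perim_px,
        circularity=circ,
        solidity=min(sol, 1.0),
        vertex_count=simplify_contour(contour).n_vertices,
        shape_class=cls,
        mesh_id=contour.mesh_id,
        provenance=contour.provenance,
    )


def _default_tolerance(contour: MeshContour) -> float:
    """5% of the equivalent diameter (diameter of the equal-area circle)."""
    area = abs(_signed_area(contour.vertices))
    return 0.05 * 2.0 * math.sqrt(max(area, 1e-12) / math.pi)


def simplify_contour(contour: MeshContour, tolerance: Optional[float] = None) -> MeshContour:
    """Reduce a densely sampled contour to its geometric corner vertices.

    Douglas-Peucker simplification of the closed ring (shapely backend,
    topology-preserving for the ring itself): every removed point lies
    within ``tolerance`` pixels of the simplified polygon boundary.
    Idempotent at fixed tolerance.  Default tolerance is 5% of the
    equivalent diameter.

    Raises
    ------
    ContourError
        If simplification collapses the polygon below 3 vertices.
    """
    if tolerance is None:
        tolerance = _default_tolerance(contour)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    poly = contour.to_polygon()
    simplified = poly.simplify(tolerance, preserve_topology=False)
    if simplified.is_empty or simplified.geom_type != "Polygon" or simplified.area <= 0:
        raise ContourError("simplification collapsed contour below a valid polygon")
    coords = np.asarray(simplified.exterior.coords[:-1], dtype=float)
    coords = _prune_redundant(coords, tolerance)
    if coords.shape[0] < 3:
        raise ContourError("simplification collapsed contour below 3 vertices")
    return contour.with_vertices(coords)


def _prune_redundant(coords: np.ndarray, tolerance: float) -> np.ndarray:
    """Ring-aware cleanup after Douglas-Peucker: repeatedly drop the vertex
    closest to its neighbours' chord while that distance is <= tolerance
    (DP only guarantees removed points are within tolerance; it may retain
    redundant ring vertices, e.g. at its arbitrary split point)."""

    def chord_dist(prev, v, nxt):
        d = nxt - prev
        L = np.hypot(*d)
        if L == 0:
            return np.hypot(*(v - prev))
        return abs(d[0] * (v[1] - prev[1]) - d[1] * (v[0] - prev[0])) / L

    pts = list(coords)
    while len(pts) > 3:
        n = len(pts)
        dists = [chord_dist(pts[i - 1], pts[i], pts[(i + 1) % n]) for i in range(n)]
        i = int(np.argmin(dists))
        if dists[i] > tolerance:
            break
        pts.pop(i)
    return np.asarray(pts)


def shape_class(contour: MeshContour, tolerance: Optional[float] = None) -> ShapeClass:
    """Classify a mesh by corner count after simplification: triangle,
    quadrilateral, pentagon, hexagon, or polygon with 7+ vertices."""
    n = simplify_contour(contour, tolerance).n_vertices
    return _SHAPE_BY_COUNT.get(n, ShapeClass.POLYGON_7PLUS)


def rasterized_area(contour: MeshContour) -> float:
    """Pixel-count area of the rasterised polygon interior (oracle helper:
    the number of pixel centres strictly inside the polygon)."""
    import shapely

    v = contour.vertices
    x0, y0 = np.floor(v.min(axis=0)).astype(int) - 1
    x1, y1 = np.ceil(v.max(axis=0)).astype(int) + 2
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    inside = shapely.contains_xy(contour.to_polygon(), xs.ravel(), ys.ravel())
    return float(inside.sum())
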