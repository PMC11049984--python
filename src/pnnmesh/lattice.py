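"""Synthetic PNN mesh lattices with exact polygonal ground truth.

A perineuronal net tiles the neuronal surface with polygonal mesh units.
This module builds such a tiling as the Voronoi tessellation of a jittered
hexagonal point grid: with no jitter the cells are regular hexagons; with
increasing jitter the vertex-count distribution spreads over 4-7 with
pentagons and hexagons most frequent, matching what manual tracing reports
for real PNNs.  Cell interiors never overlap (Voronoi property), so every
mesh polygon is an exact, simple ground-truth contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box

logger = logging.getLogger(__name__)


class LatticePlacementError(ValueError):
    """Requested mesh count cannot be placed in the domain."""


@dataclass(frozen=True)
class LatticeParams:
    """Geometry of the synthetic mesh tiling.

    Parameters
    ----------
    n_meshes
        Number of mesh polygons to return (>= 1).
    mean_mesh_diameter
        Target across-flats cell diameter in pixels (>= 6).
    diameter_cv
        Approximate coefficient of variation of cell size, realised by
        extra random site displacement.
    jitter
        Site jitter as a fraction of the grid spacing, in [0, 1].
        0 gives a regular honeycomb.
    domain_size
        (width, height) of the scene in pixels.
    annulus
        Optional ((cx, cy), r_inner, r_outer) restricting meshes to a
        band on a cell surface, emulating the PNN coat seen in a
        confocal section through a soma.
    """

    n_meshes: int = 50
    mean_mesh_diameter: float = 26.0
    diameter_cv: float = 0.15
    jitter: float = 0.35
    domain_size: tuple[int, int] = (512, 512)
    annulus: Optional[tuple[tuple[float, float], float, float]] = None

    def __post_init__(self) -> None:
        if self.n_meshes < 1:
            raise ValueError("n_meshes must be >= 1")
        if self.mean_mesh_diameter < 6.0:
            raise ValueError("mean_mesh_diameter must be >= 6 px")
        if not (0.0 <= self.jitter <= 1.0):
            raise ValueError("jitter must be in [0, 1]")
        if self.diameter_cv < 0:
            raise ValueError("diameter_cv must be >= 0")
        w, h = self.domain_size
        if w <= 0 or h <= 0:
            raise ValueError("domain_size must be positive")


@dataclass(frozen=True)
class MeshLattice:
    """Ground-truth tiling: simple, non-overlapping mesh polygons.

    ``meshes`` holds one (n_i, 2) float array of (x, y) vertices per mesh
    (counter-clockwise, implicitly closed).  ``adjacency`` lists index
    pairs of meshes sharing a Voronoi edge.
    """

    meshes: tuple[np.ndarray, ...]
    adjacency: tuple[tuple[int, int], ...]
    domain_size: tuple[int, int]
    seed: int
    params: LatticeParams = field(default_factory=LatticeParams, compare=False)

    @property
    def n_meshes(self) -> int:
        return len(self.meshes)

    def centroids(self) -> np.ndarray:
        return np.array([Polygon(m).centroid.coords[0] for m in self.meshes])

    def edges(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """All polygon edges (a, b) as vertex-coordinate pairs."""
        out = []
        for m in self.meshes:
            closed = np.vstack([m, m[:1]])
            out.extend((closed[i], closed[i + 1]) for i in range(len(m)))
        return out

    def vertices(self) -> np.ndarray:
        """Unique lattice vertex coordinates (within 0.25 px)."""
        allv = np.vstack(self.meshes)
        key = np.round(allv * 4.0).astype(np.int64)
        _, idx = np.unique(key, axis=0, return_index=True)
        return allv[np.sort(idx)]


def _hex_grid(spacing: float, width: float, height: float, margin: float) -> np.ndarray:
    """Triangular lattice of sites covering the padded domain."""
    dy = spacing * np.sqrt(3.0) / 2.0
    xs, ys = [], []
    row = 0
    y = -margin
    while y <= height + margin:
        offset = 0.5 * spacing if row % 2 else 0.0
        x = -margin + offset
        while x <= width + margin:
            xs.append(x)
            ys.append(y)
            x += spacing
        y += dy
        row += 1
    return np.column_stack([xs, ys])


def _merge_close_vertices(pts: np.ndarray, min_edge: float = 1.0) -> np.ndarray:
    """Collapse near-degenerate Voronoi edges (< min_edge px) by dropping
    one endpoint; keeps ground-truth polygons free of zero-length edges."""
    out = list(pts)
    changed = True
    while changed and len(out) > 3:
        changed = False
        n = len(out)
        for i in range(n):
            if np.hypot(*(out[i] - out[(i + 1) % n])) < min_edge:
                out.pop((i + 1) % n)
                changed = True
                break
    return np.asarray(out)


def generate_lattice(params: LatticeParams, seed: int = 0) -> MeshLattice:
    """Build a seeded Voronoi mesh lattice.

    Returns exactly ``params.n_meshes`` simple polygons lying fully inside
    the domain (and inside the annulus band when one is given), the ones
    closest to the domain (or annulus) centre.  Deterministic for fixed
    (params, seed).

    Raises
    ------
    LatticePlacementError
        If fewer than ``n_meshes`` interior cells fit, reporting the
        achievable maximum.
    """
    rng = np.random.default_rng(seed)
    w, h = params.domain_size
    s = params.mean_mesh_diameter
    sites = _hex_grid(s, w, h, margin=3.0 * s)
    sigma = 0.5 * s * params.jitter + 0.5 * s * params.diameter_cv
    sites = sites + rng.normal(0.0, sigma, size=sites.shape)

    vor = Voronoi(sites)
    domain = box(0.0, 0.0, float(w), float(h))
    if params.annulus is not None:
        (cx, cy), r_in, r_out = params.annulus
        band = Point(cx, cy).buffer(r_out, quad_segs=64)
        if r_in > 0:
            band = band.difference(Point(cx, cy).buffer(r_in, quad_segs=64))
        keep_region = domain.intersection(band)
        center = np.array([cx, cy])
    else:
        keep_region = domain
        center = np.array([w / 2.0, h / 2.0])

    candidates: list[tuple[float, int, np.ndarray]] = []
    site_of_candidate: list[int] = []
    for site_idx, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue
        poly_pts = vor.vertices[region]
        poly = Polygon(poly_pts)
        if not poly.is_valid or poly.is_empty:
            continue
        if not poly.within(keep_region):
            continue
        d = float(np.hypot(*(np.asarray(poly.centroid.coords[0]) - center)))
        candidates.append((d, site_idx, np.asarray(poly_pts, dtype=float)))
        site_of_candidate.append(site_idx)

    if len(candidates) < params.n_meshes:
        raise LatticePlacementError(
            f"only {len(candidates)} meshes of diameter ~{s:.0f} px fit the "
            f"{w}x{h} domain; requested {params.n_meshes}"
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    chosen = candidates[: params.n_meshes]
    site_to_mesh = {site: i for i, (_, site, _) in enumerate(chosen)}

    meshes = []
    for _, _, pts in chosen:
        pts = _merge_close_vertices(pts, min_edge=1.0)
        # canonical CCW order (shoelace > 0)
        x, y = pts[:, 0], pts[:, 1]
        if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
            pts = pts[::-1].copy()
        meshes.append(pts)

    adjacency = set()
    for p, q in vor.ridge_points:
        if p in site_to_mesh and q in site_to_mesh:
            i, j = site_to_mesh[p], site_to_mesh[q]
            adjacency.add((min(i, j), max(i, j)))

    logger.debug("lattice: %d meshes, %d adjacent pairs", len(meshes), len(adjacency))
    return MeshLattice(
        meshes=tuple(meshes),
        adjacency=tuple(sorted(adjacency)),
        domain_size=params.domain_size,
        seed=seed,
        params=params,
    )
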