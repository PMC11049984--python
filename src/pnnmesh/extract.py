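"""Turn a predicted contour-mask image back into a polygon.

The model outputs a thick, probability-like contour image.  Recovering a
measurable polygon proceeds: binarize (default 0.5) -> morphological
closing (bridges 1-2 px gaps) -> skeletonize (recovers the ridge
centre-line, undoing the mask dilation) -> flood-fill the mesh interior
from the given centre -> trace the interior/skeleton boundary at subpixel
resolution -> shrink to the centre-line (symmetric subpixel calibration
against the interior-only boundary) -> simplify to an ordered-vertex
polygon.

If the flood fill escapes to the image border the mask holds no closed
loop around the centre and extraction fails (flagged, not fatal, at the
evaluation level).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from shapely.geometry import Polygon
from skimage.measure import find_contours
from skimage.morphology import closing as _closing, disk, skeletonize
from skimage.segmentation import flood

from .geometry import ContourError, MeshContour, Provenance


class ExtractionError(RuntimeError):
    """No closed contour loop encloses the requested centre."""


def mask_to_contour(
    mask: np.ndarray,
    center: tuple[float, float],
    binarize_threshold: float = 0.5,
    simplify_tolerance: float = 0.8,
    closing_radius: int = 2,
    provenance: Provenance = Provenance.MODEL,
    mesh_id: str = "",
) -> MeshContour:
    """Extract the closed mesh contour enclosing ``center`` from a mask.

    ``mask`` is a [0, 1] image (probability-like or binary); ``center``
    is (x, y).  Returns the centre-line polygon with the requested
    provenance.

    Raises
    ------
    ExtractionError
        If no closed loop encloses the centre (e.g. an all-zero mask).
    """
    m = np.asarray(mask, dtype=float)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    binary = m >= binarize_threshold
    if not binary.any() or binary.all():
        raise ExtractionError("mask is uniform; no contour to extract")
    if closing_radius > 0:
        binary = _closing(binary, disk(closing_radius))
    skel = skeletonize(binary)

    h, w = m.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ExtractionError("centre outside mask")
    seed = _seed_off_skeleton(skel, cx, cy)
    if seed is None:
        raise ExtractionError("no interior pixel near the centre")

    interior = flood(skel, seed, connectivity=1)  # 4-connected fill of ~skel
    # flood() on a bool image fills the connected region of equal value;
    # seed is False so this is the non-skeleton region around the centre
    if interior[0, :].any() or interior[-1, :].any() or interior[:, 0].any() or interior[:, -1].any():
        raise ExtractionError("no closed loop around the centre (fill reached border)")

    region = interior | (skel & _dilate1(interior))
    outer = _boundary_polygon(region)
    inner = _boundary_polygon(interior)
    if outer is None:
        raise ExtractionError("no boundary found")
    # the marching-squares boundary of `region` sits ~half a pixel outside
    # the skeleton centre-line and that of `interior` ~half a pixel inside;
    # shrink the outer polygon to the mid-area between the two, which
    # cancels the orientation-dependent subpixel offset of either alone
    target = 0.5 * (outer.area + (inner.area if inner is not None else outer.area))
    shrink = (outer.area - target) / max(outer.length, 1e-9)
    shrunk = outer.buffer(-shrink)
    if shrunk.is_empty:
        raise ExtractionError("contour collapsed under subpixel shrink")
    if shrunk.geom_type == "MultiPolygon":
        shrunk = max(shrunk.geoms, key=lambda g: g.area)
    simplified = shrunk.simplify(simplify_tolerance, preserve_topology=True)
    coords = np.asarray(simplified.exterior.coords[:-1], dtype=float)
    try:
        return MeshContour(vertices=coords, provenance=provenance, mesh_id=mesh_id)
    except ContourError as exc:
        raise ExtractionError(str(exc)) from exc


def _boundary_polygon(mask: np.ndarray) -> Optional[Polygon]:
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    ring = max(contours, key=len)
    poly = Polygon(np.column_stack([ring[:, 1], ring[:, 0]]))  # (row, col) -> (x, y)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly if not poly.is_empty else None


def _seed_off_skeleton(skel: np.ndarray, cx: int, cy: int) -> Optional[tuple[int, int]]:
    """Nearest non-skeleton pixel to the centre (search radius 5 px)."""
    h, w = skel.shape
    if not skel[cy, cx]:
        return (cy, cx)
    for r in range(1, 6):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if max(abs(dy), abs(dx)) != r:
                    continue
                y, x = cy + dy, cx + dx
                if 0 <= y < h and 0 <= x < w and not skel[y, x]:
                    return (y, x)
    return None


def _dilate1(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[1:] |= mask[:-1]
    out[:-1] |= mask[1:]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out
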