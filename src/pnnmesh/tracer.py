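"""Semi-automated radial mesh tracing.

This is the annotation method used to build single-mesh ground truth in
high-resolution PNN studies: the user picks the centre of one mesh unit;
the algorithm casts equiangular rays from that centre, reads the smoothed
fluorescence profile along each ray in every available z-plane (one, or
the Z-1/Z0/Z+1 triple), and places

* the **contour** point at the radial global intensity maximum over
  [r_min, r_max], taken from whichever plane holds the highest maximum
  (ties broken toward the centre, so the trace does not jump to a
  neighbouring mesh border), and
* the **hole-edge** point at the first sample strictly above the hole
  threshold walking outward (the border of the dark mesh interior).

Rays whose profile never rises above the threshold are flagged; if more
than a quarter of the rays fail the mesh is declared unresolvable.
Flagged rays get their radii filled by circular interpolation from the
surviving neighbours.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .geometry import MeshContour, Provenance

logger = logging.getLogger(__name__)

RAY_STEP = 0.5  # px, radial sampling step


class MeshUnresolvableError(RuntimeError):
    """More than 25% of rays found no signal above threshold."""


class ThresholdMode(str, enum.Enum):
    RELATIVE = "relative"  # fraction of the per-ray maximum
    ABSOLUTE = "absolute"  # intensity units


class ZMode(str, enum.Enum):
    SINGLE = "single"
    THREE_PLANE = "three_plane"


@dataclass(frozen=True)
class TraceParams:
    """Radial-tracer settings.

    ``n_rays`` equiangular directions (>= 8, default 36 i.e. 10 degree
    spacing); the contour is searched in [r_min, r_max] px; the hole
    threshold is either a fraction of the per-ray maximum (exposure
    invariant, default 0.5) or an absolute intensity; ray profiles are
    smoothed with a Gaussian of ``smoothing_sigma`` px before the argmax.
    """

    n_rays: int = 36
    r_min: float = 2.0
    r_max: float = 30.0
    hole_threshold: float = 0.5
    threshold_mode: ThresholdMode = ThresholdMode.RELATIVE
    z_mode: ZMode = ZMode.SINGLE
    smoothing_sigma: float = 1.0
    max_failed_fraction: float = 0.25
    peak_rel_height: float = 0.6

    def __post_init__(self) -> None:
        if self.n_rays < 8:
            raise ValueError("n_rays must be >= 8")
        if not (0 <= self.r_min < self.r_max):
            raise ValueError("need 0 <= r_min < r_max")


@dataclass(frozen=True)
class RayProfile:
    """Per-direction radial intensity readout."""

    direction: float  # rad
    radii: np.ndarray
    samples: np.ndarray  # (n_planes, n_radii)
    argmax_radius: float
    argmax_plane: int
    hole_edge_radius: Optional[float]
    failed: bool


def _as_stack(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img[None]
    if img.ndim == 3 and img.shape[0] in (1, 3):
        return img
    raise ValueError("expected a (H, W) image or a (1|3, H, W) stack")


def trace_mesh_radial(
    image: np.ndarray,
    center: tuple[float, float],
    params: TraceParams = TraceParams(),
) -> tuple[MeshContour, MeshContour, list[RayProfile]]:
    """Trace one mesh from a user-selected centre.

    Returns ``(contour, hole, profiles)``: the border polygon through the
    per-ray intensity maxima (provenance ``classical``), the hole polygon
    through the first-above-threshold points, and the ray profiles.

    Raises
    ------
    MeshUnresolvableError
        If more than ``max_failed_fraction`` of rays fail.
    """
    stack = _as_stack(image)
    n_planes, h, w = stack.shape
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("center outside image")

    radii = np.arange(params.r_min, params.r_max + RAY_STEP / 2, RAY_STEP)
    angles = np.arange(params.n_rays) * (2.0 * np.pi / params.n_rays)
    sm_sigma = params.smoothing_sigma / RAY_STEP

    profiles: list[RayProfile] = []
    contour_r = np.empty(params.n_rays)
    hole_r = np.full(params.n_rays, np.nan)
    failed = np.zeros(params.n_rays, dtype=bool)
    for i, th in enumerate(angles):
        xs = cx + radii * np.cos(th)
        ys = cy + radii * np.sin(th)
        prof = np.stack(
            [map_coordinates(stack[p], [ys, xs], order=1, mode="nearest") for p in range(n_planes)]
        )
        if sm_sigma > 0:
            prof = gaussian_filter1d(prof, sm_sigma, axis=1, mode="nearest")
        plane_max = prof.max(axis=1)
        best_plane = int(np.argmax(plane_max))
        best = prof[best_plane]
        k = _first_prominent_peak(best, params.peak_rel_height)
        contour_r[i] = radii[k]
        thr = (
            params.hole_threshold * plane_max[best_plane]
            if params.threshold_mode == ThresholdMode.RELATIVE
            else params.hole_threshold
        )
        above = np.nonzero(best[: k + 1] > thr)[0]
        ray_failed = above.size == 0
        failed[i] = ray_failed
        if not ray_failed:
            hole_r[i] = radii[above[0]]
        profiles.append(
            RayProfile(
                direction=float(th), radii=radii, samples=prof,
                argmax_radius=float(radii[k]), argmax_plane=best_plane,
                hole_edge_radius=None if ray_failed else float(radii[above[0]]),
                failed=bool(ray_failed),
            )
        )

    n_failed = int(failed.sum())
    if n_failed > params.max_failed_fraction * params.n_rays:
        raise MeshUnresolvableError(
            f"{n_failed}/{params.n_rays} rays found no signal above threshold"
        )
    if n_failed:
        contour_r = _fill_circular(contour_r, failed)
        hole_r = _fill_circular(hole_r, np.isnan(hole_r))
        logger.info("trace: interpolated %d failed rays", n_failed)

    contour_xy = np.column_stack([cx + contour_r * np.cos(angles), cy + contour_r * np.sin(angles)])
    hole_xy = np.column_stack([cx + hole_r * np.cos(angles), cy + hole_r * np.sin(angles)])
    contour = MeshContour(vertices=contour_xy, provenance=Provenance.CLASSICAL)
    hole = MeshContour(vertices=hole_xy, provenance=Provenance.CLASSICAL)
    return contour, hole, profiles


def _first_prominent_peak(profile: np.ndarray, rel_height: float) -> int:
    """Index of the first local maximum whose height reaches ``rel_height``
    of the profile's global maximum; the nearest-to-centre preference that
    keeps a ray from locking onto a brighter structure (e.g. a border
    junction of a neighbouring mesh) farther out.  Falls back to the
    global argmax when no such interior peak exists."""
    from scipy.signal import find_peaks

    top = float(profile.max())
    peaks, _ = find_peaks(profile, height=rel_height * top)
    if peaks.size:
        return int(peaks[0])
    return int(np.argmax(profile))


def _fill_circular(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Fill bad entries by periodic linear interpolation over ray index."""
    out = values.copy()
    n = len(values)
    good = np.nonzero(~bad)[0]
    if good.size == 0:
        return out
    for i in np.nonzero(bad)[0]:
        # nearest good neighbours around the circle
        prev = good[(np.searchsorted(good, i) - 1) % good.size]
        nxt = good[np.searchsorted(good, i) % good.size]
        dp = (i - prev) % n
        dn = (nxt - i) % n
        if dp + dn == 0:
            out[i] = values[prev]
        else:
            out[i] = (values[prev] * dn + values[nxt] * dp) / (dp + dn)
    return out


@dataclass(frozen=True)
class CellTrace:
    """Batch trace of many meshes on one cell."""

    contours: tuple[MeshContour, ...]
    holes: tuple[Optional[MeshContour], ...]
    failures: tuple[int, ...]  # indices into `centers` that failed
    adjacency: tuple[tuple[int, int], ...]


def trace_cell(
    image: np.ndarray,
    centers: Sequence[tuple[float, float]],
    params: TraceParams = TraceParams(),
    adjacency_gap: float = 2.0,
) -> CellTrace:
    """Trace every user-selected centre; failures are reported, not fatal.

    Mesh adjacency is estimated from contour proximity: two traced meshes
    are adjacent when their border polylines come within
    ``adjacency_gap`` px of each other.
    """
    if len(centers) == 0:
        raise ValueError("need at least one centre")
    contours: list[MeshContour] = []
    holes: list[Optional[MeshContour]] = []
    failures: list[int] = []
    kept_index: list[int] = []
    for i, c in enumerate(centers):
        try:
            contour, hole, _ = trace_mesh_radial(image, c, params)
        except (MeshUnresolvableError, ValueError) as exc:
            logger.warning("mesh %d at %s failed: %s", i, c, exc)
            failures.append(i)
            continue
        contour = MeshContour(
            vertices=contour.vertices, provenance=Provenance.CLASSICAL, mesh_id=f"mesh{i}"
        )
        contours.append(contour)
        holes.append(hole)
        kept_index.append(i)

    from shapely.geometry import LinearRing

    rings = [LinearRing(np.vstack([c.vertices, c.vertices[:1]])) for c in contours]
    adjacency = []
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            if rings[a].distance(rings[b]) < adjacency_gap:
                adjacency.append((kept_index[a], kept_index[b]))
    return CellTrace(
        contours=tuple(contours),
        holes=tuple(holes),
        failures=tuple(failures),
        adjacency=tuple(adjacency),
    )
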