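"""Paired (image patch, contour-mask patch) training corpora.

The learned tracer works on square patches centred on a single mesh unit,
mirroring how annotated PNN meshes are presented to the model: the input
is the fluorescence patch, the target is the rasterised contour of the
centre mesh (dilated to the configured half-width).  Meshes whose patch
would fall outside the rendered scene are skipped and counted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon, box
from skimage.draw import line as _draw_line
from skimage.morphology import disk, dilation

from .geometry import MeshContour, Provenance
from .lattice import LatticeParams, generate_lattice
from .render import RenderParams, ScenePair, render_scene

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatchSample:
    """One training pair plus the exact ground truth behind it.

    ``image``: (patch, patch) or (3, patch, patch) float32 intensities in
    native units; ``target``: uint8 centre-mesh contour mask;
    ``contour``: the generating polygon in patch coordinates.
    """

    image: np.ndarray
    target: np.ndarray
    mesh_index: int
    scene_index: int
    contour: MeshContour
    mesh_id: str


@dataclass(frozen=True)
class SyntheticDataset:
    """A corpus of single-mesh patch pairs with exact ground truth."""

    samples: tuple[PatchSample, ...]
    patch_size: int
    seed: int
    n_skipped: int = 0
    scenes: tuple[ScenePair, ...] = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i) -> PatchSample:
        return self.samples[i]

    def subset(self, indices) -> "SyntheticDataset":
        return replace(self, samples=tuple(self.samples[i] for i in indices))

    def take(self, n: int) -> "SyntheticDataset":
        return replace(self, samples=self.samples[:n])

    def content_hash(self) -> str:
        """SHA-256 over all patch pixels (order-sensitive); determinism probe."""
        h = hashlib.sha256()
        for s in self.samples:
            h.update(np.ascontiguousarray(s.image).tobytes())
            h.update(np.ascontiguousarray(s.target).tobytes())
        return h.hexdigest()


def _center_mesh_mask(vertices: np.ndarray, patch: int, halfwidth: int) -> np.ndarray:
    grid = np.zeros((patch, patch), dtype=bool)
    closed = np.vstack([vertices, vertices[:1]])
    for a, b in zip(closed[:-1], closed[1:]):
        rr, cc = _draw_line(int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0])))
        keep = (rr >= 0) & (rr < patch) & (cc >= 0) & (cc < patch)
        grid[rr[keep], cc[keep]] = True
    if halfwidth > 0:
        grid = dilation(grid, disk(halfwidth))
    return grid.astype(np.uint8)


def extract_patches(scene: ScenePair, patch_size: int, scene_index: int = 0) -> tuple[list[PatchSample], int]:
    """One sample per mesh whose patch fits fully inside the scene.

    The patch is placed so the mesh centroid sits at the patch centre
    (rounded to the pixel grid).  Returns (samples, n_skipped).
    """
    h, w = scene.target_mask.shape
    half = patch_size // 2
    halfwidth = scene.render_params.mask_halfwidth
    samples: list[PatchSample] = []
    skipped = 0
    for mi, poly in enumerate(scene.lattice.meshes):
        c = Polygon(poly).centroid
        cx, cy = int(round(c.x)), int(round(c.y))
        x0, y0 = cx - half, cy - half
        x1, y1 = x0 + patch_size, y0 + patch_size
        local = poly - np.array([x0, y0], dtype=float)
        inside = (
            x0 >= 0 and y0 >= 0 and x1 <= w and y1 <= h
            and Polygon(local).within(box(0, 0, patch_size - 1, patch_size - 1))
        )
        if not inside:
            skipped += 1
            continue
        img = scene.image[..., y0:y1, x0:x1].astype(np.float32)
        target = _center_mesh_mask(local, patch_size, halfwidth)
        mesh_id = f"scene{scene_index}_mesh{mi}"
        contour = MeshContour(
            vertices=local, provenance=Provenance.GROUND_TRUTH, mesh_id=mesh_id
        )
        samples.append(
            PatchSample(
                image=img, target=target, mesh_index=mi,
                scene_index=scene_index, contour=contour, mesh_id=mesh_id,
            )
        )
    if skipped:
        logger.info("extract_patches: skipped %d border meshes", skipped)
    return samples, skipped


def make_patch_dataset(
    n_scenes: int,
    lattice_params: LatticeParams,
    render_params: RenderParams,
    patch_size: int = 128,
    seed: int = 0,
    keep_scenes: bool = False,
) -> SyntheticDataset:
    """Generate ``n_scenes`` seeded scenes and cut one patch per interior mesh.

    Requires ``patch_size >= 2 * mean_mesh_diameter`` so the centre mesh
    fits with context.  Scene seeds are derived from ``seed`` so the whole
    corpus is reproducible from one integer.
    """
    if patch_size < 2 * lattice_params.mean_mesh_diameter:
        raise ValueError("patch_size must be >= 2 * mean_mesh_diameter")
    rng = np.random.default_rng(seed)
    samples: list[PatchSample] = []
    scenes: list[ScenePair] = []
    skipped = 0
    for si in range(n_scenes):
        lat_seed, rend_seed = int(rng.integers(2**31)), int(rng.integers(2**31))
        lattice = generate_lattice(lattice_params, seed=lat_seed)
        scene = render_scene(lattice, render_params, seed=rend_seed)
        got, sk = extract_patches(scene, patch_size, scene_index=si)
        samples.extend(got)
        skipped += sk
        if keep_scenes:
            scenes.append(scene)
    return SyntheticDataset(
        samples=tuple(samples), patch_size=patch_size, seed=seed,
        n_skipped=skipped, scenes=tuple(scenes),
    )


def split_dataset(
    dataset: SyntheticDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Random mesh-level partition into train and test sets.

    ``|train| = round(train_fraction * N)``; the default 0.8 reproduces
    the 80% / 20% protocol.  ``train_fraction == 1.0`` is the degenerate
    all-train case.

    Raises
    ------
    ValueError
        On an empty dataset or a fraction outside (0, 1].
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_ix = np.sort(order[:n_train])
    test_ix = np.sort(order[n_train:])
    return dataset.subset(train_ix), dataset.subset(test_ix)
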