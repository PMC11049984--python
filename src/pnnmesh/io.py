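"""File formats and configuration.

Images travel as 8/16-bit grayscale TIFF (single page, or 3 pages in
z-order) or PNG; contour annotations as a self-describing JSON schema
(mesh id, provenance, vertices, z-plane, plus image reference and
adjacency); geometry tables as CSV with stable ordering; run
configuration as one strict-schema YAML file.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .geometry import ContourError, MeshContour, Provenance, compute_geometry

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Unsupported or malformed input file."""


def read_image(path) -> np.ndarray:
    """Read a grayscale 8/16-bit image or 3-plane stack.

    Returns float64 intensities, (H, W) or (3, H, W) with pages in
    z-order.  Raises :class:`FormatError` on RGB input, unsupported bit
    depth or page counts other than 1 or 3.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(f"{path.name}: RGB(A) images unsupported; need single-channel grayscale")
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}; need 8- or 16-bit")
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[0] in (1, 3):
        return arr.astype(float).reshape(arr.shape) if arr.shape[0] == 3 else arr[0].astype(float)
    raise FormatError(f"{path.name}: expected 1 or 3 pages, got shape {arr.shape}")


def write_image(image: np.ndarray, path, bit_depth: Optional[int] = None) -> None:
    """Write a (H, W) or (3, H, W) array as grayscale TIFF/PNG."""
    path = Path(path)
    arr = np.asarray(image)
    if bit_depth is not None:
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        arr = np.clip(np.round(arr), 0, 2**bit_depth - 1).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        from imageio.v3 import imwrite

        imwrite(path, arr)


@dataclass
class AnnotationFile:
    """A set of mesh contour annotations tied to one image."""

    meshes: list  # of MeshContour
    image_path: str = ""
    pixel_size: float = 1.0
    n_zplanes: int = 1
    adjacency: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        ids = [m.mesh_id for m in self.meshes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FormatError(f"duplicate mesh_id(s): {sorted(dupes)}")
        if self.pixel_size is None or self.pixel_size <= 0:
            raise FormatError("pixel_size must be a positive number (um/px)")


def write_annotations(annotations: AnnotationFile, path) -> None:
    doc = {
        "schema_version": annotations.schema_version,
        "image": {
            "path": annotations.image_path,
            "pixel_size_um": annotations.pixel_size,
            "n_zplanes": annotations.n_zplanes,
        },
        "meshes": [
            {
                "mesh_id": m.mesh_id,
                "provenance": m.provenance.value,
                "z_plane": m.z_plane,
                "vertices": [[float(x), float(y)] for x, y in m.vertices],
            }
            for m in annotations.meshes
        ],
        "adjacency": [list(p) for p in annotations.adjacency],
        "metadata": annotations.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotations(path) -> AnnotationFile:
    """Read and validate an annotation JSON file.

    Raises :class:`FormatError` naming the JSON path of the offending
    field on schema violations.
    """
    doc = json.loads(Path(path).read_text())
    img = doc.get("image", {})
    if "pixel_size_um" not in img or img["pixel_size_um"] is None:
        raise FormatError("missing field: image.pixel_size_um")
    meshes = []
    for i, m in enumerate(doc.get("meshes", [])):
        verts = m.get("vertices")
        if verts is None or len(verts) < 3:
            raise FormatError(f"meshes[{i}].vertices: need >= 3 vertices")
        try:
            meshes.append(
                MeshContour(
                    vertices=np.asarray(verts, dtype=float),
                    z_plane=m.get("z_plane"),
                    pixel_size=float(img["pixel_size_um"]),
                    provenance=Provenance(m.get("provenance", "ground_truth")),
                    mesh_id=str(m.get("mesh_id", i)),
                )
            )
        except (ContourError, ValueError) as exc:
            raise FormatError(f"meshes[{i}]: {exc}") from exc
    return AnnotationFile(
        meshes=meshes,
        image_path=img.get("path", ""),
        pixel_size=float(img["pixel_size_um"]),
        n_zplanes=int(img.get("n_zplanes", 1)),
        adjacency=[tuple(p) for p in doc.get("adjacency", [])],
        metadata=doc.get("metadata", {}),
        schema_version=int(doc.get("schema_version", SCHEMA_VERSION)),
    )


def export_geometry_table(
    annotations: AnnotationFile, path, image: Optional[np.ndarray] = None
) -> "pd.DataFrame":
    """One CSV row per mesh: geometry, polarity (when an image is given)
    and an error flag for degenerate meshes.  Deterministic byte output
    for identical inputs (stable mesh ordering)."""
    import pandas as pd

    from .geometry import simplify_contour
    from .polarity import polarity_index

    rows = []
    for m in sorted(annotations.meshes, key=lambda c: c.mesh_id):
        row = {"mesh_id": m.mesh_id, "provenance": m.provenance.value, "error": ""}
        try:
            geom = compute_geometry(m)
            row.update(
                area_um2=round(geom.area_um2, 6),
                perimeter_um=round(geom.perimeter_um, 6),
                circularity=round(geom.circularity, 6),
                solidity=round(geom.solidity, 6),
                vertex_count=geom.vertex_count,
                shape_class=geom.shape_class.value,
            )
            if image is not None:
                prof = polarity_index(image, simplify_contour(m))
                row["polarity_index"] = round(prof.polarity_index, 6)
                row["polar_label"] = prof.label.value
        except (ContourError, ValueError, ZeroDivisionError) as exc:
            row["error"] = type(exc).__name__
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df


_CONFIG_SECTIONS = {"lattice", "render", "trace", "train", "evaluate", "seed", "patch_size"}


@dataclass
class ProjectConfig:
    """Strict-schema run configuration (one YAML file)."""

    lattice: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    seed: int = 0
    patch_size: int = 128

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _CONFIG_SECTIONS
        if unknown:
            raise FormatError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**doc)

    def resolved(self) -> dict:
        return {
            "lattice": self.lattice, "render": self.render, "trace": self.trace,
            "train": self.train, "evaluate": self.evaluate, "seed": self.seed,
            "patch_size": self.patch_size,
        }


def write_manifest(out_dir, config: dict, seed: int, inputs: Optional[list] = None) -> Path:
    """Record the fully resolved run parameters next to the outputs."""
    import pnnmesh

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pnnmesh_version": pnnmesh.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
        "input_hashes": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in (inputs or [])
        },
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
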