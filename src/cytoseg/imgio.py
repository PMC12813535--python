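"""Raster and annotation I/O.

Conventions used throughout the package (stated once, here):

* arrays are indexed ``(row, col)``, 0-based, row 0 at the top;
* images are ``H x W x 3`` floats in ``[0, 1]``;
* instance label maps are ``H x W`` non-negative integers, 0 = background,
  stored as 16-bit grayscale PNG (so labels must not exceed 65535);
* angles are degrees, counterclockwise from the +col axis, i.e. a point at
  angle ``theta`` and distance ``d`` from ``(r, c)`` is
  ``(r + d*sin(theta), c + d*cos(theta))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "HEImage",
    "InstanceLabelMap",
    "ContourSet",
    "load_image",
    "save_image",
    "load_labelmap",
    "save_labelmap",
    "export_contours",
    "import_contours",
]

MAX_LABEL = 65535


@dataclass
class HEImage:
    """An RGB microscopy-style image with values in [0, 1]."""

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("zero-sized image")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class InstanceLabelMap:
    """Integer raster: 0 is background, k > 0 identifies instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {arr.dtype}")
        if arr.ndim != 2:
            raise ValueError(f"expected HxW labels, got shape {arr.shape}")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = arr.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        """Sorted nonzero instance ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    def mask(self, instance_id: int) -> np.ndarray:
        return self.labels == instance_id


@dataclass
class ContourSet:
    """Closed polygons, one per instance, vertices in (row, col) order.

    Polygons are implicitly closed: the first vertex is not repeated.
    """

    contours: dict[int, np.ndarray] = field(default_factory=dict)

    def add(self, instance_id: int, vertices: np.ndarray) -> None:
        vertices = np.asarray(vertices, dtype=np.float64)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
            raise ValueError("a contour needs >= 3 (row, col) vertices")
        self.contours[int(instance_id)] = vertices

    def __len__(self) -> int:
        return len(self.contours)


def _to_float01(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ValueError(f"unsupported bit depth: {arr.dtype}")


def load_image(path: str | Path) -> HEImage:
    """Read a PNG or TIFF into an HEImage.

    Grayscale input is replicated to 3 channels, an alpha channel is dropped,
    and integer depths are rescaled to [0, 1] full-scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    arr = _to_float01(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise ValueError(f"expected 1/3/4 channels, got shape {arr.shape}")
    return HEImage(np.clip(arr, 0.0, 1.0), source_path=str(path))


def save_image(image: HEImage, path: str | Path) -> None:
    """Write an HEImage as 8-bit RGB PNG (or TIFF by extension)."""
    path = Path(path)
    arr8 = np.round(np.clip(image.pixels, 0, 1) * 255.0).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), arr8)
    else:
        Image.fromarray(arr8, mode="RGB").save(path)


def load_labelmap(path: str | Path) -> InstanceLabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError("label maps must be single-channel")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label maps must be integer-typed")
    return InstanceLabelMap(arr.astype(np.int64))


def save_labelmap(labelmap: InstanceLabelMap, path: str | Path) -> None:
    """Write as 16-bit grayscale PNG; losslessly round-trips labels <= 65535."""
    arr = labelmap.labels
    if arr.max(initial=0) > MAX_LABEL:
        raise ValueError(f"label {arr.max()} exceeds 16-bit storage ({MAX_LABEL})")
    Image.fromarray(arr.astype(np.uint16)).save(Path(path))


def export_contours(contours: ContourSet, path: str | Path) -> None:
    """Write contours as a plain-text sidecar.

    One record per instance::

        instance <id> <n_vertices>
        <row> <col>
        ...

    Vertices are written with full float precision so import is lossless.
    """
    lines: list[str] = []
    for inst_id in sorted(contours.contours):
        verts = contours.contours[inst_id]
        if verts.shape[0] < 3:
            raise ValueError(f"instance {inst_id}: contour has < 3 vertices")
        lines.append(f"instance {inst_id} {verts.shape[0]}")
        for r, c in verts:
            lines.append(f"{float(r)!r} {float(c)!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def import_contours(path: str | Path) -> ContourSet:
    out = ContourSet()
    tokens = Path(path).read_text().split("\n")
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        i += 1
        if not line:
            continue
        parts = line.split()
        if parts[0] != "instance":
            raise ValueError(f"malformed contour file near: {line!r}")
        inst_id, n = int(parts[1]), int(parts[2])
        verts = np.empty((n, 2), dtype=np.float64)
        for k in range(n):
            r, c = tokens[i].split()
            verts[k] = (float(r), float(c))
            i += 1
        out.add(inst_id, verts)
    return out
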