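"""Grayscale ultrasonogram I/O, min-max normalization and polygonal ROIs.

Images are plain 2-D ``numpy`` integer arrays (row = y, column = x), one
value per pixel in ``[0, L]`` with ``L = 255`` for the 8-bit B-mode frames
this package targets. Multi-channel rasters are reduced to a single
luminance channel, intensities are rescaled so the darkest pixel maps to 0
and the brightest to ``T`` (min-max normalization), and a polygonal region
of interest (ROI) is rasterized into a boolean mask from which the
per-subject pixel sample is extracted.

Coordinate convention: 0-based; ``x`` is the column index, ``y`` the row
index; pixel ``(row r, column c)`` has its center at the point ``(c, r)``.
A pixel belongs to an ROI iff its center is inside the polygon under the
even-odd rule, with centers exactly on left/top edges counted inside
(half-open rule), so abutting polygons never share or drop pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .cohort import PixelSample
from .errors import (
    DegenerateImageError,
    DimensionMismatchError,
    EmptyMaskError,
    UnsupportedFormatError,
)

__all__ = [
    "RoiPolygon",
    "read_image",
    "write_image",
    "to_grayscale",
    "normalize_image",
    "rasterize_roi",
    "extract_sample",
    "load_roi",
    "save_roi",
]

# Rec.601 luma weights for RGB -> luminance reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RoiPolygon:
    """Polygonal ROI as an ordered vertex list in pixel units.

    Vertices are ``(x, y)`` pairs (x = column, y = row, 0-based). At least
    three finite vertices are required; the polygon may be non-convex and
    is interpreted under the even-odd rule.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("an ROI polygon needs at least 3 vertices")
        if not np.all(np.isfinite(np.asarray(verts))):
            raise ValueError("ROI polygon vertices must be finite")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (np.round rounds to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def to_grayscale(raster: np.ndarray) -> np.ndarray:
    """Reduce an 8-bit raster to a single-channel grayscale image.

    1-channel input passes through unchanged; 3-/4-channel input is
    converted with Rec.601 luma weights (alpha ignored) and rounded to the
    nearest integer.

    Raises
    ------
    UnsupportedFormatError
        If the per-channel bit depth is not 8 or the layout is unknown.
    """
    arr = np.asarray(raster)
    if arr.dtype != np.uint8:
        raise UnsupportedFormatError(
            f"expected 8-bit per channel input, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        luma = arr[..., :3].astype(float) @ _LUMA
        return _round_half_away(luma).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[..., 0].copy()
    raise UnsupportedFormatError(f"unsupported raster shape {arr.shape}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image and return it as an 8-bit grayscale matrix."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB", "RGBA", "LA", "P"):
            raise UnsupportedFormatError(
                f"unsupported image mode {im.mode!r} in {path}"
            )
        if im.mode == "P":
            im = im.convert("RGB")
        if im.mode == "LA":
            im = im.convert("L")
        arr = np.asarray(im)
    return to_grayscale(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a 2-D uint8 image (or an RGB overlay) as PNG/TIFF."""
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def normalize_image(
    img: np.ndarray,
    T: int = 255,
    f_min: int | None = None,
    f_max: int | None = None,
) -> np.ndarray:
    """Min-max rescale intensities so they span ``[0, T]``.

    Applies the affine map ``G_i = T * (f_i - f_min) / (f_max - f_min)``,
    rounded to the nearest integer (ties away from zero) and clamped to
    ``[0, T]``. By default ``f_min``/``f_max`` are the per-image extremes;
    pass cohort-wide extremes explicitly for global scaling.

    The map is order-preserving and idempotent: once the image spans
    ``[0, T]`` a second pass is the identity.

    Raises
    ------
    DegenerateImageError
        If ``f_max == f_min`` (single-valued image).
    """
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionMismatchError("expected a nonempty 2-D image")
    if T < 1:
        raise ValueError("T must be >= 1")
    lo = int(arr.min()) if f_min is None else int(f_min)
    hi = int(arr.max()) if f_max is None else int(f_max)
    if hi == lo:
        raise DegenerateImageError(
            "image intensity range is degenerate (f_max == f_min)"
        )
    scaled = T * (arr.astype(float) - lo) / (hi - lo)
    out = np.clip(_round_half_away(scaled), 0, T)
    dtype = np.uint8 if T <= 255 else np.int64
    return out.astype(dtype)


def rasterize_roi(poly: RoiPolygon, width: int, height: int) -> np.ndarray:
    """Rasterize a polygon into a boolean mask over a width x height grid.

    A pixel is inside iff its center ``(c, r)`` satisfies the even-odd rule
    for the polygon. The crossing test counts an edge when it spans the
    ray strictly on one side (``y1 > y != y2 > y``) and its intersection
    lies strictly right of the center, which makes left and top edges
    inclusive and right and bottom edges exclusive.

    Raises
    ------
    EmptyMaskError
        If no pixel center falls inside (polygon degenerate or fully
        outside the image).
    """
    verts = poly.as_array()
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    xc, yc = np.meshgrid(xs, ys)  # pixel centers, shape (height, width)

    inside = np.zeros((height, width), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > yc) != (y2 > yc)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (yc - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xc < x_at)

    if not inside.any():
        raise EmptyMaskError("ROI polygon covers no pixel center of the image")
    return inside


def extract_sample(
    img: np.ndarray, mask: np.ndarray, subject_id: str = "subject", L: int = 255
) -> PixelSample:
    """Collect the intensities of all masked pixels, in row-major order."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise DimensionMismatchError(
            f"image shape {img.shape} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise EmptyMaskError("cannot extract a pixel sample from an empty mask")
    return PixelSample(subject_id, img[mask].astype(np.int64), L=L)


def load_roi(path: str | Path) -> RoiPolygon:
    """Load an ROI polygon from JSON: ``{"vertices": [[x, y], ...]}``."""
    with open(path) as fh:
        data = json.load(fh)
    return RoiPolygon(tuple((float(x), float(y)) for x, y in data["vertices"]))


def save_roi(path: str | Path, poly: RoiPolygon) -> None:
    with open(path, "w") as fh:
        json.dump({"vertices": [list(v) for v in poly.vertices]}, fh)
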