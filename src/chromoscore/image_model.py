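"""Image substrate shared by the scoring modules.

Images are plain :class:`numpy.ndarray` objects on the 8-bit intensity
scale.  A *color image* is an ``(v, h, 3)`` array of RGB channel values in
``[0, 255]``; a *gray image* is a 2-D ``(v, h)`` array of intensities in
``[0, 255]``, real-valued after color conversion so that no quantization
error enters the downstream scores.  ``v`` is the vertical extent (rows)
and ``h`` the horizontal extent (columns).

Coordinate convention
---------------------
Pixel coordinates are 0-based ``(x, y)`` pairs with ``x`` the column index
increasing rightward and ``y`` the row index increasing downward, i.e.
``image[y, x]``.  Polygon vertices in annotation files follow the same
``(x, y)`` order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GRAY_WEIGHTS_BT601",
    "RegionPair",
    "load_image",
    "load_regions",
    "rasterize_region",
    "region_mean",
    "to_grayscale",
    "validate_color_image",
    "validate_gray_image",
]

#: ITU-R BT.601 luma weights for (R, G, B).  The conversion used whenever a
#: color image enters the pipeline; alternative weights may be passed to
#: :func:`to_grayscale` and are recorded in run configs for reproducibility.
GRAY_WEIGHTS_BT601: tuple[float, float, float] = (0.299, 0.587, 0.114)

#: Geometric tolerance for point-on-edge and degeneracy tests during
#: polygon rasterization.
_GEOM_TOL = 1e-9


def validate_color_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid ``(v, h, 3)`` RGB image in [0, 255]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"color image must have shape (v, h, 3), got {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("color channel values must lie in [0, 255]")
    return img


def validate_gray_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid 2-D intensity image in [0, 255]."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensity values must lie in [0, 255]")
    return img


def to_grayscale(
    img: np.ndarray,
    weights: Sequence[float] = GRAY_WEIGHTS_BT601,
) -> np.ndarray:
    """Convert an RGB image to a real-valued grayscale image.

    Per-pixel luma is ``w_r*R + w_g*G + w_b*B`` with BT.601 weights by
    default.  The result is kept as floating point (no rounding back to
    8-bit) because the contrast and texture scores operate on real
    intensities.  A gray input with ``R == G == B == k`` maps to exactly
    ``k`` since the weights sum to 1.
    """
    img = validate_color_image(img)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be a length-3 sequence")
    return img.astype(float) @ w


def load_image(path: str | Path, weights: Sequence[float] = GRAY_WEIGHTS_BT601) -> np.ndarray:
    """Read a PNG/TIFF image from disk and return it as a gray image.

    8-bit grayscale files are returned as float arrays unchanged; RGB(A)
    files are converted with :func:`to_grayscale` (alpha is dropped).
    """
    raw = iio.imread(path)
    if raw.ndim == 2:
        return validate_gray_image(raw.astype(float))
    if raw.ndim == 3 and raw.shape[2] >= 3:
        return to_grayscale(raw[:, :, :3], weights=weights)
    raise ValueError(f"unsupported image layout {raw.shape} in {path}")


# ---------------------------------------------------------------------------
# Polygon region annotations
# ---------------------------------------------------------------------------


def _polygon_area(verts: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (n, 2) vertices."""
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _on_boundary(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Boolean mask of points lying on a polygon edge (within tolerance)."""
    on = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (np.abs(cross) <= _GEOM_TOL * max(1.0, abs(x2 - x1) + abs(y2 - y1)))
            & (px >= min(x1, x2) - _GEOM_TOL)
            & (px <= max(x1, x2) + _GEOM_TOL)
            & (py >= min(y1, y2) - _GEOM_TOL)
            & (py <= max(y1, y2) + _GEOM_TOL)
        )
        on |= within
    return on


def _even_odd_inside(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd ray-casting test for strict interior membership."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not np.any(crosses):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)
    return inside


def rasterize_region(
    polygon: Sequence[Sequence[float]],
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize a polygon to a boolean pixel mask.

    A pixel belongs to the mask when its center is strictly inside the
    polygon under the even-odd rule, or lies on the polygon boundary
    (inclusive boundaries keep small hand-drawn regions stable).

    Parameters
    ----------
    polygon
        Ordered ``(x, y)`` vertices; at least 3, all inside the image.
    image_shape
        ``(v, h)`` image shape the mask is rasterized onto.

    Returns
    -------
    numpy.ndarray
        Boolean mask of shape ``image_shape``.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon must be a sequence of >= 3 (x, y) vertices")
    v, h = image_shape
    if (
        verts[:, 0].min() < 0
        or verts[:, 0].max() > h - 1
        or verts[:, 1].min() < 0
        or verts[:, 1].max() > v - 1
    ):
        raise ValueError("polygon vertices must lie inside the image bounds")
    if abs(_polygon_area(verts)) < _GEOM_TOL:
        raise ValueError("degenerate polygon: zero area")

    ys, xs = np.mgrid[0:v, 0:h]
    px = xs.astype(float)
    py = ys.astype(float)
    return _even_odd_inside(px, py, verts) | _on_boundary(px, py, verts)


@dataclass
class RegionPair:
    """Disjoint lesion / healthy pixel masks with their source polygons.

    ``lesion_mask`` covers the annotated lesion region R_l and
    ``healthy_mask`` the reference healthy-tissue region R_h used as the
    contrast baseline.
    """

    lesion_mask: np.ndarray
    healthy_mask: np.ndarray
    lesion_polygon: list[tuple[float, float]] = field(default_factory=list)
    healthy_polygon: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        self.healthy_mask = np.asarray(self.healthy_mask, dtype=bool)
        if self.lesion_mask.shape != self.healthy_mask.shape:
            raise ValueError("lesion and healthy masks must share a shape")
        if not self.lesion_mask.any():
            raise ValueError("lesion region is empty")
        if not self.healthy_mask.any():
            raise ValueError("healthy region is empty")
        if np.any(self.lesion_mask & self.healthy_mask):
            raise ValueError("lesion and healthy regions must be disjoint")

    @classmethod
    def from_polygons(
        cls,
        lesion: Sequence[Sequence[float]],
        healthy: Sequence[Sequence[float]],
        image_shape: tuple[int, int],
    ) -> "RegionPair":
        return cls(
            lesion_mask=rasterize_region(lesion, image_shape),
            healthy_mask=rasterize_region(healthy, image_shape),
            lesion_polygon=[tuple(p) for p in lesion],
            healthy_polygon=[tuple(p) for p in healthy],
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lesion": [list(p) for p in self.lesion_polygon],
            "healthy": [list(p) for p in self.healthy_polygon],
        }
        Path(path).write_text(json.dumps(payload))


def load_regions(path: str | Path, image_shape: tuple[int, int]) -> RegionPair:
    """Load a per-image annotation JSON and rasterize it onto the image.

    The file maps ``"lesion"`` and ``"healthy"`` each to an ordered list of
    ``[x, y]`` polygon vertices.
    """
    payload = json.loads(Path(path).read_text())
    for key in ("lesion", "healthy"):
        if key not in payload:
            raise ValueError(f"annotation file {path} lacks a '{key}' polygon")
    return RegionPair.from_polygons(payload["lesion"], payload["healthy"], image_shape)


def region_mean(img: np.ndarray, mask: np.ndarray, stat: str = "mean") -> float:
    """Summary gray value of the pixels selected by ``mask``.

    The arithmetic mean is the default region summary g(R); the median is
    available as a robust alternative.
    """
    img = validate_gray_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("region mask is empty")
    values = img[mask]
    if stat == "mean":
        return float(values.mean())
    if stat == "median":
        return float(np.median(values))
    raise ValueError(f"unknown region statistic {stat!r}")
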