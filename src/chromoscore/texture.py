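"""Circular-neighborhood LBP sampling and the global texture-variance score.

The mucosa-visibility score var(R,N)_g is built from the local binary
pattern (LBP) neighborhood: around each center pixel ``(c_x, c_y)`` a
circle of ``N`` samples at radius ``R`` is read off, the i-th sample at

    x_i = c_x + R * cos(2*pi*i / N),   y_i = c_y + R * sin(2*pi*i / N)

for i = 1..N, in image coordinates (x rightward, y downward).  Off-grid
positions are bilinearly interpolated from the four surrounding pixel
centers; positions within 1e-9 of a grid point are read directly.

From the sampled intensities three quantities are derived:

* the **LBP pattern**: bit i is 1 when sample i is >= the center intensity
  (``b(x) = 1 if x >= 0 else 0`` applied to ``p_n(i) - p_c``);
* the **local variance**: the population variance (divisor N) of the N
  neighbor samples, a rotation-invariant local texture measure that is
  independent of the binary coding;
* the **global texture variance** var(R,N)_g: the local variance averaged
  over every center whose full sampling circle fits inside the image.
  Centers closer than R to a border are excluded and the average is taken
  over the valid centers only, which avoids padding artifacts at the
  expense of a slightly smaller support than the full h x v grid.

The final score averages var(R,N)_g over several radii (default
R = 10, 20, 30, 40, 50) so that texture at multiple spatial frequencies
contributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_model import validate_gray_image

__all__ = [
    "DEFAULT_RADII",
    "DEFAULT_NEIGHBORS",
    "NeighborhoodSpec",
    "LbpPattern",
    "TextureVarianceResult",
    "sample_neighbors",
    "lbp_pattern",
    "local_variance",
    "global_texture_variance",
    "multi_radius_score",
]

#: Radii of the multi-scale score (pixels).
DEFAULT_RADII: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)

#: Default neighbor count N; the canonical 8-sample LBP circle.
DEFAULT_NEIGHBORS: int = 8

#: Tolerance under which an interpolation coordinate is snapped to a pixel
#: center and read directly.
_GRID_SNAP = 1e-9


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling neighborhood: radius ``R`` (pixels) and ``N`` samples."""

    R: float
    N: int = DEFAULT_NEIGHBORS

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("radius R must be positive")
        if self.N < 2:
            raise ValueError("neighbor count N must be >= 2")

    def offsets(self) -> np.ndarray:
        """(N, 2) array of (dx, dy) sample offsets for i = 1..N."""
        i = np.arange(1, self.N + 1, dtype=float)
        ang = 2.0 * math.pi * i / self.N
        return np.column_stack([self.R * np.cos(ang), self.R * np.sin(ang)])

    def margin(self) -> int:
        """Border margin (pixels) inside which no valid center exists."""
        return int(math.ceil(self.R - _GRID_SNAP))


@dataclass(frozen=True)
class LbpPattern:
    """Ordered LBP bits for one center pixel.

    ``bits[i-1]`` corresponds to neighbor i.  ``code`` is the decimal
    encoding with weight ``2**(i-1)`` on bit i.
    """

    bits: tuple[int, ...]
    center: tuple[float, float]

    @property
    def code(self) -> int:
        return sum(b << k for k, b in enumerate(self.bits))


@dataclass
class TextureVarianceResult:
    """Multi-radius texture-variance score for one image."""

    per_radius: dict[float, float]
    averaged: float
    N: int
    valid_center_count: dict[float, int] = field(default_factory=dict)


def _snap(value: float) -> float:
    r = round(value)
    return float(r) if abs(value - r) <= _GRID_SNAP else value


def _bilinear_at(img: np.ndarray, x: float, y: float) -> float:
    """Sample ``img`` at real-valued ``(x, y)``, bilinearly off-grid."""
    v, h = img.shape
    x, y = _snap(x), _snap(y)
    if x < 0 or x > h - 1 or y < 0 or y > v - 1:
        raise ValueError(f"sample position ({x}, {y}) outside image bounds")
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    fx, fy = x - x0, y - y0
    x1 = x0 + 1 if fx > 0 else x0
    y1 = y0 + 1 if fy > 0 else y0
    top = (1 - fx) * img[y0, x0] + fx * img[y0, x1]
    bot = (1 - fx) * img[y1, x0] + fx * img[y1, x1]
    return float((1 - fy) * top + fy * bot)


def sample_neighbors(
    img: np.ndarray,
    center: tuple[float, float],
    spec: NeighborhoodSpec,
) -> np.ndarray:
    """Intensities of the N circular neighbors of ``center``.

    ``center`` is an ``(x, y)`` pixel coordinate.  The full circle of
    radius ``spec.R`` must lie within the image; otherwise an out-of-bounds
    error is raised and the caller must restrict itself to interior
    centers.
    """
    img = validate_gray_image(img)
    cx, cy = center
    v, h = img.shape
    if (
        cx - spec.R < -_GRID_SNAP
        or cx + spec.R > h - 1 + _GRID_SNAP
        or cy - spec.R < -_GRID_SNAP
        or cy + spec.R > v - 1 + _GRID_SNAP
    ):
        raise ValueError(
            f"sampling circle R={spec.R} around center ({cx}, {cy}) exits the "
            f"{v}x{h} image bounds"
        )
    return np.array(
        [_bilinear_at(img, cx + dx, cy + dy) for dx, dy in spec.offsets()]
    )


def lbp_pattern(
    img: np.ndarray,
    center: tuple[float, float],
    spec: NeighborhoodSpec,
) -> LbpPattern:
    """LBP bits at ``center``: bit i = 1 iff neighbor i >= center intensity."""
    neighbors = sample_neighbors(img, center, spec)
    cx, cy = center
    pc = _bilinear_at(np.asarray(img, dtype=float), cx, cy)
    bits = tuple(int(p - pc >= 0) for p in neighbors)
    return LbpPattern(bits=bits, center=(cx, cy))


def local_variance(
    img: np.ndarray,
    center: tuple[float, float],
    spec: NeighborhoodSpec,
) -> float:
    """Population variance (divisor N) of the N neighbor intensities.

    The center pixel itself does not enter the mean.
    """
    neighbors = sample_neighbors(img, center, spec)
    mu = neighbors.mean()
    return float(np.mean((neighbors - mu) ** 2))


def _shifted(img: np.ndarray, block: tuple[slice, slice], dx: float, dy: float) -> np.ndarray:
    """Neighbor intensities for every center in ``block`` at offset (dx, dy).

    Because the offset is constant across centers, the bilinear
    interpolation reduces to a fixed-weight blend of four integer-shifted
    views of the image.
    """
    dx, dy = _snap(dx), _snap(dy)
    x0, y0 = int(math.floor(dx)), int(math.floor(dy))
    fx, fy = dx - x0, dy - y0
    ys, xs = block
    v, h = img.shape

    def view(ox: int, oy: int) -> np.ndarray:
        return img[ys.start + oy : ys.stop + oy, xs.start + ox : xs.stop + ox]

    if fx == 0 and fy == 0:
        return view(x0, y0).astype(float)
    x1 = x0 + 1 if fx > 0 else x0
    y1 = y0 + 1 if fy > 0 else y0
    return (
        (1 - fx) * (1 - fy) * view(x0, y0)
        + fx * (1 - fy) * view(x1, y0)
        + (1 - fx) * fy * view(x0, y1)
        + fx * fy * view(x1, y1)
    ).astype(float)


def global_texture_variance(img: np.ndarray, spec: NeighborhoodSpec) -> float:
    """Mean local variance over all centers with a fully in-bounds circle.

    Valid centers are at least ``R`` from every border; their count is
    ``(v - 2*ceil(R)) * (h - 2*ceil(R))`` and must be positive.
    """
    img = np.asarray(validate_gray_image(img), dtype=float)
    v, h = img.shape
    m = spec.margin()
    if v - 2 * m < 1 or h - 2 * m < 1:
        raise ValueError(
            f"image {v}x{h} too small for radius {spec.R}: needs at least "
            f"{2 * m + 1} pixels per side"
        )
    block = (slice(m, v - m), slice(m, h - m))
    samples = np.stack(
        [_shifted(img, block, dx, dy) for dx, dy in spec.offsets()]
    )
    mu = samples.mean(axis=0)
    local_var = np.mean((samples - mu) ** 2, axis=0)
    return float(local_var.mean())


def multi_radius_score(
    img: np.ndarray,
    radii: tuple[float, ...] = DEFAULT_RADII,
    N: int = DEFAULT_NEIGHBORS,
) -> TextureVarianceResult:
    """var(R,N)_g at each radius and their arithmetic mean.

    The image must accommodate the largest radius
    (``min(v, h) > 2 * max(radii)``); otherwise the offending radius is
    named in the error.
    """
    img = np.asarray(validate_gray_image(img), dtype=float)
    v, h = img.shape
    if not radii:
        raise ValueError("at least one radius is required")
    per_radius: dict[float, float] = {}
    counts: dict[float, int] = {}
    for r in radii:
        spec = NeighborhoodSpec(R=float(r), N=N)
        m = spec.margin()
        if v - 2 * m < 1 or h - 2 * m < 1:
            raise ValueError(
                f"image {v}x{h} too small for radius {r} "
                f"(needs > {2 * m} pixels per side)"
            )
        per_radius[float(r)] = global_texture_variance(img, spec)
        counts[float(r)] = (v - 2 * m) * (h - 2 * m)
    averaged = float(np.mean(list(per_radius.values())))
    return TextureVarianceResult(
        per_radius=per_radius, averaged=averaged, N=N, valid_center_count=counts
    )
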