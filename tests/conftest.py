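"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's
vectorized code paths: bilinear interpolation, circular sampling and the
global variance are re-derived with scalar Python loops so that test
comparisons are genuinely two-route.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_bilinear(img: np.ndarray, x: float, y: float) -> float:
    """Scalar bilinear interpolation with grid snapping."""
    if abs(x - round(x)) < 1e-9:
        x = round(x)
    if abs(y - round(y)) < 1e-9:
        y = round(y)
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    fx, fy = x - x0, y - y0
    x1 = min(x0 + 1, img.shape[1] - 1)
    y1 = min(y0 + 1, img.shape[0] - 1)
    return (
        (1 - fx) * (1 - fy) * img[y0, x0]
        + fx * (1 - fy) * img[y0, x1]
        + (1 - fx) * fy * img[y1, x0]
        + fx * fy * img[y1, x1]
    )


def oracle_neighbors(img: np.ndarray, cx: float, cy: float, R: float, N: int) -> list[float]:
    """Circular samples at angles 2*pi*i/N, i = 1..N, y pointing down."""
    out = []
    for i in range(1, N + 1):
        ang = 2.0 * math.pi * i / N
        out.append(oracle_bilinear(img, cx + R * math.cos(ang), cy + R * math.sin(ang)))
    return out


def oracle_local_variance(img: np.ndarray, cx: float, cy: float, R: float, N: int) -> float:
    s = oracle_neighbors(img, cx, cy, R, N)
    mu = sum(s) / N
    return sum((v - mu) ** 2 for v in s) / N


def oracle_global_variance(img: np.ndarray, R: float, N: int) -> float:
    """Double loop over every center whose circle fits inside the image."""
    v, h = img.shape
    m = math.ceil(R - 1e-9)
    total, count = 0.0, 0
    for cy in range(m, v - m):
        for cx in range(m, h - m):
            total += oracle_local_variance(img, cx, cy, R, N)
            count += 1
    return total / count


def oracle_point_in_polygon(px: float, py: float, verts: list[tuple[float, float]]) -> bool:
    """Even-odd membership with inclusive boundary, scalar re-derivation."""
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if (
            abs(cross) <= 1e-9 * max(1.0, abs(x2 - x1) + abs(y2 - y1))
            and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
            and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
        ):
            return True
    inside = False
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def ramp_3x3() -> np.ndarray:
    """The worked 3x3 intensity ramp used by the hand-derived examples."""
    return np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
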