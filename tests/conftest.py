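"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the
minimum-rectangle oracle is a dense rotation search over *all* pixel
centers (no convex hull), and mask builders rasterize shapes with
scikit-image's drawing primitives.
"""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from topmorph import InstanceMask


def rect_mask(shape, r0, r1, c0, c1, **kw) -> InstanceMask:
    """Axis-aligned filled rectangle over rows [r0, r1) and cols [c0, c1)."""
    px = np.zeros(shape, dtype=bool)
    px[r0:r1, c0:c1] = True
    return InstanceMask(px, **kw)


def rotated_rect_mask(shape, center, length, width, angle_deg, **kw) -> InstanceMask:
    """Filled rectangle of given size rotated by angle_deg (CCW from cols)."""
    cr, cc = center
    th = np.radians(angle_deg)
    # length axis direction in (row, col)
    du = np.array([np.sin(th), np.cos(th)])
    dv = np.array([np.cos(th), -np.sin(th)])
    half = [
        +du * length / 2 + dv * width / 2,
        +du * length / 2 - dv * width / 2,
        -du * length / 2 - dv * width / 2,
        -du * length / 2 + dv * width / 2,
    ]
    corners = np.array([(cr + h[0], cc + h[1]) for h in half])
    rr, cc_ = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
    px = np.zeros(shape, dtype=bool)
    px[rr, cc_] = True
    return InstanceMask(px, **kw)


def ellipse_mask(shape, center, semi_r, semi_c, **kw) -> InstanceMask:
    """Axis-aligned filled ellipse (closed region, pixel centers)."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    px = ((rr - center[0]) / semi_r) ** 2 + ((cc - center[1]) / semi_c) ** 2 <= 1.0
    return InstanceMask(px, **kw)


def random_convex_mask(rng: np.random.Generator, size: int = 64) -> InstanceMask:
    """Random convex blob: hull of random points, rasterized."""
    while True:
        k = int(rng.integers(4, 12))
        pts = rng.uniform(4, size - 4, size=(k, 2))
        hull = _hull_vertices(pts)
        rr, cc = draw_polygon(hull[:, 0], hull[:, 1], shape=(size, size))
        if rr.size >= 3:
            px = np.zeros((size, size), dtype=bool)
            px[rr, cc] = True
            return InstanceMask(px)


def _hull_vertices(pts: np.ndarray) -> np.ndarray:
    # Andrew's monotone chain, independent of scipy's Qhull
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def cross2(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(points):
        chain: list[np.ndarray] = []
        for p in points:
            while len(chain) >= 2 and cross2(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    return np.array(lower[:-1] + upper[:-1])


def brute_force_min_rect_area(mask: InstanceMask,
                              step_deg: float = 0.1) -> tuple[float, float]:
    """Dense rotation search over all pixel centers.

    Rotates the full point set through every angle in {0, step, ...,
    180 - step} degrees, takes the axis-aligned extent box (pixel-center
    convention) and returns (minimal area, argmin angle in degrees).
    """
    pts = np.argwhere(mask.pixels).astype(float)
    angles = np.arange(0.0, 180.0, step_deg)
    best_area, best_angle = np.inf, 0.0
    for start in range(0, len(angles), 200):
        chunk = np.radians(angles[start:start + 200])
        cos, sin = np.cos(chunk), np.sin(chunk)
        # rotate (row, col) by -theta: projections onto the two axes
        u = pts[:, 1, None] * cos + pts[:, 0, None] * sin
        v = -pts[:, 1, None] * sin + pts[:, 0, None] * cos
        areas = (u.max(axis=0) - u.min(axis=0)) * (v.max(axis=0) - v.min(axis=0))
        i = int(np.argmin(areas))
        if areas[i] < best_area:
            best_area = float(areas[i])
            best_angle = float(angles[start + i])
    return best_area, best_angle


def moment_orientation_deg(mask: InstanceMask) -> float:
    """Principal-axis orientation from second central moments, in [0, 180).

    Measured CCW from the column axis in the (x=col, y=row) frame —
    matching the rotated-rectangle angle convention.
    """
    pts = np.argwhere(mask.pixels).astype(float)
    d = pts - pts.mean(axis=0)
    y, x = d[:, 0], d[:, 1]
    mxx, myy, mxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    ang = 0.5 * np.degrees(np.arctan2(2 * mxy, mxx - myy))
    return float(ang % 180.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
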