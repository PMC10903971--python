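"""2D morphometry: minimum rotated rectangles and pixel-calibrated features.

The central primitive is the minimum-area rotated rectangle enclosing the
centers of a mask's foreground pixels.  Its longer side is reported as the
animal's *dorsal length* and its shorter side as the *abdominal width*;
fitting the box to the mask at any rotation rather than axis-aligned makes
these measurements pose-invariant.

Conventions
-----------
* Coordinates are 0-based ``(row, col)`` with row increasing downward.
  In the output schema ``*_x`` is the row coordinate and ``*_y`` the
  column coordinate.
* The rectangle encloses *pixel centers*: a run of ``w`` pixels has extent
  ``w - 1``.  This makes degenerate masks exact (a single pixel is a
  zero-size rectangle) at the cost of a ±1 px difference from a
  pixel-area convention.
* Angles are measured counterclockwise from the column (horizontal) axis
  in the ``(x=col, y=row)`` frame and reduced to ``[0, 180)`` degrees.
* Only measurements (lengths, areas, and downstream heights/volumes) are
  converted by PPM; coordinates stay in raw pixels because they are
  locations, not sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "InstanceMask",
    "RotatedBBox",
    "FeatureRecord",
    "fit_min_rotated_rect",
    "mask_centroid",
    "extract_2d_features",
    "features_to_frame",
    "write_feature_csv",
    "FEATURE_COLUMNS_2D",
    "FEATURE_COLUMNS_3D",
]

#: Feature-table column names, in output order.
FEATURE_COLUMNS_2D = [
    "Dorsal length",
    "Abdominal width",
    "Area",
    "bbox_topleft_x",
    "bbox_topleft_y",
    "bbox_bottomright_x",
    "bbox_bottomright_y",
    "bbox_rotatedangle",
    "Centroid_x",
    "Centroid_y",
]
FEATURE_COLUMNS_3D = ["Height_average", "Height_centroid", "Volume"]


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one foreground pixel."""


@dataclass(frozen=True)
class InstanceMask:
    """One segmented animal: a boolean pixel grid plus label and score.

    Parameters
    ----------
    pixels
        2D boolean array; True marks the animal's region of interest.
    label
        Short text identifying the instance (e.g. a class name or a
        numeric label from a label image).
    score
        Detection confidence in ``[0, 1]``.
    """

    pixels: np.ndarray
    label: str = "object"
    score: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {px.shape}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        """Number of foreground pixels."""
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass(frozen=True)
class RotatedBBox:
    """Minimum-area rectangle (any rotation) around a mask.

    ``length`` is the longer side and ``width`` the shorter, both in
    pixels under the pixel-center convention.  ``angle_deg`` is the
    orientation of the length axis, counterclockwise from the column
    axis, in ``[0, 180)``.  ``corners`` holds the four vertices in order
    around the rectangle as ``(row, col)`` pairs.
    """

    center: tuple[float, float]
    length: float
    width: float
    angle_deg: float
    corners: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise ValueError(f"corners must be 4x2, got {c.shape}")
        if self.length < self.width:
            raise ValueError("length must be >= width")
        object.__setattr__(self, "corners", c)

    @property
    def area(self) -> float:
        return self.length * self.width

    @property
    def topleft(self) -> tuple[float, float]:
        """Corner with minimal row+col (ties: smaller row)."""
        return _extreme_corner(self.corners, sign=+1)

    @property
    def bottomright(self) -> tuple[float, float]:
        """Corner with maximal row+col (ties: smaller row)."""
        return _extreme_corner(self.corners, sign=-1)


def _extreme_corner(corners: np.ndarray, sign: int) -> tuple[float, float]:
    # sign=+1 -> minimal row+col; sign=-1 -> maximal row+col.
    key = sign * corners.sum(axis=1)
    best = np.lexsort((corners[:, 0], key))[0]
    return float(corners[best, 0]), float(corners[best, 1])


@dataclass(frozen=True)
class FeatureRecord:
    """One row of the morphological feature table.

    2D fields are always present.  The three 3D fields are either all
    present (depth data available) or all ``None``.  Lengths/areas carry
    the unit implied by the PPM used at extraction (pixels at PPM=1,
    meters otherwise); coordinates are always raw pixels.
    """

    dorsal_length: float
    abdominal_width: float
    area: float
    centroid_x: float  # row
    centroid_y: float  # col
    bbox_topleft_x: float
    bbox_topleft_y: float
    bbox_bottomright_x: float
    bbox_bottomright_y: float
    bbox_rotatedangle: float
    label: str = "object"
    score: float = 1.0
    height_average: Optional[float] = None
    height_centroid: Optional[float] = None
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        three_d = [self.height_average, self.height_centroid, self.volume]
        if any(v is None for v in three_d) and not all(v is None for v in three_d):
            raise ValueError("3D fields must be all present or all absent")
        if self.dorsal_length < self.abdominal_width - 1e-9:
            raise ValueError("dorsal_length must be >= abdominal_width")

    @property
    def has_3d(self) -> bool:
        return self.volume is not None


def _require_nonempty(mask: InstanceMask) -> np.ndarray:
    pts = np.argwhere(mask.pixels)
    if pts.size == 0:
        raise EmptyMaskError("mask contains no segmented object (no foreground pixels)")
    return pts.astype(float)


def mask_centroid(mask: InstanceMask) -> tuple[float, float]:
    """Arithmetic mean of foreground pixel ``(row, col)`` coordinates."""
    pts = _require_nonempty(mask)
    r, c = pts.mean(axis=0)
    return float(r), float(c)


def fit_min_rotated_rect(mask: InstanceMask) -> RotatedBBox:
    """Fit the minimum-area rotated rectangle enclosing all foreground
    pixel centers.

    The minimum-area enclosing rectangle of a point set has one side
    collinear with an edge of the set's convex hull, so the search runs
    rotating-calipers style over hull edges only.  Degenerate masks (a
    single pixel, or all pixels collinear) return a zero-width rectangle
    rather than raising, which keeps batch processing total.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixel.
    """
    pts = _require_nonempty(mask)
    # Work in (x, y) = (col, row); angles are CCW from the column axis.
    xy = pts[:, ::-1]
    return _min_rect_from_points(xy)


def _min_rect_from_points(xy: np.ndarray) -> RotatedBBox:
    xy = np.unique(xy, axis=0)
    if len(xy) == 1:
        x, y = xy[0]
        corners = np.array([[y, x]] * 4, dtype=float)
        return RotatedBBox(center=(float(y), float(x)), length=0.0, width=0.0,
                           angle_deg=0.0, corners=corners)
    try:
        hull = ConvexHull(xy)
        hull_xy = xy[hull.vertices]
    except QhullError:
        return _collinear_rect(xy)
    return _calipers(hull_xy)


def _collinear_rect(xy: np.ndarray) -> RotatedBBox:
    center = xy.mean(axis=0)
    d = xy - center
    # principal direction of a degenerate (collinear) point set
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    direction = vt[0]
    t = d @ direction
    lo, hi = t.min(), t.max()
    p0 = center + lo * direction
    p1 = center + hi * direction
    corners_xy = np.array([p0, p1, p1, p0])
    angle = _reduce_angle(np.degrees(np.arctan2(direction[1], direction[0])))
    mid = (p0 + p1) / 2.0
    return RotatedBBox(
        center=(float(mid[1]), float(mid[0])),
        length=float(hi - lo),
        width=0.0,
        angle_deg=angle if hi > lo else 0.0,
        corners=corners_xy[:, ::-1].copy(),
    )


def _calipers(hull_xy: np.ndarray) -> RotatedBBox:
    n = len(hull_xy)
    edges = np.roll(hull_xy, -1, axis=0) - hull_xy
    phis = np.arctan2(edges[:, 1], edges[:, 0])
    best = None
    for phi in phis:
        cos_p, sin_p = np.cos(phi), np.sin(phi)
        rot = np.array([[cos_p, sin_p], [-sin_p, cos_p]])  # rotate by -phi
        proj = hull_xy @ rot.T
        mins = proj.min(axis=0)
        maxs = proj.max(axis=0)
        w, h = maxs - mins
        area = w * h
        if best is None or area < best[0] - 1e-12:
            best = (area, phi, rot, mins, maxs)
    area, phi, rot, mins, maxs = best
    # corners in the rotated frame, then back to (x, y)
    (x0, y0), (x1, y1) = mins, maxs
    rect = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    corners_xy = rect @ rot
    side_x = x1 - x0  # extent along the edge direction
    side_y = y1 - y0
    if side_x >= side_y:
        length, width = side_x, side_y
        angle = np.degrees(phi)
    else:
        length, width = side_y, side_x
        angle = np.degrees(phi) + 90.0
    center_xy = corners_xy.mean(axis=0)
    return RotatedBBox(
        center=(float(center_xy[1]), float(center_xy[0])),
        length=float(length),
        width=float(width),
        angle_deg=_reduce_angle(angle),
        corners=corners_xy[:, ::-1].copy(),
    )


def _reduce_angle(angle_deg: float) -> float:
    a = float(angle_deg) % 180.0
    if a >= 180.0 - 1e-12 or a < 0:
        a = 0.0
    return a


def extract_2d_features(mask: InstanceMask, ppm: float = 1.0) -> FeatureRecord:
    """Extract the 2D feature set from a mask.

    ``area`` is the foreground pixel count divided by ``ppm**2``;
    ``dorsal_length`` / ``abdominal_width`` are the rotated rectangle's
    long/short side divided by ``ppm``.  Centroid and box-corner
    coordinates are reported in raw pixels regardless of ``ppm``.

    Raises
    ------
    ValueError
        If ``ppm <= 0``.
    EmptyMaskError
        If the mask has no foreground pixel.
    """
    if ppm <= 0:
        raise ValueError(f"ppm must be > 0, got {ppm}")
    rect = fit_min_rotated_rect(mask)
    cr, cc = mask_centroid(mask)
    tl = rect.topleft
    br = rect.bottomright
    return FeatureRecord(
        dorsal_length=rect.length / ppm,
        abdominal_width=rect.width / ppm,
        area=mask.area_px / ppm**2,
        centroid_x=cr,
        centroid_y=cc,
        bbox_topleft_x=tl[0],
        bbox_topleft_y=tl[1],
        bbox_bottomright_x=br[0],
        bbox_bottomright_y=br[1],
        bbox_rotatedangle=rect.angle_deg,
        label=mask.label,
        score=mask.score,
    )


def features_to_frame(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Assemble feature records into a table, one row per instance.

    3D columns appear only when at least one record carries 3D fields;
    records lacking them get NaN there.
    """
    any_3d = any(r.has_3d for r in records)
    cols = ["instance_id", "label", "score"] + FEATURE_COLUMNS_2D
    if any_3d:
        cols = cols + FEATURE_COLUMNS_3D
    rows = []
    for i, r in enumerate(records):
        row = {
            "instance_id": i,
            "label": r.label,
            "score": r.score,
            "Dorsal length": r.dorsal_length,
            "Abdominal width": r.abdominal_width,
            "Area": r.area,
            "bbox_topleft_x": r.bbox_topleft_x,
            "bbox_topleft_y": r.bbox_topleft_y,
            "bbox_bottomright_x": r.bbox_bottomright_x,
            "bbox_bottomright_y": r.bbox_bottomright_y,
            "bbox_rotatedangle": r.bbox_rotatedangle,
            "Centroid_x": r.centroid_x,
            "Centroid_y": r.centroid_y,
        }
        if any_3d:
            row["Height_average"] = np.nan if r.height_average is None else r.height_average
            row["Height_centroid"] = np.nan if r.height_centroid is None else r.height_centroid
            row["Volume"] = np.nan if r.volume is None else r.volume
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_feature_csv(records: Sequence[FeatureRecord], path, ppm: float = 1.0) -> None:
    """Write the feature table as CSV.

    A leading ``# ppm=<value>`` comment line records the calibration used
    so unit conversions remain auditable downstream.  An empty record
    list still produces the header (2D columns only).
    """
    frame = features_to_frame(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# ppm={ppm:g}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def with_3d(record: FeatureRecord, height_average: float,
            height_centroid: float, volume: float) -> FeatureRecord:
    """Return a copy of ``record`` with the 3D fields filled in."""
    return dataclasses.replace(
        record,
        height_average=height_average,
        height_centroid=height_centroid,
        volume=volume,
    )
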