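"""Depth-map cleaning pipeline and 3D morphological features.

A downward-looking depth camera records, per pixel, the distance from the
camera to the first surface below it (meters); zeros mark missing
readings (sensor dropout).  The pipeline turns a raw depth grid plus a
binary animal mask into a clean per-pixel height field and from it the
3D features: average height, height at the centroid, and volume.

Pipeline order (fixed): Hadamard masking -> zero fill -> Gaussian
smoothing -> feature extraction.  Heights are ``camera_to_ground -
depth``: the camera-to-ground distance is the depth reading over bare
floor, so subtracting the animal-surface depth from it yields elevation
above the floor.  All zeros are filled — both in-ROI dropout and the
masked-out background — with the mean of the nonzero values; features
only ever read ROI pixels, so filling the background affects edge
smoothing and visualization, not the measurements directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np
from scipy import ndimage

from .geometry2d import (
    EmptyMaskError,
    FeatureRecord,
    InstanceMask,
    extract_2d_features,
    mask_centroid,
    with_3d,
)

__all__ = [
    "DepthMap",
    "CalibrationConfig",
    "HeightField",
    "load_depth_csv",
    "write_depth_csv",
    "depth_to_heatmap",
    "apply_mask",
    "fill_missing",
    "gaussian_smooth",
    "to_height_field",
    "extract_3d_features",
    "export_surface_grid",
]

logger = logging.getLogger(__name__)

#: Depth values above this (meters) suggest the file is in millimeters.
_MM_SUSPECT_THRESHOLD = 100.0


class DepthParseError(ValueError):
    """Raised when a depth CSV is malformed (ragged or non-numeric)."""


@dataclass(frozen=True)
class DepthMap:
    """Rectangular grid of camera-to-surface distances in meters.

    Values must be finite and non-negative; exact zeros denote missing
    sensor readings.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError(f"depth map must be a non-empty 2D grid, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("depth map contains non-finite values")
        if (v < 0).any():
            bad = np.argwhere(v < 0)[0]
            raise ValueError(
                f"depth map contains negative value at (row {bad[0]}, col {bad[1]})"
            )
        object.__setattr__(self, "values", v)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CalibrationConfig:
    """Scalars tying pixels and depth readings to metric units.

    ppm
        Pixels per meter; lengths divide by ppm, areas and volumes by
        ppm**2.  Default 1 (features stay in pixel units).
    camera_to_ground
        Depth reading over bare floor, meters.  Default 2.5.
    gaussian_sigma
        Standard deviation of the smoothing filter, pixels; 0 disables
        smoothing exactly.  Default 1.
    """

    ppm: float = 1.0
    camera_to_ground: float = 2.5
    gaussian_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError(f"ppm must be > 0, got {self.ppm}")
        if self.camera_to_ground <= 0:
            raise ValueError(f"camera_to_ground must be > 0, got {self.camera_to_ground}")
        if self.gaussian_sigma < 0:
            raise ValueError(f"gaussian_sigma must be >= 0, got {self.gaussian_sigma}")


@dataclass(frozen=True)
class HeightField:
    """Per-pixel elevation above the floor (meters), defined everywhere.

    ``roi`` marks the animal's pixels; heights outside it come from the
    background fill and carry no physical meaning.
    """

    heights: np.ndarray
    roi: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        r = np.asarray(self.roi, dtype=bool)
        if h.shape != r.shape:
            raise ValueError(f"heights shape {h.shape} != roi shape {r.shape}")
        if not np.isfinite(h).all():
            raise ValueError("height field contains non-finite values")
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "roi", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


def load_depth_csv(path) -> DepthMap:
    """Load a comma-separated depth grid.

    An optional single header row is auto-detected (first row entirely
    non-numeric -> skipped).  Ragged rows and non-numeric cells raise
    :class:`DepthParseError` naming the offending location.  Values that
    look millimeter-scale trigger a warning suggesting unit conversion.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise DepthParseError(f"{path}: empty depth file")

    def parse_row(line: str) -> list[float] | None:
        try:
            return [float(tok) for tok in line.split(",")]
        except ValueError:
            return None

    start = 0
    if parse_row(lines[0]) is None:
        start = 1  # header row
        if len(lines) == 1:
            raise DepthParseError(f"{path}: header row but no data")
    rows: list[list[float]] = []
    ncols = None
    for i, line in enumerate(lines[start:], start=start):
        toks = line.split(",")
        if ncols is None:
            ncols = len(toks)
        elif len(toks) != ncols:
            raise DepthParseError(
                f"{path}: ragged rows — row {i} has {len(toks)} cells, expected {ncols}"
            )
        row = []
        for j, tok in enumerate(toks):
            try:
                row.append(float(tok))
            except ValueError:
                raise DepthParseError(
                    f"{path}: non-numeric cell {tok!r} at (row {i}, col {j})"
                ) from None
        rows.append(row)
    depth = DepthMap(np.array(rows, dtype=float))
    if depth.values.max() > _MM_SUSPECT_THRESHOLD:
        logger.warning(
            "%s: max depth %.1f looks millimeter-scale; values are interpreted "
            "as meters — divide by 1000 (CLI: --mm) if the sensor emits mm",
            path, depth.values.max(),
        )
    return depth


def write_depth_csv(depth: DepthMap, path, header: bool = False) -> None:
    """Write a depth grid as plain CSV (optional column-index header)."""
    _write_grid(depth.values, path, header=header)


def _write_grid(values: np.ndarray, path, header: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write(",".join(f"c{j}" for j in range(values.shape[1])) + "\n")
        np.savetxt(fh, values, fmt="%.12g", delimiter=",")


def depth_to_heatmap(depth: DepthMap, colormap_name: str = "viridis") -> np.ndarray:
    """Render the depth grid as an 8-bit RGB heatmap.

    Per-image min-max normalization to [0, 1] followed by colormap
    lookup; a constant grid maps uniformly to the colormap's low end.
    Returns an ``(rows, cols, 3)`` uint8 array.
    """
    try:
        cmap = matplotlib.colormaps[colormap_name]
    except KeyError:
        available = ", ".join(sorted(matplotlib.colormaps)[:20])
        raise ValueError(
            f"unknown colormap {colormap_name!r}; available include: {available}, ..."
        ) from None
    v = depth.values
    lo, hi = v.min(), v.max()
    norm = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    rgba = cmap(norm)
    return (rgba[..., :3] * 255).round().astype(np.uint8)


def _check_same_shape(a_shape, b_shape, what: str) -> None:
    if a_shape != b_shape:
        raise ValueError(f"shape mismatch: {what} {a_shape} vs {b_shape}")


def apply_mask(depth: DepthMap, mask: InstanceMask) -> DepthMap:
    """Hadamard product of depth grid and binary mask.

    Background pixels become exactly 0 (i.e. "missing", to be filled);
    ROI pixels pass through bit-identical.
    """
    _check_same_shape(depth.shape, mask.shape, "depth vs mask")
    return DepthMap(depth.values * mask.pixels)


def fill_missing(depth: DepthMap) -> DepthMap:
    """Replace every zero with the mean of the nonzero values.

    Nonzero entries are untouched; the output contains no zeros.  An
    all-zero grid raises (no data to infer a fill value from).
    """
    v = depth.values
    nz = v != 0
    if not nz.any():
        raise ValueError("cannot fill an all-zero depth grid: no nonzero data")
    if nz.all():
        return DepthMap(v.copy())
    fill = v[nz].mean()
    out = v.copy()
    out[~nz] = fill
    return DepthMap(out)


def gaussian_smooth(depth: DepthMap, sigma: float) -> DepthMap:
    """2D Gaussian filter with reflect boundary handling.

    ``sigma=0`` is an exact identity; constant grids are fixed points for
    any sigma (reflect boundaries preserve the DC level).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return DepthMap(depth.values.copy())
    sm = ndimage.gaussian_filter(depth.values, sigma=sigma, mode="reflect")
    # float round-off can nick tiny negatives onto a non-negative grid
    return DepthMap(np.clip(sm, 0.0, None))


def to_height_field(depth: DepthMap, config: CalibrationConfig,
                    roi: InstanceMask) -> HeightField:
    """Run the cleaning pipeline and convert depth to height.

    Steps, in order: mask (Hadamard), fill zeros with the nonzero mean,
    Gaussian-smooth with ``config.gaussian_sigma``, then
    ``height = camera_to_ground - depth`` elementwise.
    """
    _check_same_shape(depth.shape, roi.shape, "depth vs roi")
    masked = apply_mask(depth, roi)
    filled = fill_missing(masked)
    smoothed = gaussian_smooth(filled, config.gaussian_sigma)
    heights = config.camera_to_ground - smoothed.values
    return HeightField(heights=heights, roi=roi.pixels,
                       smoothed=config.gaussian_sigma > 0)


def _centroid_pixel(mask: InstanceMask) -> tuple[int, int]:
    # nearest integer pixel; exact .5 rounds down toward the smaller index
    cr, cc = mask_centroid(mask)
    r = int(np.ceil(cr - 0.5))
    c = int(np.ceil(cc - 0.5))
    r = min(max(r, 0), mask.shape[0] - 1)
    c = min(max(c, 0), mask.shape[1] - 1)
    return r, c


def extract_3d_features(field: HeightField, mask: InstanceMask,
                        config: CalibrationConfig) -> FeatureRecord:
    """Extract the full feature set: 2D features plus heights and volume.

    ``height_average`` is the mean height over ROI pixels (meters, PPM
    free); ``height_centroid`` samples the height at the pixel nearest
    the mask centroid; ``volume`` is the sum of ROI heights divided by
    ppm**2 (at ppm=1 it is literally the sum of heights, in px^2*m).
    """
    _check_same_shape(field.shape, mask.shape, "height field vs mask")
    if mask.is_empty():
        raise EmptyMaskError("mask contains no segmented object (no foreground pixels)")
    rec = extract_2d_features(mask, ppm=config.ppm)
    roi_heights = field.heights[mask.pixels]
    r, c = _centroid_pixel(mask)
    return with_3d(
        rec,
        height_average=float(roi_heights.mean()),
        height_centroid=float(field.heights[r, c]),
        volume=float(roi_heights.sum()) / config.ppm**2,
    )


def export_surface_grid(field: HeightField, path, header: bool = False) -> None:
    """Write the cleaned height grid as a CSV loadable by any plotter.

    Round-trips losslessly to well below 1e-9 (values are written with 12
    significant digits against grids whose magnitudes are a few meters).
    """
    _write_grid(field.heights, path, header=header)


def load_surface_grid(path) -> np.ndarray:
    """Re-load a height grid written by :func:`export_surface_grid`."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        try:
            [float(t) for t in first.strip().split(",")]
            skip = 0
        except ValueError:
            skip = 1
    return np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
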