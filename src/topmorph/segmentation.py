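"""Mask providers: external label images and a classical depth segmenter.

The feature pipeline is agnostic about where masks come from.  Two
providers are built in:

* :func:`load_label_mask` ingests an integer-labelled image produced by
  any external instance segmenter (label ``k`` -> instance ``k``,
  0 = background).
* :func:`segment_classical` segments a depth scene directly by
  thresholding height above the floor and labelling connected
  components — no trained model needed, so the whole tool runs
  self-contained.

The classical segmenter's confidence score is a heuristic (the fraction
of a component's pixels well above the threshold), NOT a calibrated
probability; it exists so downstream ranking and evaluation code has a
score to sort by.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .depth3d import CalibrationConfig, DepthMap
from .geometry2d import InstanceMask

__all__ = [
    "SegmentationResult",
    "load_label_mask",
    "save_label_mask",
    "segment_classical",
    "sort_instances",
]

logger = logging.getLogger(__name__)

# 8-connectivity: thin diagonal limbs of an animal silhouette stay connected
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationResult:
    """Ordered set of detected instances for one scene.

    Instances are sorted by score descending (ties: larger area, then
    smaller first-pixel index) and are pairwise disjoint.
    """

    instances: tuple[InstanceMask, ...]
    source: str = "file"

    def __post_init__(self) -> None:
        inst = tuple(self.instances)
        scores = [m.score for m in inst]
        if scores != sorted(scores, reverse=True):
            raise ValueError("instances must be sorted by score descending")
        if inst:
            total = np.zeros(inst[0].shape, dtype=int)
            for m in inst:
                total += m.pixels
            if (total > 1).any():
                raise ValueError("instance pixel sets must be pairwise disjoint")
        object.__setattr__(self, "instances", inst)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def best(self) -> InstanceMask:
        """Highest-score instance (first after sorting)."""
        if not self.instances:
            raise ValueError("empty segmentation result")
        return self.instances[0]


def _first_pixel_index(mask: InstanceMask) -> int:
    return int(np.flatnonzero(mask.pixels.ravel())[0])


def sort_instances(instances: Sequence[InstanceMask]) -> tuple[InstanceMask, ...]:
    """Deterministic ordering: score desc, area desc, first pixel asc."""
    return tuple(
        sorted(
            instances,
            key=lambda m: (-m.score, -m.area_px, _first_pixel_index(m)),
        )
    )


def load_label_mask(path) -> SegmentationResult:
    """Load an integer-labelled instance image (0 = background).

    Each nonzero label becomes one instance with score fixed at 1.0 and
    label text equal to the numeric label.  An image with no nonzero
    label yields an empty result with a logged warning.
    """
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        # color-coded label images are ambiguous; accept only single channel
        raise ValueError(
            f"{path}: expected a single-channel integer label image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label image must be integer-typed, got {arr.dtype}")
    labels = np.unique(arr)
    labels = labels[labels != 0]
    if labels.size == 0:
        logger.warning("%s: label image contains no nonzero labels", path)
        return SegmentationResult(instances=(), source="file")
    instances = [
        InstanceMask(pixels=arr == k, label=str(int(k)), score=1.0) for k in labels
    ]
    return SegmentationResult(instances=sort_instances(instances), source="file")


def save_label_mask(result: SegmentationResult, path) -> None:
    """Write instances as an integer label image (instance i -> label i+1).

    Uses 8-bit PNG when possible, 16-bit ("I;16") beyond 255 instances.
    """
    if not result.instances:
        raise ValueError("cannot save an empty segmentation result")
    shape = result.instances[0].shape
    n = len(result.instances)
    labels = np.zeros(shape, dtype=np.uint16 if n > 255 else np.uint8)
    for i, m in enumerate(result.instances):
        labels[m.pixels] = i + 1
    if labels.dtype == np.uint16:
        Image.fromarray(labels, mode="I;16").save(path)
    else:
        Image.fromarray(labels, mode="L").save(path)


def segment_classical(depth: DepthMap, config: CalibrationConfig,
                      min_height: float = 0.1,
                      min_area_px: int = 50) -> SegmentationResult:
    """Segment animals from a raw depth scene by height thresholding.

    Pixels whose height above the floor (``camera_to_ground - depth``)
    exceeds ``min_height`` are foreground; 8-connected components smaller
    than ``min_area_px`` pixels are dropped (this also absorbs isolated
    dropout pixels, whose zero depth reads as spuriously tall).  Each
    surviving component scores the fraction of its pixels exceeding
    ``2 * min_height``, clamped to [0.05, 1].

    An empty result is valid (e.g. a bare-floor scene).
    """
    if min_height <= 0:
        raise ValueError(f"min_height must be > 0, got {min_height}")
    if min_area_px < 1:
        raise ValueError(f"min_area_px must be >= 1, got {min_area_px}")
    heights = config.camera_to_ground - depth.values
    fg = heights > min_height
    labelled, n = ndimage.label(fg, structure=_STRUCT_8)
    instances = []
    for k in range(1, n + 1):
        comp = labelled == k
        area = int(comp.sum())
        if area < min_area_px:
            continue
        tall = float((heights[comp] > 2.0 * min_height).sum()) / area
        score = float(np.clip(tall, 0.05, 1.0))
        instances.append(InstanceMask(pixels=comp, label=str(len(instances) + 1),
                                      score=score))
    return SegmentationResult(instances=sort_instances(instances),
                              source="classical")
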