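"""Embryo localisation and mean-brightness extraction.

One bounding box is computed per clip from the temporal-median frame
(the embryo is capsule-confined at this magnification, so per-frame
tracking would only inject box jitter into the measured signal), and
each frame is then reduced to the arithmetic mean of the pixels inside
that box.
"""
from __future__ import annotations

import logging

import numpy as np
from skimage.filters import threshold_mean, threshold_otsu, threshold_triangle
from skimage.measure import label, regionprops

from .containers import BoundingBox, BrightnessTrace, ClipStack

logger = logging.getLogger(__name__)

__all__ = ["NoEmbryoError", "detect_bbox", "extract_trace", "clip_to_trace"]

_THRESHOLDS = {
    "otsu": threshold_otsu,
    "mean": threshold_mean,
    "triangle": threshold_triangle,
}


class NoEmbryoError(RuntimeError):
    """Raised when no foreground object is found in a clip."""


def detect_bbox(stack: ClipStack, threshold_method: str = "otsu", margin: int = 0) -> BoundingBox:
    """Locate the embryo in a clip and return one box for the whole clip.

    The temporal-median frame is thresholded globally (bright object on a
    dark field), the largest connected foreground component is taken, and
    its bounding box is inflated by ``margin`` pixels per side and clamped
    to the frame.

    Raises
    ------
    NoEmbryoError
        If the median frame is flat or thresholding leaves no foreground.
    """
    if threshold_method not in _THRESHOLDS:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    median = np.median(stack.frames.astype(float), axis=0)
    if np.ptp(median) == 0:
        raise NoEmbryoError(f"clip {stack.embryo_id}@{stack.clip_time}h: flat median frame")
    mask = median > _THRESHOLDS[threshold_method](median)
    if not mask.any():
        raise NoEmbryoError(f"clip {stack.embryo_id}@{stack.clip_time}h: no foreground")
    regions = regionprops(label(mask))
    biggest = max(regions, key=lambda r: r.area)
    minr, minc, maxr, maxc = biggest.bbox  # half-open, matching our convention
    height, width = stack.frame_shape
    return BoundingBox(
        max(minr - margin, 0),
        max(minc - margin, 0),
        min(maxr + margin, height),
        min(maxc + margin, width),
    )


def extract_trace(stack: ClipStack, box: BoundingBox) -> BrightnessTrace:
    """Mean pixel value per frame across the entire area of the box."""
    height, width = stack.frame_shape
    if box.row_max > height or box.col_max > width:
        raise ValueError("box does not fit inside the frame")
    rows, cols = box.slices
    values = stack.frames[:, rows, cols].astype(float).mean(axis=(1, 2))
    return BrightnessTrace(values, fps=stack.fps, clip_time=stack.clip_time, embryo_id=stack.embryo_id)


def clip_to_trace(stack: ClipStack, threshold_method: str = "otsu", margin: int = 0) -> BrightnessTrace:
    """Detect the embryo and extract its brightness trace in one step."""
    return extract_trace(stack, detect_bbox(stack, threshold_method, margin))
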