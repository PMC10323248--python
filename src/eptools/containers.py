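"""Lightweight containers shared across the pipeline.

All pixel coordinates are 0-based and half-open on the max edges, so a
:class:`BoundingBox` behaves exactly like a pair of numpy slices.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BrightnessTrace", "ClipStack", "BoundingBox"]


@dataclass
class BrightnessTrace:
    """Mean pixel value per frame for one clip.

    Parameters
    ----------
    values : array of float
        One mean grey level per frame.
    fps : float
        Sampling rate of the clip in frames per second.
    clip_time : float
        Acquisition time of the clip, hours post-4-cell.
    embryo_id : str
        Identifier of the embryo the clip belongs to.
    """

    values: np.ndarray
    fps: float
    clip_time: float = 0.0
    embryo_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.n_frames / self.fps


@dataclass
class ClipStack:
    """One grayscale frame stack (a single clip of one embryo)."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float
    clip_time: float = 0.0
    embryo_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.size == 0:
            raise ValueError("frames must be a non-empty (n, H, W) array")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based, half-open on the max edges."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("box indices must be non-negative")
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("box must have positive area")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    def inflate(self, margin: int) -> "BoundingBox":
        """Grow the box by ``margin`` pixels on every side (no clamping)."""
        if margin < 0:
            raise ValueError("margin must be non-negative")
        return BoundingBox(
            self.row_min - margin,
            self.col_min - margin,
            self.row_max + margin,
            self.col_max + margin,
        )

    def clamp(self, height: int, width: int) -> "BoundingBox":
        return BoundingBox(
            max(self.row_min, 0),
            max(self.col_min, 0),
            min(self.row_max, height),
            min(self.col_max, width),
        )

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.row_min <= other.row_min
            and self.col_min <= other.col_min
            and self.row_max >= other.row_max
            and self.col_max >= other.col_max
        )

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union with another box."""
        r0 = max(self.row_min, other.row_min)
        c0 = max(self.col_min, other.col_min)
        r1 = min(self.row_max, other.row_max)
        c1 = min(self.col_max, other.col_max)
        inter = max(r1 - r0, 0) * max(c1 - c0, 0)
        union = self.area + other.area - inter
        return inter / union if union else 0.0
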