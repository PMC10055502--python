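"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package: frame indices and pixel
coordinates are 0-based, intervals are half-open ``[start, end)``, times are
in seconds, lengths in micrometres (µm).  Frame rate (``fps``) and pixel
size are always explicit metadata — the recording hardware does not embed
them reliably, so they are never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VideoStack", "MaskStack", "DiameterTrace", "ROI"]


@dataclass
class VideoStack:
    """A grayscale video: T x H x W float frames in [0, 1] plus metadata."""

    frames: np.ndarray
    fps: float
    pixel_size: float  # µm per pixel
    source_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W stack with T >= 1")
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class MaskStack:
    """Per-frame binary heart-wall labels, same T x H x W shape as the video."""

    masks: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.masks)
        if m.ndim != 3 or m.shape[0] < 1:
            raise ValueError("masks must be a T x H x W stack with T >= 1")
        if m.dtype != bool:
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValueError("mask stack must be binary (0/1 or 0/255)")
            m = m > 0
        self.masks = m

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self):
        return self.masks.shape


@dataclass
class DiameterTrace:
    """Time-resolved mean lumen diameter (µm), the pipeline's central signal.

    ``valid`` flags frames whose diameter was measured directly; invalid
    frames carry linearly interpolated values so the time base stays regular.
    """

    diameter_um: np.ndarray
    fps: float
    valid: np.ndarray = None
    area_um2: np.ndarray = None

    def __post_init__(self):
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.diameter_um.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.area_um2 is not None:
            self.area_um2 = np.asarray(self.area_um2, dtype=float)
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        if self.valid.shape != self.diameter_um.shape:
            raise ValueError("valid flags must match trace length")
        if np.any(self.diameter_um[self.valid] < 0):
            raise ValueError("diameters must be non-negative where valid")

    @property
    def n_frames(self) -> int:
        return self.diameter_um.size

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class ROI:
    """Half-open column range [column_start, column_end) of the heart tube."""

    column_start: int
    column_end: int

    def __post_init__(self):
        if not (0 <= self.column_start < self.column_end):
            raise ValueError("ROI requires 0 <= column_start < column_end")

    @property
    def width_px(self) -> int:
        return self.column_end - self.column_start

    def length_um(self, pixel_size: float) -> float:
        return self.width_px * pixel_size

    def validate(self, frame_width: int) -> None:
        if self.column_end > frame_width:
            raise ValueError(
                f"ROI ends at column {self.column_end} but frame width is {frame_width}"
            )
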