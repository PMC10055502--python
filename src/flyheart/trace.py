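"""Diameter/area time series and M-mode images from heart-wall masks.

The diameter convention is the inner-edge-to-inner-edge lumen gap: in each
pixel column the topmost and bottommost foreground runs define the walls
and the diameter is the number of rows strictly between them.  This is the
lumen diameter that the fractional-shortening and stroke-volume formulas
assume.  An ``outer_span`` switch measures outer edge to outer edge instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ROI, DiameterTrace, MaskStack, VideoStack

__all__ = ["column_diameter", "extract_diameter_trace", "build_mmode",
           "MModeImage", "trace_to_frame"]


def _column_geometry(masks: np.ndarray):
    """Vectorised wall-run geometry for a (T, H, C) boolean column stack.

    Returns (diameter_px, valid) arrays of shape (T, C).  A column is valid
    only when it contains at least two separate foreground runs; the
    topmost and bottommost runs define the walls.
    """
    t, h, c = masks.shape
    rows = np.arange(h)[None, :, None]
    any_fg = masks.any(axis=1)
    first = masks.argmax(axis=1)                       # first foreground row
    last = h - 1 - masks[:, ::-1, :].argmax(axis=1)    # last foreground row

    # Last row of the topmost run: first background row after `first`, minus 1.
    gap_after = (~masks) & (rows > first[:, None, :])
    has_gap = gap_after.any(axis=1)
    top_end = np.where(has_gap, gap_after.argmax(axis=1) - 1, last)

    # First row of the bottommost run: last background row before `last`, plus 1.
    gap_before = (~masks) & (rows < last[:, None, :])
    rev = gap_before[:, ::-1, :]
    bot_start = np.where(rev.any(axis=1), h - 1 - rev.argmax(axis=1) + 1, first)

    inner = bot_start - top_end - 1
    outer = last - first + 1
    valid = any_fg & (inner >= 1)
    return inner, outer, valid


def column_diameter(mask_frame: np.ndarray, column: int, outer_span=False):
    """Lumen diameter (px) of one column of one mask frame, or None.

    Columns with fewer than two foreground runs (empty, or walls merged at
    full contraction) are invalid and return None.
    """
    mask_frame = np.asarray(mask_frame) > 0
    if not (0 <= column < mask_frame.shape[1]):
        raise ValueError(f"column {column} outside frame of width {mask_frame.shape[1]}")
    col = mask_frame[None, :, column:column + 1]
    inner, outer, valid = _column_geometry(col)
    if not valid[0, 0]:
        return None
    return int(outer[0, 0]) if outer_span else int(inner[0, 0])


def extract_diameter_trace(masks: MaskStack, roi: ROI, pixel_size: float,
                           fps: float, min_valid_fraction: float = 0.25,
                           outer_span: bool = False) -> DiameterTrace:
    """Per-frame mean lumen diameter (µm) over the ROI columns.

    A frame is flagged invalid when fewer than ``min_valid_fraction`` of ROI
    columns have a measurable diameter; invalid frames are filled by linear
    interpolation from valid neighbours (flags preserved).  The per-frame
    area is the lumen pixel count between the walls, in µm².
    """
    if isinstance(masks, np.ndarray):
        masks = MaskStack(masks)
    roi.validate(masks.shape[2])
    stack = masks.masks[:, :, roi.column_start:roi.column_end]
    inner, outer, valid = _column_geometry(stack)
    d_px = np.asarray(outer if outer_span else inner, dtype=float)

    n_valid = valid.sum(axis=1)
    frame_valid = n_valid >= max(1, int(np.ceil(min_valid_fraction * roi.width_px)))
    if not frame_valid.any():
        raise ValueError("no frame has enough valid columns to measure a diameter")

    with np.errstate(invalid="ignore"):
        mean_px = np.where(valid, d_px, 0.0).sum(axis=1) / np.maximum(n_valid, 1)
    diam = mean_px * pixel_size
    area = np.where(valid, np.maximum(inner, 0), 0).sum(axis=1) * pixel_size ** 2

    idx = np.arange(masks.n_frames)
    diam = np.interp(idx, idx[frame_valid], diam[frame_valid])
    area = np.interp(idx, idx[frame_valid], area[frame_valid])
    return DiameterTrace(diam, fps=fps, valid=frame_valid, area_um2=area)


@dataclass
class MModeImage:
    """Space-time strip at one pixel column with DI boundary annotations."""

    strip: np.ndarray          # H x T intensities
    mask_strip: np.ndarray     # H x T booleans
    column: int
    fps: float
    di_start_times_s: np.ndarray  # annotated green in plots
    di_end_times_s: np.ndarray    # annotated red in plots

    @property
    def n_frames(self) -> int:
        return self.strip.shape[1]


def build_mmode(video: VideoStack, masks: MaskStack | None, column: int,
                beat_table: pd.DataFrame | None = None) -> MModeImage:
    """Stack one pixel column across all frames into an H x T strip.

    DI start and DI end times are taken from ``beat_table`` (may be empty or
    None for an unannotated strip).
    """
    if not (0 <= column < video.shape[2]):
        raise ValueError(f"column {column} outside frame of width {video.shape[2]}")
    strip = np.asarray(video.frames[:, :, column]).T.copy()
    if masks is not None:
        mask_strip = np.asarray(masks.masks[:, :, column]).T.copy()
    else:
        mask_strip = np.zeros_like(strip, dtype=bool)
    if beat_table is None or len(beat_table) == 0:
        starts = np.empty(0)
        ends = np.empty(0)
    else:
        starts = beat_table["di_start_s"].to_numpy(dtype=float)
        ends = beat_table["di_end_s"].to_numpy(dtype=float)
    return MModeImage(strip=strip, mask_strip=mask_strip, column=column,
                      fps=video.fps, di_start_times_s=starts, di_end_times_s=ends)


def trace_to_frame(trace: DiameterTrace) -> pd.DataFrame:
    """Tabulate a trace for CSV export (0-based frames, seconds, µm)."""
    df = pd.DataFrame({
        "frame": np.arange(trace.n_frames),
        "time_s": trace.times_s,
        "diameter_um": trace.diameter_um,
        "valid": trace.valid.astype(int),
    })
    df["area_um2"] = trace.area_um2 if trace.area_um2 is not None else np.nan
    return df[["frame", "time_s", "diameter_um", "area_um2", "valid"]]
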