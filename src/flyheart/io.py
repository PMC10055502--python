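"""Readers/writers and the run manifest.

Videos and masks are exchanged as multi-page TIFF (8-bit grayscale; masks
0/255).  Frame rate and pixel size are mandatory metadata: they come from a
``<video>.yaml`` sidecar or explicit arguments, never from guesses, because
recording hardware does not embed them reliably.  All exported files use
0-based frame indices, half-open intervals, seconds and micrometres.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import MaskStack, VideoStack

__all__ = [
    "read_video", "write_video", "read_masks", "write_masks",
    "export_results", "write_manifest", "read_sidecar",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_sidecar(path) -> dict:
    """Read the ``<video>.yaml`` metadata sidecar if present."""
    sidecar = Path(str(path) + ".yaml")
    if not sidecar.exists():
        sidecar = Path(path).with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def read_video(path, fps: float | None = None, pixel_size: float | None = None
               ) -> VideoStack:
    """Read a multi-page TIFF or AVI as a normalised grayscale stack.

    Frames are scaled to [0, 1] by the dtype range; RGB input is converted
    to luminance with a warning.  Missing fps or pixel_size (not given and
    not in a sidecar) is a hard failure.
    """
    path = Path(path)
    meta = read_sidecar(path)
    fps = fps if fps is not None else meta.get("fps")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    if fps is None:
        raise ValueError(f"{path}: fps not provided and no sidecar metadata found")
    if pixel_size is None:
        raise ValueError(f"{path}: pixel_size not provided and no sidecar metadata")

    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        frames = iio.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32) / np.iinfo(frames.dtype).max
    else:
        frames = frames.astype(np.float32)
        if frames.max() > 1.0:
            frames = frames / frames.max()
    if frames.ndim == 4:  # T x H x W x C colour input
        warnings.warn(f"{path.name}: RGB video converted to grayscale by luminance")
        frames = (frames.astype(np.float64) @ _LUMA[: frames.shape[-1]]
                  ).astype(np.float32)
    return VideoStack(frames, fps=float(fps), pixel_size=float(pixel_size),
                      source_id=path.stem)


def write_video(video: VideoStack, path, write_sidecar: bool = True):
    """Write an 8-bit grayscale multi-page TIFF plus a metadata sidecar."""
    data = np.clip(np.asarray(video.frames, dtype=float), 0, 1)
    tifffile.imwrite(path, np.rint(data * 255).astype(np.uint8),
                     photometric="minisblack")
    if write_sidecar:
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump({"fps": float(video.fps),
                            "pixel_size": float(video.pixel_size),
                            "source_id": video.source_id}, fh)


def read_masks(path, video: VideoStack | None = None) -> MaskStack:
    """Read a binary (0/255 or 0/1) multi-page TIFF mask stack."""
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if data.size == 0 or data.shape[0] < 1:
        raise ValueError(f"{path}: empty mask stack")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1, 255))):
        raise ValueError(f"{path}: mask stack is not binary (values {vals[:5]}...)")
    masks = MaskStack(data > 0)
    if video is not None and masks.shape != video.shape:
        raise ValueError(
            f"{path}: mask shape {masks.shape} does not match video {video.shape}")
    return masks


def write_masks(masks: MaskStack, path):
    if masks.n_frames < 1:
        raise ValueError("refusing to write an empty mask stack")
    tifffile.imwrite(path, (masks.masks.astype(np.uint8)) * 255,
                     photometric="minisblack")


def export_results(beats: pd.DataFrame, summary, events, path_prefix,
                   manifest: dict | None = None):
    """Write beats.csv, summary.csv, events.csv and a run manifest.

    Deterministic: re-running with the same inputs produces byte-identical
    files.  ``events.csv`` holds one row per tachycardic/bradycardic event.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    beats.to_csv(f"{prefix}_beats.csv", index=False, float_format="%.6f")

    summary_dict = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
    pd.DataFrame([summary_dict]).to_csv(f"{prefix}_summary.csv", index=False,
                                        float_format="%.6f")
    rows = [{"type": "tachycardic", "beat_index": int(r.beat_index),
             "length_s": float(r.si_s)} for r in events.tachycardic.itertuples()]
    rows += [{"type": "bradycardic", "beat_index": int(r.beat_index),
              "length_s": float(r.di_s)} for r in events.bradycardic.itertuples()]
    pd.DataFrame(rows, columns=["type", "beat_index", "length_s"]).to_csv(
        f"{prefix}_events.csv", index=False, float_format="%.6f")
    if manifest is not None:
        write_manifest(manifest, f"{prefix}_manifest.json")


def write_manifest(manifest: dict, path):
    """Record config, seeds and software version so a run can be replayed."""
    from . import __version__

    payload = {"flyheart_version": __version__}
    for key, value in manifest.items():
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            value = dataclasses.asdict(value)
        payload[key] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
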