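"""Attention U-Net heart-wall segmentation on temporal composites.

Each frame ``t`` is presented to the network as a three-channel composite of
frames ``(t - 4, t, t + 4)`` so the model can use wall motion, not just
appearance, to separate heart walls from static clutter.  The network is a
2-D U-Net with five encoder depths (8, 16, 32, 64, 128 filters by default),
additive attention gates on the skip connections, a rectangular kernel
elongated along the tube axis, and a single-channel sigmoid output trained
with Dice loss and Adam.  Training samples are balanced across lumen
diameter bins so rare fully-contracted frames are not swamped by diastole.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .core import ROI, MaskStack, VideoStack
from .nn import autograd as ag
from .trace import extract_diameter_trace

__all__ = [
    "SegmenterConfig", "TemporalComposite", "ProbabilityStack",
    "make_temporal_composite", "composite_indices", "sample_training_frames",
    "augment_sample", "dice_loss", "dice_score", "AttentionUNet",
    "build_segmenter", "train_segmenter", "segment_video",
    "save_segmenter", "load_segmenter", "HeartWallSegmenter",
]


@dataclass(frozen=True)
class SegmenterConfig:
    encoder_filters: tuple = (8, 16, 32, 64, 128)
    kernel_shape: tuple = (3, 5)   # rows x cols, elongated along the tube
    batch_size: int = 16
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    offset: int = 4                # temporal composite offset in frames

    def validate(self):
        f = tuple(self.encoder_filters)
        if len(f) != 5 or any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("encoder_filters must be five strictly increasing counts")
        kh, kw = self.kernel_shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd")
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


@dataclass
class TemporalComposite:
    """Three frames (past, present, future) stacked as channels."""

    channels: np.ndarray  # 3 x H x W
    center_index: int


def composite_indices(n_frames: int, t: int, offset: int = 4):
    """Channel frame indices (t - offset, t, t + offset), clamped to the video."""
    if not (0 <= t < n_frames):
        raise ValueError(f"frame {t} outside video of length {n_frames}")
    return (max(t - offset, 0), t, min(t + offset, n_frames - 1))


def make_temporal_composite(video: VideoStack, t: int, offset: int = 4
                            ) -> TemporalComposite:
    idx = composite_indices(video.n_frames, t, offset)
    channels = np.stack([video.frames[i] for i in idx]).astype(np.float32)
    return TemporalComposite(channels=channels, center_index=t)


def _composite_stack(frames: np.ndarray, offset: int) -> np.ndarray:
    """All composites of a video at once: (T, 3, H, W)."""
    t = frames.shape[0]
    idx = np.arange(t)
    past = np.clip(idx - offset, 0, t - 1)
    future = np.clip(idx + offset, 0, t - 1)
    return np.stack([frames[past], frames[idx], frames[future]],
                    axis=1).astype(np.float32)


def sample_training_frames(videos, masks, per_bin: int = 75,
                           bin_width_px: float = 2.0, seed: int = 0):
    """Diameter-balanced frame sampling for training.

    Frames from all annotated videos are grouped into lumen-diameter bins of
    ``bin_width_px`` (diameters measured from the annotation masks over the
    full frame width); up to ``per_bin`` frames are drawn without
    replacement from each bin.  Returns a sorted list of
    ``(video_index, frame_index)`` pairs, deterministic given ``seed``.
    """
    if per_bin < 1 or bin_width_px <= 0:
        raise ValueError("per_bin and bin_width_px must be positive")
    bins: dict[int, list] = {}
    n_annotated = 0
    for vi, (video, mask) in enumerate(zip(videos, masks)):
        if mask.n_frames != video.n_frames:
            raise ValueError(f"video {vi}: mask stack length mismatch")
        roi = ROI(0, mask.shape[2])
        try:
            trace = extract_diameter_trace(mask, roi, pixel_size=1.0,
                                           fps=video.fps)
        except ValueError:  # no measurable frame in this video
            continue
        for fi in range(mask.n_frames):
            if not trace.valid[fi]:
                continue
            n_annotated += 1
            b = int(trace.diameter_um[fi] // bin_width_px)
            bins.setdefault(b, []).append((vi, fi))
    if n_annotated == 0:
        raise ValueError("no annotated frames with a measurable diameter")
    rng = np.random.default_rng(seed)
    chosen = []
    for b in sorted(bins):
        frames = bins[b]
        if len(frames) <= per_bin:
            chosen.extend(frames)
        else:
            take = rng.choice(len(frames), size=per_bin, replace=False)
            chosen.extend(frames[i] for i in sorted(take))
    return sorted(chosen)


def augment_sample(composite: np.ndarray, mask: np.ndarray, seed=None,
                   enabled: bool = True, brightness: float = 0.1):
    """Random flips (image and mask together) and brightness jitter (image only).

    Identity when ``enabled`` is False; deterministic given ``seed``.
    """
    composite = np.asarray(composite)
    mask = np.asarray(mask)
    if composite.shape[-2:] != mask.shape[-2:]:
        raise ValueError("composite and mask spatial shapes must match")
    if not enabled:
        return composite, mask
    rng = np.random.default_rng(seed)
    comp, msk = composite, mask
    if rng.random() < 0.5:  # horizontal flip
        comp, msk = comp[..., ::-1], msk[..., ::-1]
    if rng.random() < 0.5:  # vertical flip
        comp, msk = comp[..., ::-1, :], msk[..., ::-1, :]
    factor = 1.0 + rng.uniform(-brightness, brightness)
    comp = np.clip(comp * factor, 0.0, 1.0)
    return np.ascontiguousarray(comp), np.ascontiguousarray(msk)


def dice_loss(pred, target, eps: float = 1e-6) -> float:
    """1 − (2 Σ p·t + ε) / (Σ p + Σ t + ε); symmetric and bounded in [0, 1]."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("pred and target shapes must match")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred must lie in [0, 1]")
    inter = float((p * t).sum())
    return 1.0 - (2.0 * inter + eps) / (float(p.sum()) + float(t.sum()) + eps)


def dice_score(pred_mask, target_mask, eps: float = 1e-6) -> float:
    """Dice overlap of two binary masks (1 = perfect)."""
    return 1.0 - dice_loss(np.asarray(pred_mask, float) > 0.5,
                           np.asarray(target_mask, float) > 0.5, eps)


def _dice_loss_t(pred: ag.Tensor, target: np.ndarray, eps: float = 1e-6):
    t = ag.Tensor(np.asarray(target, dtype=np.float32))
    inter = ag.tensor_sum(ag.mul(pred, t))
    denom = ag.tensor_sum(pred) + float(target.sum()) + eps
    return 1.0 - ag.div(2.0 * inter + eps, denom)


class AttentionUNet(nn.Module):
    """Symmetric encoder/decoder U-Net with attention-gated skips.

    Five encoder depths, three input channels (the temporal composite), one
    sigmoid output channel.  Inputs are padded internally to multiples of 16
    and cropped back, so arbitrary frame sizes work.
    """

    def __init__(self, config: SegmenterConfig = SegmenterConfig()):
        config.validate()
        self.config = config
        f = tuple(config.encoder_filters)
        k = tuple(config.kernel_shape)
        rng = np.random.default_rng(config.seed)
        chans = (3,) + f
        self.encoders = [nn.ConvBlock(chans[i], f[i], k, rng) for i in range(5)]
        self.gates = [nn.AttentionGate(f[i], f[i + 1], max(f[i] // 2, 1), rng)
                      for i in range(4)]
        self.decoders = [nn.ConvBlock(f[i] + f[i + 1], f[i], k, rng)
                         for i in range(4)]
        self.head = nn.Conv2d(f[0], 1, (1, 1), rng)

    def forward(self, x) -> ag.Tensor:
        """Composite batch (N, 3, H, W) -> probability Tensor (N, H, W, 1)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("input must be (N, 3, H, W)")
        x = ag.Tensor(np.ascontiguousarray(np.moveaxis(x, 1, -1)))
        _, h, w, _ = x.shape
        ph, pw = (-h) % 16, (-w) % 16
        if ph or pw:
            x = ag.pad2d(x, ph, pw)
        skips = []
        for i, enc in enumerate(self.encoders):
            x = enc(x if i == 0 else ag.maxpool2(x))
            skips.append(x)
        d = skips[-1]
        for i in range(3, -1, -1):
            u = ag.upsample2(d)
            gated = self.gates[i](skips[i], u)
            d = self.decoders[i](ag.concat([u, gated], axis=3))
        out = ag.sigmoid(self.head(d))
        if ph or pw:
            out = ag.crop2d(out, h, w)
        return out

    __call__ = forward


def build_segmenter(config: SegmenterConfig = SegmenterConfig()) -> AttentionUNet:
    """Seeded random initialisation of the attention U-Net."""
    return AttentionUNet(config)


def train_segmenter(model: AttentionUNet, train_samples, val_samples,
                    config: SegmenterConfig):
    """Adam training with Dice loss; returns the best-validation-epoch model.

    ``train_samples``/``val_samples`` are sequences of ``(composite, mask)``
    pairs with composite (3, H, W) and mask (H, W).  The per-epoch history
    has exactly ``config.epochs`` rows; the returned model carries the
    parameters of the epoch with the lowest validation loss.
    """
    config.validate()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("train and validation sets must be non-empty")
    xtr = np.stack([np.asarray(c, dtype=np.float32) for c, _ in train_samples])
    ytr = np.stack([np.asarray(m, dtype=np.float32)[..., None] for _, m in train_samples])
    xva = np.stack([np.asarray(c, dtype=np.float32) for c, _ in val_samples])
    yva = np.stack([np.asarray(m, dtype=np.float32)[..., None] for _, m in val_samples])

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = []
    best = (np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(xtr))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            opt.zero_grad()
            pred = model.forward(xtr[sel])
            loss = _dice_loss_t(pred, ytr[sel])
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            loss.backward()
            opt.step()
            losses.append(value)
        val_loss = _evaluate_dice(model, xva, yva, config.batch_size)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = int(hist["val_loss"].idxmin())
    return model, hist


def _evaluate_dice(model, x, y, batch_size):
    num = den = 0.0
    eps = 1e-6
    for lo in range(0, len(x), batch_size):
        p = model.forward(x[lo:lo + batch_size]).data
        t = y[lo:lo + batch_size]
        num += 2.0 * float((p * t).sum())
        den += float(p.sum()) + float(t.sum())
    return 1.0 - (num + eps) / (den + eps)


def segment_video(model: AttentionUNet, video: VideoStack,
                  threshold: float = 0.5, batch_size: int = 16,
                  offset: int | None = None):
    """Segment every frame of a video via its temporal composite.

    Returns ``(ProbabilityStack, MaskStack)``; the binary mask is
    probability >= threshold, so raising the threshold never grows the mask.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if offset is None:
        offset = model.config.offset
    comps = _composite_stack(np.asarray(video.frames, dtype=np.float32), offset)
    probs = np.empty(video.shape, dtype=np.float32)
    for lo in range(0, video.n_frames, batch_size):
        probs[lo:lo + batch_size] = model.forward(comps[lo:lo + batch_size]).data[..., 0]
    return ProbabilityStack(probs, threshold), MaskStack(probs >= threshold)


@dataclass
class ProbabilityStack:
    """Per-frame, per-pixel heart-wall probability in [0, 1]."""

    probs: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        p = np.asarray(self.probs)
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = p

    def to_masks(self, threshold: float | None = None) -> MaskStack:
        thr = self.threshold if threshold is None else threshold
        return MaskStack(self.probs >= thr)


def save_segmenter(model: AttentionUNet, path):
    """Single-file checkpoint with the config embedded."""
    cfg = model.config
    meta = json.dumps({
        "encoder_filters": list(cfg.encoder_filters),
        "kernel_shape": list(cfg.kernel_shape),
        "batch_size": cfg.batch_size, "epochs": cfg.epochs,
        "learning_rate": cfg.learning_rate, "seed": cfg.seed,
        "offset": cfg.offset,
    })
    with open(path, "wb") as fh:  # keep the exact path (no .npz suffixing)
        np.savez(fh, __config__=np.array(meta), **model.state_dict())


def load_segmenter(path) -> AttentionUNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg = SegmenterConfig(encoder_filters=tuple(meta["encoder_filters"]),
                          kernel_shape=tuple(meta["kernel_shape"]),
                          batch_size=meta["batch_size"], epochs=meta["epochs"],
                          learning_rate=meta["learning_rate"], seed=meta["seed"],
                          offset=meta["offset"])
    model = AttentionUNet(cfg)
    model.load_state_dict(state)
    return model


class HeartWallSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper: fit on annotated videos, predict masks.

    ``fit`` splits the annotated videos into train/validation sets (by video
    when possible, to avoid temporal leakage), draws diameter-balanced
    frames, optionally augments them, and trains the attention U-Net;
    ``predict`` segments a new video at the configured threshold.
    """

    def __init__(self, encoder_filters=(8, 16, 32, 64, 128), kernel_shape=(3, 5),
                 batch_size=16, epochs=30, learning_rate=1e-3, offset=4,
                 per_bin=75, bin_width_px=2.0, augment=True, brightness=0.1,
                 val_fraction=0.15, threshold=0.5, seed=0):
        self.encoder_filters = encoder_filters
        self.kernel_shape = kernel_shape
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.offset = offset
        self.per_bin = per_bin
        self.bin_width_px = bin_width_px
        self.augment = augment
        self.brightness = brightness
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed

    def _config(self) -> SegmenterConfig:
        return SegmenterConfig(encoder_filters=tuple(self.encoder_filters),
                               kernel_shape=tuple(self.kernel_shape),
                               batch_size=self.batch_size, epochs=self.epochs,
                               learning_rate=self.learning_rate, seed=self.seed,
                               offset=self.offset)

    def _gather(self, videos, masks, pairs, augment, rng):
        samples = []
        for vi, fi in pairs:
            comp = make_temporal_composite(videos[vi], fi, self.offset).channels
            msk = masks[vi].masks[fi].astype(np.float32)
            if augment:
                comp, msk = augment_sample(comp, msk,
                                           seed=int(rng.integers(0, 2 ** 31)),
                                           brightness=self.brightness)
            samples.append((comp, msk))
        return samples

    def fit(self, videos, masks):
        if len(videos) == 0 or len(videos) != len(masks):
            raise ValueError("need matching non-empty video and mask lists")
        config = self._config()
        config.validate()
        rng = np.random.default_rng(self.seed)
        n = len(videos)
        if n >= 2:
            n_val = min(max(1, int(round(self.val_fraction * n))), n - 1)
            order = rng.permutation(n)
            val_vids, train_vids = sorted(order[:n_val]), sorted(order[n_val:])
            tr_pairs = sample_training_frames(
                [videos[i] for i in train_vids], [masks[i] for i in train_vids],
                per_bin=self.per_bin, bin_width_px=self.bin_width_px,
                seed=int(rng.integers(0, 2 ** 31)))
            tr_pairs = [(train_vids[vi], fi) for vi, fi in tr_pairs]
            va_pairs = sample_training_frames(
                [videos[i] for i in val_vids], [masks[i] for i in val_vids],
                per_bin=self.per_bin, bin_width_px=self.bin_width_px,
                seed=int(rng.integers(0, 2 ** 31)))
            va_pairs = [(val_vids[vi], fi) for vi, fi in va_pairs]
        else:
            pairs = sample_training_frames(videos, masks, per_bin=self.per_bin,
                                           bin_width_px=self.bin_width_px,
                                           seed=int(rng.integers(0, 2 ** 31)))
            order = rng.permutation(len(pairs))
            n_val = max(1, int(round(self.val_fraction * len(pairs))))
            va_pairs = [pairs[i] for i in sorted(order[:n_val])]
            tr_pairs = [pairs[i] for i in sorted(order[n_val:])]
        train = self._gather(videos, masks, tr_pairs, self.augment, rng)
        val = self._gather(videos, masks, va_pairs, False, rng)
        model = build_segmenter(config)
        self.model_, self.history_ = train_segmenter(model, train, val, config)
        self.best_epoch_ = self.history_.attrs["best_epoch"]
        self.config_ = config
        return self

    def predict_proba(self, video: VideoStack) -> ProbabilityStack:
        probs, _ = segment_video(self.model_, video, threshold=self.threshold,
                                 batch_size=self.batch_size, offset=self.offset)
        return probs

    def predict(self, video: VideoStack) -> MaskStack:
        _, masks = segment_video(self.model_, video, threshold=self.threshold,
                                 batch_size=self.batch_size, offset=self.offset)
        return masks
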