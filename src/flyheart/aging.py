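"""Age-class prediction from cardiac statistics or raw video clips.

Two independent routes:

1. A logistic model on the per-heart summary features DD, SD, FS, DI, SI,
   HP and AI, evaluated with stratified k-fold cross-validation and
   explained with exact linear-model Shapley attributions.
2. A convolutional network on 96 automatically selected frames per video.
   Frames are selected from the sum-of-squared-differences (SSD) motion
   signal against a reference frame: the SSD series is min-max normalised,
   binarised at 0.5, and the centre frame of each run of consecutive equal
   values is kept, so selections alternate near the diameter extremes.  The
   inter-selection durations are fused with the convolutional features
   before the dense head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import nn
from .core import VideoStack
from .nn import autograd as ag

__all__ = [
    "FEATURE_COLUMNS", "assemble_feature_table", "crossval_logistic",
    "linear_shap", "shap_from_pipeline", "select_classifier_frames",
    "ClipFeatures", "CvMetrics", "VideoCnn", "build_video_classifier",
    "VideoAgeClassifier", "crossval_video_classifier", "clips_to_arrays",
]

FEATURE_COLUMNS = ("dd", "sd", "fs", "di", "si", "hp", "ai")
_SUMMARY_FIELDS = ("dd_um", "sd_um", "fs_pct", "di_s", "si_s", "hp_s", "ai")


def assemble_feature_table(summaries, labels) -> pd.DataFrame:
    """Build the classifier feature table from per-heart summaries.

    Columns are fixed in the order DD, SD, FS, DI, SI, HP, AI plus a
    ``label`` column.  Hearts with fewer than two beats (undefined AI) are
    excluded with a warning; fewer than two hearts per class is an error.
    Standardisation is deliberately left to the cross-validation pipeline so
    that only training-fold statistics are ever used.
    """
    rows, kept_labels = [], []
    for summary, label in zip(summaries, labels):
        vals = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
        feats = [vals[f] for f in _SUMMARY_FIELDS]
        if vals.get("n_beats", 0) < 2 or any(not np.isfinite(v) for v in feats):
            warnings.warn("heart excluded: needs >= 2 beats for a defined AI")
            continue
        rows.append(feats)
        kept_labels.append(label)
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    table["label"] = kept_labels
    counts = table["label"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least two hearts per class after exclusions")
    return table


@dataclass
class CvMetrics:
    """Cross-validation results: per-fold and mean accuracy/AUROC, pooled
    confusion matrix, and per-sample class probabilities."""

    fold_accuracy: np.ndarray
    fold_auroc: np.ndarray
    confusion: np.ndarray
    proba: pd.DataFrame  # sample index, label, p_positive, fold

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))


def _encode_labels(labels):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    # "old" is the positive class when present, else the second sorted class.
    positive = "old" if "old" in classes else classes[1]
    return (labels == positive).astype(int), positive


def crossval_logistic(table: pd.DataFrame, k: int = 5, seed: int = 0,
                      C: float = 1.0):
    """Stratified k-fold CV of the logistic age model.

    Each fold fits ``StandardScaler + LogisticRegression`` (L2, strength
    ``C``) on the training fold only.  Returns ``(CvMetrics, pipeline)``
    where the pipeline is refit on the full table for coefficient
    inspection.  Deterministic given ``seed``.
    """
    x = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y, positive = _encode_labels(table["label"].to_numpy())
    if k > np.bincount(y).min():
        raise ValueError("k exceeds the smallest class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, aucs, prob_rows = [], [], []
    cm = np.zeros((2, 2), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        pipe = _logistic_pipeline(C)
        pipe.fit(x[tr], y[tr])
        p = pipe.predict_proba(x[te])[:, 1]
        yhat = (p >= 0.5).astype(int)
        accs.append(float(np.mean(yhat == y[te])))
        aucs.append(float(roc_auc_score(y[te], p)))
        cm += confusion_matrix(y[te], yhat, labels=[0, 1])
        prob_rows.extend({"sample": int(i), "label": int(y[i]),
                          "p_positive": float(pi), "fold": fold}
                         for i, pi in zip(te, p))
    full = _logistic_pipeline(C).fit(x, y)
    metrics = CvMetrics(fold_accuracy=np.array(accs), fold_auroc=np.array(aucs),
                        confusion=cm, proba=pd.DataFrame(prob_rows))
    metrics.proba.attrs["positive_class"] = positive
    return metrics, full


def _logistic_pipeline(C: float) -> Pipeline:
    # default penalty is the conventional unit-strength L2
    return Pipeline([("scale", StandardScaler()),
                     ("logit", LogisticRegression(C=C, solver="lbfgs",
                                                  max_iter=1000))])


def linear_shap(coefficients, X, background_mean=None, feature_names=None):
    """Exact Shapley attributions of a linear model under feature independence.

    For a linear logit ``w·x + b`` the Shapley value of feature j at input x
    is ``phi_j = w_j (x_j - mean_j)`` with the mean taken over the background
    (training) data; the attributions plus ``b + w·mean`` reconstruct the
    logit exactly.  Returns ``(per-sample DataFrame, global ranking Series)``
    with global importance = mean |phi_j|.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(coefficients, dtype=float).reshape(-1)
    if X.shape[1] != w.size:
        raise ValueError("coefficient and feature dimensions differ")
    mean = np.zeros_like(w) if background_mean is None else \
        np.asarray(background_mean, dtype=float)
    if feature_names is None:
        feature_names = (FEATURE_COLUMNS if w.size == len(FEATURE_COLUMNS)
                         else [f"x{j}" for j in range(w.size)])
    phi = (X - mean) * w
    per_sample = pd.DataFrame(phi, columns=list(feature_names))
    ranking = per_sample.abs().mean().sort_values(ascending=False)
    return per_sample, ranking


def shap_from_pipeline(pipeline: Pipeline, table: pd.DataFrame):
    """Shapley attributions of a fitted scaler+logistic pipeline on its table."""
    x = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    z = pipeline.named_steps["scale"].transform(x)
    coef = pipeline.named_steps["logit"].coef_
    return linear_shap(coef, z, background_mean=z.mean(axis=0))


# -- video-clip route ------------------------------------------------------

@dataclass
class ClipFeatures:
    """Input of the video classifier: selected frames plus their spacing."""

    frames: np.ndarray         # n x H x W grayscale
    frame_indices: np.ndarray  # strictly increasing
    durations_s: np.ndarray    # n - 1 inter-selection gaps, > 0
    label: str | None = None

    def __post_init__(self):
        idx = np.asarray(self.frame_indices)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if np.any(np.asarray(self.durations_s) <= 0):
            raise ValueError("durations must be positive")


def select_classifier_frames(video: VideoStack, n: int = 96, t0: int = 0
                             ) -> ClipFeatures:
    """SSD run-centre frame selection.

    ``ssd_t = Σ_pixels (I_t − I_t0)²`` is min-max normalised, binarised at
    0.5, and split into maximal runs of equal value; each run contributes
    its centre frame ``floor((first + last)/2)`` until ``n`` frames are
    collected.  Invariant to affine intensity rescaling of the video.
    """
    frames = np.asarray(video.frames, dtype=np.float32)
    diff = frames - frames[t0]
    ssd = np.einsum("thw,thw->t", diff, diff, dtype=np.float64)
    lo, hi = float(ssd.min()), float(ssd.max())
    if hi <= lo:
        raise ValueError("constant video: SSD normalisation is degenerate")
    binary = ((ssd - lo) / (hi - lo)) >= 0.5
    centers = _run_centers(binary)
    if centers.size < n:
        raise ValueError(
            f"only {centers.size} motion runs available but {n} frames "
            f"requested ({n - centers.size} short); record a longer video")
    sel = centers[:n]
    return ClipFeatures(frames=frames[sel], frame_indices=sel,
                        durations_s=np.diff(sel) / video.fps)


def _run_centers(binary: np.ndarray) -> np.ndarray:
    """Centre index floor((first+last)/2) of each maximal run, in order."""
    binary = np.asarray(binary).astype(bool)
    if binary.size == 0:
        return np.empty(0, dtype=int)
    change = np.nonzero(np.diff(binary))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [binary.size - 1]])
    return (starts + ends) // 2


class VideoCnn(nn.Module):
    """Three conv blocks (two 2-D convs + 2x2 max pool each), flatten,
    duration fusion, three dense layers, sigmoid output."""

    def __init__(self, input_shape, n_durations, filters=(16, 32, 64),
                 dense=(128, 32, 8), kernel=(3, 3), seed=0):
        n_frames, h, w = input_shape
        if h // 8 < 1 or w // 8 < 1 or h % 8 or w % 8:
            raise ValueError(
                f"spatial dims {h}x{w} must be divisible by 8 to survive 3 pools")
        rng = np.random.default_rng(seed)
        chans = (n_frames,) + tuple(filters)
        self.blocks = [nn.ConvBlock(chans[i], chans[i + 1], kernel, rng)
                       for i in range(3)]
        flat = filters[-1] * (h // 8) * (w // 8)
        widths = (flat + n_durations,) + tuple(dense)
        self.dense = [nn.Dense(widths[i], widths[i + 1], rng)
                      for i in range(len(dense))]
        self.out = nn.Dense(dense[-1], 1, rng)
        self.input_shape = tuple(input_shape)
        self.n_durations = int(n_durations)

    def forward(self, clips, durations) -> ag.Tensor:
        clips = np.asarray(clips, dtype=np.float32)
        x = ag.Tensor(np.ascontiguousarray(np.moveaxis(clips, 1, -1)))
        for block in self.blocks:
            x = ag.maxpool2(block(x))
        n = x.shape[0]
        x = ag.reshape(x, (n, -1))
        x = ag.concat([x, ag.Tensor(np.asarray(durations, dtype=np.float32))],
                      axis=1)
        for layer in self.dense:
            x = ag.relu(layer(x))
        return ag.sigmoid(ag.reshape(self.out(x), (n,)))


def build_video_classifier(input_shape, n_durations=95, filters=(16, 32, 64),
                           dense=(128, 32, 8), seed=0) -> VideoCnn:
    """Seeded random initialisation of the clip classifier."""
    return VideoCnn(input_shape, n_durations, filters=filters, dense=dense,
                    seed=seed)


def clips_to_arrays(clips):
    """Stack ClipFeatures into (frames, durations, labels) arrays."""
    frames = np.stack([c.frames for c in clips]).astype(np.float32)
    durs = np.stack([c.durations_s for c in clips]).astype(np.float32)
    labels = np.array([c.label for c in clips])
    return frames, durs, labels


class VideoAgeClassifier(BaseEstimator, ClassifierMixin):
    """CNN age classifier over (clip frames, durations) pairs.

    ``fit(X, y)`` takes ``X = (frames, durations)`` with frames
    (N, n_frames, H, W) and durations (N, n_frames - 1); durations are
    z-scored with training-set statistics before fusion.  Trained with
    binary cross-entropy and Adam; deterministic given ``seed``.
    """

    def __init__(self, filters=(16, 32, 64), dense=(128, 32, 8), epochs=15,
                 batch_size=16, learning_rate=1e-3, seed=0):
        self.filters = filters
        self.dense = dense
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X, y):
        frames, durations = X
        frames = np.asarray(frames, dtype=np.float32)
        durations = np.asarray(durations, dtype=np.float32)
        y, self.positive_class_ = _encode_labels(y)
        self.classes_ = np.array([0, 1])
        self.dur_mean_ = durations.mean()
        self.dur_sd_ = durations.std() + 1e-9
        dz = (durations - self.dur_mean_) / self.dur_sd_
        self.model_ = build_video_classifier(frames.shape[1:],
                                             n_durations=durations.shape[1],
                                             filters=tuple(self.filters),
                                             dense=tuple(self.dense),
                                             seed=self.seed)
        rng = np.random.default_rng(self.seed)
        opt = nn.Adam(self.model_.parameters(), lr=self.learning_rate)
        losses = []
        for _ in range(self.epochs):
            order = rng.permutation(len(frames))
            for lo in range(0, len(order), self.batch_size):
                sel = order[lo:lo + self.batch_size]
                opt.zero_grad()
                p = self.model_.forward(frames[sel], dz[sel])
                loss = _bce(p, y[sel])
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(f"non-finite training loss: {value}")
                loss.backward()
                opt.step()
                losses.append(value)
        self.loss_history_ = np.array(losses)
        return self

    def predict_proba(self, X):
        frames, durations = X
        dz = (np.asarray(durations, np.float32) - self.dur_mean_) / self.dur_sd_
        frames = np.asarray(frames, dtype=np.float32)
        p = np.empty(len(frames), dtype=float)
        for lo in range(0, len(frames), self.batch_size):
            p[lo:lo + self.batch_size] = self.model_.forward(
                frames[lo:lo + self.batch_size], dz[lo:lo + self.batch_size]).data
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _bce(pred: ag.Tensor, target: np.ndarray) -> ag.Tensor:
    t = np.asarray(target, dtype=np.float32)
    p = ag.clip(pred, 1e-6, 1.0 - 1e-6)
    pos = ag.mul(ag.log(p), t)
    neg = ag.mul(ag.log(1.0 - p), 1.0 - t)
    return -ag.tensor_mean(pos + neg)


def crossval_video_classifier(clips, labels=None, k: int = 5, seed: int = 0,
                              epochs: int = 15, **classifier_kwargs):
    """Stratified k-fold CV of the clip CNN.

    ``clips`` is either a list of labelled :class:`ClipFeatures` or a
    ``(frames, durations)`` tuple with explicit ``labels``.  Returns
    :class:`CvMetrics` whose ``proba`` table also carries the per-sample
    class log-likelihood ``log p(old)``.
    """
    if labels is None:
        frames, durations, labels = clips_to_arrays(clips)
    else:
        frames, durations = clips
        labels = np.asarray(labels)
    y, positive = _encode_labels(labels)
    counts = np.bincount(y)
    if k > counts.min():
        raise ValueError("k exceeds the smallest class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, aucs, prob_rows = [], [], []
    cm = np.zeros((2, 2), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(frames, y)):
        clf = VideoAgeClassifier(epochs=epochs, seed=seed + fold,
                                 **classifier_kwargs)
        clf.fit((frames[tr], durations[tr]), labels[tr])
        p = clf.predict_proba((frames[te], durations[te]))[:, 1]
        yhat = (p >= 0.5).astype(int)
        accs.append(float(np.mean(yhat == y[te])))
        aucs.append(float(roc_auc_score(y[te], p)))
        cm += confusion_matrix(y[te], yhat, labels=[0, 1])
        prob_rows.extend({"sample": int(i), "label": int(y[i]),
                          "p_positive": float(pi),
                          "log_likelihood": float(np.log(max(pi if y[i] else 1 - pi,
                                                             1e-12))),
                          "fold": fold}
                         for i, pi in zip(te, p))
    metrics = CvMetrics(fold_accuracy=np.array(accs), fold_auroc=np.array(aucs),
                        confusion=cm, proba=pd.DataFrame(prob_rows))
    metrics.proba.attrs["positive_class"] = positive
    return metrics
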