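"""Desk-scale reference experiments on simulated hearts.

Each study builds its own synthetic data with a known ground truth, runs
one stage of the pipeline end to end, and reports recovery errors or
classification metrics.  The studies double as reproducible benchmarks:
they are what the test suite and the acceptance script execute.  Problem
sizes are desk-scale by design (tens of hearts, minutes of video) so a
full run completes on a single CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from .aging import (assemble_feature_table, clips_to_arrays, crossval_logistic,
                    crossval_video_classifier, select_classifier_frames,
                    shap_from_pipeline)
from .beats import (arrhythmia_index, detect_beats, per_beat_parameters,
                    summarize_heart)
from .core import ROI
from .segmentation import HeartWallSegmenter, dice_score
from .simulate import (RenderConfig, SimulationConfig, build_beat_schedule,
                       make_cohort, old_preset, old_video_preset, render_video,
                       synthesize_trace, young_preset, young_video_preset)
from .trace import extract_diameter_trace

__all__ = [
    "align_truth", "roundtrip_study", "beat_counting_study",
    "segmentation_study", "feature_classifier_study", "video_classifier_study",
]


def align_truth(truth, beats):
    """Match each detected beat to the nearest ground-truth beat by DI start."""
    ti = truth["di_start_s"].to_numpy()
    idx = [int(np.argmin(np.abs(ti - s))) for s in beats["di_start_s"]]
    return truth.iloc[idx].reset_index(drop=True)


def _random_config(rng) -> SimulationConfig:
    return SimulationConfig(
        n_beats=int(rng.integers(8, 13)),
        di_mean=float(rng.uniform(0.35, 0.5)), di_sd=0.02,
        si_mean=float(rng.uniform(0.18, 0.28)), si_sd=0.012,
        dd_mean=float(rng.uniform(70, 85)), dd_sd=2.0,
        sd_mean=float(rng.uniform(38, 48)), sd_sd=2.0,
        fps=150.0, seed=int(rng.integers(0, 2 ** 31)),
        transition_time=0.05, lead_in=0.2)


def roundtrip_study(n_videos: int = 50, seed: int = 123) -> dict:
    """Noise-free render -> mask -> trace -> beats recovery errors.

    Returns worst-case absolute errors over the whole study: trace (px),
    per-beat DD/SD (px), DI/SI boundary times (frames), per-heart mean FS
    (percentage points) and AI.
    """
    rng = np.random.default_rng(seed)
    worst = dict(trace_px=0.0, dd_px=0.0, sd_px=0.0, boundary_frames=0.0,
                 fs_points=0.0, ai=0.0)
    render = RenderConfig(height=112, width=64, pixel_size=1.0, noise_sd=0.0)
    for v in range(n_videos):
        cfg = _random_config(rng)
        trace, truth = synthesize_trace(build_beat_schedule(cfg), cfg.fps)
        video, masks = render_video(trace, render)
        rec = extract_diameter_trace(masks, ROI(10, 54), render.pixel_size,
                                     cfg.fps)
        worst["trace_px"] = max(worst["trace_px"], float(
            np.abs(rec.diameter_um - trace.diameter_um).max()))
        beats = per_beat_parameters(rec, detect_beats(rec))
        tt = align_truth(truth, beats)
        worst["dd_px"] = max(worst["dd_px"],
                             float(np.abs(tt.dd_um - beats.dd_um).max()))
        worst["sd_px"] = max(worst["sd_px"],
                             float(np.abs(tt.sd_um - beats.sd_um).max()))
        for col in ("di_start_s", "di_end_s", "si_end_s"):
            worst["boundary_frames"] = max(worst["boundary_frames"], float(
                np.abs(tt[col] - beats[col]).max() * cfg.fps))
        fs_truth = float((100 * (1 - tt.sd_um / tt.dd_um)).mean())
        worst["fs_points"] = max(worst["fs_points"],
                                 abs(fs_truth - float(beats.fs_pct.mean())))
        hp_truth = tt.si_end_s - tt.di_start_s
        ai_truth = float(np.std(hp_truth, ddof=1) / np.median(hp_truth))
        worst["ai"] = max(worst["ai"],
                          abs(ai_truth - arrhythmia_index(beats)))
    worst["n_videos"] = n_videos
    return worst


def beat_counting_study(seed: int = 0, counts=(1, 5, 50)) -> dict:
    """Detected complete-beat counts on noise-free traces with N beats."""
    out = {}
    for n in counts:
        cfg = SimulationConfig(n_beats=n, di_sd=0.01, si_sd=0.006, dd_sd=1.0,
                               sd_sd=1.0, seed=seed + n,
                               transition_time=0.05, lead_in=0.2, lead_out=0.3)
        trace, _ = synthesize_trace(build_beat_schedule(cfg), cfg.fps)
        out[n] = int(len(detect_beats(trace)))
    return out


def _training_video(seed: int):
    cfg = SimulationConfig(n_beats=5, di_mean=0.4, di_sd=0.03, si_mean=0.2,
                           si_sd=0.02, dd_mean=80.0, dd_sd=4.0, sd_mean=44.0,
                           sd_sd=4.0, fps=150.0, seed=seed,
                           transition_time=0.05, lead_in=0.1)
    trace, truth = synthesize_trace(build_beat_schedule(cfg), cfg.fps)
    render = RenderConfig(height=64, width=128, pixel_size=2.0,
                          wall_thickness=3, noise_sd=0.05, clutter_blobs=2,
                          seed=seed + 1000)
    video, masks = render_video(trace, render)
    return video, masks, trace, truth, render


def segmentation_study(seed: int = 0, epochs: int = 6, per_bin: int = 30
                       ) -> dict:
    """Train the attention U-Net on 64x128 synthetic videos; evaluate on a
    held-out video: segmentation Dice score and the FS error of the full
    video -> masks -> trace -> summary pipeline."""
    videos, masks, traces, truths = [], [], [], []
    for k in range(4):
        v, m, tr, tt, render = _training_video(seed * 10 + k)
        videos.append(v)
        masks.append(m)
        traces.append(tr)
        truths.append(tt)
    seg = HeartWallSegmenter(epochs=epochs, per_bin=per_bin, seed=seed)
    seg.fit(videos[:3], masks[:3])

    held_video, held_masks, held_truth = videos[3], masks[3], truths[3]
    pred = seg.predict(held_video)
    dice = dice_score(pred.masks, held_masks.masks)

    roi = ROI(20, 108)
    rec = extract_diameter_trace(pred, roi, held_video.pixel_size,
                                 held_video.fps)
    beats = per_beat_parameters(rec, detect_beats(rec))
    if len(beats):
        # compare FS over the beats the detector completed (the final beat
        # of a recording is incomplete and correctly dropped)
        tt = align_truth(held_truth, beats)
        fs_truth = float((100 * (1 - tt.sd_um / tt.dd_um)).mean())
        fs_rec = float(beats.fs_pct.mean())
    else:
        fs_truth = float((100 * (1 - held_truth.sd_um / held_truth.dd_um)).mean())
        fs_rec = float("nan")
    return {"dice": float(dice), "fs_error_points": abs(fs_truth - fs_rec),
            "fs_truth": fs_truth, "fs_recovered": fs_rec,
            "best_epoch": seg.best_epoch_,
            "val_loss": float(seg.history_["val_loss"].min()),
            "history": seg.history_}


def feature_classifier_study(seed: int = 0, n_per_class: int = 60, k: int = 5,
                             permutation_reps: int = 10) -> dict:
    """Logistic age classification on simulated cardiac summaries."""
    cohort = make_cohort(n_per_class, young_preset(), old_preset(), seed=seed)
    summaries, labels = [], []
    roi = ROI(0, 100)
    for sp in cohort:
        beats = per_beat_parameters(sp.trace, detect_beats(sp.trace))
        summaries.append(summarize_heart(beats, roi, 1.0))
        labels.append(sp.label)
    table = assemble_feature_table(summaries, labels)
    metrics, pipeline = crossval_logistic(table, k=k, seed=seed)
    _, ranking = shap_from_pipeline(pipeline, table)

    rng = np.random.default_rng(seed + 1)
    null_aucs = []
    for rep in range(permutation_reps):
        shuffled = table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        m, _ = crossval_logistic(shuffled, k=k, seed=seed + rep)
        null_aucs.append(m.mean_auroc)
    return {"auroc": metrics.mean_auroc, "accuracy": metrics.mean_accuracy,
            "top_feature": str(ranking.index[0]), "ranking": ranking,
            "null_auroc": float(np.mean(null_aucs)) if null_aucs else None,
            "n_hearts": len(table)}


def video_cohort_clips(n_per_class: int, seed: int):
    """Render the video-classification cohort and select classifier frames."""
    render = RenderConfig(height=32, width=64, pixel_size=4.0,
                          wall_thickness=3, noise_sd=0.05, seed=seed)
    cohort = make_cohort(n_per_class, young_video_preset(),
                         old_video_preset(), seed=seed, render=render)
    clips = []
    for sp in cohort:
        clip = select_classifier_frames(sp.video, n=96)
        clip.label = sp.label
        clips.append(clip)
    return cohort, clips


def video_classifier_study(seed: int = 0, n_per_class: int = 60, k: int = 5,
                           epochs: int = 4, permutation_reps: int = 3,
                           permutation_epochs: int = 2) -> dict:
    """CNN age classification from raw clips of the simulated video cohort."""
    _, clips = video_cohort_clips(n_per_class, seed)
    frames, durations, labels = clips_to_arrays(clips)
    metrics = crossval_video_classifier((frames, durations), labels, k=k,
                                        seed=seed, epochs=epochs)
    rng = np.random.default_rng(seed + 1)
    null_accs = []
    for rep in range(permutation_reps):
        shuffled = rng.permutation(labels)
        m = crossval_video_classifier((frames, durations), shuffled, k=k,
                                      seed=seed + rep,
                                      epochs=permutation_epochs)
        null_accs.append(m.mean_accuracy)
    return {"accuracy": metrics.mean_accuracy, "auroc": metrics.mean_auroc,
            "null_accuracy": float(np.mean(null_accs)) if null_accs else None,
            "n_clips": len(clips)}
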