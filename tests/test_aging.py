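"""Age classification: feature table, logistic CV, SHAP, frame selection, CNN."""

import numpy as np
import pandas as pd
import pytest

from flyheart.aging import (FEATURE_COLUMNS, ClipFeatures, _run_centers,
                            assemble_feature_table, build_video_classifier,
                            crossval_logistic, crossval_video_classifier,
                            linear_shap, select_classifier_frames,
                            shap_from_pipeline)
from flyheart.beats import CardiacSummary
from flyheart.core import VideoStack


def summary(n_beats=10, dd=80, sd=50, fs=None, di=0.4, si=0.2, hp=0.6, ai=0.03):
    fs = 100 * (dd - sd) / dd if fs is None else fs
    return CardiacSummary(n_beats=n_beats, dd_um=dd, sd_um=sd, fs_pct=fs,
                          ef_pct=100 * (1 - (sd / dd) ** 2), di_s=di, si_s=si,
                          hp_s=hp, hr_hz=1 / hp, ai=ai)


@pytest.fixture(scope="module")
def feature_cohort():
    """Trace-level synthetic cohort with the aging FS contrast."""
    from flyheart.beats import detect_beats, per_beat_parameters, summarize_heart
    from flyheart.core import ROI
    from flyheart.simulate import make_cohort, old_preset, young_preset

    cohort = make_cohort(60, young_preset(), old_preset(), seed=42)
    summaries, labels = [], []
    for sp in cohort:
        beats = per_beat_parameters(sp.trace, detect_beats(sp.trace))
        summaries.append(summarize_heart(beats, ROI(0, 100), 1.0))
        labels.append(sp.label)
    return assemble_feature_table(summaries, labels)


def test_assemble_excludes_underbeaten_hearts_and_orders_columns():
    with pytest.warns(UserWarning):
        table = assemble_feature_table(
            [summary(), summary(), summary(n_beats=1, ai=float("nan")),
             summary(sd=60), summary(sd=62)],
            ["young", "young", "young", "old", "old"])
    assert len(table) == 4
    assert tuple(table.columns[:-1]) == FEATURE_COLUMNS
    with pytest.raises(ValueError):
        assemble_feature_table([summary(), summary(sd=60)], ["young", "old"])


def test_logistic_crossval_separates_aging_cohort(feature_cohort):
    metrics, pipeline = crossval_logistic(feature_cohort, k=5, seed=0)
    assert metrics.mean_auroc >= 0.95
    assert metrics.confusion.sum() == len(feature_cohort)
    # determinism: same seed, same folds and metrics
    again, _ = crossval_logistic(feature_cohort, k=5, seed=0)
    assert np.array_equal(metrics.fold_accuracy, again.fold_accuracy)
    assert metrics.proba.equals(again.proba)


def test_logistic_permutation_null_is_chance(feature_cohort):
    rng = np.random.default_rng(1)
    aucs = []
    for rep in range(20):
        shuffled = feature_cohort.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        m, _ = crossval_logistic(shuffled, k=5, seed=rep)
        aucs.append(m.mean_auroc)
    assert abs(np.mean(aucs) - 0.5) <= 0.15


def test_shap_centering_and_formula():
    phi, _ = linear_shap(np.array([2.0, 0.0, 0.0]), np.zeros((1, 3)),
                         background_mean=np.zeros(3))
    assert np.allclose(phi.to_numpy(), 0.0)  # at the mean: no attribution
    phi, ranking = linear_shap(np.array([2.0, 0.0, 0.0]),
                               np.array([[1.5, 3.0, -1.0]]),
                               background_mean=np.zeros(3))
    assert phi.iloc[0, 0] == pytest.approx(3.0)
    assert np.allclose(phi.iloc[0, 1:], 0.0)


def test_shap_reconstructs_logit_and_ranks_fs_first(feature_cohort):
    metrics, pipeline = crossval_logistic(feature_cohort, k=5, seed=0)
    phi, ranking = shap_from_pipeline(pipeline, feature_cohort)
    x = feature_cohort[list(FEATURE_COLUMNS)].to_numpy(float)
    z = pipeline.named_steps["scale"].transform(x)
    logit = z @ pipeline.named_steps["logit"].coef_.ravel() \
        + pipeline.named_steps["logit"].intercept_[0]
    base = pipeline.named_steps["logit"].intercept_[0] \
        + z.mean(axis=0) @ pipeline.named_steps["logit"].coef_.ravel()
    assert np.allclose(phi.sum(axis=1) + base, logit)
    assert ranking.index[0] == "fs"


def brute_force_run_centers(binary):
    """Independent oracle: enumerate runs one element at a time."""
    centers, start = [], 0
    for i in range(1, len(binary) + 1):
        if i == len(binary) or binary[i] != binary[start]:
            centers.append((start + i - 1) // 2)
            start = i
    return centers


def test_run_centers_match_brute_force_enumeration():
    series = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1], dtype=bool)
    assert list(_run_centers(series)[:4]) == [0, 3, 5, 7]
    rng = np.random.default_rng(0)
    for _ in range(100):
        b = rng.random(rng.integers(1, 200)) > 0.5
        assert list(_run_centers(b)) == brute_force_run_centers(b)


def test_frame_selection_degenerate_and_affine_invariance():
    constant = VideoStack(np.full((50, 8, 8), 0.5), fps=10, pixel_size=1)
    with pytest.raises(ValueError, match="constant"):
        select_classifier_frames(constant, n=4)
    rng = np.random.default_rng(3)
    t = np.arange(200)
    wave = 0.5 + 0.4 * np.sin(2 * np.pi * t / 20)
    frames = (wave[:, None, None] * rng.random((8, 8))
              + rng.normal(0, 0.01, (200, 8, 8))).astype(np.float32)
    video = VideoStack(frames, fps=10, pixel_size=1)
    a = select_classifier_frames(video, n=8)
    scaled = VideoStack(frames * 3.0 + 0.1, fps=10, pixel_size=1)
    b = select_classifier_frames(scaled, n=8)
    assert np.array_equal(a.frame_indices, b.frame_indices)
    with pytest.raises(ValueError, match="runs"):
        select_classifier_frames(video, n=10_000)


def test_clip_features_validation():
    with pytest.raises(ValueError):
        ClipFeatures(frames=np.zeros((3, 4, 4)),
                     frame_indices=np.array([0, 2, 2]),
                     durations_s=np.array([0.2, 0.0]))


def test_video_classifier_build_contracts():
    model = build_video_classifier((8, 16, 32), n_durations=7, seed=4)
    out = model.forward(np.random.rand(2, 8, 16, 32), np.random.rand(2, 7))
    assert out.shape == (2,)
    assert 0.0 <= out.data.min() and out.data.max() <= 1.0
    twin = build_video_classifier((8, 16, 32), n_durations=7, seed=4)
    for a, b in zip(model.parameters(), twin.parameters()):
        assert np.array_equal(a.data, b.data)
    with pytest.raises(ValueError):
        build_video_classifier((8, 4, 6), n_durations=3)


def test_video_crossval_partitions_folds():
    rng = np.random.default_rng(0)
    frames = rng.random((20, 6, 8, 16)).astype(np.float32)
    durs = rng.random((20, 5)).astype(np.float32) + 0.1
    labels = np.array(["young", "old"] * 10)
    metrics = crossval_video_classifier((frames, durs), labels, k=5, seed=0,
                                        epochs=1)
    seen = np.sort(metrics.proba["sample"].to_numpy())
    assert np.array_equal(seen, np.arange(20))  # disjoint folds cover all
    assert metrics.confusion.sum() == 20
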