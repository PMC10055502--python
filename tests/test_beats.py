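"""Beat detection and the cardiac-statistics formula suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyheart.beats import (DetectorConfig, arrhythmia_index, beat_latencies,
                            detect_beats, filter_arrhythmia_events,
                            per_beat_parameters, stroke_metrics,
                            summarize_heart, wall_velocity)
from flyheart.core import ROI, DiameterTrace
from conftest import align_truth


def enriched(trace):
    return per_beat_parameters(trace, detect_beats(trace))


def make_beat_table(di, si, dd=80.0, sd=40.0):
    di, si = np.asarray(di, float), np.asarray(si, float)
    if di.size == 0:
        start = np.empty(0)
    else:
        start = np.concatenate([[0.0], np.cumsum(di + si)[:-1]])
    t = pd.DataFrame({
        "beat_index": np.arange(di.size), "di_start_s": start,
        "di_end_s": start + di, "si_end_s": start + di + si,
        "dd_um": dd, "sd_um": sd,
    })
    t["fs_pct"] = 100 * (t.dd_um - t.sd_um) / t.dd_um
    t["ef_pct"] = 100 * (1 - (t.sd_um / t.dd_um) ** 2)
    t["hp_s"] = di + si
    t["di_s"], t["si_s"] = di, si
    return t


def test_constant_trace_yields_empty_table():
    trace = DiameterTrace(np.full(300, 60.0), fps=150)
    assert len(detect_beats(trace)) == 0


def test_regular_beats_detected_with_correct_period(regular_trace):
    trace, truth = regular_trace
    beats = detect_beats(trace)
    assert 9 <= len(beats) <= 10
    assert np.abs(beats["si_end_s"] - beats["di_start_s"] - 0.6).max() \
        <= 1 / trace.fps


def test_shallow_wiggle_is_ignored_by_hysteresis():
    fps = 100.0
    t = np.arange(0, 3.0, 1 / fps)
    d = np.where((t > 0.5) & (t < 2.5), 80.0, 40.0)
    # mid-DI wiggle dips to 65 µm: below T_high but never below T_low
    d[(t > 1.4) & (t < 1.6)] = 65.0
    smooth_free = DetectorConfig(smooth_window=1)
    beats = detect_beats(DiameterTrace(d, fps=fps), smooth_free)
    # the wiggle must not split the single DI into two beats
    assert len(beats) <= 1
    d2 = d.copy()
    d2[(t > 1.4) & (t < 1.6)] = 42.0  # now a real dip below T_low
    starts2 = detect_beats(DiameterTrace(d2, fps=fps), smooth_free)
    assert len(starts2) == 1  # one complete beat between the two DIs


def test_per_beat_formulas():
    table = make_beat_table([0.4], [0.2], dd=80, sd=40)
    assert table.fs_pct.iloc[0] == pytest.approx(50.0)
    assert table.ef_pct.iloc[0] == pytest.approx(75.0)
    equal = make_beat_table([0.4], [0.2], dd=60, sd=60)
    assert equal.fs_pct.iloc[0] == 0 and equal.ef_pct.iloc[0] == 0


def test_parameter_recovery_on_rendered_specimen(rendered_specimen):
    from flyheart.trace import extract_diameter_trace

    sp = rendered_specimen
    rec = extract_diameter_trace(sp["masks"], sp["roi"], 1.0, sp["config"].fps)
    beats = enriched(rec)
    tt = align_truth(sp["truth"], beats)
    assert np.abs(tt.dd_um - beats.dd_um).max() <= 1.0
    assert np.abs(tt.sd_um - beats.sd_um).max() <= 1.0
    fs_truth = (100 * (1 - tt.sd_um / tt.dd_um)).mean()
    assert abs(fs_truth - beats.fs_pct.mean()) <= 2.0


def test_wall_velocity_constant_and_linear():
    const = DiameterTrace(np.full(100, 55.0), fps=100)
    assert np.allclose(wall_velocity(const), 0.0)
    ramp = DiameterTrace(40 + 5 * np.arange(200) / 100, fps=100)
    v = wall_velocity(ramp)
    assert np.allclose(v[1:-1], 5.0)


def test_wall_velocity_matches_analytic_derivative():
    fps = 100.0
    t = np.arange(0, 3.0, 1 / fps)
    trace = DiameterTrace(60 + 10 * np.sin(2 * np.pi * t), fps=fps)
    v = wall_velocity(trace)
    expected = 20 * np.pi * np.cos(2 * np.pi * t)
    assert np.abs(v[1:-1] - expected[1:-1]).max() < 0.05


def test_latencies_nonnegative_and_repeatable(regular_trace):
    trace, _ = regular_trace
    beats = enriched(trace)
    table = beat_latencies(trace, wall_velocity(trace), beats)
    assert (table["latency_to_peak_contraction_s"] >= 0).all()
    assert (table["latency_contraction_to_relaxation_s"] >= 0).all()
    # identical beats: per-beat latencies identical to within one frame
    for col in ("latency_to_peak_contraction_s",
                "latency_contraction_to_relaxation_s"):
        assert table[col].max() - table[col].min() <= 1 / trace.fps + 1e-9
    # boundaries sit at the ramp midpoints, where contraction velocity peaks,
    # so the latency from DI end to peak contraction is zero (to one frame)
    assert table["latency_to_peak_contraction_s"].max() <= 1 / trace.fps + 1e-9


def test_stroke_volume_and_cardiac_output():
    table = make_beat_table([0.4] * 10, [0.2] * 10, dd=80, sd=40)
    roi = ROI(0, 100)
    table, co = stroke_metrics(table, roi, pixel_size=1.0)  # L = 100 µm
    assert table.sv_pl.iloc[0] == pytest.approx(np.pi / 4 * 100 * 4800 / 1e6)
    assert round(table.sv_pl.iloc[0], 3) == 0.377
    assert co == pytest.approx(table.sv_pl.sum() / 6.0)
    assert round(co, 3) == 0.628
    flat = make_beat_table([0.4], [0.2], dd=60, sd=60)
    flat, _ = stroke_metrics(flat, roi, pixel_size=1.0)
    assert flat.sv_pl.iloc[0] == 0.0


def test_arrhythmia_index_conventions():
    assert arrhythmia_index(make_beat_table([0.4] * 3, [0.2] * 3)) == 0.0
    table = make_beat_table([0.3, 0.3, 0.8], [0.2, 0.2, 0.2])
    assert arrhythmia_index(table) == pytest.approx(
        np.std([0.5, 0.5, 1.0], ddof=1) / 0.5)
    assert round(arrhythmia_index(table), 3) == 0.577
    assert np.isnan(arrhythmia_index(make_beat_table([0.4], [0.2])))


def test_arrhythmia_index_time_unit_invariant():
    table = make_beat_table([0.3, 0.5, 0.4], [0.2, 0.3, 0.25])
    scaled = table.copy()
    scaled["hp_s"] = scaled["hp_s"] * 1000  # express in milliseconds
    assert arrhythmia_index(table) == pytest.approx(arrhythmia_index(scaled))


def test_event_filters_use_strict_inequalities():
    table = make_beat_table([0.8, 1.2, 0.9, 1.0], [0.3, 0.6, 0.7, 0.5])
    events = filter_arrhythmia_events(table)
    assert len(events.tachycardic) == 2   # 0.6 and 0.7; 0.5 excluded
    assert len(events.bradycardic) == 1   # 1.2; 1.0 excluded
    quiet = filter_arrhythmia_events(make_beat_table([0.4] * 3, [0.2] * 3))
    assert quiet.n_events == 0
    assert events.brachycardic.equals(events.bradycardic)


def test_summary_of_identical_beats():
    table = make_beat_table([0.4] * 10, [0.2] * 10, dd=80, sd=40)
    summary = summarize_heart(table, ROI(0, 100), pixel_size=1.0)
    assert summary.dd_um == 80 and summary.sd_um == 40
    assert summary.fs_pct == pytest.approx(50.0)
    assert summary.hp_s == pytest.approx(0.6)
    assert summary.hr_hz == pytest.approx(10 / 6.0)
    assert summary.ai == pytest.approx(0.0, abs=1e-12)
    assert summary.hr_hz * summary.hp_s == pytest.approx(1.0)


def test_summary_of_empty_table_is_missing_values():
    empty = make_beat_table([], [])
    summary = summarize_heart(empty)
    assert summary.n_beats == 0
    assert np.isnan(summary.fs_pct)


def test_beat_intervals_partition_analyzed_time(regular_trace):
    trace, _ = regular_trace
    beats = detect_beats(trace)
    total = (beats["si_end_s"] - beats["di_start_s"]).sum()
    span = beats["si_end_s"].iloc[-1] - beats["di_start_s"].iloc[0]
    assert total == pytest.approx(span)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(scale=st.floats(min_value=0.2, max_value=5.0))
def test_fs_ef_invariant_to_diameter_rescaling(scale):
    table = make_beat_table([0.4, 0.45], [0.2, 0.25], dd=80, sd=44)
    rescaled = table.copy()
    rescaled["dd_um"] *= scale
    rescaled["sd_um"] *= scale
    fs = 100 * (rescaled.dd_um - rescaled.sd_um) / rescaled.dd_um
    assert np.allclose(fs, table.fs_pct)
    sv, _ = stroke_metrics(rescaled, ROI(0, 100), pixel_size=1.0)
    assert np.allclose(sv.sv_pl, scale ** 2
                       * stroke_metrics(table, ROI(0, 100), 1.0)[0].sv_pl)
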