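"""Beat detection and the cardiac-statistics suite.

Diastolic intervals (DI, relaxed plateau at the diastolic diameter DD) and
systolic intervals (SI, contracted plateau at the systolic diameter SD) are
detected on the diameter trace with a hysteresis threshold pair placed at
fractions of the trace excursion; each reported boundary is then refined to
the 50 %-excursion crossing by linear interpolation (the mid-reference-level
timing convention for pulses).  From the per-beat DD/SD/DI/SI the suite
derives fractional shortening, ejection fraction, heart period and rate,
arrhythmia index, wall velocities and latencies, and cylindrical-model
stroke volume and cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ROI, DiameterTrace

__all__ = [
    "DetectorConfig", "detect_beats", "per_beat_parameters", "wall_velocity",
    "beat_latencies", "stroke_metrics", "arrhythmia_index",
    "filter_arrhythmia_events", "summarize_heart", "CardiacSummary",
    "ArrhythmiaEvents", "BEAT_COLUMNS",
]

BEAT_COLUMNS = ["beat_index", "di_start_s", "di_end_s", "si_end_s"]


@dataclass(frozen=True)
class DetectorConfig:
    """Hysteresis beat-detector constants.

    ``alpha``/``beta`` place the low/high thresholds at those fractions of
    the trace excursion; a candidate DI end is only confirmed once the trace
    dips below the low threshold, so shallow wiggles near the high threshold
    do not split a beat.  ``min_excursion_frac`` (relative to the trace
    maximum) rejects traces with no real beating.
    """

    smooth_window: int = 5
    alpha: float = 0.35
    beta: float = 0.65
    min_excursion_frac: float = 0.10

    def validate(self):
        if not (0 < self.alpha < self.beta < 1):
            raise ValueError("need 0 < alpha < beta < 1")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def _refine_crossing(s: np.ndarray, i: int, level: float, fps: float,
                     upward: bool) -> float:
    """Sub-frame time where the smoothed trace crosses ``level`` near index i."""
    n = s.size
    if upward:
        j = i
        while j > 0 and s[j - 1] >= level:
            j -= 1
        if j == 0:
            return 0.0
    else:
        j = i
        while j < n and s[j] >= level:
            j += 1
        if j >= n:
            return (n - 1) / fps
    lo, hi = s[j - 1], s[j]
    frac = 0.5 if hi == lo else (level - lo) / (hi - lo)
    return (j - 1 + np.clip(frac, 0.0, 1.0)) / fps


def detect_beats(trace: DiameterTrace, cfg: DetectorConfig = DetectorConfig()
                 ) -> pd.DataFrame:
    """Detect complete beats (DI start ... next DI start) on a trace.

    Returns a table of boundary times in seconds (columns ``di_start_s``,
    ``di_end_s``, ``si_end_s``); an empty table is a value, not an error.
    """
    cfg.validate()
    d = np.asarray(trace.diameter_um, dtype=float)
    if d.size < 2:
        return pd.DataFrame(columns=BEAT_COLUMNS)
    s = _smooth(d, cfg.smooth_window)
    m, big = float(s.min()), float(s.max())
    if big - m < cfg.min_excursion_frac * big:
        return pd.DataFrame(columns=BEAT_COLUMNS)
    t_low = m + cfg.alpha * (big - m)
    t_high = m + cfg.beta * (big - m)

    starts, ends = [], []
    state = "high" if s[0] >= t_high else "low"
    candidate = None  # pending DI-end index awaiting a dip below t_low
    for i in range(1, s.size):
        if state == "low":
            if s[i] >= t_high:
                starts.append(i)
                state = "high"
        else:
            if candidate is None:
                if s[i] < t_high:
                    candidate = i
                    if s[i] <= t_low:
                        ends.append(candidate)
                        candidate = None
                        state = "low"
            else:
                if s[i] >= t_high:
                    candidate = None          # shallow wiggle: DI continues
                elif s[i] <= t_low:
                    ends.append(candidate)    # confirmed DI end
                    candidate = None
                    state = "low"

    # Boundary timing is refined against the *local* plateau levels (the
    # minimum before / maximum after an upward crossing, and vice versa), so
    # per-beat DD/SD variation does not bias the mid-level crossing time.
    n = s.size

    def refine_start(i):
        prev_e = max((j for j in ends if j < i), default=0)
        next_e = min((j for j in ends if j > i), default=n - 1)
        mid = 0.5 * (s[prev_e:i + 1].min() + s[i:next_e + 1].max())
        return _refine_crossing(s, i, mid, trace.fps, True)

    def refine_end(j):
        prev_s = max((i for i in starts if i < j), default=0)
        next_s = min((i for i in starts if i > j), default=n - 1)
        mid = 0.5 * (s[prev_s:j + 1].max() + s[j:next_s + 1].min())
        return _refine_crossing(s, j, mid, trace.fps, False)

    rows = []
    for k in range(len(starts) - 1):
        e = [j for j in ends if starts[k] < j <= starts[k + 1]]
        if not e:
            continue
        rows.append({
            "beat_index": len(rows),
            "di_start_s": refine_start(starts[k]),
            "di_end_s": refine_end(e[0]),
            "si_end_s": refine_start(starts[k + 1]),
        })
    return pd.DataFrame(rows, columns=BEAT_COLUMNS)


def per_beat_parameters(trace: DiameterTrace, beats: pd.DataFrame) -> pd.DataFrame:
    """Enrich detected beats with DD, SD, FS, EF, HP and interval lengths.

    DD is the largest diameter attained during the DI, SD the smallest over
    the following SI; FS = 100 (DD − SD)/DD, EF = 100 (1 − (SD/DD)²) under
    the cylindrical lumen model, HP = si_end − di_start.  Beats with DD = 0
    are dropped with a warning.
    """
    import warnings

    if len(beats) == 0:
        return beats.assign(dd_um=[], sd_um=[], fs_pct=[], ef_pct=[],
                            hp_s=[], di_s=[], si_s=[])
    d = np.asarray(trace.diameter_um, dtype=float)
    fps = trace.fps
    rows = []
    for _, b in beats.iterrows():
        i0 = int(round(b.di_start_s * fps))
        i1 = int(round(b.di_end_s * fps))
        i2 = int(round(b.si_end_s * fps))
        i1 = max(i1, i0 + 1)
        i2 = max(min(i2, d.size), i1 + 1)
        dd = float(d[i0:i1].max())
        sd = float(d[i1:i2].min())
        if dd <= 0:
            warnings.warn(f"beat {int(b.beat_index)} dropped: zero diastolic diameter")
            continue
        rows.append({
            **{c: b[c] for c in BEAT_COLUMNS},
            "dd_um": dd,
            "sd_um": sd,
            "fs_pct": 100.0 * (dd - sd) / dd,
            "ef_pct": 100.0 * (1.0 - (sd / dd) ** 2),
            "hp_s": b.si_end_s - b.di_start_s,
            "di_s": b.di_end_s - b.di_start_s,
            "si_s": b.si_end_s - b.di_end_s,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["beat_index"] = np.arange(len(out))
    return out


def wall_velocity(trace: DiameterTrace) -> np.ndarray:
    """Heart-wall velocity (µm/s) by numeric differentiation of the trace.

    Central differences at interior points, one-sided at the endpoints
    (contraction is negative velocity, relaxation positive).
    """
    d = np.asarray(trace.diameter_um, dtype=float)
    if d.size < 3:
        raise ValueError("velocity needs at least 3 frames")
    return np.gradient(d, 1.0 / trace.fps)


def beat_latencies(trace: DiameterTrace, velocity: np.ndarray,
                   beats: pd.DataFrame) -> pd.DataFrame:
    """Per-beat peak contraction/relaxation velocities and latencies.

    Peak contraction is the most negative velocity during the SI; peak
    relaxation the most positive velocity between it and the end of the
    next beat's DI.  Latencies are measured from the DI end and from peak
    contraction respectively; both are non-negative by construction.
    """
    if len(beats) == 0:
        return beats.assign(peak_contraction_velocity_um_s=[],
                            peak_relaxation_velocity_um_s=[],
                            latency_to_peak_contraction_s=[],
                            latency_contraction_to_relaxation_s=[])
    fps = trace.fps
    n = velocity.size
    beats = beats.reset_index(drop=True)
    rows = []
    for k, b in beats.iterrows():
        i1 = int(round(b.di_end_s * fps))
        i2 = min(int(round(b.si_end_s * fps)), n - 1)
        if k + 1 < len(beats):
            nxt = beats.iloc[k + 1]
            hi = b.si_end_s + (nxt.di_end_s - nxt.di_start_s)
        else:
            hi = b.si_end_s
        i3 = min(int(round(hi * fps)) + 1, n)
        i2 = max(i2, i1 + 1)
        i3 = max(i3, i2 + 1)
        tc = i1 + int(np.argmin(velocity[i1:i2]))
        tr = tc + int(np.argmax(velocity[tc:i3]))
        rows.append({
            "peak_contraction_velocity_um_s": float(velocity[tc]),
            "peak_relaxation_velocity_um_s": float(velocity[tr]),
            "latency_to_peak_contraction_s": max(tc / fps - b.di_end_s, 0.0),
            "latency_contraction_to_relaxation_s": (tr - tc) / fps,
        })
    return pd.concat([beats, pd.DataFrame(rows, index=beats.index)], axis=1)


def stroke_metrics(beats: pd.DataFrame, roi: ROI, pixel_size: float):
    """Cylindrical-lumen stroke volume per beat (pL) and cardiac output (pL/s).

    sv_k = (π/4) L (DD_k² − SD_k²) with L the ROI length in µm;
    1 pL = 10⁶ µm³.  Cardiac output normalises the summed stroke volumes by
    the summed beat times.
    """
    length_um = roi.length_um(pixel_size)
    if length_um <= 0:
        raise ValueError("ROI length must be positive")
    beats = beats.copy()
    sv_um3 = (np.pi / 4.0) * length_um * (beats["dd_um"] ** 2 - beats["sd_um"] ** 2)
    beats["sv_pl"] = sv_um3 / 1e6
    total_hp = float(beats["hp_s"].sum())
    co = float(beats["sv_pl"].sum() / total_hp) if total_hp > 0 else float("nan")
    return beats, co


def arrhythmia_index(beats: pd.DataFrame) -> float:
    """AI = sample standard deviation of heart periods / median heart period.

    Dimensionless; undefined (NaN) with fewer than two beats.
    """
    hp = np.asarray(beats["hp_s"], dtype=float) if len(beats) else np.empty(0)
    if hp.size < 2:
        return float("nan")
    return float(np.std(hp, ddof=1) / np.median(hp))


@dataclass
class ArrhythmiaEvents:
    """Abnormally long intervals: tachycardic SIs and bradycardic DIs."""

    tachycardic: pd.DataFrame
    bradycardic: pd.DataFrame
    si_threshold_s: float
    di_threshold_s: float

    @property
    def brachycardic(self) -> pd.DataFrame:
        """Alias for :attr:`bradycardic` (both spellings appear in the field)."""
        return self.bradycardic

    @property
    def n_events(self) -> int:
        return len(self.tachycardic) + len(self.bradycardic)


def filter_arrhythmia_events(beats: pd.DataFrame, si_threshold: float = 0.5,
                             di_threshold: float = 1.0) -> ArrhythmiaEvents:
    """Strict-inequality interval filters: SI > 0.5 s (tachy), DI > 1.0 s (brady)."""
    tachy = beats.loc[beats["si_s"] > si_threshold,
                      ["beat_index", "si_s"]].reset_index(drop=True)
    brady = beats.loc[beats["di_s"] > di_threshold,
                      ["beat_index", "di_s"]].reset_index(drop=True)
    return ArrhythmiaEvents(tachycardic=tachy, bradycardic=brady,
                            si_threshold_s=si_threshold, di_threshold_s=di_threshold)


@dataclass
class CardiacSummary:
    """Per-heart aggregate cardiac statistics (the classifier feature vector)."""

    n_beats: int
    dd_um: float = float("nan")
    sd_um: float = float("nan")
    fs_pct: float = float("nan")
    ef_pct: float = float("nan")
    di_s: float = float("nan")
    si_s: float = float("nan")
    hp_s: float = float("nan")
    hr_hz: float = float("nan")
    ai: float = float("nan")
    sv_pl: float = float("nan")
    co_pl_s: float = float("nan")
    latency_to_peak_contraction_s: float = float("nan")
    latency_contraction_to_relaxation_s: float = float("nan")
    n_tachycardic: int = 0
    n_bradycardic: int = 0

    def to_dict(self):
        return dict(vars(self))


def summarize_heart(beats: pd.DataFrame, roi: ROI | None = None,
                    pixel_size: float = 1.0,
                    si_threshold: float = 0.5,
                    di_threshold: float = 1.0) -> CardiacSummary:
    """Aggregate an enriched beat table into one per-heart summary.

    Means of the per-beat diameters/intervals; HR = n_beats / Σ HP; AI, SV
    and CO as defined above.  An empty beat table yields a summary of
    missing values with ``n_beats = 0``.
    """
    if len(beats) == 0:
        return CardiacSummary(n_beats=0)
    out = CardiacSummary(n_beats=int(len(beats)))
    out.dd_um = float(beats["dd_um"].mean())
    out.sd_um = float(beats["sd_um"].mean())
    out.fs_pct = float(beats["fs_pct"].mean())
    out.ef_pct = float(beats["ef_pct"].mean())
    out.di_s = float(beats["di_s"].mean())
    out.si_s = float(beats["si_s"].mean())
    out.hp_s = float(beats["hp_s"].mean())
    if len(beats) >= 2:
        out.hr_hz = float(len(beats) / beats["hp_s"].sum())
        out.ai = arrhythmia_index(beats)
    for col, attr in (("latency_to_peak_contraction_s",
                       "latency_to_peak_contraction_s"),
                      ("latency_contraction_to_relaxation_s",
                       "latency_contraction_to_relaxation_s")):
        if col in beats:
            setattr(out, attr, float(beats[col].mean()))
    if roi is not None:
        enriched, co = stroke_metrics(beats, roi, pixel_size)
        out.sv_pl = float(enriched["sv_pl"].mean())
        out.co_pl_s = co
    events = filter_arrhythmia_events(beats, si_threshold, di_threshold)
    out.n_tachycardic = len(events.tachycardic)
    out.n_bradycardic = len(events.bradycardic)
    return out
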