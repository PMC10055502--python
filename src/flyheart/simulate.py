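"""Synthetic beating heart-tube generator with ground truth.

Emulates high-speed optical recordings of the Drosophila heart tube: a
bright two-walled tube on a dark noisy background whose lumen diameter
follows a beat schedule.  Each heartbeat consists of a relaxed plateau at
the diastolic diameter (DD) lasting the diastolic interval (DI) and a
contracted plateau at the systolic diameter (SD) lasting the systolic
interval (SI), joined by cosine ramps of ``transition_time`` seconds.

Ramps are centred on the DI/SI boundaries (the boundary is the ramp's
mid-reference-level crossing, the standard pulse-timing convention), so a
beat occupies exactly DI + SI seconds and ground-truth boundary times are
well defined even though the waveform is smooth.  Every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import DiameterTrace, MaskStack, VideoStack

__all__ = [
    "Beat", "BeatSchedule", "SimulationConfig", "RenderConfig", "Specimen",
    "build_beat_schedule", "synthesize_trace", "render_video", "make_cohort",
    "young_preset", "old_preset", "young_video_preset", "old_video_preset",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["beat_index", "di_start_s", "di_end_s", "si_end_s", "dd_um", "sd_um"]


@dataclass(frozen=True)
class Beat:
    di_length: float  # s
    si_length: float  # s
    dd: float         # µm
    sd: float         # µm


@dataclass
class BeatSchedule:
    beats: list
    transition_time: float  # s, ramp between plateaus
    lead_in: float = 0.0    # s, resting (systolic-level) baseline before beat 1
    lead_out: float = 0.0   # s, relaxed (diastolic-level) hold after the last beat

    def __post_init__(self):
        if self.transition_time <= 0:
            raise ValueError("transition_time must be positive")
        if self.lead_in < 0 or self.lead_out < 0:
            raise ValueError("lead_in/lead_out must be non-negative")
        for k, b in enumerate(self.beats):
            if b.di_length <= 0 or b.si_length <= 0:
                raise ValueError(f"beat {k}: interval lengths must be positive")
            if not (0 < b.sd < b.dd):
                raise ValueError(f"beat {k}: requires 0 < sd < dd")
            if self.transition_time >= min(b.di_length, b.si_length):
                raise ValueError(
                    f"beat {k}: transition_time must be shorter than both intervals"
                )

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    @property
    def total_duration_s(self) -> float:
        return (self.lead_in + self.lead_out
                + sum(b.di_length + b.si_length for b in self.beats))


@dataclass(frozen=True)
class SimulationConfig:
    """Beat-schedule statistics for one phenotype (truncated-normal draws)."""

    n_beats: int = 10
    di_mean: float = 0.40    # s
    di_sd: float = 0.0
    si_mean: float = 0.20    # s
    si_sd: float = 0.0
    dd_mean: float = 80.0    # µm
    dd_sd: float = 0.0
    sd_mean: float = 40.0    # µm
    sd_sd: float = 0.0
    fps: float = 150.0       # Hz
    seed: int = 0
    phenotype_label: str | None = None
    transition_time: float = 0.04  # s
    lead_in: float = 0.0     # s
    lead_out: float = 0.0    # s

    def validate(self):
        if self.n_beats < 0:
            raise ValueError("n_beats must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("di_mean", "si_mean", "dd_mean", "sd_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sd_mean >= self.dd_mean:
            raise ValueError("infeasible truncation: sd_mean must be < dd_mean")
        if self.transition_time >= min(self.di_mean, self.si_mean):
            raise ValueError("transition_time must be < min(di_mean, si_mean)")


@dataclass(frozen=True)
class RenderConfig:
    height: int = 112
    width: int = 64
    pixel_size: float = 1.0        # µm/px
    wall_thickness: int = 4        # px
    wall_intensity: float = 0.8
    background_intensity: float = 0.12
    noise_sd: float = 0.0
    clutter_blobs: int = 0
    seed: int = 0

    def validate(self):
        if self.wall_thickness < 2:
            raise ValueError("wall_thickness must be >= 2")
        for name in ("wall_intensity", "background_intensity", "noise_sd"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.height < 8 or self.width < 1:
            raise ValueError("frame too small")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _trunc_draw(rng, mean, sd, low, high, max_tries=1000):
    """Draw from N(mean, sd) truncated to (low, high), resampling until valid."""
    if sd == 0:
        if not (low < mean < high):
            raise ValueError(
                f"zero-variance draw {mean} outside feasible range ({low}, {high})"
            )
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    raise ValueError(
        f"truncation bounds infeasible: N({mean}, {sd}) rarely falls in ({low}, {high})"
    )


def build_beat_schedule(config: SimulationConfig) -> BeatSchedule:
    """Draw a beat schedule from the configured truncated normals.

    Deterministic given ``config.seed``; rejects infeasible truncations
    (e.g. ``sd_mean >= dd_mean``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tau = config.transition_time
    beats = []
    for _ in range(config.n_beats):
        di = _trunc_draw(rng, config.di_mean, config.di_sd, tau, np.inf)
        si = _trunc_draw(rng, config.si_mean, config.si_sd, tau, np.inf)
        dd = _trunc_draw(rng, config.dd_mean, config.dd_sd, 0.0, np.inf)
        sd = _trunc_draw(rng, config.sd_mean, config.sd_sd, 0.0, dd)
        beats.append(Beat(di, si, dd, sd))
    return BeatSchedule(beats=beats, transition_time=tau, lead_in=config.lead_in,
                        lead_out=config.lead_out)


def schedule_truth_table(schedule: BeatSchedule) -> pd.DataFrame:
    """Exact per-beat DI/SI boundaries (ramp midpoints) and DD/SD."""
    rows = []
    t = schedule.lead_in
    for k, b in enumerate(schedule.beats):
        rows.append({
            "beat_index": k,
            "di_start_s": t,
            "di_end_s": t + b.di_length,
            "si_end_s": t + b.di_length + b.si_length,
            "dd_um": b.dd,
            "sd_um": b.sd,
        })
        t += b.di_length + b.si_length
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def synthesize_trace(schedule: BeatSchedule, fps: float):
    """Sample the piecewise diameter waveform at 1/fps.

    Returns ``(DiameterTrace, truth_table)`` where the truth table records
    the exact DI/SI boundary times and per-beat DD/SD.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    truth = schedule_truth_table(schedule)
    n = int(round(schedule.total_duration_s * fps))
    if schedule.n_beats == 0 or n == 0:
        return DiameterTrace(np.empty(0), fps=fps), truth

    t = np.arange(n) / fps
    tau = schedule.transition_time
    # Step levels between boundaries: before the first DI start the tube rests
    # at the first beat's systolic level.
    bounds, levels = [], [schedule.beats[0].sd]
    for k, b in enumerate(schedule.beats):
        row = truth.iloc[k]
        bounds.extend([row.di_start_s, row.di_end_s])
        levels.extend([b.dd, b.sd])
    if schedule.lead_out > 0:
        # hold at the last diastolic level after the final up-ramp
        bounds.append(truth.iloc[-1].si_end_s)
        levels.append(schedule.beats[-1].dd)
    bounds = np.asarray(bounds)
    d = np.asarray(levels)[np.searchsorted(bounds, t, side="right")]

    # Overwrite cosine ramps centred on every boundary.
    ramp_bounds, pre, post = list(bounds), levels[:-1], levels[1:]
    if schedule.lead_out == 0:
        # Final up-ramp at the last si_end (toward the last beat's dd).
        ramp_bounds = ramp_bounds + [truth.iloc[-1].si_end_s]
        pre = pre + [schedule.beats[-1].sd]
        post = post + [schedule.beats[-1].dd]
    for b0, p, q in zip(ramp_bounds, pre, post):
        sel = np.abs(t - b0) <= tau / 2
        if not np.any(sel):
            continue
        s = (t[sel] - (b0 - tau / 2)) / tau
        d[sel] = p + (q - p) * (1 - np.cos(np.pi * np.clip(s, 0, 1))) / 2
    return DiameterTrace(d, fps=fps), truth


def render_video(trace: DiameterTrace, render: RenderConfig):
    """Render a diameter trace as a two-walled tube video plus truth masks.

    Walls are horizontal bright bands with Gaussian cross-section centred at
    ``mid_row -/+ (d(t)/2 + wall_thickness/2)``; the binary mask marks the
    wall bands only (clutter and noise excluded).  Same seed gives
    bit-identical output.
    """
    render.validate()
    h, w, wt = render.height, render.width, render.wall_thickness
    d_px = trace.diameter_um / render.pixel_size
    mid = h // 2
    r_a = np.rint(mid - d_px / 2).astype(int)  # top wall: rows [r_a - wt, r_a - 1]
    r_b = np.rint(mid + d_px / 2).astype(int)  # bottom wall: rows [r_b, r_b + wt - 1]

    bad = np.nonzero((r_a - wt < 0) | (r_b + wt > h))[0]
    if bad.size:
        raise ValueError(
            f"rendered geometry overflows the frame at frame {bad[0]}: "
            f"diameter {trace.diameter_um[bad[0]]:.1f} µm needs more than "
            f"{h} rows at {render.pixel_size} µm/px"
        )

    rows = np.arange(h)[None, :]
    sigma = wt / 2.355  # FWHM equals the wall thickness
    # Intensity uses the continuous wall positions (sub-pixel motion, as in
    # real optics); only the masks are quantised to pixel rows.
    c_top = (mid - d_px / 2 - (wt + 1) / 2)[:, None]
    c_bot = (mid + d_px / 2 + (wt - 1) / 2)[:, None]
    profile = render.background_intensity + render.wall_intensity * (
        np.exp(-((rows - c_top) ** 2) / (2 * sigma ** 2))
        + np.exp(-((rows - c_bot) ** 2) / (2 * sigma ** 2))
    )
    frames = np.repeat(profile[:, :, None], w, axis=2).astype(np.float32)

    rng = np.random.default_rng(render.seed)
    if render.clutter_blobs > 0:
        top_lim = int(r_a.min()) - wt - 3
        bot_lim = int(r_b.max()) + wt + 3
        safe_rows = np.concatenate([np.arange(0, max(top_lim, 0)),
                                    np.arange(min(bot_lim, h), h)])
        if safe_rows.size:
            rr = np.arange(h)[:, None]
            cc = np.arange(w)[None, :]
            blob = np.zeros((h, w), dtype=np.float32)
            for _ in range(render.clutter_blobs):
                br = int(rng.choice(safe_rows))
                bc = int(rng.integers(0, w))
                amp = rng.uniform(0.3, 0.7) * render.wall_intensity
                bs = rng.uniform(1.0, 3.0)
                blob += amp * np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * bs ** 2))
            frames += blob[None, :, :]
    if render.noise_sd > 0:
        frames += rng.normal(0, render.noise_sd, frames.shape).astype(np.float32)
    np.clip(frames, 0.0, 1.0, out=frames)

    band = ((rows >= (r_a - wt)[:, None]) & (rows <= (r_a - 1)[:, None])) | (
        (rows >= r_b[:, None]) & (rows <= (r_b + wt - 1)[:, None]))
    masks = np.repeat(band[:, :, None], w, axis=2)

    video = VideoStack(frames, fps=trace.fps, pixel_size=render.pixel_size,
                       source_id="synthetic")
    return video, MaskStack(masks)


# -- phenotype presets -----------------------------------------------------
# The presets encode the aging contrast used throughout the package's tests:
# old hearts have lower fractional shortening, longer and more variable beats.

def young_preset(**overrides) -> SimulationConfig:
    """Young phenotype: FS ~= 35 %, HP ~= 0.60 s, low beat-to-beat variability."""
    base = dict(n_beats=12, di_mean=0.40, di_sd=0.012, si_mean=0.20, si_sd=0.008,
                dd_mean=80.0, dd_sd=0.8, sd_mean=52.0, sd_sd=0.8,
                fps=150.0, transition_time=0.04, phenotype_label="young")
    base.update(overrides)
    return SimulationConfig(**base)


def old_preset(**overrides) -> SimulationConfig:
    """Old phenotype: FS ~= 22 %, HP ~= 0.66 s, mildly higher variability.

    The aging contrast is carried by contractility (FS) with only a small
    rhythm shift: aged hearts slow down and lose fractional shortening much
    more than they gain arrhythmia.
    """
    base = dict(n_beats=12, di_mean=0.44, di_sd=0.022, si_mean=0.22, si_sd=0.013,
                dd_mean=74.0, dd_sd=0.8, sd_mean=57.7, sd_sd=0.8,
                fps=150.0, transition_time=0.04, phenotype_label="old")
    base.update(overrides)
    return SimulationConfig(**base)


def young_video_preset(**overrides) -> SimulationConfig:
    """Video-classification contrast, young arm: FS ~= 50 %, HP ~= 0.6 s."""
    base = dict(n_beats=60, di_mean=0.40, di_sd=0.015, si_mean=0.20, si_sd=0.010,
                dd_mean=80.0, dd_sd=1.0, sd_mean=40.0, sd_sd=1.0,
                fps=50.0, transition_time=0.05, lead_in=0.3,
                phenotype_label="young")
    base.update(overrides)
    return SimulationConfig(**base)


def old_video_preset(**overrides) -> SimulationConfig:
    """Video-classification contrast, old arm: FS ~= 20 %, HP ~= 1.0 s."""
    base = dict(n_beats=60, di_mean=0.65, di_sd=0.030, si_mean=0.35, si_sd=0.020,
                dd_mean=75.0, dd_sd=1.0, sd_mean=60.0, sd_sd=1.0,
                fps=50.0, transition_time=0.05, lead_in=0.3,
                phenotype_label="old")
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class Specimen:
    """One simulated heart: the config actually used, its truth, and data."""

    label: str
    config: SimulationConfig
    schedule: BeatSchedule
    trace: DiameterTrace
    truth: pd.DataFrame
    video: VideoStack | None = None
    masks: MaskStack | None = None


def _jitter_config(cfg: SimulationConfig, rng, size_cv, tempo_cv,
                   dd_cv, sd_cv, interval_cv) -> SimulationConfig:
    """Per-specimen variation of the phenotype means.

    A common size scale multiplies DD and SD together (heart size varies
    between flies but leaves FS untouched); a common tempo scale stretches
    DI and SI together; small independent jitters perturb each mean.
    """
    size = rng.normal(1.0, size_cv)
    tempo = rng.normal(1.0, tempo_cv)
    dd_mean = cfg.dd_mean * size * rng.normal(1.0, dd_cv)
    sd_mean = cfg.sd_mean * size * rng.normal(1.0, sd_cv)
    sd_mean = min(sd_mean, 0.95 * dd_mean)
    di_mean = max(cfg.di_mean * tempo * rng.normal(1.0, interval_cv),
                  cfg.transition_time * 1.5)
    si_mean = max(cfg.si_mean * tempo * rng.normal(1.0, interval_cv),
                  cfg.transition_time * 1.5)
    return replace(cfg, dd_mean=dd_mean, sd_mean=sd_mean,
                   di_mean=di_mean, si_mean=si_mean,
                   seed=int(rng.integers(0, 2 ** 31)))


def make_cohort(n_per_class: int, young_cfg: SimulationConfig,
                old_cfg: SimulationConfig, seed: int,
                render: RenderConfig | None = None,
                size_cv=0.08, tempo_cv=0.06,
                dd_cv=0.02, sd_cv=0.03, interval_cv=0.03) -> list:
    """Generate a labelled two-class cohort of simulated hearts.

    Each specimen gets re-seeded draws and jittered phenotype means; videos
    and truth masks are rendered only when a ``render`` config is given
    (trace-level cohorts are much cheaper and serve the feature-based
    classifier).  Returns a list of :class:`Specimen`, exactly
    ``n_per_class`` per class.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for label, cfg in (("young", young_cfg), ("old", old_cfg)):
        for _ in range(n_per_class):
            used = _jitter_config(cfg, rng, size_cv, tempo_cv, dd_cv, sd_cv,
                                  interval_cv)
            schedule = build_beat_schedule(used)
            trace, truth = synthesize_trace(schedule, used.fps)
            video = masks = None
            if render is not None:
                r = replace(render, seed=int(rng.integers(0, 2 ** 31)))
                video, masks = render_video(trace, r)
            cohort.append(Specimen(label=label, config=used, schedule=schedule,
                                   trace=trace, truth=truth, video=video,
                                   masks=masks))
    return cohort


def config_to_text(config) -> str:
    """Serialise a config dataclass as simple ``key: value`` lines."""
    lines = [f"{f.name}: {getattr(config, f.name)}"
             for f in dataclasses.fields(config)]
    return "\n".join(lines) + "\n"
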