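import numpy as np
import pytest

from flyheart.core import ROI
from flyheart.simulate import (RenderConfig, SimulationConfig,
                               build_beat_schedule, render_video,
                               synthesize_trace)


def align_truth(truth, beats):
    """Match each detected beat to the nearest ground-truth beat by DI start."""
    ti = truth["di_start_s"].to_numpy()
    idx = [int(np.argmin(np.abs(ti - s))) for s in beats["di_start_s"]]
    return truth.iloc[idx].reset_index(drop=True)


@pytest.fixture(scope="session")
def regular_config():
    """Ten regular beats: DI 0.4 s, SI 0.2 s, DD 80 µm, SD 40 µm at 150 fps."""
    return SimulationConfig(n_beats=10, di_mean=0.4, si_mean=0.2, dd_mean=80.0,
                            sd_mean=40.0, fps=150.0, seed=0,
                            transition_time=0.05, lead_in=0.2, lead_out=0.3)


@pytest.fixture(scope="session")
def regular_trace(regular_config):
    schedule = build_beat_schedule(regular_config)
    return synthesize_trace(schedule, regular_config.fps)


@pytest.fixture(scope="session")
def rendered_specimen():
    """A noise-free rendered heart video with variable beats and its truth."""
    cfg = SimulationConfig(n_beats=8, di_mean=0.4, di_sd=0.02, si_mean=0.2,
                           si_sd=0.012, dd_mean=80.0, dd_sd=2.0, sd_mean=40.0,
                           sd_sd=2.0, fps=150.0, seed=7, transition_time=0.05,
                           lead_in=0.2, lead_out=0.3)
    schedule = build_beat_schedule(cfg)
    trace, truth = synthesize_trace(schedule, cfg.fps)
    render = RenderConfig(height=112, width=64, pixel_size=1.0, noise_sd=0.0,
                          seed=3)
    video, masks = render_video(trace, render)
    return {"config": cfg, "render": render, "trace": trace, "truth": truth,
            "video": video, "masks": masks, "roi": ROI(10, 54)}
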