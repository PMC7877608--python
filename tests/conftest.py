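import numpy as np
import pytest

import hybridtrack as ht


@pytest.fixture
def small_cfg() -> ht.TrackerConfig:
    """Tracker config scaled to the small synthetic insect used in tests."""
    return ht.TrackerConfig.for_insect(insect_area=300.0, insect_length=26.0)


def make_scene(
    seed: int,
    n_frames: int = 450,
    width: int = 320,
    height: int = 240,
    **kwargs,
) -> ht.SceneConfig:
    """Scene config in the test regime: a 320×240 downscale of the field
    setup with a ~300 px insect walking at ~3 px/frame."""
    defaults = dict(
        width=width,
        height=height,
        n_frames=n_frames,
        body_area=300.0,
        body_length=26.0,
        speed_mean=3.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return ht.SceneConfig(**defaults)


@pytest.fixture
def clean_scene():
    """One noiseless distractor-free scene with its truth and frames."""
    cfg = make_scene(seed=11, n_frames=300)
    truth = ht.simulate_trajectory(cfg)
    frames = ht.render_frames(truth, cfg)
    return cfg, truth, frames


def run_tracker(scene_cfg, tracker_cfg, detector_noise=(0.0, 0.0, 0.0), det_seed=None):
    """Simulate, render and track one scene; returns (truth, tracks)."""
    truth = ht.simulate_trajectory(scene_cfg)
    frames = ht.render_frames(truth, scene_cfg)
    miss, sigma, fp = detector_noise
    det = ht.OracleDetector(
        truth,
        miss_rate=miss,
        position_sigma=sigma,
        false_positive_rate=fp,
        seed=scene_cfg.seed if det_seed is None else det_seed,
    )
    source = ht.ArraySource(frames, fps=scene_cfg.fps)
    tracks = ht.track_video(source, det, tracker_cfg)
    return truth, tracks
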