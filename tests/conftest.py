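"""Shared fixtures: synthetic videos and (expensive) end-to-end detector runs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from blinkflow.config import RunConfig
from blinkflow.detector import run_detector
from blinkflow.synth import default_blink_video_config, generate_video


@pytest.fixture(scope="session")
def textured_image() -> np.ndarray:
    """A smooth random texture with enough gradient structure for flow."""
    rng = np.random.default_rng(42)
    tex = ndimage.gaussian_filter(rng.standard_normal((360, 220)), 2.0)
    return (tex - tex.min()) / np.ptp(tex) * 255.0


@pytest.fixture(scope="session")
def clean_blink_run():
    """Detector output on the standard clean scene: 5 spontaneous blinks,
    mean phase durations, 100 fps, zero pixel noise.

    Returns (frames, ground_truth, records, events, config).
    """
    cfg = default_blink_video_config(n_blinks=5, fps=100.0, noise_sd=0.0, seed=0)
    frames, gt = generate_video(cfg)
    run_cfg = RunConfig()
    records, events = run_detector(frames, run_cfg)
    return frames, gt, records, events, run_cfg


@pytest.fixture(scope="session")
def one_blink_video():
    """A short single-blink clean scene (for stepwise/FSM tests)."""
    cfg = default_blink_video_config(n_blinks=1, fps=100.0, noise_sd=0.0, seed=3)
    frames, gt = generate_video(cfg)
    return frames, gt, cfg
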