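"""Run configuration: every tunable of the pipeline in one validated record.

The defaults encode the intended operating point for the nominal input (a
portrait 240 x 320 eye view at ~100 fps): crop the left 70-px headset band,
sample flow every 10 px, verify closure at NCC threshold 0.80, adapt the
closure threshold over the last 10 blink peaks.  Values not pinned down by the
method description (flow solver parameters, history window, initial threshold,
NCC cut-off, reopening threshold) are deliberately explicit here so that every
such choice is visible and overridable from a TOML or YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from blinkflow.flow import FlowParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # -- frame input ---------------------------------------------------------
    crop_px: int = 70                  #: width of the headset band to remove
    crop_edge: str = "left"            #: which edge carries the headset band
    fps: float | None = None           #: frame rate override (else container)

    # -- motion sampling -----------------------------------------------------
    grid_spacing: int = 10             #: marker spacing d (px)
    flow_backend: str = "polyexp"
    flow_pyr_levels: int = 3
    flow_poly_n: int = 3
    flow_poly_sigma: float = 1.2
    flow_win_sigma: float = 4.0
    flow_iterations: int = 3
    downward_criterion: str = "own"    #: y >= 0.5 * own |v| ("own") or 0.5 * |total| ("total")

    # -- dynamic closure threshold ------------------------------------------
    threshold_window_n: int = 10       #: per-blink peaks retained
    initial_threshold: float = 50.0    #: closure threshold before first blink (px)

    # -- localization --------------------------------------------------------
    cascade_model: str | None = None   #: cascade XML path; None = dark-blob backend
    cascade_selection: str = "largest"
    dark_threshold: int = 80
    dark_min_area: int = 30
    dark_margin: float = 0.1

    # -- verification --------------------------------------------------------
    ncc_threshold: float = 0.80        #: Q below this registers closure
    ncc_zero_mean: bool = False
    template_wait_ms: float = 500.0    #: post-reopening delay before capture
    #: Minimum NCC of the current frame (at the existing template's box)
    #: against the existing template for a refresh capture to be adopted.
    #: Far stricter than ncc_threshold: a refresh must be near-identical to
    #: the current template (slow drift passes, a saccade-displaced gaze does
    #: not), otherwise a displaced capture poisons later verifications.
    template_refresh_min_q: float = 0.95

    # -- reopening -----------------------------------------------------------
    #: UMV magnitude above which reopening is detected.  A genuine reopening
    #: sweeps the lid across the whole eye region (hundreds of grid markers,
    #: several px each, i.e. >= ~1000 px summed), while spurious upward flow
    #: vectors during a closing stay in the low hundreds at worst; 400 px sits
    #: between the scales.  None instead tracks the dynamic closure threshold,
    #: which is unsuitable when small fixational episodes anchor that median
    #: near the flow-noise floor.  The NCC template check remains the fallback
    #: reopening path either way.
    reopening_threshold: float | None = 400.0

    # -- evaluation ----------------------------------------------------------
    match_slack_frames: int = 0        #: temporal slack when matching detections to GT

    # -- randomness ----------------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_px < 0:
            raise ValueError("crop_px must be >= 0")
        if self.crop_edge not in ("left", "right", "top", "bottom"):
            raise ValueError(f"invalid crop_edge {self.crop_edge!r}")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if not 0.0 < self.ncc_threshold < 1.0:
            raise ValueError("ncc_threshold must lie in (0, 1)")
        if self.threshold_window_n < 1:
            raise ValueError("threshold_window_n must be >= 1")
        if self.initial_threshold <= 0:
            raise ValueError("initial_threshold must be > 0")
        if self.downward_criterion not in ("own", "total"):
            raise ValueError(f"invalid downward_criterion {self.downward_criterion!r}")
        if self.reopening_threshold is not None and self.reopening_threshold <= 0:
            raise ValueError("reopening_threshold must be > 0 when set")
        if self.match_slack_frames < 0:
            raise ValueError("match_slack_frames must be >= 0")

    def flow_params(self) -> FlowParams:
        return FlowParams(
            pyr_levels=self.flow_pyr_levels,
            poly_n=self.flow_poly_n,
            poly_sigma=self.flow_poly_sigma,
            win_sigma=self.flow_win_sigma,
            iterations=self.flow_iterations,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a TOML (``.toml``) or YAML (``.yml``/``.yaml``) file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        elif path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            raise ValueError(f"unsupported config format: {path.suffix!r} (use .toml or .yaml)")
        return cls.from_dict(data)
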