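"""Synthetic non-frontal eye video with scripted blink kinematics.

The generator emulates the structure of the headset recordings the detector is
designed for: a portrait 240 (w) x 320 (h) grayscale view of a single eye at
>= 100 fps, whose leftmost 70-px band images the headset interior.  The scene
contains a textured skin field, a bright sclera, a dark iris/pupil (the
feature both the dark-blob localizer and the NCC verification rely on), and a
textured upper-lid occluder.  During a scripted blink the lid descends
linearly over the closing duration, holds over the pause, and ascends over the
reopening duration; scripted saccades translate the iris between fixations;
optional Gaussian pixel noise models sensor noise.  Everything is
deterministic given the seed.

Default phase durations are the published means for healthy adults:
spontaneous blinks 71.5 / 13.7 / 171.5 ms (closing / pause / reopening,
total 256.7 ms) and voluntary blinks 70.8 / 44.2 / 168.5 ms (total 283.5 ms).

The renderer is deliberately simple — layered geometric shapes and smoothed
noise textures.  It exercises dense flow, localization and template
correlation, not photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from blinkflow.frameio import Frame

__all__ = [
    "BlinkKinematics",
    "SynthConfig",
    "GroundTruthBlink",
    "spontaneous_defaults",
    "voluntary_defaults",
    "SPONTANEOUS_SD",
    "VOLUNTARY_SD",
    "jittered_kinematics",
    "generate_video",
    "default_blink_video_config",
]

Direction = Literal["up", "down", "left", "right"]


@dataclass(frozen=True)
class BlinkKinematics:
    """Durations of the three blink phases, in milliseconds."""

    closing_ms: float
    pause_ms: float
    reopening_ms: float

    def __post_init__(self) -> None:
        if min(self.closing_ms, self.pause_ms, self.reopening_ms) <= 0:
            raise ValueError("phase durations must be > 0")

    @property
    def total_ms(self) -> float:
        return self.closing_ms + self.pause_ms + self.reopening_ms


def spontaneous_defaults() -> BlinkKinematics:
    """Mean spontaneous-blink phase durations (71.5 / 13.7 / 171.5 ms)."""
    return BlinkKinematics(71.5, 13.7, 171.5)


def voluntary_defaults() -> BlinkKinematics:
    """Mean voluntary-blink phase durations (70.8 / 44.2 / 168.5 ms)."""
    return BlinkKinematics(70.8, 44.2, 168.5)


#: Published standard deviations of the phase durations (ms).
SPONTANEOUS_SD = BlinkKinematics(4.7, 3.3, 13.8)
VOLUNTARY_SD = BlinkKinematics(4.3, 9.6, 15.9)


def jittered_kinematics(
    mean: BlinkKinematics, sd: BlinkKinematics, rng: np.random.Generator
) -> BlinkKinematics:
    """Draw phase durations around ``mean`` with the given SDs (clipped > 0)."""
    draw = lambda m, s: float(max(1.0, rng.normal(m, s)))
    return BlinkKinematics(
        draw(mean.closing_ms, sd.closing_ms),
        draw(mean.pause_ms, sd.pause_ms),
        draw(mean.reopening_ms, sd.reopening_ms),
    )


@dataclass(frozen=True)
class GroundTruthBlink:
    """Frame-index interval of a scripted blink with its phase boundaries."""

    start_frame: int      #: first frame with the lid in motion (closure begun)
    closing_end: int      #: first frame with the lid fully down
    pause_end: int        #: last frame with the lid fully down
    end_frame: int        #: last frame with the lid still away from rest

    def __post_init__(self) -> None:
        if not (self.start_frame <= self.closing_end <= self.pause_end <= self.end_frame):
            raise ValueError("phase boundaries must be ordered")

    def interval(self) -> tuple[int, int]:
        return (self.start_frame, self.end_frame)


@dataclass(frozen=True)
class SynthConfig:
    """Scene script and rendering parameters.

    ``blink_schedule`` holds ``(onset_ms, BlinkKinematics)`` pairs;
    ``saccade_schedule`` holds ``(onset_ms, direction, amplitude_px)`` with
    direction one of up/down/left/right.  ``eye_center`` is in full-frame
    coordinates (before cropping); ``eye_size`` is the iris radius.
    """

    fps: float = 100.0
    duration_s: float = 2.0
    frame_w: int = 240
    frame_h: int = 320
    eye_center: tuple[int, int] = (155, 160)
    eye_size: int = 20
    blink_schedule: tuple[tuple[float, BlinkKinematics], ...] = ()
    saccade_schedule: tuple[tuple[float, Direction, float], ...] = ()
    noise_sd: float = 2.0
    seed: int = 0
    headset_band_px: int = 70

    def __post_init__(self) -> None:
        if self.fps < 30:
            raise ValueError("fps must be >= 30")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        sched = tuple(sorted(self.blink_schedule, key=lambda b: b[0]))
        object.__setattr__(self, "blink_schedule", sched)
        object.__setattr__(self, "saccade_schedule", tuple(self.saccade_schedule))
        end = 0.0
        for onset, kin in sched:
            if onset < end:
                raise ValueError("blink schedule entries overlap")
            end = onset + kin.total_ms
            if end > self.duration_s * 1000.0:
                raise ValueError("blink schedule extends past the video duration")
        for onset, direction, _amp in self.saccade_schedule:
            if direction not in ("up", "down", "left", "right"):
                raise ValueError(f"invalid saccade direction {direction!r}")
            if not 0 <= onset <= self.duration_s * 1000.0:
                raise ValueError("saccade onset outside the video duration")


#: Saccade motion profile: ramp to the new fixation, hold, ramp back.
_SACCADE_RAMP_MS = 30.0
_SACCADE_HOLD_MS = 200.0


def _closure_fraction(t_ms: float, onset: float, kin: BlinkKinematics) -> float:
    """Lid closure c(t) in [0, 1]: 0 = rest (open), 1 = fully down."""
    if t_ms <= onset or t_ms >= onset + kin.total_ms:
        return 0.0
    dt = t_ms - onset
    if dt < kin.closing_ms:
        return dt / kin.closing_ms
    if dt <= kin.closing_ms + kin.pause_ms:
        return 1.0
    return max(0.0, 1.0 - (dt - kin.closing_ms - kin.pause_ms) / kin.reopening_ms)


def _saccade_offset(t_ms: float, schedule) -> tuple[float, float]:
    gx = gy = 0.0
    for onset, direction, amp in schedule:
        dt = t_ms - onset
        total = 2 * _SACCADE_RAMP_MS + _SACCADE_HOLD_MS
        if dt <= 0 or dt >= total:
            continue
        if dt < _SACCADE_RAMP_MS:
            a = amp * dt / _SACCADE_RAMP_MS
        elif dt < _SACCADE_RAMP_MS + _SACCADE_HOLD_MS:
            a = amp
        else:
            a = amp * (total - dt) / _SACCADE_RAMP_MS
        if direction == "right":
            gx += a
        elif direction == "left":
            gx -= a
        elif direction == "down":
            gy += a
        else:
            gy -= a
    return gx, gy


class _Scene:
    """Static layers and lid texture, rendered once per configuration."""

    def __init__(self, cfg: SynthConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        h, w = cfg.frame_h, cfg.frame_w
        cx, cy = cfg.eye_center
        r = cfg.eye_size

        yy, xx = np.mgrid[0:h, 0:w]
        self.yy, self.xx = yy, xx

        # Textures are clipped well above the iris/pupil intensities so the
        # dark pupil remains the frame's only dark structure (the premise the
        # localizer and the NCC discrimination rest on).
        skin = np.clip(170.0 + 20.0 * _smooth_noise(rng, (h, w), sigma=3.0), 120.0, 230.0)
        self.skin = skin

        # Sclera: bright ellipse around the eye centre.
        self.sclera_mask_base = ((xx - cx) / (2.2 * r)) ** 2 + ((yy - cy) / (1.4 * r)) ** 2 <= 1.0
        self.sclera_val = 215.0 + 6.0 * _smooth_noise(rng, (h, w), sigma=2.0)

        # Lid travel range: from just above the sclera to just below it.
        self.lid_open_y = cy - int(2.0 * r) - 15
        self.lid_closed_y = cy + int(1.4 * r) + 8
        travel = self.lid_closed_y - self.lid_open_y

        tex_h = h + travel + 8
        self.lid_tex = np.clip(
            165.0 + 25.0 * _smooth_noise(rng, (tex_h, w), sigma=2.0), 115.0, 225.0
        )
        self.lash_val = 105.0

    def render(self, t_ms: float) -> np.ndarray:
        cfg = self.cfg
        cx, cy = cfg.eye_center
        r = cfg.eye_size
        gx, gy = _saccade_offset(t_ms, cfg.saccade_schedule)

        img = self.skin.copy()
        img[self.sclera_mask_base] = self.sclera_val[self.sclera_mask_base]

        # Iris (radial shading) and pupil, shifted by the gaze offset but kept
        # inside the sclera.
        icx = cx + np.clip(gx, -0.9 * r, 0.9 * r)
        icy = cy + np.clip(gy, -0.5 * r, 0.5 * r)
        d2 = (self.xx - icx) ** 2 + (self.yy - icy) ** 2
        iris = d2 <= r * r
        img[iris] = 12.0 + 18.0 * (d2[iris] / (r * r))
        pupil = d2 <= (0.45 * r) ** 2
        img[pupil] = 8.0

        # Upper lid: textured occluder anchored to its (moving) lower edge.
        c = 0.0
        for onset, kin in cfg.blink_schedule:
            c = max(c, _closure_fraction(t_ms, onset, kin))
        lid_y = self.lid_open_y + c * (self.lid_closed_y - self.lid_open_y)
        lid_row = int(round(lid_y))
        if lid_row > 0:
            top = min(lid_row, cfg.frame_h)
            # Texture row 0 sits ``top`` rows above the edge, so the whole lid
            # surface translates with the edge.
            tex_off = self.lid_tex.shape[0] - 8 - top
            img[:top, :] = self.lid_tex[tex_off : tex_off + top, :]
            # Lash line at the lid margin.
            lash0 = max(0, top - 3)
            img[lash0:top, :] = self.lash_val

        return img

    def lid_edge_row(self, t_ms: float) -> float:
        c = 0.0
        for onset, kin in self.cfg.blink_schedule:
            c = max(c, _closure_fraction(t_ms, onset, kin))
        return self.lid_open_y + c * (self.lid_closed_y - self.lid_open_y)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = n.std()
    return n / s if s > 0 else n


def generate_video(config: SynthConfig) -> tuple[list[Frame], list[GroundTruthBlink]]:
    """Render the scripted scene into frames plus ground-truth blink intervals.

    Frames are full (uncropped) 8-bit portrait images including the static
    headset band; timestamps follow ``index * 1000 / fps``.  Ground-truth
    intervals are derived from the closure profile: ``start_frame`` is the
    first frame with the lid in motion, ``closing_end``/``pause_end`` bound
    the fully-closed span, ``end_frame`` is the last frame before the lid is
    back at rest.

    Raises
    ------
    ValueError
        If the configuration is invalid (overlapping schedule entries,
        schedule past the duration, fps < 30).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scene = _Scene(cfg, rng)
    noise_rng = np.random.default_rng(cfg.seed + 1)

    n_frames = int(round(cfg.duration_s * cfg.fps))
    dt = 1000.0 / cfg.fps
    frames: list[Frame] = []
    for i in range(n_frames):
        t = i * dt
        img = scene.render(t)
        if cfg.headset_band_px > 0:
            img[:, : cfg.headset_band_px] = 45.0
        if cfg.noise_sd > 0:
            img = img + noise_rng.normal(0.0, cfg.noise_sd, img.shape)
        px = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        frames.append(Frame(pixels=px, index=i, timestamp_ms=t))

    gt: list[GroundTruthBlink] = []
    for onset, kin in cfg.blink_schedule:
        start = int(math.floor(onset / dt)) + 1
        closing_end = int(math.ceil((onset + kin.closing_ms) / dt))
        pause_end = int(math.floor((onset + kin.closing_ms + kin.pause_ms) / dt))
        end = int(math.ceil((onset + kin.total_ms) / dt)) - 1
        if pause_end < closing_end:
            # Pause shorter than the frame period and no frame landed in it.
            mid = int(round((onset + kin.closing_ms + 0.5 * kin.pause_ms) / dt))
            closing_end = pause_end = mid
        start = max(0, min(start, n_frames - 1))
        end = max(0, min(end, n_frames - 1))
        closing_end = min(max(closing_end, start), end)
        pause_end = min(max(pause_end, closing_end), end)
        gt.append(GroundTruthBlink(start, closing_end, pause_end, end))
    return frames, gt


#: Amplitude (px) of the fixational micro-saccades the default scene scripts
#: between blinks.  Real eyes are never still: the recordings this generator
#: emulates show constant small gaze shifts, and the dynamic closure threshold
#: (median of motion-episode peaks) relies on such small episodes to anchor
#: its median well below blink scale.
MICRO_SACCADE_AMP_PX = 8.0


def default_blink_video_config(
    n_blinks: int = 5,
    kinematics: BlinkKinematics | None = None,
    fps: float = 100.0,
    noise_sd: float = 0.0,
    lead_in_ms: float = 900.0,
    gap_ms: float = 700.0,
    seed: int = 0,
    saccades: tuple[tuple[float, Direction, float], ...] = (),
    fixational_saccades: bool = True,
) -> SynthConfig:
    """A standard test scene: ``n_blinks`` spontaneous blinks at 100 fps.

    The lead-in and inter-blink gaps leave enough motion-free time for the
    open-eye template to bootstrap and refresh (>= 500 ms).  Unless disabled,
    one small downward micro-saccade is scripted in the lead-in and in every
    inter-blink gap, emulating the fixational eye movement present in any real
    recording; extra ``saccades`` are appended verbatim.
    """
    kin = kinematics or spontaneous_defaults()
    schedule = []
    micro: list[tuple[float, Direction, float]] = []
    if fixational_saccades and lead_in_ms >= 900.0:
        micro.append((560.0, "down", MICRO_SACCADE_AMP_PX))
    t = lead_in_ms
    for _ in range(n_blinks):
        schedule.append((t, kin))
        blink_end = t + kin.total_ms
        if fixational_saccades:
            micro.append((blink_end + 120.0, "down", MICRO_SACCADE_AMP_PX))
        t = blink_end + gap_ms
    duration_s = (t + 400.0) / 1000.0
    return SynthConfig(
        fps=fps,
        duration_s=duration_s,
        blink_schedule=tuple(schedule),
        saccade_schedule=tuple(micro) + tuple(saccades),
        noise_sd=noise_sd,
        seed=seed,
    )
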