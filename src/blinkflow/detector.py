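"""Per-frame orchestration and the eyeblink finite state machine.

Each pair of successive frames is processed by two cooperating paths whose
results are both available before the state decision (in the reference sensor
they run on separate threads; here they are sequential — concurrency is an
optimization, not semantics):

1. *appearance*: localize the eye ROI and, when asked, compare it to the
   open-eye template by normalized cross-correlation;
2. *motion*: estimate dense flow, sample it on the marker grid, and compute
   the downward (DMV) or upward (UMV) motion vector depending on the current
   eye state.

The blink FSM has four states: S0 (initial, eye state unknown), S1 (eye open,
waiting for closure), S2 (candidate closure under verification — transient
within one frame step), S3 (verified blink, eye closed).  Allowed transitions
are S0->S1, S1->S2, S2->S1, S2->S3 and S3->S1.  While open, a DMV magnitude
above the dynamic threshold moves S1->S2 and triggers NCC verification: if the
ROI no longer matches the open-eye template the blink is registered (S2->S3,
eye closed) — this happens during the closing or pause phase, before
reopening.  While closed, a UMV magnitude above the reopening threshold — or,
failing that, an NCC match with the open-eye template — detects reopening
(S3->S1, eye open).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from blinkflow.config import RunConfig
from blinkflow.frameio import Frame, crop_frame
from blinkflow.localize import ROI, DarkBlobLocalizer, CascadeLocalizer, EyeLocalizer, localize_eye
from blinkflow.motion import (
    SampleGrid,
    downward_motion_vector,
    estimate_flow,
    make_sample_grid,
    sample_vectors,
    upward_motion_vector,
)
from blinkflow.threshold import ThresholdState, update_threshold
from blinkflow.verify import (
    Template,
    TemplateFsmState,
    TemplateState,
    is_closed,
    ncc,
    template_fsm_step,
)

__all__ = [
    "DetectorFsm",
    "EyeState",
    "DetectorState",
    "FrameRecord",
    "BlinkEvent",
    "Detector",
    "run_detector",
]

logger = logging.getLogger(__name__)


class DetectorFsm(enum.Enum):
    S0 = "S0"  #: initial state, eye state not yet known
    S1 = "S1"  #: eye open, waiting for eyelid closure
    S2 = "S2"  #: candidate closure, verification in progress
    S3 = "S3"  #: verified blink, eye closed


class EyeState(enum.Enum):
    UNKNOWN = "unknown"
    OPEN = "open"
    CLOSED = "closed"


@dataclass(frozen=True)
class DetectorState:
    fsm: DetectorFsm = DetectorFsm.S0
    eye_state: EyeState = EyeState.UNKNOWN
    threshold_state: ThresholdState = field(default_factory=ThresholdState.initial)
    template: Template | None = None
    last_roi: ROI | None = None
    template_fsm: TemplateFsmState = field(default_factory=TemplateFsmState)
    quiet_since_ms: float | None = None  #: start of the motion-free span used for template bootstrap

    def __post_init__(self) -> None:
        if self.fsm is DetectorFsm.S3 and self.eye_state is not EyeState.CLOSED:
            raise ValueError("FSM S3 requires eye_state CLOSED")
        if self.fsm is DetectorFsm.S1 and self.eye_state is not EyeState.OPEN:
            raise ValueError("FSM S1 requires eye_state OPEN")


@dataclass(frozen=True)
class FrameRecord:
    """Per-frame log entry (the annotation-file row)."""

    frame_number: int
    dmv_magnitude: float
    umv_magnitude: float
    eye_state: str
    blink_detected: bool
    roi_detected: bool

    def __post_init__(self) -> None:
        if self.dmv_magnitude < 0 or self.umv_magnitude < 0:
            raise ValueError("magnitudes must be >= 0")


@dataclass
class BlinkEvent:
    """One detected blink: DMV crossing, NCC confirmation, and reopening."""

    initial_frame: int
    verified_frame: int
    reopen_frame: int | None = None
    verification_q: float = 0.0

    def __post_init__(self) -> None:
        if not (self.initial_frame <= self.verified_frame):
            raise ValueError("initial_frame must be <= verified_frame")
        if self.reopen_frame is not None and not (self.verified_frame < self.reopen_frame):
            raise ValueError("reopen_frame must be > verified_frame")

    def interval(self) -> tuple[int, int]:
        return (self.initial_frame, self.reopen_frame if self.reopen_frame is not None else self.verified_frame)


def _default_localizer(config: RunConfig) -> EyeLocalizer:
    if config.cascade_model is not None:
        return CascadeLocalizer(config.cascade_model, selection=config.cascade_selection)
    return DarkBlobLocalizer(
        dark_threshold=config.dark_threshold,
        min_area=config.dark_min_area,
        margin=config.dark_margin,
    )


class Detector:
    """Stateful wrapper binding a configuration and a localizer backend.

    ``step`` is a pure transition on :class:`DetectorState`; the class itself
    only caches the sample grid and flow parameters.
    """

    def __init__(self, config: RunConfig | None = None, localizer: EyeLocalizer | None = None) -> None:
        self.config = config or RunConfig()
        self.localizer = localizer if localizer is not None else _default_localizer(self.config)
        self._grid: SampleGrid | None = None
        self._flow_params = self.config.flow_params()

    def _grid_for(self, frame: Frame) -> SampleGrid:
        if self._grid is None or self._grid.points[-1][0] >= frame.width or self._grid.points[-1][1] >= frame.height:
            self._grid = make_sample_grid(frame.width, frame.height, self.config.grid_spacing)
        return self._grid

    # ------------------------------------------------------------------ step
    def step(
        self, state: DetectorState, prev: Frame, curr: Frame
    ) -> tuple[DetectorState, FrameRecord, BlinkEvent | None]:
        """Process one frame transition; returns the successor state, the
        per-frame record, and a blink event if one was verified on this frame.

        Raises
        ------
        ValueError
            If the frames have different shapes.
        """
        cfg = self.config
        if prev.pixels.shape != curr.pixels.shape:
            raise ValueError("successive frames must have the same shape")

        grid = self._grid_for(curr)
        flow = estimate_flow(prev, curr, backend=cfg.flow_backend, params=self._flow_params)
        mvs = sample_vectors(flow, grid, frame_index=curr.index)

        # Appearance path: localize the eye; on failure reuse the last ROI.
        roi = localize_eye(curr, self.localizer)
        roi_detected = roi is not None
        if roi is None:
            roi = state.last_roi
        roi_patch = roi.extract(curr.pixels) if roi is not None else None

        def verification_patch(template: Template | None) -> np.ndarray | None:
            # Compare like with like: sample the current frame at the region
            # the template was captured from (the camera is rigidly mounted,
            # so the open-eye region moves only slowly; template refreshes
            # track that drift).  Fall back to the localized ROI.
            if template is not None and template.box is not None:
                x, y, w, h = template.box
                return curr.pixels[y : y + h, x : x + w]
            return roi_patch

        fsm = state.fsm
        eye_state = state.eye_state
        threshold_state = state.threshold_state
        template = state.template
        quiet_since = state.quiet_since_ms
        event: BlinkEvent | None = None
        reopening_detected = False
        dmv_mag = 0.0
        umv_mag = 0.0

        if eye_state in (EyeState.OPEN, EyeState.UNKNOWN):
            dmv = downward_motion_vector(mvs, criterion=cfg.downward_criterion)
            dmv_mag = dmv.magnitude

            if dmv_mag > threshold_state.current_threshold:
                # Candidate closure: S1 -> S2, verify against the template.
                vp = verification_patch(template)
                if template is None:
                    logger.warning(
                        "frame %d: closure candidate but no open-eye template yet; detection discarded",
                        curr.index,
                    )
                elif vp is None or vp.size == 0:
                    logger.warning(
                        "frame %d: closure candidate but no ROI available; detection discarded",
                        curr.index,
                    )
                else:
                    fsm = DetectorFsm.S2
                    q = ncc(vp, template, zero_mean=cfg.ncc_zero_mean)
                    if is_closed(q, cfg.ncc_threshold):
                        fsm = DetectorFsm.S3
                        eye_state = EyeState.CLOSED
                        event = BlinkEvent(
                            initial_frame=curr.index,
                            verified_frame=curr.index,
                            verification_q=q,
                        )
                    else:
                        fsm = DetectorFsm.S1
                        eye_state = EyeState.OPEN

            # The dynamic threshold consumes every frame on which the DMV was
            # computed (closing events end when the magnitude returns to zero).
            threshold_state = update_threshold(threshold_state, dmv_mag)

            # Template bootstrap: before any template exists, adopt the first
            # confidently localized ROI after a quiet (no downward motion)
            # span of the template wait time.
            if template is None:
                now = curr.timestamp_ms
                if dmv_mag > 0:
                    quiet_since = now
                elif quiet_since is None:
                    quiet_since = prev.timestamp_ms
                if (
                    template is None
                    and dmv_mag == 0
                    and roi_detected
                    and roi_patch is not None
                    and roi_patch.size > 0
                    and float((np.asarray(roi_patch, dtype=np.float64) ** 2).sum()) > 0
                    and now - quiet_since >= cfg.template_wait_ms
                ):
                    template = Template(
                        patch=roi_patch,
                        captured_at_frame=curr.index,
                        captured_at_ms=now,
                        box=(roi.x, roi.y, roi.w, roi.h),
                    )
                    if fsm is DetectorFsm.S0:
                        fsm = DetectorFsm.S1
                        eye_state = EyeState.OPEN

        else:  # EyeState.CLOSED — watch for reopening
            umv = upward_motion_vector(mvs)
            umv_mag = umv.magnitude
            reopen_thr = (
                cfg.reopening_threshold
                if cfg.reopening_threshold is not None
                else threshold_state.current_threshold
            )
            # Reopening means upward motion DOMINATES: while the lid is still
            # descending, flow artifacts can produce sizeable spurious upward
            # sums, but the concurrent downward sum dwarfs them; during a
            # genuine reopening the downward sum is near zero.  The downward
            # sum here serves only this comparison — it never feeds the
            # dynamic threshold, which adapts on open-eye frames alone.
            dmv_closed = downward_motion_vector(mvs, criterion=cfg.downward_criterion)
            if umv_mag > reopen_thr and umv_mag > dmv_closed.magnitude:
                reopening_detected = True
            elif template is not None:
                # Secondary reinitialisation: the eye region looking like the
                # open-eye template again also signals reopening.
                vp = verification_patch(template)
                if vp is not None and vp.size > 0 and float((vp.astype(np.float64) ** 2).sum()) > 0:
                    q = ncc(vp, template, zero_mean=cfg.ncc_zero_mean)
                    if not is_closed(q, cfg.ncc_threshold):
                        reopening_detected = True
            if reopening_detected:
                fsm = DetectorFsm.S1
                eye_state = EyeState.OPEN

        # Template refresh machine (post-reopening wait, then recapture).
        tfsm, new_template = template_fsm_step(
            state.template_fsm,
            reopening_detected=reopening_detected,
            now_ms=curr.timestamp_ms,
            eye_open=eye_state is EyeState.OPEN,
            current_roi=roi_patch if roi_detected else None,
            frame_index=curr.index,
            wait_ms=cfg.template_wait_ms,
        )
        if new_template is not None and float((new_template.patch**2).sum()) > 0:
            # Conservative update: adopt the refresh only while the current
            # frame still scores "open" inside the EXISTING template's box.
            # A capture taken with the gaze displaced (e.g. mid-fixation after
            # a saccade) carries a displaced box; adopting it would poison
            # every subsequent verification, because even the resting open eye
            # then scores below the closure threshold at that box.
            if template is None:
                accept = True
            else:
                vp_old = verification_patch(template)
                accept = (
                    vp_old is not None
                    and vp_old.size > 0
                    and float((vp_old.astype(np.float64) ** 2).sum()) > 0
                    and ncc(vp_old, template, zero_mean=cfg.ncc_zero_mean)
                    >= cfg.template_refresh_min_q
                )
            if accept:
                box = (roi.x, roi.y, roi.w, roi.h) if roi_detected and roi is not None else (
                    template.box if template is not None else None
                )
                template = Template(
                    patch=new_template.patch,
                    captured_at_frame=new_template.captured_at_frame,
                    captured_at_ms=new_template.captured_at_ms,
                    box=box,
                )
            else:
                logger.info(
                    "frame %d: template refresh rejected (capture dissimilar to current template)",
                    curr.index,
                )

        new_state = DetectorState(
            fsm=fsm,
            eye_state=eye_state,
            threshold_state=threshold_state,
            template=template,
            last_roi=roi if roi is not None else state.last_roi,
            template_fsm=tfsm,
            quiet_since_ms=quiet_since,
        )
        record = FrameRecord(
            frame_number=curr.index,
            dmv_magnitude=dmv_mag,
            umv_magnitude=umv_mag,
            eye_state=eye_state.value,
            blink_detected=event is not None,
            roi_detected=roi_detected,
        )
        return new_state, record, event


def run_detector(
    frames: Iterable[Frame],
    config: RunConfig | None = None,
    localizer: EyeLocalizer | None = None,
    precropped: bool = False,
) -> tuple[list[FrameRecord], list[BlinkEvent]]:
    """Fold the per-frame step over a frame stream.

    Frames are cropped per the configuration unless ``precropped`` is set.
    Deterministic given the frames and the configuration.  Returns the
    per-frame records (one per transition, i.e. ``len(frames) - 1``) and the
    verified blink events with their reopening frames filled in when a
    reopening was observed.

    Raises
    ------
    ValueError
        If fewer than two frames are supplied.
    """
    cfg = config or RunConfig()
    det = Detector(cfg, localizer)
    state = DetectorState(threshold_state=ThresholdState.initial(cfg.threshold_window_n, cfg.initial_threshold))

    records: list[FrameRecord] = []
    events: list[BlinkEvent] = []
    open_event: BlinkEvent | None = None

    prev: Frame | None = None
    n = 0
    for frame in frames:
        n += 1
        if not precropped and cfg.crop_px:
            frame = crop_frame(frame, cfg.crop_px, cfg.crop_edge)  # type: ignore[arg-type]
        if prev is not None:
            was_closed = state.eye_state is EyeState.CLOSED
            state, record, event = det.step(state, prev, frame)
            records.append(record)
            if event is not None:
                events.append(event)
                open_event = event
            reopened = was_closed and state.eye_state is EyeState.OPEN
            if reopened and open_event is not None:
                open_event.reopen_frame = frame.index
                open_event = None
        prev = frame
    if n < 2:
        raise ValueError("run_detector requires at least 2 frames")
    return records, events
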