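"""Eyelid-closure verification by normalized cross-correlation (NCC).

A candidate closure flagged by the downward motion vector is confirmed by
comparing the current eye ROI against a template image of the open eye:

    Q = sum(f * t) / sqrt(sum(f^2) * sum(t^2))

For the non-negative intensities of camera frames this similarity lies in
[0, 1]; Q near 1 means the ROI still looks like the open-eye template, and a
value strictly below the verification threshold registers the eye as closed.
An optional zero-mean variant subtracts each patch's mean first (giving the
signed correlation coefficient in [-1, 1]).

The open-eye template is captured automatically by a small state machine: after
a reopening is detected the machine waits 500 ms (long enough for every blink
phase — and a possible double blink — to finish), then, if the eye is open,
adopts the current ROI as the new template.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "Template",
    "TemplateFsmState",
    "TemplateState",
    "ncc",
    "is_closed",
    "template_fsm_step",
    "TEMPLATE_WAIT_MS",
]

#: Delay between a detected reopening and template capture (ms).
TEMPLATE_WAIT_MS = 500.0


@dataclass(frozen=True)
class Template:
    """An open-eye reference patch and when/where it was captured.

    ``box`` records the frame region the patch was extracted from (an
    ``(x, y, w, h)`` tuple); verification samples later frames at this same
    region, so the template and candidate always cover the same scene area.
    """

    patch: np.ndarray
    captured_at_frame: int = 0
    captured_at_ms: float = 0.0
    box: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        patch = np.asarray(self.patch, dtype=np.float64)
        if patch.size == 0:
            raise ValueError("template patch must be non-empty")
        if float((patch**2).sum()) <= 0.0:
            raise ValueError("template patch must have nonzero intensity energy")
        object.__setattr__(self, "patch", patch)


class TemplateState(enum.Enum):
    """States of the template-selection machine.

    S0 initial; S1 waiting for a reopening; S2 timing the post-reopening wait;
    S3 checking the eye state; S5 template accepted (terminal for one capture
    cycle — the machine restarts at S1 for subsequent refreshes).
    """

    S0 = "S0"
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S5 = "S5"


@dataclass(frozen=True)
class TemplateFsmState:
    state: TemplateState = TemplateState.S0
    wait_started_ms: float | None = None

    def __post_init__(self) -> None:
        if (self.state is TemplateState.S2) != (self.wait_started_ms is not None):
            raise ValueError("wait_started_ms must be set exactly in state S2")


def ncc(roi_image: np.ndarray, template: Template, zero_mean: bool = False) -> float:
    """Normalized cross-correlation between the current ROI and the template.

    The ROI is resampled (bilinear) to the template's shape if needed.  With
    ``zero_mean=False`` (default) raw intensities are correlated, giving
    Q in [0, 1] for non-negative images; with ``zero_mean=True`` patch means
    are subtracted first, giving the signed coefficient in [-1, 1].

    Raises
    ------
    ValueError
        If either patch has zero energy (normalization undefined).
    """
    f = np.asarray(roi_image, dtype=np.float64)
    t = template.patch
    if f.size == 0:
        raise ValueError("roi_image must be non-empty")
    if f.shape != t.shape:
        f = resize(f, t.shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    if zero_mean:
        f = f - f.mean()
        t = t - t.mean()
    ef = float((f**2).sum())
    et = float((t**2).sum())
    if ef <= 0.0 or et <= 0.0:
        raise ValueError("NCC undefined for zero-energy input")
    return float((f * t).sum() / math.sqrt(ef * et))


def is_closed(q: float, ncc_threshold: float = 0.80) -> bool:
    """True iff the correlation is strictly under the verification threshold.

    Raises
    ------
    ValueError
        If ``ncc_threshold`` is outside (0, 1).
    """
    if not 0.0 < ncc_threshold < 1.0:
        raise ValueError("ncc_threshold must lie in (0, 1)")
    return q < ncc_threshold


def template_fsm_step(
    state: TemplateFsmState,
    *,
    reopening_detected: bool,
    now_ms: float,
    eye_open: bool,
    current_roi: np.ndarray | None,
    frame_index: int = 0,
    wait_ms: float = TEMPLATE_WAIT_MS,
) -> tuple[TemplateFsmState, Template | None]:
    """Advance the template-selection machine by one frame.

    Transitions: S0 -> S1 on start; S1 -> S2 when a reopening is detected
    (recording the wait start time); S2 -> S3 once ``wait_ms`` have elapsed;
    S3 -> S1 if the eye is closed, otherwise the current ROI is emitted as the
    new open-eye template and the machine moves to S5, from which the next
    step restarts at S1.  At most one template is emitted per call.
    """
    s = state.state
    if s is TemplateState.S0:
        return TemplateFsmState(TemplateState.S1), None
    if s is TemplateState.S5:
        state = TemplateFsmState(TemplateState.S1)
        s = TemplateState.S1
    if s is TemplateState.S1:
        if reopening_detected:
            return TemplateFsmState(TemplateState.S2, wait_started_ms=now_ms), None
        return state, None
    if s is TemplateState.S2:
        if now_ms - state.wait_started_ms >= wait_ms:
            state = TemplateFsmState(TemplateState.S3)
            s = TemplateState.S3
        else:
            return state, None
    if s is TemplateState.S3:
        if not eye_open:
            return TemplateFsmState(TemplateState.S1), None
        if current_roi is None or np.asarray(current_roi).size == 0:
            # Nothing usable to capture; try again next frame.
            return state, None
        tmpl = Template(patch=current_roi, captured_at_frame=frame_index, captured_at_ms=now_ms)
        return TemplateFsmState(TemplateState.S5), tmpl
    return state, None  # pragma: no cover
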