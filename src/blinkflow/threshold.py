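"""Dynamic eyelid-closure detection threshold.

The closure threshold adapts to each wearer and session: while the DMV
magnitude is positive the per-frame magnitudes accumulate (one closing event);
when it falls back to zero the event's peak magnitude is recorded, and the
threshold becomes the median of the peaks of the most recent blinks.  The
median makes the threshold robust to the occasional outlier peak (for example
a vigorous voluntary blink or a vertical saccade that produced downward flow).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ThresholdState", "update_threshold", "median"]

#: Number of per-blink peaks retained in the history window.
DEFAULT_WINDOW_N = 10
#: Threshold used before the first closing event completes (px).  A genuine
#: closure sums dozens of grid vectors of several px each (thousands of px in
#: total), while flow noise over the 544-marker grid can reach tens of px, so
#: the pre-calibration cut-off sits between those scales.
DEFAULT_INITIAL_THRESHOLD = 50.0


def median(values: list[float]) -> float:
    """Median per the order-statistic definition used by the threshold update.

    Values are sorted increasing; the middle element is returned for an odd
    count, the mean of the two middle elements for an even count.

    Raises
    ------
    ValueError
        If ``values`` is empty.
    """
    if not values:
        raise ValueError("median of an empty list is undefined")
    s = sorted(values)
    c = len(s)
    if c % 2 == 1:
        return float(s[c // 2])
    return 0.5 * (s[c // 2 - 1] + s[c // 2])


@dataclass(frozen=True)
class ThresholdState:
    """Running state of the dynamic closure threshold.

    Attributes
    ----------
    current_blink_mags : tuple of float
        Positive DMV magnitudes of the ongoing closing event.
    peak_history : tuple of float
        Peak DMV magnitude of each of the most recent closing events, oldest
        first, at most ``window_n`` entries.
    window_n : int
        History capacity.
    current_threshold : float
        The active closure threshold in pixels: the median of
        ``peak_history``, or ``initial_threshold`` before any event completed.
    """

    current_blink_mags: tuple[float, ...] = ()
    peak_history: tuple[float, ...] = ()
    window_n: int = DEFAULT_WINDOW_N
    initial_threshold: float = DEFAULT_INITIAL_THRESHOLD
    current_threshold: float = DEFAULT_INITIAL_THRESHOLD

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if self.current_threshold <= 0 or self.initial_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if len(self.peak_history) > self.window_n:
            raise ValueError("peak_history exceeds window_n")

    @classmethod
    def initial(cls, window_n: int = DEFAULT_WINDOW_N, initial_threshold: float = DEFAULT_INITIAL_THRESHOLD) -> "ThresholdState":
        return cls(
            window_n=window_n,
            initial_threshold=initial_threshold,
            current_threshold=initial_threshold,
        )


def update_threshold(state: ThresholdState, dmv_magnitude: float) -> ThresholdState:
    """Fold one frame's DMV magnitude into the threshold state.

    A positive magnitude extends the ongoing closing event.  A non-positive
    magnitude ends it: the event's peak joins the history (evicting the oldest
    entry beyond ``window_n``) and the threshold becomes the history median.
    A non-positive magnitude with no ongoing event leaves the state unchanged.

    Raises
    ------
    ValueError
        If ``dmv_magnitude`` is negative (magnitudes are norms).
    """
    if dmv_magnitude < 0:
        raise ValueError("dmv_magnitude must be >= 0")
    if dmv_magnitude > 0:
        return replace(state, current_blink_mags=state.current_blink_mags + (dmv_magnitude,))
    if not state.current_blink_mags:
        return state
    peak = max(state.current_blink_mags)
    history = (state.peak_history + (peak,))[-state.window_n :]
    return replace(
        state,
        current_blink_mags=(),
        peak_history=history,
        current_threshold=median(list(history)),
    )
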