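"""Published validation counts for the non-frontal VR eye-monitoring dataset.

The detector was originally validated on a 12-participant dataset of
headset-internal eye recordings (deposited on Mendeley Data,
DOI 10.17632/9yzdnng594.1).  This module ships the raw outcome counts of that
validation — per-sample frame tallies for eye-localization hit rate, and
per-sample blink detection counts (TP/FN/FP) — so that every derived quantity
(hit rates and their mean, precision/recall/accuracy/FDR and their means) can
be recomputed from first principles without the video data.

Only raw counts live here; all derived values are computed by
:mod:`blinkflow.localize` and :mod:`blinkflow.evaluate`.
"""

from __future__ import annotations

from blinkflow.evaluate import EvalCounts
from blinkflow.localize import LocalizationTally

__all__ = ["LOCALIZATION_TALLIES", "DETECTION_COUNTS", "detection_counts"]

#: Per-sample (total frames, frames with a localized ROI) of the
#: eye-localization validation, samples S1-S9.
LOCALIZATION_TALLIES: dict[str, LocalizationTally] = {
    "S1": LocalizationTally(total_frames=31071, localized_frames=31071),
    "S2": LocalizationTally(total_frames=32230, localized_frames=32230),
    "S3": LocalizationTally(total_frames=41388, localized_frames=40972),
    "S4": LocalizationTally(total_frames=8720, localized_frames=8719),
    "S5": LocalizationTally(total_frames=34355, localized_frames=34354),
    "S6": LocalizationTally(total_frames=20460, localized_frames=20459),
    "S7": LocalizationTally(total_frames=32074, localized_frames=32055),
    "S8": LocalizationTally(total_frames=11278, localized_frames=11277),
    "S9": LocalizationTally(total_frames=57556, localized_frames=57556),
}

#: Per-sample blink detection outcomes (tp, fn, fp), samples S1-S12.
#: GT and DB follow as tp + fn and tp + fp.
DETECTION_COUNTS: dict[str, tuple[int, int, int]] = {
    "S1": (19, 2, 2),
    "S2": (82, 11, 8),
    "S3": (56, 5, 5),
    "S4": (14, 5, 1),
    "S5": (45, 6, 3),
    "S6": (58, 6, 4),
    "S7": (12, 2, 4),
    "S8": (8, 0, 0),
    "S9": (210, 22, 32),
    "S10": (160, 9, 5),
    "S11": (99, 6, 6),
    "S12": (186, 7, 10),
}


def detection_counts() -> dict[str, EvalCounts]:
    """The per-sample outcome counts as :class:`EvalCounts` records."""
    return {
        name: EvalCounts.from_counts(tp=tp, fn=fn, fp=fp)
        for name, (tp, fn, fp) in DETECTION_COUNTS.items()
    }
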