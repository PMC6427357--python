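"""Detector evaluation: annotation I/O, GT matching, metrics, kinematics.

Detections are matched to ground-truth blink intervals by temporal overlap
(one-to-one, greedy in temporal order): a detection overlapping a not yet
matched ground-truth interval is a true positive (TP), unmatched detections
are false positives (FP), unmatched ground-truth blinks are false negatives
(FN).  From the counts:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    FDR       = FP / (FP + TP)
    accuracy  = TP / (TP + FP + FN)

Kinematics helpers compute blink-phase budgets (total duration, per-phase
percentage) and the minimum camera frame rate needed to never skip the
shortest phase (one frame period <= the pause duration).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from blinkflow.detector import FrameRecord
from blinkflow.synth import BlinkKinematics

__all__ = [
    "EvalCounts",
    "Metrics",
    "PhaseBreakdown",
    "match_detections",
    "compute_metrics",
    "mean_metrics",
    "phase_breakdown",
    "required_fps",
    "frame_period_ms",
    "write_annotations",
    "read_annotations",
    "records_from_annotations",
    "ANNOTATION_COLUMNS",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class EvalCounts:
    """Blink-detection outcome counts for one sample."""

    gt: int   #: actual blinks in the sample
    tp: int   #: detections intersecting a ground-truth blink
    fn: int   #: ground-truth blinks with no detection
    fp: int   #: detections intersecting no ground-truth blink
    db: int   #: total detections (tp + fp)

    def __post_init__(self) -> None:
        if min(self.gt, self.tp, self.fn, self.fp, self.db) < 0:
            raise ValueError("counts must be non-negative")
        if self.db != self.tp + self.fp:
            raise ValueError("db must equal tp + fp")
        if self.gt != self.tp + self.fn:
            raise ValueError("gt must equal tp + fn")

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int) -> "EvalCounts":
        return cls(gt=tp + fn, tp=tp, fn=fn, fp=fp, db=tp + fp)


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Decimal round-half-up (0.0625 -> 0.063), the convention of reported
    metric tables, unlike Python's banker's rounding."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    """Detection metrics; a field is ``None`` when its denominator is zero."""

    precision: float | None
    recall: float | None
    accuracy: float | None
    fdr: float | None

    def rounded(self, ndigits: int = 3) -> "Metrics":
        r = lambda v: None if v is None else round_half_up(v, ndigits)
        return Metrics(r(self.precision), r(self.recall), r(self.accuracy), r(self.fdr))


def _overlaps(a: Interval, b: Interval, slack: int) -> bool:
    return a[0] <= b[1] + slack and b[0] <= a[1] + slack


def match_detections(
    gt_intervals: Sequence[Interval],
    detected_intervals: Sequence[Interval],
    slack_frames: int = 0,
) -> EvalCounts:
    """Greedy one-to-one matching of detections to ground-truth intervals.

    Intervals are inclusive ``(start_frame, end_frame)`` pairs.  Detections
    are processed in temporal order; each claims the earliest still-unmatched
    overlapping ground-truth interval (within ``slack_frames`` of temporal
    slack).  A second detection overlapping an already claimed blink counts as
    a false positive.  The result is invariant to the input ordering of the
    detections.
    """
    gt = sorted(tuple(g) for g in gt_intervals)
    det = sorted(tuple(d) for d in detected_intervals)
    matched = [False] * len(gt)
    tp = 0
    for d in det:
        for i, g in enumerate(gt):
            if not matched[i] and _overlaps(g, d, slack_frames):
                matched[i] = True
                tp += 1
                break
    fp = len(det) - tp
    fn = len(gt) - tp
    return EvalCounts.from_counts(tp=tp, fn=fn, fp=fp)


def compute_metrics(counts: EvalCounts) -> Metrics:
    """Precision, recall, accuracy and FDR from outcome counts.

    Full precision is retained; round only at reporting time (conventionally
    3 decimals).  Any metric with a zero denominator is ``None``.
    """
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    recall = tp / (tp + fn) if tp + fn > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None
    fdr = fp / (fp + tp) if fp + tp > 0 else None
    accuracy = tp / (tp + fp + fn) if tp + fp + fn > 0 else None
    return Metrics(precision=precision, recall=recall, accuracy=accuracy, fdr=fdr)


def mean_metrics(per_sample: Sequence[Metrics]) -> Metrics:
    """Unweighted mean of per-sample metrics (samples with defined values)."""

    def mean_of(attr: str) -> float | None:
        vals = [getattr(m, attr) for m in per_sample if getattr(m, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return Metrics(
        precision=mean_of("precision"),
        recall=mean_of("recall"),
        accuracy=mean_of("accuracy"),
        fdr=mean_of("fdr"),
    )


# --------------------------------------------------------------------------
# Blink kinematics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseBreakdown:
    """Phase durations and their share of the total blink duration."""

    closing_ms: float
    pause_ms: float
    reopening_ms: float
    total_ms: float
    closing_pct: float
    pause_pct: float
    reopening_pct: float


def phase_breakdown(k: BlinkKinematics) -> PhaseBreakdown:
    """Total blink duration and per-phase percentages.

    The total is the sum of the three phase durations; each percentage is
    ``100 * phase / total``.  Values are unrounded; report percentages to one
    decimal.
    """
    total = k.closing_ms + k.pause_ms + k.reopening_ms
    return PhaseBreakdown(
        closing_ms=k.closing_ms,
        pause_ms=k.pause_ms,
        reopening_ms=k.reopening_ms,
        total_ms=total,
        closing_pct=100.0 * k.closing_ms / total,
        pause_pct=100.0 * k.pause_ms / total,
        reopening_pct=100.0 * k.reopening_ms / total,
    )


def frame_period_ms(fps: float) -> float:
    """Time between successive frames at the given rate (ms)."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    return 1000.0 / fps


def required_fps(pause_ms: float) -> int:
    """Minimum capture rate whose frame period does not exceed the pause.

    The pause is the shortest blink phase; a camera sampling slower than one
    frame per pause duration can miss the fully closed eye entirely.  For the
    13.7 ms spontaneous pause this gives 73 fps.
    """
    if pause_ms <= 0:
        raise ValueError("pause_ms must be > 0")
    return int(round(1000.0 / pause_ms))


# --------------------------------------------------------------------------
# Annotation files
# --------------------------------------------------------------------------

#: Mandatory per-frame log columns.
ANNOTATION_COLUMNS = [
    "frame_number",
    "dmv_magnitude",
    "umv_magnitude",
    "eye_state",
    "blink_detected",
    "roi_detected",
]
#: Optional columns added during manual review.
OPTIONAL_COLUMNS = ["ground_truth", "category"]


def write_annotations(
    records: Sequence[FrameRecord],
    path: str | Path,
    ground_truth: Sequence[bool] | None = None,
    categories: Sequence[str] | None = None,
) -> None:
    """Write per-frame records as a CSV annotation file.

    ``ground_truth`` (per-frame blink flag) and ``categories`` (TP/FP/FN
    labels) are the manually reviewed columns; omit them for fresh detector
    output.
    """
    df = pd.DataFrame(
        {
            "frame_number": [r.frame_number for r in records],
            "dmv_magnitude": [r.dmv_magnitude for r in records],
            "umv_magnitude": [r.umv_magnitude for r in records],
            "eye_state": [r.eye_state for r in records],
            "blink_detected": [r.blink_detected for r in records],
            "roi_detected": [r.roi_detected for r in records],
        }
    )
    if ground_truth is not None:
        df["ground_truth"] = list(ground_truth)
    if categories is not None:
        df["category"] = list(categories)
    # %.17g keeps the magnitude columns lossless across a write/read cycle.
    df.to_csv(path, index=False, float_format="%.17g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV, validating the mandatory schema.

    Raises
    ------
    ValueError
        Naming the first missing mandatory column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation file {path} is missing mandatory column {col!r}")
    df["blink_detected"] = df["blink_detected"].astype(bool)
    df["roi_detected"] = df["roi_detected"].astype(bool)
    return df


def records_from_annotations(df: pd.DataFrame) -> list[FrameRecord]:
    """Reconstruct :class:`FrameRecord` rows from an annotation table."""
    return [
        FrameRecord(
            frame_number=int(row.frame_number),
            dmv_magnitude=float(row.dmv_magnitude),
            umv_magnitude=float(row.umv_magnitude),
            eye_state=str(row.eye_state),
            blink_detected=bool(row.blink_detected),
            roi_detected=bool(row.roi_detected),
        )
        for row in df.itertuples()
    ]
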