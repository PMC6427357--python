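"""Eye region-of-interest (ROI) localization.

Two interchangeable backends find the eye in a frame:

``DarkBlobLocalizer`` (default)
    Exploits the darkness of the pupil/iris under near-infrared illumination:
    pixels below an intensity threshold are grouped into connected components,
    and the bounding box of the largest sufficiently large dark blob — padded
    by a margin — is returned.  Self-contained, used for synthetic fixtures
    and as the shipped fallback.

``CascadeLocalizer``
    A boosted-cascade sliding-window detector that consumes a model file in
    the standard cascade-XML stages format (axis-aligned Haar-like rectangle
    features, decision-stump weak classifiers, variance-normalized windows).
    Training such a model is out of scope; any pretrained file with that
    schema can be loaded.

Localization quality over a stream is summarized by the hit rate: the fraction
of frames in which an ROI was found.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from scipy import ndimage

from blinkflow.frameio import Frame

__all__ = [
    "ROI",
    "LocalizationTally",
    "EyeLocalizer",
    "DarkBlobLocalizer",
    "CascadeLocalizer",
    "localize_eye",
    "hit_rate",
]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned eye bounding box in image coordinates (origin top-left)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI extent must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI corner must be non-negative")

    def clip(self, width: int, height: int) -> "ROI":
        x = min(self.x, width - 1)
        y = min(self.y, height - 1)
        return ROI(x, y, min(self.w, width - x), min(self.h, height - y))

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.y : self.y + self.h, self.x : self.x + self.w]

    def iou(self, other: "ROI") -> float:
        x1 = max(self.x, other.x)
        y1 = max(self.y, other.y)
        x2 = min(self.x + self.w, other.x + other.w)
        y2 = min(self.y + self.h, other.y + other.h)
        inter = max(0, x2 - x1) * max(0, y2 - y1)
        union = self.w * self.h + other.w * other.h - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class LocalizationTally:
    """Counts entering the hit-rate computation."""

    total_frames: int
    localized_frames: int

    def __post_init__(self) -> None:
        if self.total_frames < 0 or self.localized_frames < 0:
            raise ValueError("counts must be non-negative")
        if self.localized_frames > self.total_frames:
            raise ValueError("localized_frames cannot exceed total_frames")


def hit_rate(tally: LocalizationTally) -> float:
    """Fraction of frames in which the ROI was localized.

    Raises
    ------
    ValueError
        If the tally covers zero frames.
    """
    if tally.total_frames == 0:
        raise ValueError("hit rate undefined for zero frames")
    return tally.localized_frames / tally.total_frames


class EyeLocalizer(Protocol):
    def detect(self, pixels: np.ndarray) -> ROI | None: ...


class DarkBlobLocalizer:
    """Bounding box of the largest connected dark region (the pupil/iris).

    Parameters
    ----------
    dark_threshold : int
        Intensity below which a pixel counts as dark.
    min_area : int
        Smallest blob area (px^2) accepted as an eye; rejects specks.
    margin : float
        Fractional padding added around the blob bounding box on each side,
        so the ROI includes some lid/sclera context for verification.
    """

    def __init__(self, dark_threshold: int = 80, min_area: int = 30, margin: float = 0.1) -> None:
        self.dark_threshold = dark_threshold
        self.min_area = min_area
        self.margin = margin

    def detect(self, pixels: np.ndarray) -> ROI | None:
        mask = np.asarray(pixels) < self.dark_threshold
        if not mask.any():
            return None
        labels, n = ndimage.label(mask)
        if n == 0:
            return None
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        if sizes[best - 1] < self.min_area:
            return None
        ys, xs = np.nonzero(labels == best)
        x0, x1 = int(xs.min()), int(xs.max())
        y0, y1 = int(ys.min()), int(ys.max())
        mx = int(round((x1 - x0 + 1) * self.margin))
        my = int(round((y1 - y0 + 1) * self.margin))
        h, w = np.asarray(pixels).shape
        x0 = max(0, x0 - mx)
        y0 = max(0, y0 - my)
        x1 = min(w - 1, x1 + mx)
        y1 = min(h - 1, y1 + my)
        return ROI(x0, y0, x1 - x0 + 1, y1 - y0 + 1)


@dataclass(frozen=True)
class _HaarRect:
    x: int
    y: int
    w: int
    h: int
    weight: float


@dataclass(frozen=True)
class _Stump:
    feature: int
    threshold: float
    left: float
    right: float


@dataclass(frozen=True)
class _Stage:
    threshold: float
    stumps: tuple[_Stump, ...]


class CascadeLocalizer:
    """Boosted cascade of Haar-like features, loaded from a cascade-XML file.

    Candidate windows are scanned over a scale pyramid; for each window the
    weighted rectangle sums of every queried feature are read from an integral
    image and variance-normalized, stumps vote per stage, and the window is
    rejected at the first stage whose vote sum falls below the stage threshold.
    Among accepted windows the one selected by ``selection`` is returned.

    Parameters
    ----------
    model_path : path to a cascade XML file (``<cascade>`` stages schema).
    scale_factor : multiplicative window growth between pyramid scales.
    step_frac : window step as a fraction of the current window size.
    selection : ``"largest"`` (default) or ``"best"`` (highest final-stage
        vote sum), deciding among multiple accepted candidates.
    """

    def __init__(
        self,
        model_path: str | Path,
        scale_factor: float = 1.25,
        step_frac: float = 0.125,
        selection: str = "largest",
    ) -> None:
        if selection not in ("largest", "best"):
            raise ValueError("selection must be 'largest' or 'best'")
        self.scale_factor = scale_factor
        self.step_frac = step_frac
        self.selection = selection
        self._load(Path(model_path))

    def _load(self, path: Path) -> None:
        try:
            root = ET.parse(path).getroot()
            cascade = root.find("cascade")
            if cascade is None:
                raise ValueError("no <cascade> element")
            self.win_w = int(cascade.findtext("width"))
            self.win_h = int(cascade.findtext("height"))
            stages = []
            for st in cascade.find("stages"):
                thr = float(st.findtext("stageThreshold"))
                stumps = []
                for wc in st.find("weakClassifiers"):
                    nodes = wc.findtext("internalNodes").split()
                    leaves = [float(v) for v in wc.findtext("leafValues").split()]
                    # internalNodes: left right featureIdx nodeThreshold
                    stumps.append(
                        _Stump(
                            feature=int(nodes[2]),
                            threshold=float(nodes[3]),
                            left=leaves[0],
                            right=leaves[1],
                        )
                    )
                stages.append(_Stage(threshold=thr, stumps=tuple(stumps)))
            self.stages = tuple(stages)
            feats = []
            for ft in cascade.find("features"):
                rects = []
                for r in ft.find("rects"):
                    vals = r.text.split()
                    rects.append(
                        _HaarRect(int(vals[0]), int(vals[1]), int(vals[2]), int(vals[3]), float(vals[4]))
                    )
                feats.append(tuple(rects))
            self.features = tuple(feats)
        except (OSError, ET.ParseError, TypeError, ValueError, AttributeError) as exc:
            raise ValueError(f"cannot load cascade model {path}: {exc}") from exc
        if not self.stages or not self.features:
            raise ValueError(f"cascade model {path} has no stages or features")

    @staticmethod
    def _integrals(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.asarray(pixels, dtype=np.float64)
        ii = np.zeros((f.shape[0] + 1, f.shape[1] + 1))
        ii[1:, 1:] = f.cumsum(0).cumsum(1)
        sq = np.zeros_like(ii)
        sq[1:, 1:] = (f * f).cumsum(0).cumsum(1)
        return ii, sq

    @staticmethod
    def _rect_sum(ii: np.ndarray, x: int, y: int, w: int, h: int) -> float:
        return ii[y + h, x + w] - ii[y, x + w] - ii[y + h, x] + ii[y, x]

    def _window_passes(self, ii, sq, x, y, scale) -> float | None:
        w = int(round(self.win_w * scale))
        h = int(round(self.win_h * scale))
        area = w * h
        total = self._rect_sum(ii, x, y, w, h)
        total_sq = self._rect_sum(sq, x, y, w, h)
        mean = total / area
        var = max(total_sq / area - mean * mean, 0.0)
        norm = max(np.sqrt(var), 1e-6) * area
        score = 0.0
        for stage in self.stages:
            score = 0.0
            for stump in stage.stumps:
                fval = 0.0
                for r in self.features[stump.feature]:
                    rx = x + int(round(r.x * scale))
                    ry = y + int(round(r.y * scale))
                    rw = max(1, int(round(r.w * scale)))
                    rh = max(1, int(round(r.h * scale)))
                    fval += r.weight * self._rect_sum(ii, rx, ry, rw, rh)
                fval /= norm
                score += stump.left if fval < stump.threshold else stump.right
            if score < stage.threshold:
                return None
        return score

    def detect(self, pixels: np.ndarray) -> ROI | None:
        pixels = np.asarray(pixels)
        H, W = pixels.shape
        ii, sq = self._integrals(pixels)
        candidates: list[tuple[float, ROI]] = []
        scale = 1.0
        while self.win_w * scale <= W and self.win_h * scale <= H:
            w = int(round(self.win_w * scale))
            h = int(round(self.win_h * scale))
            step = max(1, int(round(w * self.step_frac)))
            for y in range(0, H - h + 1, step):
                for x in range(0, W - w + 1, step):
                    score = self._window_passes(ii, sq, x, y, scale)
                    if score is not None:
                        candidates.append((score, ROI(x, y, w, h)))
            scale *= self.scale_factor
        if not candidates:
            return None
        if self.selection == "best":
            return max(candidates, key=lambda c: c[0])[1]
        return max(candidates, key=lambda c: c[1].w * c[1].h)[1]


def localize_eye(frame: Frame | np.ndarray, detector: EyeLocalizer) -> ROI | None:
    """Run the localizer on a frame, clipping the result to the frame extent."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    roi = detector.detect(pixels)
    if roi is None:
        return None
    return roi.clip(pixels.shape[1], pixels.shape[0])
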