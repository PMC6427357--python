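"""Frame input: video/image-sequence reading, grayscale conversion, cropping.

Image coordinates follow the usual convention for camera frames: origin at the
top-left corner, x increasing rightward, y increasing downward.  All frames are
single-channel 8-bit.  The nominal input is a portrait 240 (w) x 320 (h) eye
view; the leftmost 70-pixel band images the headset interior and carries no eye
information, so the default preprocessing crops it, leaving 170 x 320.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Literal

import imageio.v3 as iio
import numpy as np

__all__ = ["Frame", "crop_frame", "read_frames", "frames_from_arrays"]

Edge = Literal["left", "right", "top", "bottom"]

#: Width in pixels of the band at the frame edge that images the inside of the
#: headset rather than the eye; removed before any processing.
DEFAULT_CROP_PX = 70

_IMAGE_SUFFIXES = {".png", ".pgm", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class Frame:
    """A single grayscale video frame.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (height, width)
        Intensities, row-major (y down).
    index : int
        Ordinal frame number, starting at 0.
    timestamp_ms : float
        Milliseconds since stream start (``index * 1000 / fps`` for
        constant-rate streams).
    """

    pixels: np.ndarray
    index: int = 0
    timestamp_ms: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError(f"frame pixels must be a non-empty 2D grid, got shape {px.shape}")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def crop_frame(frame: Frame, crop_px: int = DEFAULT_CROP_PX, edge: Edge = "left") -> Frame:
    """Remove a ``crop_px``-wide band at the given frame edge.

    The default removes the left 70 px of the portrait view (the headset
    interior), reducing a 240 x 320 frame to 170 x 320.  All remaining pixels
    are preserved bit-exactly; ``crop_px=0`` returns an identical frame.

    Raises
    ------
    ValueError
        If ``crop_px`` is negative or not smaller than the cropped dimension.
    """
    if crop_px < 0:
        raise ValueError("crop_px must be >= 0")
    limit = frame.width if edge in ("left", "right") else frame.height
    if crop_px >= limit:
        raise ValueError(f"crop_px={crop_px} must be < {limit} for edge={edge!r}")
    if crop_px == 0:
        return frame
    if edge == "left":
        px = frame.pixels[:, crop_px:]
    elif edge == "right":
        px = frame.pixels[:, :-crop_px]
    elif edge == "top":
        px = frame.pixels[crop_px:, :]
    elif edge == "bottom":
        px = frame.pixels[:-crop_px, :]
    else:  # pragma: no cover - Literal guards this
        raise ValueError(f"unknown edge {edge!r}")
    return replace(frame, pixels=px)


def _to_gray_u8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        # ITU-R 601 luma; alpha channel, if any, is ignored.
        rgb = img[..., :3].astype(np.float64)
        img = rgb @ np.array([0.299, 0.587, 0.114])
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def _natural_key(p: Path) -> list:
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]


def read_frames(path: str | Path, grayscale: bool = True, fps: float | None = None) -> Iterator[Frame]:
    """Yield :class:`Frame` objects from a video file or an image directory.

    Directories are read as an image sequence in natural filename order
    (``frame2.png`` before ``frame10.png``).  Timestamps are ``index * 1000 /
    fps``; for video containers the rate is taken from the container metadata
    unless ``fps`` overrides it, for directories ``fps`` defaults to 100 (the
    nominal capture rate of the headset camera).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the source contains no frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_natural_key,
        )
        if not files:
            raise ValueError(f"no image files found in directory {path}")
        rate = 100.0 if fps is None else float(fps)
        yield from _emit(map(iio.imread, files), rate, grayscale)
        return

    if fps is None:
        try:
            meta = iio.immeta(path)
            fps = float(meta.get("fps", 0.0)) or None
        except Exception:
            fps = None
    rate = fps if fps else 100.0

    def _video_arrays() -> Iterator[np.ndarray]:
        count = 0
        for img in iio.imiter(path):
            count += 1
            yield img
        if count == 0:
            raise ValueError(f"no frames decoded from {path}")

    if path.suffix.lower() in _IMAGE_SUFFIXES:
        yield from _emit(iter([iio.imread(path)]), rate, grayscale)
    else:
        yield from _emit(_video_arrays(), rate, grayscale)


def _emit(arrays: Iterator[np.ndarray], fps: float, grayscale: bool) -> Iterator[Frame]:
    for i, img in enumerate(arrays):
        px = _to_gray_u8(img) if grayscale else np.asarray(img)
        yield Frame(pixels=px, index=i, timestamp_ms=i * 1000.0 / fps)


def frames_from_arrays(arrays: list[np.ndarray], fps: float = 100.0) -> list[Frame]:
    """Wrap in-memory grayscale arrays as a frame sequence at a constant rate."""
    return [
        Frame(pixels=_to_gray_u8(a), index=i, timestamp_ms=i * 1000.0 / fps)
        for i, a in enumerate(arrays)
    ]
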