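"""Motion-vector analysis: grid sampling of dense flow and DMV/UMV estimation.

Between two successive frames the dense flow field is sampled at a regular
grid of marker points (spacing ``d``, default 10 px, giving ``floor(w/d) *
floor(h/d)`` points — 544 for the default 170 x 320 processing region).  The
sampled vectors are filtered by direction/magnitude selection criteria and
summed:

- the *downward motion vector* (DMV) sums vectors with magnitude >= 2 px whose
  y-component is positive (downward, y grows down the image) and carries at
  least half of the vector's own magnitude — the signature of the upper eyelid
  descending during the closing phase, while rejecting saccade-induced motion
  in other directions;
- the *upward motion vector* (UMV) sums vectors with magnitude >= 2 px and a
  negative y-component — the signature of the reopening phase.

A large DMV magnitude therefore flags eyelid closing, a large UMV magnitude
eyelid reopening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from blinkflow.flow import FlowParams, get_backend
from blinkflow.frameio import Frame

__all__ = [
    "FlowField",
    "SampleGrid",
    "Vec2",
    "MotionVectorSet",
    "make_sample_grid",
    "estimate_flow",
    "sample_vectors",
    "total_motion_vector",
    "downward_motion_vector",
    "upward_motion_vector",
    "MIN_VECTOR_MAGNITUDE",
]

#: Vectors shorter than this (px) are treated as noise and never contribute to
#: the DMV or UMV sums.
MIN_VECTOR_MAGNITUDE = 2.0

DownwardCriterion = Literal["own", "total"]


@dataclass(frozen=True)
class Vec2:
    """A 2D displacement in image coordinates (x right, y down), in pixels."""

    x: float
    y: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)

    def __add__(self, other: "Vec2") -> "Vec2":
        return Vec2(self.x + other.x, self.y + other.y)

    def __iter__(self):
        return iter((self.x, self.y))


@dataclass(frozen=True)
class FlowField:
    """Per-pixel forward displacements between two successive frames."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        dx = np.asarray(self.dx, dtype=np.float64)
        dy = np.asarray(self.dy, dtype=np.float64)
        if dx.shape != dy.shape or dx.ndim != 2:
            raise ValueError("dx and dy must be equal-shape 2D arrays")
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape


@dataclass(frozen=True)
class SampleGrid:
    """Evenly spaced marker points at which the flow field is sampled."""

    spacing_d: int
    points: np.ndarray  # (n, 2) array of (x, y) pixel coordinates

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MotionVectorSet:
    """Flow vectors sampled at the grid points for one frame transition."""

    vectors: np.ndarray  # (n, 2) array of (x, y) displacements
    frame_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def from_vecs(cls, vecs: Iterable[Vec2 | tuple[float, float]], frame_index: int = 0) -> "MotionVectorSet":
        arr = np.array([tuple(v) for v in vecs], dtype=np.float64).reshape(-1, 2)
        return cls(vectors=arr, frame_index=frame_index)


def make_sample_grid(width: int, height: int, spacing_d: int = 10) -> SampleGrid:
    """Lay out ``floor(width/d) * floor(height/d)`` marker points.

    Points sit at cell centres ``((i + 1/2) d, (j + 1/2) d)`` so that no marker
    lies on the frame border, where flow estimates are least reliable.  For the
    default 170 x 320 processing region with ``d = 10`` this yields 544 points.

    Raises
    ------
    ValueError
        If ``spacing_d`` is not positive or exceeds either dimension.
    """
    if spacing_d <= 0:
        raise ValueError("spacing_d must be > 0")
    if spacing_d > min(width, height):
        raise ValueError("spacing_d must not exceed the frame dimensions")
    nx = width // spacing_d
    ny = height // spacing_d
    xs = (np.arange(nx) + 0.5) * spacing_d
    ys = (np.arange(ny) + 0.5) * spacing_d
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return SampleGrid(spacing_d=spacing_d, points=pts)


def estimate_flow(
    prev: Frame | np.ndarray,
    curr: Frame | np.ndarray,
    backend: str = "polyexp",
    params: FlowParams | None = None,
    **backend_kwargs,
) -> FlowField:
    """Dense forward flow between two frames via the selected backend.

    Raises
    ------
    ValueError
        If the frames have different shapes or the backend name is unknown.
    """
    p = prev.pixels if isinstance(prev, Frame) else np.asarray(prev)
    c = curr.pixels if isinstance(curr, Frame) else np.asarray(curr)
    if p.shape != c.shape:
        raise ValueError(f"frame shapes differ: {p.shape} vs {c.shape}")
    fn = get_backend(backend)
    if backend == "polyexp" and params is not None:
        dx, dy = fn(p, c, params=params)
    else:
        dx, dy = fn(p, c, **backend_kwargs)
    return FlowField(dx=dx, dy=dy)


def sample_vectors(flow: FlowField, grid: SampleGrid, frame_index: int = 0) -> MotionVectorSet:
    """Read the flow displacement at every grid marker point.

    Marker coordinates are truncated to pixel indices (cell-centre markers at
    half-integer positions read the pixel they fall in).

    Raises
    ------
    ValueError
        If any grid point lies outside the flow extent.
    """
    h, w = flow.shape
    xs = grid.points[:, 0].astype(np.intp)
    ys = grid.points[:, 1].astype(np.intp)
    if (xs < 0).any() or (xs >= w).any() or (ys < 0).any() or (ys >= h).any():
        raise ValueError("grid points outside the flow extent")
    vecs = np.column_stack([flow.dx[ys, xs], flow.dy[ys, xs]])
    return MotionVectorSet(vectors=vecs, frame_index=frame_index)


def total_motion_vector(vectors: MotionVectorSet) -> Vec2:
    """Componentwise sum of all sampled vectors (zero for an empty set)."""
    if len(vectors) == 0:
        return Vec2(0.0, 0.0)
    s = vectors.vectors.sum(axis=0)
    return Vec2(float(s[0]), float(s[1]))


def _magnitudes(v: np.ndarray) -> np.ndarray:
    return np.hypot(v[:, 0], v[:, 1])


def downward_motion_vector(
    vectors: MotionVectorSet, criterion: DownwardCriterion = "own"
) -> Vec2:
    """Sum of vectors surviving the downward-motion selection criteria.

    A vector survives iff (i) its magnitude is at least 2 px, (ii) its
    y-component is positive (pointing down the image), and (iii) its
    y-component carries at least 50% of the reference magnitude.  With the
    default ``criterion="own"`` the reference is the vector's own magnitude;
    ``criterion="total"`` instead references the magnitude of the unfiltered
    total motion vector.  Boundary values (magnitude exactly 2; y exactly half
    the reference) are kept.  Returns the zero vector if nothing survives.
    """
    v = vectors.vectors
    if len(v) == 0:
        return Vec2(0.0, 0.0)
    mags = _magnitudes(v)
    if criterion == "own":
        ref = mags
    elif criterion == "total":
        ref = np.full(len(v), math.hypot(*v.sum(axis=0)))
    else:
        raise ValueError(f"unknown downward criterion {criterion!r}")
    keep = (mags >= MIN_VECTOR_MAGNITUDE) & (v[:, 1] > 0) & (v[:, 1] >= 0.5 * ref)
    if not keep.any():
        return Vec2(0.0, 0.0)
    s = v[keep].sum(axis=0)
    return Vec2(float(s[0]), float(s[1]))


def upward_motion_vector(vectors: MotionVectorSet) -> Vec2:
    """Sum of vectors with magnitude >= 2 px pointing upward (y < 0).

    Returns the zero vector if nothing survives.
    """
    v = vectors.vectors
    if len(v) == 0:
        return Vec2(0.0, 0.0)
    mags = _magnitudes(v)
    keep = (mags >= MIN_VECTOR_MAGNITUDE) & (v[:, 1] < 0)
    if not keep.any():
        return Vec2(0.0, 0.0)
    s = v[keep].sum(axis=0)
    return Vec2(float(s[0]), float(s[1]))
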