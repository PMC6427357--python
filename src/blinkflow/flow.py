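"""Dense optical-flow backends.

Three interchangeable estimators sit behind one contract: given two equal-shape
grayscale frames, return per-pixel forward displacements ``(dx, dy)`` such that
content at ``(x, y)`` in the previous frame appears near ``(x+dx, y+dy)`` in
the current frame (image coordinates, y down).  The contract every backend must
satisfy, and which the test suite enforces, is translation recovery: for a
rigid integer shift of a textured image by ``(tx, ty)`` with ``|t| <= 5``, the
median sampled displacement recovers ``(tx, ty)`` within 0.5 px.

Backends
--------
``"polyexp"`` (default)
    Polynomial-expansion dense flow: each local neighbourhood of both frames is
    approximated by a quadratic polynomial via Gaussian-weighted least squares,
    and the displacement that maps one expansion onto the other is solved per
    pixel, smoothed over a Gaussian averaging window, and refined coarse-to-fine
    over an image pyramid with iterative warping.
``"block"``
    Exhaustive block matching (sum of squared differences) on a coarse pixel
    grid, upsampled to a dense field.  Slow but conceptually independent of the
    polynomial-expansion machinery; used as an oracle in tests.
``"ilk"``
    Iterative Lucas-Kanade solver from scikit-image.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage

__all__ = [
    "FlowParams",
    "polynomial_expansion_flow",
    "block_matching_flow",
    "ilk_flow",
    "get_backend",
    "register_backend",
    "BACKENDS",
]


class FlowParams:
    """Parameters for the polynomial-expansion backend.

    Attributes
    ----------
    pyr_levels : int
        Number of pyramid levels (1 = no pyramid).  Each level halves the
        resolution; more levels extend the capture range to larger motions.
    poly_n : int
        Half-width of the polynomial-expansion neighbourhood (window is
        ``2*poly_n+1`` wide).
    poly_sigma : float
        Std-dev of the Gaussian applicability weighting the expansion fit.
    win_sigma : float
        Std-dev of the Gaussian window averaging the per-pixel normal
        equations before the displacement solve.
    iterations : int
        Warp-and-refine iterations per pyramid level.
    """

    def __init__(
        self,
        pyr_levels: int = 3,
        poly_n: int = 3,
        poly_sigma: float = 1.2,
        win_sigma: float = 4.0,
        iterations: int = 3,
    ) -> None:
        if pyr_levels < 1 or poly_n < 1 or iterations < 1:
            raise ValueError("pyr_levels, poly_n and iterations must be >= 1")
        self.pyr_levels = pyr_levels
        self.poly_n = poly_n
        self.poly_sigma = poly_sigma
        self.win_sigma = win_sigma
        self.iterations = iterations


def _poly_expand(img: np.ndarray, n: int, sigma: float):
    """Quadratic expansion f(x) ~ c + b.x + x'Ax of every neighbourhood.

    Returns ``(A, b)`` with ``A`` of shape (h, w, 2, 2) and ``b`` of shape
    (h, w, 2); the constant term is not needed for displacement estimation.
    Components are ordered (x, y) = (col, row).
    """
    t = np.arange(-n, n + 1, dtype=np.float64)
    g = np.exp(-(t**2) / (2.0 * sigma**2))
    k0, k1, k2 = g, g * t, g * t**2

    a = k0.sum()
    m2 = k2.sum()
    m4 = (g * t**4).sum()

    # Normal matrix for the basis (1, x, y, x^2, y^2, xy) under the separable
    # Gaussian applicability; only nonzero entries by parity.
    G = np.zeros((6, 6))
    G[0, 0] = a * a
    G[1, 1] = G[2, 2] = a * m2
    G[0, 3] = G[3, 0] = G[0, 4] = G[4, 0] = a * m2
    G[3, 3] = G[4, 4] = a * m4
    G[3, 4] = G[4, 3] = m2 * m2
    G[5, 5] = m2 * m2
    Ginv = np.linalg.inv(G)

    f = img.astype(np.float64)

    def corr(image: np.ndarray, ky: np.ndarray, kx: np.ndarray) -> np.ndarray:
        out = ndimage.correlate1d(image, ky, axis=0, mode="reflect")
        return ndimage.correlate1d(out, kx, axis=1, mode="reflect")

    # Projections of the signal onto each (weighted) basis function.
    p = np.stack(
        [
            corr(f, k0, k0),  # 1
            corr(f, k0, k1),  # x
            corr(f, k1, k0),  # y
            corr(f, k0, k2),  # x^2
            corr(f, k2, k0),  # y^2
            corr(f, k1, k1),  # xy
        ],
        axis=-1,
    )
    r = p @ Ginv.T  # (h, w, 6) coefficients (c, bx, by, axx, ayy, axy)

    b = r[..., 1:3]
    A = np.empty(img.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * r[..., 5]
    return A, b


def _warp(arr: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Sample a (h, w, ...) field at positions displaced by the current flow."""
    h, w = arr.shape[:2]
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    coords = [np.clip(yy + dy, 0, h - 1), np.clip(xx + dx, 0, w - 1)]
    if arr.ndim == 2:
        return ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
    flat = arr.reshape(h, w, -1)
    out = np.empty_like(flat)
    for k in range(flat.shape[2]):
        out[..., k] = ndimage.map_coordinates(flat[..., k], coords, order=1, mode="nearest")
    return out.reshape(arr.shape)


def _flow_one_level(A1, b1, A2, b2, dx, dy, win_sigma: float, iterations: int):
    for _ in range(iterations):
        A2w = _warp(A2, dx, dy)
        b2w = _warp(b2, dx, dy)
        A = 0.5 * (A1 + A2w)
        d0 = np.stack([dx, dy], axis=-1)
        # Matching the two quadratic expansions gives A d = delta_b.
        db = -0.5 * (b2w - b1) + np.einsum("...ij,...j->...i", A, d0)

        # Normal equations per pixel, then Gaussian-window averaging.
        AtA = np.einsum("...ki,...kj->...ij", A, A)
        Atb = np.einsum("...ki,...k->...i", A, db)
        sm = lambda m: ndimage.gaussian_filter(m, win_sigma, mode="reflect")
        g00 = sm(AtA[..., 0, 0])
        g01 = sm(AtA[..., 0, 1])
        g11 = sm(AtA[..., 1, 1])
        h0 = sm(Atb[..., 0])
        h1 = sm(Atb[..., 1])

        det = g00 * g11 - g01 * g01
        eps = 1e-9 * max(float(np.abs(det).max()), 1.0)
        det = np.where(np.abs(det) < eps, np.inf, det)
        dx = (g11 * h0 - g01 * h1) / det
        dy = (g00 * h1 - g01 * h0) / det
    return dx, dy


def _downscale(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, 1.0, mode="reflect")[::2, ::2]


def polynomial_expansion_flow(
    prev: np.ndarray, curr: np.ndarray, params: FlowParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dense forward flow from ``prev`` to ``curr`` via polynomial expansion."""
    params = params or FlowParams()
    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")

    pyr = [(prev, curr)]
    for _ in range(params.pyr_levels - 1):
        p, c = pyr[-1]
        if min(p.shape) // 2 < 2 * params.poly_n + 1:
            break
        pyr.append((_downscale(p), _downscale(c)))

    dx = dy = None
    for p, c in reversed(pyr):
        if dx is None:
            dx = np.zeros(p.shape)
            dy = np.zeros(p.shape)
        else:
            zoom = (p.shape[0] / dx.shape[0], p.shape[1] / dx.shape[1])
            dx = ndimage.zoom(dx, zoom, order=1) * 2.0
            dy = ndimage.zoom(dy, zoom, order=1) * 2.0
            dx = dx[: p.shape[0], : p.shape[1]]
            dy = dy[: p.shape[0], : p.shape[1]]
        A1, b1 = _poly_expand(p, params.poly_n, params.poly_sigma)
        A2, b2 = _poly_expand(c, params.poly_n, params.poly_sigma)
        dx, dy = _flow_one_level(A1, b1, A2, b2, dx, dy, params.win_sigma, params.iterations)
    return dx, dy


def block_matching_flow(
    prev: np.ndarray,
    curr: np.ndarray,
    block_radius: int = 4,
    search_radius: int = 8,
    stride: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-displacement flow by exhaustive SSD block matching.

    The SSD between ``prev`` and ``curr`` shifted by every candidate offset is
    evaluated with a uniform box filter, the best offset is kept per pixel on a
    ``stride``-spaced grid, and the result is upsampled to a dense field by
    nearest-neighbour replication.  Independent of any gradient or polynomial
    machinery, hence useful as a test oracle.
    """
    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    h, w = prev.shape
    size = 2 * block_radius + 1

    best_ssd = np.full((h, w), np.inf)
    best_dx = np.zeros((h, w))
    best_dy = np.zeros((h, w))
    for oy in range(-search_radius, search_radius + 1):
        for ox in range(-search_radius, search_radius + 1):
            shifted = np.roll(curr, (-oy, -ox), axis=(0, 1))
            diff2 = (prev - shifted) ** 2
            # Invalidate wrapped-around borders.
            if oy > 0:
                diff2[h - oy :, :] = np.inf
            elif oy < 0:
                diff2[: -oy, :] = np.inf
            if ox > 0:
                diff2[:, w - ox :] = np.inf
            elif ox < 0:
                diff2[:, : -ox] = np.inf
            ssd = ndimage.uniform_filter(np.where(np.isfinite(diff2), diff2, 1e12), size, mode="reflect")
            better = ssd < best_ssd
            best_ssd[better] = ssd[better]
            best_dx[better] = ox
            best_dy[better] = oy

    if stride > 1:
        best_dx = np.repeat(np.repeat(best_dx[::stride, ::stride], stride, 0), stride, 1)[:h, :w]
        best_dy = np.repeat(np.repeat(best_dy[::stride, ::stride], stride, 0), stride, 1)[:h, :w]
    return best_dx, best_dy


def ilk_flow(prev: np.ndarray, curr: np.ndarray, radius: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Iterative Lucas-Kanade dense flow (scikit-image)."""
    from skimage.registration import optical_flow_ilk

    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    v, u = optical_flow_ilk(prev, curr, radius=radius)
    return u, v


FlowBackend = Callable[..., tuple[np.ndarray, np.ndarray]]

BACKENDS: dict[str, FlowBackend] = {
    "polyexp": polynomial_expansion_flow,
    "block": block_matching_flow,
    "ilk": ilk_flow,
}


def register_backend(name: str, fn: FlowBackend) -> None:
    """Register an additional flow estimator under ``name``."""
    BACKENDS[name] = fn


def get_backend(name: str) -> FlowBackend:
    try:
        return BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown flow backend {name!r}; available: {sorted(BACKENDS)}") from None
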