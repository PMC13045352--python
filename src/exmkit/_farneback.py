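"""Dense two-frame optical flow by polynomial expansion (Farnebäck 2003).

Each image is locally approximated by a quadratic polynomial
``f(x) ~ x^T A x + b^T x + c`` fitted under a Gaussian applicability window;
equating the expansions of the two frames yields, per pixel, a linear
constraint ``A d = delta_b`` on the displacement ``d``, which is solved in a
Gaussian-weighted least-squares sense over a neighborhood.  The estimate is
refined over a Gaussian image pyramid with warping between iterations.

Flow convention: ``fixed(x) ~ moving(x + flow(x))`` with flow returned as
``(2, H, W)`` in (row, col) = (dy, dx) pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["FlowParams", "farneback"]


@dataclass(frozen=True)
class FlowParams:
    """Tuning knobs of the dense flow estimator.

    ``poly_n`` is the half-size of the polynomial-expansion window (sigma
    ``poly_sigma``); ``winsize`` the averaging window (pixels) for the
    displacement solve; ``levels`` the number of pyramid levels (each a 2x
    downsample); ``iterations`` warping iterations per level.
    """

    levels: int = 3
    winsize: int = 15
    iterations: int = 5
    poly_n: int = 7
    poly_sigma: float = 1.5


def _poly_expand(img: np.ndarray, n: int, sigma: float):
    """Quadratic polynomial expansion coefficients of a 2D image.

    Returns (A11, A12, A22, b1, b2) per pixel, with subscript 1 = row (y) and
    2 = col (x).  Solved via separable Gaussian-applicability correlations
    against the basis {1, y, x, y^2, x^2, xy} and the precomputed metric G.
    """
    x = np.arange(-n, n + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    k0, k1, k2 = g, x * g, (x**2) * g

    f = np.asarray(img, dtype=np.float64)
    # correlate: rows (axis 0) then cols (axis 1); basis order 1,y,x,y2,x2,xy
    r0 = ndi.correlate1d(f, k0, axis=0, mode="reflect")
    r1 = ndi.correlate1d(f, k1, axis=0, mode="reflect")
    r2 = ndi.correlate1d(f, k2, axis=0, mode="reflect")
    v1 = ndi.correlate1d(r0, k0, axis=1, mode="reflect")   # 1
    vy = ndi.correlate1d(r1, k0, axis=1, mode="reflect")   # y
    vx = ndi.correlate1d(r0, k1, axis=1, mode="reflect")   # x
    vyy = ndi.correlate1d(r2, k0, axis=1, mode="reflect")  # y^2
    vxx = ndi.correlate1d(r0, k2, axis=1, mode="reflect")  # x^2
    vxy = ndi.correlate1d(r1, k1, axis=1, mode="reflect")  # xy

    # metric G = sum a * basis basis^T over the window (basis order as above)
    yy, xx = np.meshgrid(x, x, indexing="ij")
    a = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    basis = np.stack([np.ones_like(yy), yy, xx, yy**2, xx**2, yy * xx])
    G = np.einsum("iyx,jyx,yx->ij", basis, basis, a)
    Ginv = np.linalg.inv(G)

    v = np.stack([v1, vy, vx, vyy, vxx, vxy], axis=-1)
    r = v @ Ginv.T  # coefficients (c, by, bx, ayy, axx, axy-combined)
    b1, b2 = r[..., 1], r[..., 2]
    A11, A22, A12 = r[..., 3], r[..., 4], r[..., 5] / 2.0
    return A11, A12, A22, b1, b2


def _solve_flow(A11f, A12f, A22f, b1f, b2f, A11m, A12m, A22m, b1m, b2m, flow, winsize):
    """One displacement update given expansions of both frames and prior flow."""
    h, w = b1f.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    ys = yy + flow[0]
    xs = xx + flow[1]
    inside = (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
    coords = np.stack([np.clip(ys, 0, h - 1), np.clip(xs, 0, w - 1)])

    def warp(f):
        return ndi.map_coordinates(f, coords, order=1, mode="nearest")

    A11 = 0.5 * (A11f + warp(A11m))
    A12 = 0.5 * (A12f + warp(A12m))
    A22 = 0.5 * (A22f + warp(A22m))
    db1 = -0.5 * (warp(b1m) - b1f) + A11 * flow[0] + A12 * flow[1]
    db2 = -0.5 * (warp(b2m) - b2f) + A12 * flow[0] + A22 * flow[1]

    cert = inside.astype(float)
    # normal equations of |A d - db|^2, Gaussian-averaged over the window
    sig = winsize / 4.0
    def avg(f):
        return ndi.gaussian_filter(f * cert, sig, mode="constant", truncate=2.5)

    G11 = avg(A11 * A11 + A12 * A12)
    G12 = avg(A11 * A12 + A12 * A22)
    G22 = avg(A12 * A12 + A22 * A22)
    h1 = avg(A11 * db1 + A12 * db2)
    h2 = avg(A12 * db1 + A22 * db2)

    det = G11 * G22 - G12 * G12
    # Tikhonov floor keeps flat regions at (approximately) zero flow
    eps = 1e-9 * max(float(np.max(det)), 1e-30) + 1e-30
    det = np.where(np.abs(det) < eps, eps, det)
    d1 = (G22 * h1 - G12 * h2) / det
    d2 = (G11 * h2 - G12 * h1) / det
    return np.stack([d1, d2])


def _downsample(img: np.ndarray) -> np.ndarray:
    return ndi.gaussian_filter(img, 1.0, mode="reflect")[::2, ::2]


def farneback(fixed: np.ndarray, moving: np.ndarray, params: FlowParams = FlowParams()) -> np.ndarray:
    """Dense flow such that ``fixed(x) ~ moving(x + flow(x))``.

    Returns a ``(2, H, W)`` float array in (dy, dx) pixel units.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError("fixed and moving must be 2D images of the same shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("no structure to track: image has zero variance")

    pyr_f, pyr_m = [fixed], [moving]
    for _ in range(params.levels - 1):
        if min(pyr_f[-1].shape) < 2 * params.poly_n + 3:
            break
        pyr_f.append(_downsample(pyr_f[-1]))
        pyr_m.append(_downsample(pyr_m[-1]))

    flow = np.zeros((2, *pyr_f[-1].shape))
    for lvl in range(len(pyr_f) - 1, -1, -1):
        f, m = pyr_f[lvl], pyr_m[lvl]
        exp_f = _poly_expand(f, params.poly_n, params.poly_sigma)
        exp_m = _poly_expand(m, params.poly_n, params.poly_sigma)
        for _ in range(params.iterations):
            flow = _solve_flow(*exp_f, *exp_m, flow, params.winsize)
        if lvl > 0:
            target = pyr_f[lvl - 1].shape
            zoom = (target[0] / flow.shape[1], target[1] / flow.shape[2])
            flow = np.stack(
                [ndi.zoom(flow[i], zoom, order=1) * zoom[i] for i in range(2)]
            )
    return flow
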