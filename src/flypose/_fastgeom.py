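"""JIT-compiled geometry kernels for the loss hot path.

These mirror the reference implementations in :mod:`flypose.projection`
(scipy convex hull, vectorized rasterizers), which remain the public
API and serve as cross-checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def convex_hull_ccw(pts):
    """Andrew's monotone chain; returns CCW hull vertices.

    Ties in x are broken by a tiny y-dependent key perturbation, which
    is safe at pixel-coordinate magnitudes.
    """
    n = pts.shape[0]
    key = pts[:, 0] + pts[:, 1] * 1e-9
    order = np.argsort(key)
    P = pts[order]
    hull = np.empty((2 * n, 2))
    k = 0
    for i in range(n):
        while k >= 2 and ((hull[k - 1, 0] - hull[k - 2, 0])
                          * (P[i, 1] - hull[k - 2, 1])
                          - (hull[k - 1, 1] - hull[k - 2, 1])
                          * (P[i, 0] - hull[k - 2, 0])) <= 0.0:
            k -= 1
        hull[k, 0] = P[i, 0]
        hull[k, 1] = P[i, 1]
        k += 1
    lower_n = k + 1
    for i in range(n - 2, -1, -1):
        while k >= lower_n and ((hull[k - 1, 0] - hull[k - 2, 0])
                                * (P[i, 1] - hull[k - 2, 1])
                                - (hull[k - 1, 1] - hull[k - 2, 1])
                                * (P[i, 0] - hull[k - 2, 0])) <= 0.0:
            k -= 1
        hull[k, 0] = P[i, 0]
        hull[k, 1] = P[i, 1]
        k += 1
    return hull[:k - 1].copy()


@njit(cache=True)
def add_convex_patch(model, xs, ys, i0, j0, smooth, sharp):
    """Accumulate one convex CCW polygon into a view's model buffer.

    ``model`` is a float32 (H, W) buffer in ROI coordinates with origin
    (i0, j0); pixel values are max-combined.  ``smooth`` selects the
    anti-aliased signed-distance coverage (transition width 1/sharp px)
    versus the exact pixel-centre membership (values 0/1).
    """
    H, W = model.shape
    n = xs.shape[0]
    pad = 1.0 if smooth else 0.5
    xmin = xs[0]
    xmax = xs[0]
    ymin = ys[0]
    ymax = ys[0]
    for k in range(1, n):
        if xs[k] < xmin:
            xmin = xs[k]
        if xs[k] > xmax:
            xmax = xs[k]
        if ys[k] < ymin:
            ymin = ys[k]
        if ys[k] > ymax:
            ymax = ys[k]
    ia = max(int(np.ceil(xmin - i0 - pad)), 0)
    ib = min(int(np.floor(xmax - i0 + pad)), W - 1)
    ja = max(int(np.ceil(ymin - j0 - pad)), 0)
    jb = min(int(np.floor(ymax - j0 + pad)), H - 1)
    if ib < ia or jb < ja:
        return
    ex = np.empty(n)
    ey = np.empty(n)
    for k in range(n):
        k2 = k + 1 if k + 1 < n else 0
        dx = xs[k2] - xs[k]
        dy = ys[k2] - ys[k]
        if smooth:
            ln = (dx * dx + dy * dy) ** 0.5
            if ln == 0.0:
                ln = 1.0
            dx /= ln
            dy /= ln
        ex[k] = dx
        ey[k] = dy
    for j in range(ja, jb + 1):
        py = j + j0
        for i in range(ia, ib + 1):
            px = i + i0
            dmin = 1e30
            for k in range(n):
                d = ex[k] * (py - ys[k]) - ey[k] * (px - xs[k])
                if d < dmin:
                    dmin = d
                    if dmin < -pad:
                        break
            if smooth:
                v = 0.5 + dmin * sharp
                if v > 1.0:
                    v = 1.0
                elif v < 0.0:
                    v = 0.0
            else:
                v = 1.0 if dmin >= 0.0 else 0.0
            if v > model[j, i]:
                model[j, i] = v


@njit(cache=True)
def abs_diff_sum(mask, model):
    """Sum of |mask - model| over a view ROI (the XOR area when both
    are binary)."""
    s = 0.0
    H, W = mask.shape
    for j in range(H):
        for i in range(W):
            s += abs(mask[j, i] - model[j, i])
    return s
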