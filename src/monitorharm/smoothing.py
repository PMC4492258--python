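"""Deterministic local-linear smoother with tri-cube weights.

Used both to summarize pooled time-series into smoothed temporal patterns
and to smooth the SVD trend. The smoother is linear in the data values:
smoothing ``a*y + b`` yields ``a*smooth(y) + b``.
"""

from __future__ import annotations

import numpy as np


def tricube(u: np.ndarray) -> np.ndarray:
    """Tri-cube kernel (1 - |u|^3)^3 on |u| < 1, else 0."""
    u = np.abs(np.asarray(u, dtype=float))
    w = np.zeros_like(u)
    inside = u < 1
    w[inside] = (1 - u[inside] ** 3) ** 3
    return w


def local_linear_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Evaluate a local-linear tri-cube smoother at ``x_eval``.

    At each evaluation point a weighted straight line is fitted to the
    points within one bandwidth and its value at the point returned. With
    fewer than two distinct in-window abscissae the fit degenerates to the
    weighted mean (so a bandwidth of one grid step interpolates the data).
    Points outside ``[min(x), max(x)]`` are not extrapolated and come back
    as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if x.size == 0:
        raise ValueError("no data points to smooth")
    lo, hi = x.min(), x.max()
    out = np.full(x_eval.shape, np.nan)
    for j, x0 in enumerate(x_eval):
        if x0 < lo or x0 > hi:
            continue
        w = tricube((x - x0) / bandwidth)
        if not np.any(w > 0):
            # data exist inside the support but none within the bandwidth;
            # fall back to the nearest point so the pattern stays defined
            out[j] = y[np.argmin(np.abs(x - x0))]
            continue
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            out[j] = ym  # degenerate window: weighted mean
        else:
            slope = (w * (x - xm) * (y - ym)).sum() / sxx
            out[j] = ym + slope * (x0 - xm)
    return out
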