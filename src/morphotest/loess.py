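"""Small LOESS smoother: tricube-weighted local polynomial regression.

Local quadratic by default, span as the fraction of points entering each
local fit, no robustness iterations.  Used to summarise the goodness-vs-
dissimilarity point clouds of the calibration-pair search.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["loess"]


def loess(
    x: Sequence[float],
    y: Sequence[float],
    x_eval: Optional[Sequence[float]] = None,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Evaluate a LOESS curve of ``y`` on ``x`` at ``x_eval`` (default: ``x``).

    For each evaluation point the ``ceil(span * n)`` nearest data points get
    tricube weights scaled by the distance to the furthest neighbour, and a
    weighted degree-``degree`` polynomial is fitted by least squares.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    xe = x if x_eval is None else np.asarray(x_eval, dtype=float).ravel()
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(xe.size)
    for i, x0 in enumerate(xe):
        d = np.abs(x - x0)
        dk = np.partition(d, k - 1)[k - 1]
        if dk == 0.0:
            # all nearest neighbours coincide with x0: weighted mean there
            out[i] = y[d == 0.0].mean()
            continue
        u = np.clip(d / dk, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        mask = w > 0.0
        xm, ym, wm = x[mask] - x0, y[mask], w[mask]
        basis = np.vander(xm, degree + 1, increasing=True)
        sw = np.sqrt(wm)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], ym * sw, rcond=None)
        out[i] = coef[0]
    return out
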