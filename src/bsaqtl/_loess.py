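"""Minimal 1-D loess: local weighted polynomial regression, tricube weights.

Nearest-neighbour bandwidth from a span fraction, no robustness iterations.
Written here because no pre-installed library exposes degree-2 loess.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_fit"]


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.3, degree: int = 2
) -> np.ndarray:
    """Fit y ~ local polynomial of x, returning fitted values at each x.

    ``x`` must be sorted ascending.  For each point the ``ceil(span * n)``
    nearest neighbours (at least degree + 2) define the bandwidth; weights
    are tricube in scaled distance.  With noiseless polynomial input of the
    given degree the fit reproduces the input exactly (up to conditioning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        return np.empty(0)
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    k = min(n, max(int(np.ceil(span * n)), degree + 2))
    fitted = np.empty(n)
    lo = 0
    for i in range(n):
        # slide the k-window to keep the k nearest neighbours of x[i]
        while lo + k < n and x[lo + k] - x[i] < x[i] - x[lo]:
            lo += 1
        xs = x[lo : lo + k]
        ys = y[lo : lo + k]
        d = np.abs(xs - x[i])
        h = d.max()
        if h <= 0.0:
            fitted[i] = ys.mean()
            continue
        w = (1.0 - np.minimum(d / h, 1.0) ** 3) ** 3
        # points exactly at the bandwidth edge get weight 0; keep the fit
        # solvable by flooring total weight
        if w.sum() <= 0:
            fitted[i] = ys.mean()
            continue
        t = (xs - x[i]) / h  # center & scale for conditioning
        V = np.vander(t, degree + 1, increasing=True)
        Vw = V * w[:, None]
        A = V.T @ Vw
        b = Vw.T @ ys
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        fitted[i] = coef[0]
    return fitted
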