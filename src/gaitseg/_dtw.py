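"""Dynamic-programming kernel for slope-constrained DTW.

The recursion is the classic one (steps diagonal, vertical, horizontal)
restricted to an Itakura-parallelogram feasibility mask. Ties between
predecessors are broken deterministically: diagonal, then vertical
(first-series advance), then horizontal — so warping paths, and therefore
transferred event indices, are reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import ArgumentError

_EPS = 1e-9


def itakura_mask(n: int, m: int, slope: float) -> np.ndarray:
    """Boolean feasibility mask of the Itakura parallelogram.

    In coordinates normalized to the unit square, a cell is feasible when it
    lies between lines of slope ``slope`` and ``1/slope`` drawn from both
    corners. ``slope`` is the maximum local tempo distortion allowed.
    """
    if slope < 1.0:
        raise ArgumentError(f"Itakura slope must be >= 1, got {slope}")
    if n < 2 or m < 2:
        raise ArgumentError("series must have length >= 2")
    u = (np.arange(n) / (n - 1))[:, None]
    v = (np.arange(m) / (m - 1))[None, :]
    return ((v <= slope * u + _EPS)
            & (v >= u / slope - _EPS)
            & (1 - v <= slope * (1 - u) + _EPS)
            & (1 - v >= (1 - u) / slope - _EPS))


@njit(cache=True)
def _dtw_fill(C, mask):  # pragma: no cover - exercised via mdtwd
    n, m = C.shape
    D = np.full((n, m), np.inf)
    P = np.zeros((n, m), dtype=np.int8)  # 1=diag, 2=vertical, 3=horizontal
    D[0, 0] = C[0, 0]
    for i in range(n):
        for j in range(m):
            if (i == 0 and j == 0) or not mask[i, j]:
                continue
            best = np.inf
            p = 0
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
                p = 1
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
                p = 2
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
                p = 3
            if p > 0 and np.isfinite(best):
                D[i, j] = best + C[i, j]
                P[i, j] = p
    return D, P


def dtw_constrained(C: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-cost path through cost matrix *C* within *mask*.

    Returns the total cost and the path as an (L, 2) array of index pairs
    from (0, 0) to (n-1, m-1).
    """
    D, P = _dtw_fill(np.ascontiguousarray(C, dtype=np.float64),
                     np.ascontiguousarray(mask, dtype=np.bool_))
    n, m = C.shape
    if not np.isfinite(D[n - 1, m - 1]):
        from .errors import ConstraintError
        raise ConstraintError(
            f"no Itakura-feasible warping path for sizes ({n}, {m})"
        )
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        p = P[i, j]
        if p == 1:
            i, j = i - 1, j - 1
        elif p == 2:
            i = i - 1
        elif p == 3:
            j = j - 1
        else:  # pragma: no cover - fill guarantees a predecessor
            raise RuntimeError("broken DTW traceback")
        path.append((i, j))
    path.reverse()
    return float(D[n - 1, m - 1]), np.asarray(path, dtype=int)
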