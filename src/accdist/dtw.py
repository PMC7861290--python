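"""Length-normalized dynamic time warping between feature matrices.

The cost matrix holds Euclidean distances between frame pairs; the cumulative
cost follows the classic three-move recursion

    g(i, j) = d(i, j) + min(g(i-1, j-1), g(i-1, j), g(i, j-1))

with unit step weights and no warping window.  The accumulated cost g(n, m)
is divided by (n + m) so that comparisons between words of different lengths
are on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .mfcc import FeatureMatrix


@dataclass(frozen=True)
class DtwResult:
    distance: float        # raw_cost / (n + m)
    raw_cost: float        # g(n, m)
    n_frames_target: int
    m_frames_reference: int


def _frames(x) -> np.ndarray:
    a = x.frames if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] == 0:
        raise ValueError("empty feature matrix")
    return np.ascontiguousarray(a, dtype=np.float64)


def frame_cost(x_i: np.ndarray, y_j: np.ndarray, squared: bool = False) -> float:
    """Euclidean distance between two frames (optionally squared)."""
    x_i = np.asarray(x_i, dtype=np.float64)
    y_j = np.asarray(y_j, dtype=np.float64)
    if x_i.shape != y_j.shape:
        raise ValueError(f"dimension mismatch: {x_i.shape} vs {y_j.shape}")
    ss = np.sum((x_i - y_j) ** 2)
    return float(ss if squared else np.sqrt(ss))


def cost_matrix(X: np.ndarray, Y: np.ndarray, squared: bool = False,
                block: int = 128) -> np.ndarray:
    """Pairwise frame costs, computed in row blocks to bound memory."""
    n, m = X.shape[0], Y.shape[0]
    D = np.empty((n, m))
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        ss = ((X[i0:i1, None, :] - Y[None, :, :]) ** 2).sum(axis=-1)
        D[i0:i1] = ss if squared else np.sqrt(ss)
    return D


@njit(cache=False)
def _cumulative_cost(D):  # pragma: no cover — exercised via dtw_distance
    n, m = D.shape
    g = np.empty((n, m))
    g[0, 0] = D[0, 0]
    for j in range(1, m):
        g[0, j] = g[0, j - 1] + D[0, j]
    for i in range(1, n):
        g[i, 0] = g[i - 1, 0] + D[i, 0]
        for j in range(1, m):
            best = g[i - 1, j - 1]
            if g[i - 1, j] < best:
                best = g[i - 1, j]
            if g[i, j - 1] < best:
                best = g[i, j - 1]
            g[i, j] = D[i, j] + best
    return g[n - 1, m - 1]


def dtw_distance(target, reference, squared: bool = False) -> DtwResult:
    """Normalized DTW distance between two feature matrices.

    ``squared=True`` uses squared-difference frame costs instead of the
    (default) rooted Euclidean distance.
    """
    X, Y = _frames(target), _frames(reference)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    raw = float(_cumulative_cost(cost_matrix(X, Y, squared=squared)))
    n, m = X.shape[0], Y.shape[0]
    return DtwResult(
        distance=raw / (n + m),
        raw_cost=raw,
        n_frames_target=n,
        m_frames_reference=m,
    )
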