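"""Independent reference computations used only by the test suite."""

import numpy as np
from scipy.linalg import solve_toeplitz


def brute_force_dtw_raw(D) -> float:
    """Minimum path cost by exhaustive enumeration of all monotone warping
    paths (steps down, right, diagonal) from (0,0) to (n-1,m-1).

    Costs accumulate left-to-right along each path, matching the
    association order of the dynamic program, so agreement is exact.
    """
    D = [list(map(float, row)) for row in np.asarray(D)]
    n, m = len(D), len(D[0])
    best = np.inf

    stack = [(0, 0, D[0][0])]
    while stack:
        i, j, acc = stack.pop()
        if i == n - 1 and j == m - 1:
            if acc < best:
                best = acc
            continue
        if i + 1 < n and j + 1 < m:
            stack.append((i + 1, j + 1, acc + D[i + 1][j + 1]))
        if i + 1 < n:
            stack.append((i + 1, j, acc + D[i + 1][j]))
        if j + 1 < m:
            stack.append((i, j + 1, acc + D[i][j + 1]))
    return best


def pairwise_euclidean(X, Y) -> np.ndarray:
    """Naive loop-and-sum cost matrix (oracle-side)."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    D = np.empty((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[0]):
            D[i, j] = np.sqrt(np.sum((X[i] - Y[j]) ** 2))
    return D


def lpc_formants(x: np.ndarray, rate: int, order: int = 10) -> list[float]:
    """Formant frequencies via autocorrelation LPC root-solving.

    The glottal -12 dB/oct tilt is undone by double pre-emphasis before
    fitting; roots with bandwidth < 600 Hz above 150 Hz are kept, sorted.
    """
    x = np.asarray(x, float)
    for _ in range(2):
        x = np.append(x[0], x[1:] - 0.97 * x[:-1])
    x = x * np.hamming(x.size)
    r = np.correlate(x, x, "full")[x.size - 1 : x.size + order]
    a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    roots = np.roots(np.concatenate(([1.0], -a)))
    roots = roots[np.imag(roots) > 0.01]
    freqs = np.angle(roots) * rate / (2 * np.pi)
    bws = -0.5 * rate / np.pi * np.log(np.abs(roots))
    return sorted(f for f, b in zip(freqs, bws) if b < 600 and f > 150)


def autocorrelation_f0(x: np.ndarray, rate: int,
                       fmin: float = 60.0, fmax: float = 400.0) -> float:
    """Fundamental frequency of a voiced snippet by autocorrelation peak."""
    x = np.asarray(x, float) - np.mean(x)
    ac = np.correlate(x, x, "full")[x.size - 1 :]
    lo, hi = int(rate / fmax), int(rate / fmin)
    lag = lo + int(np.argmax(ac[lo:hi]))
    return rate / lag
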