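"""Independent reference implementations used as test oracles.

Everything here is deliberately brute-force and shares no code with the
package: dense-vector similarity metrics, central finite differences,
walk enumeration for Katz scores, and a one-step walk propensity.
"""

from __future__ import annotations

import numpy as np


def dense_cosine(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        return 0.0
    return float((x * y).sum() / (nx * ny))


def dense_pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum()) * np.sqrt((yc * yc).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def numerical_gradient(fun, X: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of a matrix."""
    X = np.asarray(X, dtype=float)
    grad = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = X[idx]
        X[idx] = orig + h
        fp = fun(X)
        X[idx] = orig - h
        fmn = fun(X)
        X[idx] = orig
        grad[idx] = (fp - fmn) / (2 * h)
        it.iternext()
    return grad


def katz_block_power(
    G: np.ndarray, P: np.ndarray, Q: np.ndarray, beta: float, max_len: int = 3
) -> np.ndarray:
    """Gene-disease block of sum_L beta^L A^L for the block adjacency A."""
    m, n = P.shape
    A = np.zeros((m + n, m + n))
    A[:m, :m] = G
    A[:m, m:] = P
    A[m:, :m] = P.T
    A[m:, m:] = Q
    total = np.zeros_like(A)
    power = np.eye(m + n)
    for length in range(1, max_len + 1):
        power = power @ A
        total += beta**length * power
    return total[:m, m:]


def katz_walk_enumeration(
    G: np.ndarray, P: np.ndarray, Q: np.ndarray, beta: float, max_len: int = 3
) -> np.ndarray:
    """Literal DFS over all heterogeneous walks of length <= max_len.

    Nodes 0..m-1 are genes, m..m+n-1 diseases; each walk from gene i to
    disease j contributes beta^length times the product of edge weights.
    """
    m, n = P.shape
    A = np.zeros((m + n, m + n))
    A[:m, :m] = G
    A[:m, m:] = P
    A[m:, :m] = P.T
    A[m:, m:] = Q
    scores = np.zeros((m, n))

    def walk(start: int, node: int, weight: float, length: int) -> None:
        if length > 0 and node >= m:
            scores[start, node - m] += beta**length * weight
        if length == max_len:
            return
        for nxt in range(m + n):
            w = A[node, nxt]
            if w != 0.0:
                walk(start, nxt, weight * w, length + 1)

    for i in range(m):
        walk(i, i, 1.0, 0)
    return scores


def one_step_walk_propensity(
    S_g: np.ndarray, Y: np.ndarray, S_d: np.ndarray
) -> np.ndarray:
    """Triple-loop row/column-stochastic walk probability."""
    m, n = Y.shape
    row = S_g.sum(axis=1)
    col = S_d.sum(axis=0)
    P = np.zeros((m, n))
    for i in range(m):
        if row[i] == 0:
            continue
        for j in range(n):
            total = 0.0
            for g in range(m):
                for d in range(n):
                    if Y[g, d] and col[j] > 0:
                        total += (S_g[i, g] / row[i]) * (S_d[d, j] / col[j])
            P[i, j] = total
    return P
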