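"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the DTW oracle
enumerates every monotone warp path recursively, the Hausdorff oracle is
the plain O(n*m) double loop.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_dtw_cost(local: np.ndarray) -> float:
    """Minimum total cost over all monotone paths (0,0) -> (nx-1, ny-1)."""
    local = np.asarray(local, dtype=float)
    n_x, n_y = local.shape
    best = math.inf

    def walk(i: int, j: int, acc: float) -> None:
        nonlocal best
        acc += local[i, j]
        if i == n_x - 1 and j == n_y - 1:
            if acc < best:
                best = acc
            return
        if i + 1 < n_x and j + 1 < n_y:
            walk(i + 1, j + 1, acc)
        if i + 1 < n_x:
            walk(i + 1, j, acc)
        if j + 1 < n_y:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best


def brute_force_local_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-pairs sum-of-absolute-differences, written as explicit loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.zeros((x.shape[1], y.shape[1]))
    for i in range(x.shape[1]):
        for j in range(y.shape[1]):
            total = 0.0
            for p in range(x.shape[0]):
                total += abs(x[p, i] - y[p, j])
            out[i, j] = total
    return out


def brute_force_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance via the O(n*m) double loop."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def directed(u: np.ndarray, v: np.ndarray) -> float:
        worst_sq = 0.0
        for p in u:
            nearest_sq = math.inf
            for q in v:
                dx = p[0] - q[0]
                dy = p[1] - q[1]
                d_sq = dx * dx + dy * dy
                if d_sq < nearest_sq:
                    nearest_sq = d_sq
            if nearest_sq > worst_sq:
                worst_sq = nearest_sq
        return worst_sq

    return math.sqrt(max(directed(a, b), directed(b, a)))
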