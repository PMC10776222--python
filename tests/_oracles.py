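"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic-programming and
vectorized rank machinery: alignments are found by exhaustive
enumeration of monotone lattice paths (with branch-and-bound pruning on
the nonnegative running sum), and projection-quality measures by direct
summation of the rank-based formulas with per-point sorted neighbor
lists.
"""

from __future__ import annotations

import math

import numpy as np


def best_monotone_path(cost: np.ndarray) -> tuple[float, int]:
    """Lexicographically optimal (total cost, path length) over all
    monotone endpoint-anchored paths (diagonal/right/down steps)."""
    n, m = cost.shape
    best = [math.inf, 0]

    def go(i: int, j: int, s: float, length: int) -> None:
        s += cost[i, j]
        length += 1
        if s > best[0]:
            return
        if i == n - 1 and j == m - 1:
            if s < best[0] or (s == best[0] and length < best[1]):
                best[0], best[1] = s, length
            return
        if i < n - 1 and j < m - 1:
            go(i + 1, j + 1, s, length)
        if i < n - 1:
            go(i + 1, j, s, length)
        if j < m - 1:
            go(i, j + 1, s, length)

    go(0, 0, 0.0, 0)
    return best[0], best[1]


def oracle_frame_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Unconstrained frequency-alignment cost, path-length normalized."""
    cost = np.abs(a[:, None] - b[None, :])
    total, length = best_monotone_path(cost)
    return total / length


def oracle_dftw(A: np.ndarray, B: np.ndarray) -> float:
    """Unconstrained two-level alignment distance on (frames × bands)
    arrays, enumerating both levels exhaustively."""
    ta, tb = A.shape[0], B.shape[0]
    local = np.empty((ta, tb))
    for i in range(ta):
        for j in range(tb):
            local[i, j] = oracle_frame_cost(A[i], B[j])
    total, length = best_monotone_path(local)
    return total / length


def oracle_trustworthiness(D: np.ndarray, coords: np.ndarray, k: int) -> float:
    """Venna & Kaski trustworthiness by direct summation."""
    n = D.shape[0]
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    penalty = 0.0
    for i in range(n):
        orig_order = sorted((j for j in range(n) if j != i), key=lambda j: (D[i, j], j))
        emb_order = sorted((j for j in range(n) if j != i), key=lambda j: (emb[i, j], j))
        orig_rank = {j: r + 1 for r, j in enumerate(orig_order)}
        for j in emb_order[:k]:
            if orig_rank[j] > k:
                penalty += orig_rank[j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty


def oracle_continuity(D: np.ndarray, coords: np.ndarray, k: int) -> float:
    """Continuity: original neighbors missing from embedded
    neighborhoods, penalized by embedded rank excess."""
    n = D.shape[0]
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    penalty = 0.0
    for i in range(n):
        orig_order = sorted((j for j in range(n) if j != i), key=lambda j: (D[i, j], j))
        emb_order = sorted((j for j in range(n) if j != i), key=lambda j: (emb[i, j], j))
        emb_rank = {j: r + 1 for r, j in enumerate(emb_order)}
        for j in orig_order[:k]:
            if emb_rank[j] > k:
                penalty += emb_rank[j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty
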