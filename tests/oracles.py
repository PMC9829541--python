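"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: Betti
numbers are computed from explicit boundary matrices over GF(2) with
plain Gaussian elimination, clique enumeration uses itertools, and the
edge ordering is re-derived from scratch.
"""

from itertools import combinations

import numpy as np


def gf2_rank(M: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination."""
    M = (np.asarray(M) % 2).astype(np.uint8).copy()
    rank = 0
    n_rows, n_cols = M.shape
    for col in range(n_cols):
        pivot = None
        for row in range(rank, n_rows):
            if M[row, col]:
                pivot = row
                break
        if pivot is None:
            continue
        M[[rank, pivot]] = M[[pivot, rank]]
        for row in range(n_rows):
            if row != rank and M[row, col]:
                M[row] ^= M[rank]
        rank += 1
    return rank


def edge_order(S: np.ndarray):
    """Edges sorted by decreasing similarity, ties lexicographic (i, j)."""
    n = S.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda p: (-S[p[0], p[1]], p[0], p[1]))
    return pairs


def betti_numbers_of_graph(n: int, edges, max_dim: int = 3):
    """Betti numbers beta_1..beta_max_dim of the clique complex of a graph.

    beta_m = dim ker d_m - rank d_{m+1}, boundary matrices over GF(2).
    """
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    simplices = {0: [(v,) for v in range(n)]}
    for q in range(1, max_dim + 2):
        sims = []
        for c in combinations(range(n), q + 1):
            ok = True
            for a, b in combinations(c, 2):
                if not adj[a, b]:
                    ok = False
                    break
            if ok:
                sims.append(c)
        simplices[q] = sims
    index = {q: {s: i for i, s in enumerate(simplices[q])} for q in simplices}

    def boundary_rank(q):
        rows = simplices[q - 1]
        cols = simplices[q]
        if not rows or not cols:
            return 0
        M = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for ci, s in enumerate(cols):
            for drop in range(q + 1):
                face = s[:drop] + s[drop + 1:]
                M[index[q - 1][face], ci] = 1
        return gf2_rank(M)

    betti = []
    for m in range(1, max_dim + 1):
        n_m = len(simplices[m])
        r_m = boundary_rank(m) if n_m else 0
        r_m1 = boundary_rank(m + 1) if simplices[m + 1] else 0
        betti.append((n_m - r_m) - r_m1)
    return betti


def brute_betti_curves(S: np.ndarray, max_dim: int = 3) -> np.ndarray:
    """Betti curves over the full density grid by per-density recomputation."""
    n = S.shape[0]
    pairs = edge_order(S)
    E = len(pairs)
    curves = np.zeros((max_dim, E + 1), dtype=np.int64)
    for k in range(1, E + 1):
        curves[:, k] = betti_numbers_of_graph(n, pairs[:k], max_dim=max_dim)
    return curves
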