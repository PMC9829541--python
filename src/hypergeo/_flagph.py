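"""Persistent homology of flag-complex order filtrations over GF(2).

Internal engine behind :mod:`hypergeo.topology`.  Given a symmetric
similarity matrix, edges are ranked by decreasing similarity and each
higher simplex enters the filtration at the rank of its last edge.  The
persistence pairing is computed by coboundary-matrix reduction with
clearing (the cohomology formulation: in each dimension the columns are
the positive m-simplices, which is dramatically cheaper than reducing
the top-dimensional boundary matrix directly).  Coefficients are GF(2).

Conventions
-----------
* Columns are processed in order of decreasing filtration position of
  the m-simplex; the pivot of a column is its cofacet with the minimal
  filtration position.  Under the anti-transpose correspondence this
  reproduces exactly the standard homology persistence pairs.
* A pair (sigma^m, tau^(m+1)) contributes the half-open interval
  [f(sigma), f(tau)) to beta_m, in units of edge rank.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _union_find_negative_edges(edge_i, edge_j, n):
    """Edges (in filtration order) that merge two components (negative)."""
    parent = np.arange(n)
    negative = np.zeros(edge_i.shape[0], np.bool_)
    for k in range(edge_i.shape[0]):
        a = edge_i[k]
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        b = edge_j[k]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a != b:
            parent[a] = b
            negative[k] = True
    return negative


@njit(cache=True)
def _reduce(cols_rows, n_rows):
    """Reduce a coboundary matrix given per-column sorted row positions.

    cols_rows : (n_cols, width) int64, each row sorted ascending; columns
        are already in processing order (decreasing m-simplex position).
    Returns pair_row[c] = pivot row position of column c, or -1 if the
    column reduced to zero (essential class).
    """
    n_cols = cols_rows.shape[0]
    width = cols_rows.shape[1]
    pivot_owner = np.full(n_rows, -1, np.int64)
    # storage for reduced pivot columns, indexed by owning column
    cap = max(64, 2 * n_cols * width)
    data = np.empty(cap, np.int64)
    offs = np.full(n_cols, -1, np.int64)
    lens = np.zeros(n_cols, np.int64)
    data_len = 0
    pair_row = np.full(n_cols, -1, np.int64)

    for c in range(n_cols):
        cur = cols_rows[c].copy()
        l = width
        while l > 0:
            p = cur[0]
            o = pivot_owner[p]
            if o == -1:
                pivot_owner[p] = c
                pair_row[c] = p
                while data_len + l > cap:
                    cap *= 2
                    newdata = np.empty(cap, np.int64)
                    newdata[:data_len] = data[:data_len]
                    data = newdata
                data[data_len:data_len + l] = cur[:l]
                offs[c] = data_len
                lens[c] = l
                data_len += l
                break
            # symmetric difference with the stored column owning this pivot
            ob = offs[o]
            lb = lens[o]
            out = np.empty(l + lb, np.int64)
            i = 0
            j = 0
            k = 0
            while i < l and j < lb:
                ai = cur[i]
                bj = data[ob + j]
                if ai < bj:
                    out[k] = ai
                    i += 1
                    k += 1
                elif ai > bj:
                    out[k] = bj
                    j += 1
                    k += 1
                else:
                    i += 1
                    j += 1
            while i < l:
                out[k] = cur[i]
                i += 1
                k += 1
            while j < lb:
                out[k] = data[ob + j]
                j += 1
                k += 1
            cur = out
            l = k
    return pair_row


_BINOM_CACHE: dict[int, np.ndarray] = {}


def _binom_table(n: int, kmax: int) -> np.ndarray:
    """Pascal triangle table C[v, i] for v in [0, n], i in [0, kmax]."""
    key = (n, kmax)
    tab = _BINOM_CACHE.get(key)
    if tab is None:
        tab = np.zeros((n + 1, kmax + 1), dtype=np.int64)
        tab[:, 0] = 1
        for v in range(1, n + 1):
            for i in range(1, kmax + 1):
                tab[v, i] = tab[v - 1, i - 1] + tab[v - 1, i]
        _BINOM_CACHE[key] = tab
    return tab


def _combinations(n: int, k: int) -> np.ndarray:
    """All k-subsets of range(n) in lexicographic order, shape (C(n,k), k)."""
    if k == 0:
        return np.zeros((1, 0), dtype=np.int32)
    if k > n:
        return np.zeros((0, k), dtype=np.int32)
    # iterative construction: extend (k-1)-subsets by every larger vertex
    prev = np.arange(n, dtype=np.int32)[:, None]
    for _ in range(k - 1):
        last = prev[:, -1]
        reps = (n - 1 - last).astype(np.int64)
        rows = np.repeat(np.arange(prev.shape[0]), reps)
        # new last vertex runs from last+1 to n-1 for each row
        ends = np.cumsum(reps)
        starts = ends - reps
        newlast = np.arange(ends[-1], dtype=np.int64) - starts[rows] + last[rows] + 1
        prev = np.column_stack([prev[rows], newlast.astype(np.int32)])
    return prev


def _colex_rank(combos: np.ndarray, binom: np.ndarray) -> np.ndarray:
    """Colexicographic rank of each sorted combination row."""
    k = combos.shape[1]
    rank = np.zeros(combos.shape[0], dtype=np.int64)
    for i in range(k):
        rank += binom[combos[:, i], i + 1]
    return rank


def _simplex_filtration(combos: np.ndarray, edge_rank: np.ndarray) -> np.ndarray:
    """Filtration value (max edge rank) of each simplex."""
    k = combos.shape[1]
    f = np.zeros(combos.shape[0], dtype=np.int64)
    for a in range(k):
        for b in range(a + 1, k):
            np.maximum(f, edge_rank[combos[:, a], combos[:, b]], out=f)
    return f


def flag_persistence_pairs(S: np.ndarray, max_dim: int = 2):
    """Persistence pairs of the decreasing-similarity flag filtration.

    Parameters
    ----------
    S : (n, n) symmetric similarity matrix (diagonal ignored).
    max_dim : highest homology dimension m; simplices up to dimension
        max_dim + 1 are enumerated so every beta_m (m <= max_dim) is exact.

    Returns
    -------
    n_edges : total number of possible edges E = C(n, 2).
    pairs : dict {m: (births, deaths)} in edge-rank units (1-based);
        beta_m at edge count k counts pairs with birth <= k < death.
        death = E + 1 flags an essential class (cannot occur when the
        full (m+1)-skeleton is included, kept for safety).
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[1] != n:
        raise ValueError("similarity matrix must be square")
    if not np.all(np.isfinite(S[np.triu_indices(n, 1)])):
        raise ValueError("similarity matrix contains non-finite entries")
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    max_dim = int(min(max_dim, n - 2))
    iu, ju = np.triu_indices(n, 1)
    E = iu.shape[0]
    vals = S[iu, ju]
    # decreasing similarity; ties by lexicographic (i, j)
    order = np.lexsort((ju, iu, -vals))
    edge_rank = np.zeros((n, n), dtype=np.int64)
    r = np.empty(E, dtype=np.int64)
    r[order] = np.arange(1, E + 1)
    edge_rank[iu, ju] = r
    edge_rank[ju, iu] = r

    binom = _binom_table(n, max_dim + 3)

    # per-dimension simplex bookkeeping: combos in position (filtration) order
    combos = {}
    fvals = {}
    pos_by_colex = {}
    for q in range(1, max_dim + 2):  # simplex dimension q has q+1 vertices
        cb = _combinations(n, q + 1)
        f = _simplex_filtration(cb, edge_rank)
        srt = np.argsort(f, kind="stable")
        cb = cb[srt]
        f = f[srt]
        combos[q] = cb
        fvals[q] = f
        lookup = np.full(binom[n, q + 1], -1, dtype=np.int64)
        lookup[_colex_rank(cb, binom)] = np.arange(cb.shape[0])
        pos_by_colex[q] = lookup

    # negative edges via union-find (clearing for dimension 1)
    ei = combos[1][:, 0].astype(np.int64)
    ej = combos[1][:, 1].astype(np.int64)
    negative = _union_find_negative_edges(ei, ej, n)

    pairs = {}
    for m in range(1, max_dim + 1):
        cb_m = combos[m]
        f_m = fvals[m]
        positive_pos = np.flatnonzero(~negative)
        if positive_pos.size == 0:
            pairs[m] = (np.zeros(0, np.int64), np.zeros(0, np.int64))
            negative = np.zeros(combos[m + 1].shape[0], np.bool_)
            continue
        # processing order: decreasing filtration position
        proc = positive_pos[::-1]
        verts = cb_m[proc]  # (n_cols, m+1)
        # cofacet row positions: add every vertex not in the simplex
        n_cols = verts.shape[0]
        member = np.zeros((n_cols, n), dtype=bool)
        rows_idx = np.repeat(np.arange(n_cols), m + 1)
        member[rows_idx, verts.ravel()] = True
        # colex rank of sorted(verts + v): insert v at its order position
        cof = np.empty((n_cols, n - m - 1), dtype=np.int64)
        col_fill = np.zeros(n_cols, dtype=np.int64)
        for v in range(n):
            sel = ~member[:, v]
            if not np.any(sel):
                continue
            vv = verts[sel]
            # rank of union: for vertices below v keep index, above v shift up
            below = vv < v
            idx = np.where(below, np.arange(1, m + 2), np.arange(2, m + 3))
            rk = np.zeros(sel.sum(), dtype=np.int64)
            for i in range(m + 1):
                rk += binom[vv[:, i], idx[:, i]]
            nbelow = below.sum(axis=1)
            rk += binom[v, nbelow + 1]
            pos = pos_by_colex[m + 1][rk]
            rows = np.flatnonzero(sel)
            cof[rows, col_fill[rows]] = pos
            col_fill[rows] += 1
        cof.sort(axis=1)
        n_rows = combos[m + 1].shape[0]
        pair_row = _reduce(cof, n_rows)
        paired = pair_row >= 0
        births = f_m[proc[paired]]
        deaths = fvals[m + 1][pair_row[paired]]
        ess_births = f_m[proc[~paired]]
        if ess_births.size:
            births = np.concatenate([births, ess_births])
            deaths = np.concatenate([deaths, np.full(ess_births.size, E + 1, np.int64)])
        pairs[m] = (births, deaths)
        # clearing for the next dimension: pivot rows are negative (m+1)-simplices
        negative = np.zeros(n_rows, np.bool_)
        negative[pair_row[paired]] = True
    return E, pairs
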