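"""Vietoris-Rips persistent homology for H0, H1 and H2.

Standard persistence computation over Z/2: H0 by union-find over the sorted
edge filtration (Kruskal pairing), H1 and H2 by boundary-matrix reduction
with the clearing (reduce tetrahedra first, skip their pivot triangles) and
compression (drop rows of negative simplices) optimizations. Simplex
enumeration and face lookups are vectorized; reduction columns are sparse
sets of row indices, which stay small because zero-persistence pairs — the
vast majority in a Rips filtration — resolve after a single pivot check.

The filtration value of a simplex is its diameter (longest pairwise
distance). Bars of zero persistence are discarded. Classes still alive at
the threshold are reported with ``death = inf``; downstream significance
rules cap them at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: guard on the number of triangles + tetrahedra a single run may enumerate
DEFAULT_SIMPLEX_CAP = 12_000_000


@dataclass
class Barcode:
    """Birth/death pairs per homology group for one (sub)cloud."""

    bars: dict[int, np.ndarray]
    threshold: float
    n_points: int
    subsample_ids: np.ndarray | None = None
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, arr in self.bars.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 2)
            if arr.size and np.any(arr[:, 1] < arr[:, 0]):
                raise ValueError(f"H{k} bar with death < birth")
            self.bars[k] = arr

    def persistence(self, k: int) -> np.ndarray:
        """Bar lengths for group k, infinite deaths capped at the threshold."""
        arr = self.bars.get(k, np.empty((0, 2)))
        if not arr.size:
            return np.empty(0)
        death = np.minimum(arr[:, 1], self.threshold)
        return death - arr[:, 0]


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if self.rank[ri] < self.rank[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        if self.rank[ri] == self.rank[rj]:
            self.rank[ri] += 1
        return True


def enclosing_radius(dm: np.ndarray) -> float:
    """min_i max_j d(i, j): beyond this radius the complex is a cone and no
    further homology is created."""
    return float(np.min(np.max(dm, axis=1)))


def _reduce_columns(col_rows: list[set[int]]):
    """Z/2 reduction of sparse columns given in filtration order.

    Returns ``(pairs, zero_cols)``: ``pairs`` maps pivot row -> column index;
    ``zero_cols`` lists columns that reduced to zero.
    """
    pivot_of_row: dict[int, int] = {}
    stored: dict[int, set[int]] = {}
    zero_cols: list[int] = []
    for j, col in enumerate(col_rows):
        while col:
            low = max(col)
            other = pivot_of_row.get(low)
            if other is None:
                pivot_of_row[low] = j
                stored[j] = col
                break
            col = col ^ stored[other]
        else:
            zero_cols.append(j)
    return pivot_of_row, zero_cols


def _sorted_edges(dm: np.ndarray, thresh: float):
    n = dm.shape[0]
    iu, ju = np.triu_indices(n, 1)
    d = dm[iu, ju]
    keep = d <= thresh
    ei, ej, ed = iu[keep], ju[keep], d[keep]
    order = np.lexsort((ej, ei, ed))
    return ei[order], ej[order], ed[order]


def _enumerate_triangles(dm, adj, ei, ej, ed):
    """All triangles i<j<k with pairwise distances <= thresh, sorted by
    (diameter, lex)."""
    parts = []
    for idx in range(ed.size):
        i, j = int(ei[idx]), int(ej[idx])
        common = np.flatnonzero(adj[i] & adj[j])
        common = common[common > j]
        if common.size:
            diam = np.maximum(ed[idx], np.maximum(dm[i, common], dm[j, common]))
            parts.append(
                (
                    np.full(common.size, i),
                    np.full(common.size, j),
                    common,
                    diam,
                )
            )
    if not parts:
        z = np.empty(0, dtype=int)
        return z, z, z, np.empty(0)
    ti = np.concatenate([p[0] for p in parts])
    tj = np.concatenate([p[1] for p in parts])
    tk = np.concatenate([p[2] for p in parts])
    td = np.concatenate([p[3] for p in parts])
    order = np.lexsort((tk, tj, ti, td))
    return ti[order], tj[order], tk[order], td[order]


def _enumerate_tetrahedra(dm, adj, ti, tj, tk, td, budget):
    parts = []
    count = 0
    for s in range(td.size):
        i, j, k = int(ti[s]), int(tj[s]), int(tk[s])
        common = np.flatnonzero(adj[i] & adj[j] & adj[k])
        common = common[common > k]
        if common.size:
            diam = np.maximum(
                td[s], np.maximum(dm[i, common], np.maximum(dm[j, common], dm[k, common]))
            )
            parts.append(
                (
                    np.full(common.size, i),
                    np.full(common.size, j),
                    np.full(common.size, k),
                    common,
                    diam,
                )
            )
            count += common.size
            if count > budget:
                raise MemoryError(
                    "tetrahedron count exceeds the simplex cap; "
                    "reduce thresh or the subsample size"
                )
    if not parts:
        z = np.empty(0, dtype=int)
        return z, z, z, z, np.empty(0)
    qi = np.concatenate([p[0] for p in parts])
    qj = np.concatenate([p[1] for p in parts])
    qk = np.concatenate([p[2] for p in parts])
    ql = np.concatenate([p[3] for p in parts])
    qd = np.concatenate([p[4] for p in parts])
    order = np.lexsort((ql, qk, qj, qi, qd))
    return qi[order], qj[order], qk[order], ql[order], qd[order]


def _row_lookup(keys_in_order: np.ndarray):
    """Map simplex keys (given in filtration order) to their filtration index
    via a sorted-key table + searchsorted."""
    sorter = np.argsort(keys_in_order)
    sorted_keys = keys_in_order[sorter]

    def lookup(query: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(sorted_keys, query)
        return sorter[pos]

    return lookup


def rips_persistence(
    X: np.ndarray | None = None,
    maxdim: int = 2,
    thresh: float | None = None,
    dm: np.ndarray | None = None,
    simplex_cap: int = DEFAULT_SIMPLEX_CAP,
) -> Barcode:
    """Compute the Rips barcode of a point cloud (or distance matrix).

    Parameters
    ----------
    X : ndarray (n, d), optional
        Point cloud; Euclidean distances are used. Alternatively pass ``dm``.
    maxdim : int
        Highest homology group (0..2).
    thresh : float, optional
        Filtration cap. Defaults to the enclosing radius, at which every
        class that will ever die has died — note this default can be very
        expensive above H0; pass an explicit threshold for maxdim >= 1.
    simplex_cap : int
        Bound on enumerated triangles + tetrahedra; exceeding it raises a
        ``MemoryError`` with guidance to lower ``thresh`` or subsample.
    """
    if dm is None:
        if X is None:
            raise ValueError("pass a point cloud or a distance matrix")
        dm = squareform(pdist(np.asarray(X, dtype=float)))
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if maxdim not in (0, 1, 2):
        raise ValueError("maxdim must be 0, 1 or 2")
    if thresh is None:
        thresh = enclosing_radius(dm)

    ei, ej, ed = _sorted_edges(dm, thresh)

    # ---- H0: Kruskal pairing ----
    # alongside each finite bar, record the size of the smaller component
    # absorbed at that merge: real clusters die as macroscopic components,
    # stragglers as tiny ones, and significance rules exploit that
    uf = _UnionFind(n)
    size = np.ones(n, dtype=int)
    h0 = []
    merge_sizes = []
    mst_mask = np.zeros(ed.size, dtype=bool)
    for idx in range(ed.size):
        i, j = int(ei[idx]), int(ej[idx])
        ri, rj = uf.find(i), uf.find(j)
        if ri != rj:
            smaller = min(size[ri], size[rj])
            uf.union(ri, rj)
            size[uf.find(ri)] = size[ri] + size[rj]
            mst_mask[idx] = True
            if ed[idx] > 0:
                h0.append((0.0, ed[idx]))
                merge_sizes.append(smaller)
    roots = {uf.find(i) for i in range(n)}
    for r in roots:
        h0.append((0.0, np.inf))
        merge_sizes.append(int(size[r]))
    bars = {0: np.asarray(h0, dtype=float).reshape(-1, 2)}
    meta = {"h0_component_sizes": np.asarray(merge_sizes, dtype=int)}
    if maxdim == 0:
        return Barcode(bars, threshold=thresh, n_points=n, meta=meta)

    adj = dm <= thresh
    np.fill_diagonal(adj, False)

    ti, tj, tk, td = _enumerate_triangles(dm, adj, ei, ej, ed)
    if td.size > simplex_cap:
        raise MemoryError(
            f"{td.size} triangles exceed the simplex cap {simplex_cap}; "
            "reduce thresh or the subsample size"
        )

    base = np.int64(n)
    edge_lookup = _row_lookup(ei.astype(np.int64) * base + ej)
    tri_cleared = np.zeros(td.size, dtype=bool)
    tet_pairs: dict[int, float] = {}

    if maxdim == 2 and td.size:
        qi, qj, qk, ql, qd = _enumerate_tetrahedra(
            dm, adj, ti, tj, tk, td, budget=simplex_cap - td.size
        )
        if qd.size:
            tri_lookup = _row_lookup(
                (ti.astype(np.int64) * base + tj) * base + tk
            )
            f0 = tri_lookup((qi.astype(np.int64) * base + qj) * base + qk)
            f1 = tri_lookup((qi.astype(np.int64) * base + qj) * base + ql)
            f2 = tri_lookup((qi.astype(np.int64) * base + qk) * base + ql)
            f3 = tri_lookup((qj.astype(np.int64) * base + qk) * base + ql)
            cols = [
                {int(a), int(b), int(c), int(d)}
                for a, b, c, d in zip(f0, f1, f2, f3)
            ]
            pairs3, _ = _reduce_columns(cols)
            for tri_row, tet_col in pairs3.items():
                tri_cleared[tri_row] = True
                if qd[tet_col] > td[tri_row]:
                    tet_pairs[tri_row] = float(qd[tet_col])

    # ---- reduce triangle boundaries over positive edges for H1 ----
    edge_is_positive = ~mst_mask
    h1 = []
    zero_tri: list[int] = []
    if td.size:
        e01 = edge_lookup(ti.astype(np.int64) * base + tj)
        e02 = edge_lookup(ti.astype(np.int64) * base + tk)
        e12 = edge_lookup(tj.astype(np.int64) * base + tk)
        cols = []
        col_tri = []
        for s in range(td.size):
            if tri_cleared[s]:
                continue  # clearing: column would reduce to zero
            col = {
                int(r)
                for r in (e01[s], e02[s], e12[s])
                if edge_is_positive[r]
            }
            cols.append(col)
            col_tri.append(s)
        pairs2, zero2 = _reduce_columns(cols)
        paired_edges = set(pairs2)
        for edge_row, cj in pairs2.items():
            if td[col_tri[cj]] > ed[edge_row]:
                h1.append((float(ed[edge_row]), float(td[col_tri[cj]])))
        for r in np.flatnonzero(edge_is_positive):
            if int(r) not in paired_edges:
                h1.append((float(ed[r]), np.inf))
        zero_tri = [col_tri[cj] for cj in zero2]
    else:
        for r in np.flatnonzero(edge_is_positive):
            h1.append((float(ed[r]), np.inf))
    bars[1] = np.asarray(h1, dtype=float).reshape(-1, 2)
    if maxdim == 1:
        return Barcode(bars, threshold=thresh, n_points=n, meta=meta)

    # ---- H2 bars ----
    h2 = [(float(td[tri]), death) for tri, death in tet_pairs.items()]
    # positive triangles never killed by a tetrahedron are alive at thresh
    h2.extend((float(td[s]), np.inf) for s in zero_tri)
    bars[2] = np.asarray(h2, dtype=float).reshape(-1, 2)
    return Barcode(bars, threshold=thresh, n_points=n, meta=meta)
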