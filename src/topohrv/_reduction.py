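"""Numba kernels: dim-1 persistence pairing of a Vietoris-Rips filtration.

The pairing is computed the way modern flag-complex persistence codes do it:

* dim-0 pairs come from union-find over edges in filtration order; spanning
  (negative) edges are *cleared* -- their coboundary columns are skipped.
* For each remaining (positive) edge, its minimal cofacet triangle is found
  combinatorially; when the edge is in turn the maximal facet of that
  triangle, the two form an *apparent pair*, which is a persistence pair of
  the simplexwise filtration and needs no matrix reduction.  On flag
  filtrations apparent pairs account for nearly all pairs.
* The few edges left are reduced in the anti-transposed (coboundary) matrix,
  columns in decreasing edge order; the working column lives in a max-heap
  with lazy Z2 cancellation (equal entries annihilate in pairs), apparent
  pairs act as pre-reduced pivot owners whose columns (raw coboundaries of
  their edges) are regenerated on demand, and fully reduced columns are
  stored compressed as the list of edges whose coboundaries sum to them.

Simplexwise order: edges by (length, i, j); triangles by (diameter, i, j, k).
All comparisons use these keys exactly, so ties (duplicate points) are
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import List

__all__ = ["rips_dim1_pairs"]


@njit(cache=False)
def _edge_key_less(la, ia, ja, lb, ib, jb):
    """Filtration order of edges: (length, i, j) lexicographic."""
    if la != lb:
        return la < lb
    if ia != ib:
        return ia < ib
    return ja < jb


@njit(cache=False)
def _sort3(a, b, c):
    if a > b:
        a, b = b, a
    if b > c:
        b, c = c, b
    if a > b:
        a, b = b, a
    return a, b, c


@njit(cache=False)
def _min_cofacet(a, b, le, dist, n, thr):
    """Minimal cofacet triangle of edge (a, b) by (diam, i, j, k); v or -1."""
    best_v = -1
    best_diam = np.inf
    bi = bj = bk = n
    for v in range(n):
        if v == a or v == b:
            continue
        dv = max(dist[v, a], dist[v, b])
        diam = max(le, dv)
        if diam > thr:
            continue
        i, j, k = _sort3(a, b, v)
        if (diam < best_diam
                or (diam == best_diam
                    and (i < bi or (i == bi and (j < bj or (j == bj and k < bk)))))):
            best_v = v
            best_diam = diam
            bi, bj, bk = i, j, k
    return best_v


@njit(cache=False)
def _is_max_facet(a, b, v, le, dist):
    """Is edge (a, b) the maximal facet of triangle (a, b, v)?"""
    for (x, y) in ((a, v), (b, v)):
        i, j = (x, y) if x < y else (y, x)
        if not _edge_key_less(dist[i, j], i, j, le, min(a, b), max(a, b)):
            return False
    return True


# -- max-heap of int64 with lazy Z2 cancellation ----------------------------

@njit(cache=False)
def _heap_push(heap, size, val):
    if size == heap.size:
        grown = np.empty(heap.size * 2, np.int64)
        grown[:size] = heap[:size]
        heap = grown
    heap[size] = val
    i = size
    size += 1
    while i > 0:
        p = (i - 1) >> 1
        if heap[p] < heap[i]:
            heap[p], heap[i] = heap[i], heap[p]
            i = p
        else:
            break
    return heap, size


@njit(cache=False)
def _heap_pop(heap, size):
    top = heap[0]
    size -= 1
    heap[0] = heap[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        big = i
        if l < size and heap[l] > heap[big]:
            big = l
        if r < size and heap[r] > heap[big]:
            big = r
        if big == i:
            break
        heap[i], heap[big] = heap[big], heap[i]
        i = big
    return top, size


@njit(cache=False)
def _pop_pivot(heap, size):
    """Largest entry of odd multiplicity (removed from the heap), or -1."""
    while size > 0:
        v, size = _heap_pop(heap, size)
        if size > 0 and heap[0] == v:
            _, size = _heap_pop(heap, size)  # Z2: pairs cancel
        else:
            return v, size
    return -1, size


@njit(cache=False)
def _push_coboundary(heap, size, a, b, le, dist, n, thr, tri_rank, m):
    """Push every cofacet of edge (a, b) (as reversed rank) onto the heap."""
    for v in range(n):
        if v == a or v == b:
            continue
        diam = max(le, max(dist[v, a], dist[v, b]))
        if diam > thr:
            continue
        i, j, k = _sort3(a, b, v)
        heap, size = _heap_push(heap, size,
                                m - 1 - tri_rank[(i * n + j) * n + k])
    return heap, size


@njit(cache=False)
def _dim1_pairing(dist, ei, ej, ew, positive, tri_rank, m, thr):
    """Full dim-1 pairing; returns (edge -> triangle rank or -1, essential mask)."""
    n = dist.shape[0]
    E = ei.size
    pair = np.full(E, -1, np.int64)
    essential = np.zeros(E, np.bool_)
    needs = np.zeros(E, np.bool_)
    apparent_owner = np.full(m, -1, np.int64)

    for e in range(E):
        if not positive[e]:
            continue
        a, b, le = ei[e], ej[e], ew[e]
        v = _min_cofacet(a, b, le, dist, n, thr)
        if v == -1:
            essential[e] = True
            continue
        if _is_max_facet(a, b, v, le, dist):
            i, j, k = _sort3(a, b, v)
            t = tri_rank[(i * n + j) * n + k]
            apparent_owner[t] = e
            pair[e] = t
        else:
            needs[e] = True

    regular_owner = np.full(m, -1, np.int64)
    stored = List()  # per claimed pivot: edges whose coboundaries sum to it
    stored.append(np.empty(0, np.int64))
    stored.pop()
    for e in range(E - 1, -1, -1):
        if not needs[e]:
            continue
        heap = np.empty(1024, np.int64)
        size = 0
        heap, size = _push_coboundary(heap, size, ei[e], ej[e], ew[e],
                                      dist, n, thr, tri_rank, m)
        acc = np.empty(64, np.int64)  # edge representation of the column
        acc[0] = e
        acc_n = 1
        while True:
            piv, size = _pop_pivot(heap, size)
            if piv == -1:
                essential[e] = True
                break
            t = m - 1 - piv
            ao = apparent_owner[t]
            if ao >= 0:
                add = np.empty(1, np.int64)
                add[0] = ao
            else:
                ro = regular_owner[t]
                if ro == -1:
                    regular_owner[t] = len(stored)
                    stored.append(acc[:acc_n].copy())
                    pair[e] = t
                    break
                add = stored[ro]
            # put the pivot back; the added column contains it and cancels it
            heap, size = _heap_push(heap, size, piv)
            for idx in range(add.size):
                e2 = add[idx]
                heap, size = _push_coboundary(heap, size, ei[e2], ej[e2],
                                              ew[e2], dist, n, thr,
                                              tri_rank, m)
                if acc_n == acc.size:
                    grown = np.empty(acc.size * 2, np.int64)
                    grown[:acc_n] = acc[:acc_n]
                    acc = grown
                acc[acc_n] = e2
                acc_n += 1
    return pair, essential


def rips_dim1_pairs(dist, ei, ej, ew, positive, tri_rank, n_triangles, thr):
    """Pair positive edges with triangle ranks (see :func:`_dim1_pairing`).

    Parameters are the distance matrix, edges in filtration order (arrays of
    endpoints and lengths plus a positivity mask from union-find), a dense
    rank lookup ``tri_rank[(i*n+j)*n+k]`` over triangles in filtration order,
    the triangle count, and the diameter threshold.
    """
    return _dim1_pairing(
        np.ascontiguousarray(dist, dtype=np.float64),
        ei.astype(np.int64), ej.astype(np.int64),
        ew.astype(np.float64), positive.astype(np.bool_),
        tri_rank, np.int64(n_triangles), np.float64(thr),
    )
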