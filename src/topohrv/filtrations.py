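"""Filtrations of a 1-D time series: sub-level sets and Vietoris-Rips.

Two complementary topological views of a signal are built here:

* the **sub-level set filtration** of the signal itself, whose dim-0
  persistence pairs every local minimum with the local maximum at which its
  valley merges into an older one (elder rule) -- capturing the oscillation
  pattern of the series;
* the **Vietoris-Rips (VR) filtration** of the Takens delay embedding, whose
  dim-0/dim-1 persistence describes the geometry of the reconstructed
  attractor in R^p.

Scale convention: all VR births and deaths are on the epsilon (radius) scale,
i.e. a simplex enters at epsilon = diam(sigma) / 2.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .persistence import Filtration, PersistenceDiagram
from ._reduction import rips_dim1_pairs

__all__ = [
    "sublevel_diagram",
    "takens_embedding",
    "vr_diagrams",
    "explicit_sublevel_filtration",
    "explicit_vr_filtration",
]


# ---------------------------------------------------------------------------
# Sub-level set filtration (dim 0, union-find)
# ---------------------------------------------------------------------------

def sublevel_diagram(series) -> PersistenceDiagram:
    """Dim-0 persistence diagram of the sub-level set filtration of a series.

    Births are local-minimum values; a class dies at the local-maximum value
    where its component merges into an older one (elder rule: the component
    whose minimum appeared later dies; exact ties broken by sample index).
    Exactly one essential point (global minimum, inf) is returned.
    Zero-persistence merges (flat regions) are not reported.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    parent = np.arange(n)
    # birth bookkeeping per component root: (value, activation rank)
    birth_val = np.empty(n)
    birth_ord = np.empty(n, dtype=int)
    active = np.zeros(n, dtype=bool)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs: list[tuple] = []
    order = np.lexsort((np.arange(n), x))  # ascending value, index tie-break
    for rank, i in enumerate(order):
        active[i] = True
        birth_val[i] = x[i]
        birth_ord[i] = rank
        for nb in (i - 1, i + 1):
            if 0 <= nb < n and active[nb]:
                ra, rb = find(i), find(nb)
                if ra == rb:
                    continue
                # elder rule: the younger component (later birth) dies now
                if (birth_val[ra], birth_ord[ra]) <= (birth_val[rb], birth_ord[rb]):
                    elder, younger = ra, rb
                else:
                    elder, younger = rb, ra
                death = x[i]
                if death > birth_val[younger]:
                    pairs.append((birth_val[younger], death, 0))
                parent[younger] = elder
    pairs.append((float(x.min()), math.inf, 0))
    return PersistenceDiagram.from_pairs(pairs)


def explicit_sublevel_filtration(series) -> Filtration:
    """The sub-level filtration as an explicit simplicial complex.

    Vertices enter at their sample value, consecutive edges at the max of
    their endpoints.  Used to cross-check :func:`sublevel_diagram` against
    the generic reduction engine.
    """
    x = np.asarray(series, dtype=float).ravel()
    filt = Filtration()
    for i, v in enumerate(x):
        filt.add(v, (i,))
    for i in range(x.size - 1):
        filt.add(max(x[i], x[i + 1]), (i, i + 1))
    return filt


# ---------------------------------------------------------------------------
# Takens delay embedding
# ---------------------------------------------------------------------------

def takens_embedding(series, p: int, tau: int) -> np.ndarray:
    """Delay embedding of a scalar series into R^p with lag ``tau``.

    Row t is (x(t), x(t - tau), ..., x(t - (p-1) tau)) for every admissible
    t, in increasing t order; the output has n - (p-1)*tau rows.
    """
    x = np.asarray(series, dtype=float).ravel()
    if p < 1 or tau < 1:
        raise ValueError("p and tau must be positive integers")
    needed = (p - 1) * tau + 1
    if x.size < needed:
        raise ValueError(
            f"series of length {x.size} too short for Takens embedding with "
            f"p={p}, tau={tau}: at least {needed} samples required"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    t0 = (p - 1) * tau
    offsets = np.arange(p) * tau  # 0, tau, ..., (p-1) tau
    idx = np.arange(t0, x.size)[:, None] - offsets[None, :]
    return x[idx]


# ---------------------------------------------------------------------------
# Vietoris-Rips filtration (dim 0 via union-find, dim 1 via matrix reduction)
# ---------------------------------------------------------------------------

def _vr_dim0(n: int, order_i, order_j, lengths) -> list[tuple]:
    """Dim-0 pairs from Kruskal-style union-find over filtration-ordered edges."""
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs: list[tuple] = []
    for i, j, w in zip(order_i, order_j, lengths):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
            pairs.append((0.0, w / 2.0, 0))
    roots = {find(i) for i in range(n)}
    for _ in roots:
        pairs.append((0.0, math.inf, 0))
    return pairs


def vr_diagrams(cloud, max_dim: int = 1, max_scale: float = math.inf
                ) -> PersistenceDiagram:
    """Persistence diagrams of the Vietoris-Rips filtration of a point cloud.

    Births/deaths are on the epsilon (radius) scale: a simplex enters at
    epsilon = diam(sigma)/2.  Dim-0 deaths are half the merge distances
    (the Euclidean minimum-spanning-tree structure); the essential dim-0
    class (0, inf) is retained.  In dim >= 1 only positive-persistence
    points are reported.  Classes whose death exceeds ``max_scale`` are
    reported with death = inf (truncated filtration semantics).

    ``max_dim`` 0 and 1 run the optimized path; higher dimensions fall back
    to explicit enumeration through the generic engine and are only suitable
    for small clouds.
    """
    X = np.atleast_2d(np.asarray(cloud, dtype=float))
    if X.size == 0:
        raise ValueError("empty point cloud")
    n = X.shape[0]
    if max_scale <= 0:
        raise ValueError("max_scale must be positive")
    if max_dim >= 2:
        filt = explicit_vr_filtration(X, max_dim=max_dim, max_scale=max_scale)
        from .persistence import compute_persistence
        return compute_persistence(filt, max_dim).drop_zero_persistence()

    if n == 1:
        return PersistenceDiagram.from_pairs([(0.0, math.inf, 0)])

    dist = squareform(pdist(X))
    thr_diam = 2.0 * max_scale
    # enclosing-radius pruning: beyond r_enc the flag complex is a cone,
    # hence contractible; dim>=1 diagrams are unaffected
    r_enc = float(dist.max(axis=1).min())
    eff_thr = min(thr_diam, r_enc) if math.isfinite(thr_diam) else r_enc

    iu, ju = np.triu_indices(n, 1)
    w = dist[iu, ju]
    # filtration order: (length, lexicographic (i, j))
    edge_order = np.lexsort((ju, iu, w))
    ei, ej, ew = iu[edge_order], ju[edge_order], w[edge_order]

    pairs = _vr_dim0(n, ei[ew <= thr_diam], ej[ew <= thr_diam],
                     ew[ew <= thr_diam])
    if max_dim == 0:
        return PersistenceDiagram.from_pairs(pairs)

    # --- dim 1 ---
    keep = ew <= eff_thr
    ei, ej, ew = ei[keep], ej[keep], ew[keep]
    n_edges = ei.size

    # identify positive edges (cycle creators = non-merging edges)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    positive = np.zeros(n_edges, dtype=bool)
    for e in range(n_edges):
        ri, rj = find(ei[e]), find(ej[e])
        if ri == rj:
            positive[e] = True
        else:
            parent[rj] = ri

    dim1_pairs: list[tuple] = []
    if positive.any():
        # enumerate triangles with diameter <= eff_thr, in (i, j, k) order
        tri_chunks = []
        diam_chunks = []
        jj, kk = np.triu_indices(n, 1)
        d_jk = dist[jj, kk]
        for i in range(n - 2):
            mask = jj > i
            j_, k_ = jj[mask], kk[mask]
            dm = np.maximum(d_jk[mask], np.maximum(dist[i, j_], dist[i, k_]))
            sel = dm <= eff_thr
            if sel.any():
                j_, k_, dm = j_[sel], k_[sel], dm[sel]
                tri_chunks.append(np.column_stack(
                    [np.full(j_.size, i), j_, k_]
                ))
                diam_chunks.append(dm)
        if tri_chunks:
            tris = np.concatenate(tri_chunks)
            diams = np.concatenate(diam_chunks)
            # stable sort on diameter keeps the lexicographic tie order
            tri_order = np.argsort(diams, kind="stable")
            tris = tris[tri_order]
            diams = diams[tri_order]
            m = tris.shape[0]
            tri_rank = np.full(n * n * n, -1, dtype=np.int32)
            tri_rank[(tris[:, 0] * n + tris[:, 1]) * n + tris[:, 2]] = \
                np.arange(m, dtype=np.int32)
            edge_pair, essential = rips_dim1_pairs(
                dist, ei, ej, ew, positive, tri_rank, m, eff_thr)
        else:
            edge_pair = np.full(n_edges, -1, dtype=np.int64)
            essential = positive.copy()
        for e in np.nonzero(positive)[0]:
            birth = ew[e] / 2.0
            t = edge_pair[e]
            if t >= 0:
                death = diams[t] / 2.0
                if death > birth:
                    dim1_pairs.append((birth, death, 1))
            elif essential[e]:
                dim1_pairs.append((birth, math.inf, 1))
    return PersistenceDiagram.from_pairs(pairs + dim1_pairs)


def explicit_vr_filtration(cloud, max_dim: int = 1,
                           max_scale: float = math.inf) -> Filtration:
    """Enumerate the VR filtration explicitly (simplexes up to max_dim + 1).

    Entry values are on the epsilon scale (diam/2).  Exponential in cloud
    size; intended for small clouds in oracle comparisons.
    """
    from itertools import combinations

    X = np.atleast_2d(np.asarray(cloud, dtype=float))
    n = X.shape[0]
    dist = squareform(pdist(X)) if n > 1 else np.zeros((1, 1))
    thr_diam = 2.0 * max_scale
    filt = Filtration()
    for i in range(n):
        filt.add(0.0, (i,))
    for q in range(2, max_dim + 3):
        for simplex in combinations(range(n), q):
            diam = max(dist[a, b] for a, b in combinations(simplex, 2))
            if diam <= thr_diam:
                filt.add(diam / 2.0, simplex)
    return filt
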