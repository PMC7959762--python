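"""Persistent homology of filtered simplicial complexes over Z2.

This module is the combinatorial engine of the package.  A *filtration* is a
nested sequence of simplicial complexes; its persistent homology records, per
homology dimension q, the (birth, death) scale of every q-dimensional hole
(connected components for q = 0, loops for q = 1, ...).  Persistence is
computed by the standard column reduction of the filtration-ordered boundary
matrix over the two-element field, with the low-pivot pairing realizing the
birth/death pairing.

Conventions
-----------
* Simplexes are tuples of strictly increasing non-negative vertex ids; the
  dimension of a simplex is its vertex count minus one.
* Simplexes entering at the same filtration value are ordered by
  (dimension ascending, lexicographic vertex tuple).  This fixes the pairing
  for ties and makes :func:`compute_persistence` fully deterministic.
* Zero-persistence pairs (birth == death) are legal output of the core and
  are *not* filtered here; callers that want a "paper-style" diagram use
  :meth:`PersistenceDiagram.drop_zero_persistence`.

The engine is written for desk scale (explicit filtrations of at most a few
thousand simplexes); the production Vietoris-Rips path in
:mod:`topohrv.filtrations` has its own optimized reduction and uses this
module only as a cross-check oracle.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "Simplex",
    "Filtration",
    "PersistenceDiagram",
    "InvalidFiltrationError",
    "compute_persistence",
    "betti_numbers",
    "bottleneck_distance",
]

Simplex = tuple  # tuple of strictly increasing non-negative ints


class InvalidFiltrationError(ValueError):
    """Raised when a filtration violates the face-nesting contract."""


def _validate_simplex(simplex: Sequence[int]) -> tuple:
    s = tuple(int(v) for v in simplex)
    if len(s) == 0:
        raise InvalidFiltrationError("empty simplex")
    if any(v < 0 for v in s):
        raise InvalidFiltrationError(f"negative vertex id in simplex {s}")
    if any(a >= b for a, b in zip(s, s[1:])):
        raise InvalidFiltrationError(
            f"simplex vertices must be strictly increasing, got {s}"
        )
    return s


def _facets(simplex: tuple) -> list[tuple]:
    """Codimension-1 faces (boundary simplexes) of a simplex."""
    if len(simplex) == 1:
        return []
    return [simplex[:i] + simplex[i + 1:] for i in range(len(simplex))]


@dataclass
class Filtration:
    """An ordered collection of (value, simplex) entries.

    Every face of every simplex must be present with a value not larger than
    the simplex's own value.  Entries are sortable into filtration order by
    (value, dimension, lexicographic vertex tuple).
    """

    entries: list = field(default_factory=list)

    def add(self, value: float, simplex: Sequence[int]) -> None:
        self.entries.append((float(value), _validate_simplex(simplex)))

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_entries(self) -> list:
        return sorted(self.entries, key=lambda e: (e[0], len(e[1]), e[1]))

    def validate(self) -> None:
        """Check the nesting invariant; raise InvalidFiltrationError if broken."""
        value_of: dict[tuple, float] = {}
        for value, simplex in self.entries:
            if simplex in value_of:
                raise InvalidFiltrationError(f"duplicate simplex {simplex}")
            value_of[simplex] = value
        for value, simplex in self.entries:
            for face in _facets(simplex):
                if face not in value_of:
                    raise InvalidFiltrationError(
                        f"face {face} of {simplex} missing from filtration"
                    )
                if value_of[face] > value:
                    raise InvalidFiltrationError(
                        f"face {face} enters at {value_of[face]} after its "
                        f"coface {simplex} at {value}"
                    )

    def max_dim(self) -> int:
        return max(len(s) - 1 for _, s in self.entries) if self.entries else -1

    def value_range(self) -> tuple[float, float]:
        values = [v for v, _ in self.entries]
        return min(values), max(values)

    # -- CSV round trip: columns value, v0, v1, ... (variable arity) -------
    def write_csv(self, path) -> None:
        width = max(len(s) for _, s in self.entries) if self.entries else 0
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["value"] + [f"v{i}" for i in range(width)])
            for value, simplex in self.entries:
                row = [repr(value)] + [str(v) for v in simplex]
                writer.writerow(row)

    @classmethod
    def read_csv(cls, path) -> "Filtration":
        filt = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)  # header
            for row in reader:
                value = float(row[0])
                simplex = [int(tok) for tok in row[1:] if tok != ""]
                filt.add(value, simplex)
        return filt


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death, dim) points; death may be ``inf``."""

    points: np.ndarray  # shape (n, 3): birth, death, dim

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "PersistenceDiagram":
        rows = [(float(b), float(d), float(q)) for b, d, q in pairs]
        arr = np.asarray(rows, dtype=float).reshape(-1, 3)
        return cls(arr)

    def __len__(self) -> int:
        return self.points.shape[0]

    def in_dimension(self, dim: int) -> np.ndarray:
        """(birth, death) pairs of the given homology dimension."""
        mask = self.points[:, 2] == dim
        return self.points[mask, :2]

    def finite(self, dim: int) -> np.ndarray:
        pts = self.in_dimension(dim)
        return pts[np.isfinite(pts[:, 1])]

    def essential(self, dim: int) -> np.ndarray:
        pts = self.in_dimension(dim)
        return pts[~np.isfinite(pts[:, 1])]

    def drop_zero_persistence(self) -> "PersistenceDiagram":
        keep = self.points[:, 1] != self.points[:, 0]
        return PersistenceDiagram(self.points[keep])

    def dims(self) -> list[int]:
        return sorted({int(q) for q in self.points[:, 2]})

    def as_multiset(self) -> tuple:
        """Canonical hashable form for multiset comparison in tests."""
        return tuple(sorted(map(tuple, self.points.tolist())))

    # -- CSV round trip: dim, birth, death ("inf" for infinite death) ------
    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dim", "birth", "death"])
            for b, d, q in self.points:
                death = "inf" if math.isinf(d) else repr(float(d))
                writer.writerow([int(q), repr(float(b)), death])

    @classmethod
    def read_csv(cls, path) -> "PersistenceDiagram":
        pairs = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            for dim, birth, death in reader:
                d = math.inf if death == "inf" else float(death)
                pairs.append((float(birth), d, int(dim)))
        return cls.from_pairs(pairs)


def compute_persistence(filtration: Filtration, max_dim: int) -> PersistenceDiagram:
    """Persistent homology of a filtration by Z2 boundary-matrix reduction.

    Returns all (birth, death, dim) pairs for dims 0..max_dim, including
    essential classes (death = inf) and zero-persistence pairs.  Deterministic:
    ties at equal filtration values are broken by (dim, lexicographic vertices).
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    filtration.validate()
    order = filtration.sorted_entries()
    position = {simplex: i for i, (_, simplex) in enumerate(order)}
    values = [v for v, _ in order]
    dims = [len(s) - 1 for _, s in order]

    # column i holds the positions of the boundary simplexes of simplex i
    columns: list[set[int] | None] = []
    for _, simplex in order:
        columns.append({position[f] for f in _facets(simplex)})

    low_to_col: dict[int, int] = {}
    paired: set[int] = set()
    pairs: list[tuple] = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= columns[other]  # Z2 addition
        if col:
            low = max(col)
            low_to_col[low] = j
            paired.add(low)
            paired.add(j)
            q = dims[low]
            if q <= max_dim:
                pairs.append((values[low], values[j], q))
        columns[j] = col

    # unpaired positive simplexes carry essential classes
    for i in range(len(order)):
        if i in paired:
            continue
        if not columns[i]:  # positive (creator) simplex
            q = dims[i]
            if q <= max_dim:
                pairs.append((values[i], math.inf, q))
    return PersistenceDiagram.from_pairs(pairs)


def betti_numbers(filtration: Filtration, at_value: float) -> tuple[int, ...]:
    """Betti numbers of the sub-complex of simplexes with value <= at_value.

    beta_q counts diagram points alive at the queried value
    (birth <= at_value < death); zero-persistence pairs contribute nothing.
    """
    lo, hi = filtration.value_range()
    if not (lo <= at_value <= hi):
        raise ValueError(
            f"at_value {at_value} outside filtration range [{lo}, {hi}]"
        )
    qmax = filtration.max_dim()
    diagram = compute_persistence(filtration, qmax)
    betti = []
    for q in range(qmax + 1):
        pts = diagram.in_dimension(q)
        alive = (pts[:, 0] <= at_value) & (at_value < pts[:, 1])
        betti.append(int(alive.sum()))
    return tuple(betti)


# ---------------------------------------------------------------------------
# Bottleneck distance (exact, for stability testing at desk scale)
# ---------------------------------------------------------------------------

def _bottleneck_feasible(cost: np.ndarray, diag1: np.ndarray,
                         diag2: np.ndarray, lam: float) -> bool:
    """Perfect-matching feasibility at threshold lam.

    Bipartite graph on (points of d1 + one diagonal copy per point of d2)
    vs (points of d2 + one diagonal copy per point of d1); diagonal copies
    match each other at zero cost.
    """
    n1, n2 = len(diag1), len(diag2)
    size = n1 + n2
    rows, cols = [], []
    for i in range(n1):
        for j in range(n2):
            if cost[i, j] <= lam:
                rows.append(i)
                cols.append(j)
        if diag1[i] <= lam:  # point i to any diagonal slot
            for j in range(n2, size):
                rows.append(i)
                cols.append(j)
    for i in range(n1, size):
        j2 = i - n1
        if diag2[j2] <= lam:  # diagonal slot to point j2 of d2
            rows.append(i)
            cols.append(j2)
        for j in range(n2, size):  # diagonal-diagonal always allowed
            rows.append(i)
            cols.append(j)
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(size, size)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return bool((match >= 0).all())


def bottleneck_distance(d1: PersistenceDiagram, d2: PersistenceDiagram,
                        dim: int) -> float:
    """Exact bottleneck distance between the dim-q layers of two diagrams.

    Finite-death points are matched to each other or to the diagonal; the
    infimum over bijections of the max infinity-norm displacement is found by
    a binary search over the finite set of candidate thresholds with a
    bipartite perfect-matching feasibility test.  Diagrams with unequal
    numbers of essential (infinite-death) points in the dimension are at
    distance ``inf``.
    """
    if len(d1.essential(dim)) != len(d2.essential(dim)):
        return math.inf
    p1 = d1.finite(dim)
    p2 = d2.finite(dim)
    if len(p1) == 0 and len(p2) == 0:
        return 0.0
    diag1 = (p1[:, 1] - p1[:, 0]) / 2.0 if len(p1) else np.empty(0)
    diag2 = (p2[:, 1] - p2[:, 0]) / 2.0 if len(p2) else np.empty(0)
    if len(p1) and len(p2):
        cost = np.maximum(
            np.abs(p1[:, 0][:, None] - p2[:, 0][None, :]),
            np.abs(p1[:, 1][:, None] - p2[:, 1][None, :]),
        )
    else:
        cost = np.empty((len(p1), len(p2)))
    candidates = np.unique(
        np.concatenate([cost.ravel(), diag1, diag2, [0.0]])
    )
    lo, hi = 0, len(candidates) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if _bottleneck_feasible(cost, diag1, diag2, candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])
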