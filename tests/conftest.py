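"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms:
Betti numbers come from brute-force Z2 matrix ranks, sub-level component
counts from a threshold sweep, and spanning-tree structure from scipy.
"""

from itertools import combinations

import numpy as np
import pytest

from topohrv.persistence import Filtration


# ---------------------------------------------------------------------------
# Brute-force Z2 homology oracle
# ---------------------------------------------------------------------------

def gf2_rank(mat: np.ndarray) -> int:
    """Rank of a binary matrix over the two-element field."""
    m = (np.asarray(mat, dtype=np.int8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for col in range(cols):
        pivot = None
        for row in range(rank, rows):
            if m[row, col]:
                pivot = row
                break
        if pivot is None:
            continue
        m[[rank, pivot]] = m[[pivot, rank]]
        for row in range(rows):
            if row != rank and m[row, col]:
                m[row] ^= m[rank]
        rank += 1
    return rank


def betti_rank_oracle(filtration: Filtration, at_value: float) -> list[int]:
    """Betti numbers of the sub-complex at ``at_value`` via boundary ranks.

    beta_q = dim C_q - rank d_q - rank d_{q+1}.
    """
    present = sorted(
        {s for v, s in filtration.entries if v <= at_value},
        key=lambda s: (len(s), s),
    )
    max_dim = max((len(s) - 1 for s in present), default=-1)
    by_dim = {q: [s for s in present if len(s) - 1 == q]
              for q in range(max_dim + 1)}

    def boundary_rank(q: int) -> int:
        rows = by_dim.get(q - 1, [])
        cols = by_dim.get(q, [])
        if not rows or not cols:
            return 0
        row_index = {s: i for i, s in enumerate(rows)}
        mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for j, simplex in enumerate(cols):
            for i in range(len(simplex)):
                face = simplex[:i] + simplex[i + 1:]
                mat[row_index[face], j] = 1
        return gf2_rank(mat)

    betti = []
    for q in range(max_dim + 1):
        n_q = len(by_dim.get(q, []))
        betti.append(n_q - boundary_rank(q) - boundary_rank(q + 1))
    return betti


def random_filtration(rng: np.random.Generator, n_vertices: int = 6,
                      max_dim: int = 3) -> Filtration:
    """A random valid filtration: face-closed, values monotone on faces."""
    n = int(rng.integers(2, n_vertices + 1))
    value = {}
    for v in range(n):
        value[(v,)] = int(rng.integers(0, 3))
    for q in range(1, max_dim + 1):
        for simplex in combinations(range(n), q + 1):
            faces = [simplex[:i] + simplex[i + 1:] for i in range(len(simplex))]
            if all(f in value for f in faces) and rng.random() < 0.6:
                value[simplex] = max(value[f] for f in faces) + int(
                    rng.integers(0, 3))
    filt = Filtration()
    for simplex, v in value.items():
        filt.add(v, simplex)
    return filt


def sublevel_component_count(series: np.ndarray, h: float) -> int:
    """Number of connected components of {i : x_i <= h} (runs of samples)."""
    mask = np.asarray(series) <= h
    return int(np.sum(mask[1:] & ~mask[:-1]) + (1 if mask[0] else 0))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_subject():
    """One mixed wake/NREM recording with cleaned beats and windows."""
    import topohrv as th

    spec = th.SyntheticRecordingSpec(stages=["W"] * 4 + ["N"] * 8, seed=7)
    times, labels = th.synthetic_recording(spec)
    cleaned = th.clean_rpeaks(times)
    series = th.compute_ihr(cleaned)
    windows = th.extract_windows(series, labels, cleaned, subject_id="sA")
    return {"times": times, "labels": labels, "cleaned": cleaned,
            "series": series, "windows": windows}
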