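"""Z2 persistence engine: worked filtration, rank oracle, contracts."""

import math

import numpy as np
import pytest

from conftest import betti_rank_oracle, random_filtration
from topohrv.persistence import (Filtration, InvalidFiltrationError,
                                 PersistenceDiagram, betti_numbers,
                                 bottleneck_distance, compute_persistence)
from topohrv.synthetic import worked_filtration


class TestComputePersistence:
    def test_worked_filtration_full_output(self):
        """The 4-vertex worked filtration: one essential component born at 1,
        one loop born at 3 and filled at 5; tie merges appear as
        zero-persistence pairs."""
        diagram = compute_persistence(worked_filtration(), max_dim=1)
        positive = diagram.drop_zero_persistence()
        assert positive.as_multiset() == ((1.0, math.inf, 0.0),
                                          (3.0, 5.0, 1.0))
        # zero-persistence pairs are legal core output
        assert (2.0, 2.0, 0.0) in diagram.as_multiset()

    def test_single_vertex(self):
        filt = Filtration()
        filt.add(2.5, (0,))
        diagram = compute_persistence(filt, max_dim=1)
        assert diagram.as_multiset() == ((2.5, math.inf, 0.0),)

    def test_essential_count_equals_components(self, rng):
        """Essential dim-0 classes = connected components of the final complex."""
        import networkx as nx
        for _ in range(20):
            filt = random_filtration(rng)
            diagram = compute_persistence(filt, max_dim=0)
            graph = nx.Graph()
            for _, s in filt.entries:
                if len(s) == 1:
                    graph.add_node(s[0])
                elif len(s) == 2:
                    graph.add_edge(*s)
            assert len(diagram.essential(0)) == nx.number_connected_components(graph)

    def test_matches_rank_oracle(self, rng):
        """Diagram-derived Betti curves equal brute-force Z2 ranks everywhere."""
        for _ in range(30):
            filt = random_filtration(rng)
            qmax = filt.max_dim()
            diagram = compute_persistence(filt, max_dim=qmax)
            for value in sorted({v for v, _ in filt.entries}):
                expected = betti_rank_oracle(filt, value)
                for q, beta in enumerate(expected):
                    pts = diagram.in_dimension(q)
                    alive = int(((pts[:, 0] <= value) & (value < pts[:, 1])).sum())
                    assert alive == beta, (value, q)

    def test_birth_not_after_death(self, rng):
        for _ in range(10):
            diagram = compute_persistence(random_filtration(rng), max_dim=3)
            finite = diagram.points[np.isfinite(diagram.points[:, 1])]
            assert np.all(finite[:, 0] <= finite[:, 1])

    def test_deterministic(self, rng):
        filt = random_filtration(rng)
        a = compute_persistence(filt, max_dim=2).as_multiset()
        b = compute_persistence(filt, max_dim=2).as_multiset()
        assert a == b

    @pytest.mark.parametrize("build", [
        lambda f: f.add(0.0, (0, 1)),                       # missing vertices
        lambda f: (f.add(1.0, (0,)), f.add(1.0, (1,)),
                   f.add(0.5, (0, 1))),                     # face after coface
    ])
    def test_invalid_filtration_rejected(self, build):
        filt = Filtration()
        build(filt)
        with pytest.raises(InvalidFiltrationError):
            compute_persistence(filt, max_dim=1)


class TestBettiNumbers:
    def test_worked_filtration_hole_counts(self):
        """One component throughout; the loop exists at indices 3 and 4."""
        filt = worked_filtration()
        assert betti_numbers(filt, 3)[:2] == (1, 1)
        assert betti_numbers(filt, 2)[:2] == (1, 0)
        assert betti_numbers(filt, 4)[:2] == (1, 1)
        assert betti_numbers(filt, 5)[:2] == (1, 0)

    def test_hollow_triangle(self):
        filt = Filtration()
        for v in range(3):
            filt.add(0, (v,))
        for e in [(0, 1), (0, 2), (1, 2)]:
            filt.add(0, e)
        assert betti_numbers(filt, 0)[:2] == (1, 1)

    def test_two_disjoint_edges(self):
        filt = Filtration()
        for v in range(4):
            filt.add(0, (v,))
        filt.add(0, (0, 1))
        filt.add(0, (2, 3))
        assert betti_numbers(filt, 0)[0] == 2

    def test_out_of_range_value(self):
        with pytest.raises(ValueError):
            betti_numbers(worked_filtration(), 99)


class TestBottleneck:
    def test_identical_diagrams(self):
        d = PersistenceDiagram.from_pairs([(0, 2, 0), (1, 5, 0)])
        assert bottleneck_distance(d, d, 0) == 0.0

    def test_single_point_shift(self):
        """Direct match costs 1; projecting both to the diagonal costs 1.5."""
        a = PersistenceDiagram.from_pairs([(0, 2, 0)])
        b = PersistenceDiagram.from_pairs([(0, 3, 0)])
        assert bottleneck_distance(a, b, 0) == pytest.approx(1.0)

    def test_point_versus_empty(self):
        a = PersistenceDiagram.from_pairs([(0, 2, 0)])
        b = PersistenceDiagram(np.empty((0, 3)))
        assert bottleneck_distance(a, b, 0) == pytest.approx(1.0)

    def test_essential_mismatch_is_infinite(self):
        a = PersistenceDiagram.from_pairs([(0, math.inf, 0)])
        b = PersistenceDiagram(np.empty((0, 3)))
        assert bottleneck_distance(a, b, 0) == math.inf

    def test_matches_exhaustive_search(self, rng):
        """Agree with a permutation-enumeration matcher on tiny diagrams."""
        from itertools import permutations

        for _ in range(25):
            n1, n2 = rng.integers(0, 4, size=2)
            p1 = np.sort(rng.uniform(0, 4, size=(int(n1), 2)), axis=1)
            p2 = np.sort(rng.uniform(0, 4, size=(int(n2), 2)), axis=1)
            a = PersistenceDiagram.from_pairs([(b, d, 0) for b, d in p1])
            b_ = PersistenceDiagram.from_pairs([(b, d, 0) for b, d in p2])
            # exhaustive: pad both sides with diagonal slots, try all matchings
            size = len(p1) + len(p2)
            costs = np.zeros((size, size))
            for i in range(size):
                for j in range(size):
                    if i < len(p1) and j < len(p2):
                        costs[i, j] = max(abs(p1[i, 0] - p2[j, 0]),
                                          abs(p1[i, 1] - p2[j, 1]))
                    elif i < len(p1):
                        costs[i, j] = (p1[i, 1] - p1[i, 0]) / 2
                    elif j < len(p2):
                        costs[i, j] = (p2[j, 1] - p2[j, 0]) / 2
            best = 0.0 if size == 0 else min(
                max(costs[i, perm[i]] for i in range(size))
                for perm in permutations(range(size)))
            assert bottleneck_distance(a, b_, 0) == pytest.approx(best)


class TestDiagramIO:
    def test_csv_round_trip(self, tmp_path, rng):
        diagram = compute_persistence(random_filtration(rng), max_dim=2)
        path = tmp_path / "diagram.csv"
        diagram.write_csv(path)
        assert PersistenceDiagram.read_csv(path).as_multiset() == \
            diagram.as_multiset()

    def test_filtration_csv_round_trip(self, tmp_path):
        filt = worked_filtration()
        path = tmp_path / "filt.csv"
        filt.write_csv(path)
        loaded = Filtration.read_csv(path)
        assert sorted(loaded.entries) == sorted(filt.entries)
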