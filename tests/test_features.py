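"""Persistence statistics: multisets, entropy, the 16-vector, epoch features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topohrv.features import (FEATURE_NAMES, PersistenceFeaturizer,
                              diagram_to_multisets, epoch_features,
                              persistence_statistics, persistent_entropy)
from topohrv.persistence import PersistenceDiagram


class TestMultisets:
    def test_worked_loop_point(self):
        """The (3, 5) loop gives midpoint 4 and lifespan 2."""
        M, L = diagram_to_multisets(PersistenceDiagram.from_pairs([(3, 5, 1)]))
        assert M.tolist() == [4.0] and L.tolist() == [2.0]

    def test_essential_point_dropped(self):
        M, L = diagram_to_multisets(
            PersistenceDiagram.from_pairs([(0, math.inf, 0), (1, 2, 0)]))
        assert M.tolist() == [1.5] and L.tolist() == [1.0]

    def test_two_points(self):
        M, L = diagram_to_multisets(np.array([[1, 3], [2, 6]], float))
        assert sorted(M) == [2, 4] and sorted(L) == [2, 4]

    def test_empty_diagram(self):
        M, L = diagram_to_multisets(np.empty((0, 2)))
        assert M.size == 0 and L.size == 0


class TestPersistentEntropy:
    def test_uniform_two_masses(self):
        assert persistent_entropy([3.5, 3.5]) == pytest.approx(math.log(2))

    def test_singleton_is_zero(self):
        assert persistent_entropy([7.0]) == 0.0

    def test_hand_value(self):
        expected = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        assert persistent_entropy([1, 3]) == pytest.approx(expected)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_empty_and_zero_mass(self):
        assert persistent_entropy([]) == 0.0
        assert persistent_entropy([0.0, 0.0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            persistent_entropy([1.0, -0.5])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=12),
           st.floats(0.1, 50))
    def test_scale_invariant(self, values, c):
        arr = np.asarray(values)
        assert persistent_entropy(c * arr) == pytest.approx(
            persistent_entropy(arr), rel=1e-9, abs=1e-12)

    def test_maximal_iff_uniform(self, rng):
        n = 6
        assert persistent_entropy(np.full(n, 2.0)) == pytest.approx(math.log(n))
        ragged = rng.uniform(0.1, 5, size=n)
        ragged[0] *= 10
        assert persistent_entropy(ragged) < math.log(n)


class TestPersistenceStatistics:
    def test_always_sixteen_components(self, rng):
        for n in (0, 1, 5):
            pts = np.column_stack([rng.uniform(0, 1, n),
                                   rng.uniform(1, 2, n), np.zeros(n)])
            assert persistence_statistics(
                PersistenceDiagram(pts.reshape(-1, 3))).shape == (16,)

    def test_single_point_degenerate_values(self):
        b, d = 1.0, 3.0
        stats = persistence_statistics(np.array([[b, d]]))
        mid = (b + d) / 2
        # M block: mean and all percentiles at the midpoint, spread stats 0
        assert stats[0] == mid
        assert stats[1] == stats[2] == stats[3] == 0.0
        assert tuple(stats[4:7]) == (mid, mid, mid)
        assert stats[7] == 0.0
        # L block mirrors with the lifespan
        assert stats[8] == d - b and np.all(stats[12:15] == d - b)

    def test_matches_independent_statistics(self):
        """Each of the 16 values against scipy/numpy computed directly."""
        from scipy.stats import kurtosis, skew

        diagram = np.array([[0, 4], [1, 3], [2, 6]], float)
        M = (diagram[:, 0] + diagram[:, 1]) / 2
        L = diagram[:, 1] - diagram[:, 0]
        got = persistence_statistics(diagram)
        for offset, vals in ((0, M), (8, L)):
            assert got[offset + 0] == pytest.approx(np.mean(vals))
            assert got[offset + 1] == pytest.approx(np.std(vals))
            assert got[offset + 2] == pytest.approx(skew(vals, bias=True))
            assert got[offset + 3] == pytest.approx(
                kurtosis(vals, fisher=False, bias=True))
            assert got[offset + 4:offset + 7] == pytest.approx(
                np.percentile(vals, [25, 50, 75]))
            total = vals.sum()
            assert got[offset + 7] == pytest.approx(
                float(-sum(v / total * math.log(v / total) for v in vals)))

    def test_symmetric_multiset_zero_skewness(self):
        diagram = np.array([[0, 2], [0, 4], [0, 6]], float)  # L = 2, 4, 6
        assert persistence_statistics(diagram)[10] == pytest.approx(0.0)

    def test_two_mass_kurtosis(self):
        # {a, a, b, b} has population kurtosis exactly 1
        diagram = np.array([[0, 1], [0, 1], [0, 3], [0, 3]], float)
        assert persistence_statistics(diagram)[11] == pytest.approx(1.0)

    def test_point_order_invariance(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, 8), rng.uniform(1, 3, 8)])
        shuffled = pts[rng.permutation(8)]
        # equality up to float summation order
        assert np.allclose(persistence_statistics(pts),
                           persistence_statistics(shuffled),
                           rtol=1e-12, atol=1e-12)


class TestEpochFeatures:
    def test_output_width_is_48(self, rng):
        window = rng.normal(size=60)
        feats = epoch_features(window, p=10, tau=1)
        assert feats.shape == (48,)
        assert np.all(np.isfinite(feats))

    def test_constant_window_degenerate_but_finite(self):
        feats = epoch_features(np.zeros(40), p=8, tau=1)
        assert np.all(np.isfinite(feats))
        # sub-level diagram has no finite point: first 16 stats all zero
        assert np.all(feats[:16] == 0.0)

    def test_constant_shift_moves_only_sublevel_locations(self, rng):
        """The embedding and the sub-level spread statistics are translation
        invariant; only the location statistics of the sub-level midpoints
        move, by exactly the shift."""
        window = rng.normal(size=60)
        shift = 2.75
        base = epoch_features(window, p=10, tau=1)
        moved = epoch_features(window + shift, p=10, tau=1)
        assert np.allclose(moved[16:], base[16:])               # both VR blocks
        for idx in (0, 4, 5, 6):                                # mean, p25/50/75 of M
            assert moved[idx] == pytest.approx(base[idx] + shift)
        for idx in (1, 2, 3):                                   # sd, skew, kurt of M
            assert moved[idx] == pytest.approx(base[idx])
        assert np.allclose(moved[8:16], base[8:16])             # whole L block

    def test_window_shorter_than_embedding_rejected(self):
        with pytest.raises(ValueError):
            epoch_features(np.zeros(50), p=120, tau=1)

    def test_deterministic(self, rng):
        window = rng.normal(size=80)
        assert np.array_equal(epoch_features(window, p=12, tau=2),
                              epoch_features(window, p=12, tau=2))


class TestFeaturizer:
    def test_transform_shape_and_names(self, rng):
        X = rng.normal(size=(3, 50))
        tf = PersistenceFeaturizer(embedding_dim=10, lag=1).fit(X)
        out = tf.transform(X)
        assert out.shape == (3, 48)
        assert list(tf.get_feature_names_out()) == FEATURE_NAMES

    def test_rejects_short_windows(self, rng):
        with pytest.raises(ValueError):
            PersistenceFeaturizer(embedding_dim=120).fit(rng.normal(size=(2, 80)))

    def test_sklearn_pipeline_compatible(self, rng):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        X = rng.normal(size=(4, 40))
        pipe = make_pipeline(PersistenceFeaturizer(embedding_dim=8),
                             StandardScaler())
        assert pipe.fit_transform(X).shape == (4, 48)
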