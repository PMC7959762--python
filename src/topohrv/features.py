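"""Persistence statistics: vectorizing persistence diagrams.

A diagram is condensed into two multisets, the midpoints
M = {(b + d)/2} and the lifespans L = {d - b} of its finite points
(infinite-death points are discarded).  Each multiset is summarized by eight
statistics -- mean, standard deviation, skewness, kurtosis, 25th/50th/75th
percentile, and persistent entropy -- giving a 16-vector per diagram, and a
48-vector per analysis window (sub-level dim-0, VR dim-0, VR dim-1).

Moment conventions: population (biased) standard deviation and skewness,
non-excess kurtosis (normal -> 3).  Percentiles interpolate linearly between
order statistics.  Degenerate inputs fall back to zeros: every statistic of
an empty multiset is 0, and sd/skewness/kurtosis of a zero-variance multiset
are 0.  Short-lifespan (even zero-lifespan) points present in a diagram are
retained: no persistence cutoff is applied.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .filtrations import sublevel_diagram, takens_embedding, vr_diagrams
from .persistence import PersistenceDiagram

__all__ = [
    "diagram_to_multisets",
    "persistent_entropy",
    "persistence_statistics",
    "epoch_features",
    "PersistenceFeaturizer",
    "STAT_NAMES",
    "FEATURE_NAMES",
]

STAT_NAMES = [
    "M_mean", "M_sd", "M_skew", "M_kurt", "M_p25", "M_p50", "M_p75", "M_entropy",
    "L_mean", "L_sd", "L_skew", "L_kurt", "L_p25", "L_p50", "L_p75", "L_entropy",
]

_BLOCKS = ["sub0", "vr0", "vr1"]
FEATURE_NAMES = [f"{block}_{stat}" for block in _BLOCKS for stat in STAT_NAMES]


def diagram_to_multisets(diagram) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint and lifespan multisets (M, L) of the finite diagram points.

    Accepts a :class:`PersistenceDiagram` or an (n, 2) array of
    (birth, death) rows; infinite-death points are discarded.
    """
    if isinstance(diagram, PersistenceDiagram):
        pts = diagram.points[:, :2]
    else:
        pts = np.asarray(diagram, dtype=float).reshape(-1, 2)
    finite = pts[np.isfinite(pts[:, 1])]
    M = (finite[:, 0] + finite[:, 1]) / 2.0
    L = finite[:, 1] - finite[:, 0]
    return M, L


def persistent_entropy(values) -> float:
    """Shannon entropy of a non-negative multiset normalized by its sum.

    E = sum(-(v/S) log(v/S)) with S = sum(v), natural log; zero elements
    contribute nothing (limit convention), and an empty multiset or S = 0
    gives 0.  Negative values are rejected.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return 0.0
    if np.any(v < 0):
        raise ValueError("persistent entropy requires non-negative values")
    total = v.sum()
    if total <= 0:
        return 0.0
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def _eight_stats(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return np.zeros(8)
    mean = v.mean()
    sd = v.std()  # population
    if sd > 0:
        z = (v - mean) / sd
        skew = float((z ** 3).mean())
        kurt = float((z ** 4).mean())  # non-excess: normal -> 3
    else:
        skew = 0.0
        kurt = 0.0
    p25, p50, p75 = np.percentile(v, [25, 50, 75])
    # midpoints of a median-centered signal may be negative; entropy treats
    # magnitudes as masses (identical to the plain definition on L and on
    # any non-negative multiset)
    return np.array([mean, sd, skew, kurt, p25, p50, p75,
                     persistent_entropy(np.abs(v))])


def persistence_statistics(diagram) -> np.ndarray:
    """The 16 persistence statistics of a diagram: 8 of M then 8 of L."""
    M, L = diagram_to_multisets(diagram)
    return np.concatenate([_eight_stats(M), _eight_stats(L)])


def epoch_features(window, p: int = 120, tau: int = 1,
                   max_scale: float = math.inf) -> np.ndarray:
    """48-component feature vector of one analysis window.

    Concatenates the persistence statistics of (i) the dim-0 sub-level
    diagram of the window, (ii) the dim-0 and (iii) the dim-1 VR diagrams of
    its Takens embedding R_{p,tau}.  Essential (infinite-death) points drop
    out inside :func:`diagram_to_multisets`.
    """
    x = np.asarray(window, dtype=float).ravel()
    sub = sublevel_diagram(x)
    cloud = takens_embedding(x, p=p, tau=tau)
    vr = vr_diagrams(cloud, max_dim=1, max_scale=max_scale)
    return np.concatenate([
        persistence_statistics(sub.in_dimension(0)),
        persistence_statistics(vr.in_dimension(0)),
        persistence_statistics(vr.in_dimension(1)),
    ])


class PersistenceFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer: rows of windows -> rows of 48 persistence statistics.

    Parameters
    ----------
    embedding_dim : int, default 120
        Takens embedding dimension p; 120 samples = 30 s at 4 Hz.
    lag : int, default 1
        Takens lag tau in samples.
    max_scale : float, default inf
        Radius cap of the VR filtration; inf keeps the filtration exact.

    The transformer is stateless; ``fit`` only records the window length for
    validation.
    """

    def __init__(self, embedding_dim: int = 120, lag: int = 1,
                 max_scale: float = math.inf):
        self.embedding_dim = embedding_dim
        self.lag = lag
        self.max_scale = max_scale

    def fit(self, X, y=None):
        X = check_array(X)
        needed = (self.embedding_dim - 1) * self.lag + 1
        if X.shape[1] < needed:
            raise ValueError(
                f"window length {X.shape[1]} < {needed} required by "
                f"embedding_dim={self.embedding_dim}, lag={self.lag}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"window length {X.shape[1]} != fitted length "
                f"{self.n_features_in_}"
            )
        return np.vstack([
            epoch_features(row, p=self.embedding_dim, tau=self.lag,
                           max_scale=self.max_scale)
            for row in X
        ])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
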