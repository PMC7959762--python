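"""Class-balanced linear-SVM sleep-stage classification.

Training pools are balanced by down-sampling every majority class to the
minority-class size with a fixed random seed; the SVM itself is a linear
kernel at library defaults (C = 1, no internal feature scaling).  With three
classes the underlying libsvm machine combines pairwise (one-versus-one)
binary learners.  Test data are never balanced: evaluation always runs on
every available epoch.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "balance_downsample",
    "SleepStageClassifier",
    "task_labels",
    "TASKS",
]

TASKS = ("ws", "rn", "wrn")

# class display order: wake before REM before NREM
_TASK_CLASS_ORDER = {
    "ws": ["W", "S"],
    "rn": ["R", "N"],
    "wrn": ["W", "R", "N"],
}


def task_labels(labels, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Map raw W/R/N stage labels onto a classification task.

    Returns (mapped labels, boolean row mask).  ``ws`` merges R and N into
    sleep ("S"); ``rn`` keeps only sleep epochs; ``wrn`` keeps everything.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    y = np.asarray(labels, dtype=object)
    if task == "ws":
        mapped = np.where(y == "W", "W", "S")
        mask = np.ones(y.size, dtype=bool)
    elif task == "rn":
        mask = y != "W"
        mapped = y.copy()
    else:
        mask = np.ones(y.size, dtype=bool)
        mapped = y.copy()
    return mapped[mask].astype(str), mask


def class_order(task: str) -> list[str]:
    return list(_TASK_CLASS_ORDER[task])


def balance_downsample(X, y, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Down-sample every majority class to the minority-class size.

    The minority class is kept whole; from each larger class a uniform
    sample without replacement is drawn with the given seed.  Returns
    (X_balanced, y_balanced, row indices into the input), indices ascending
    so row order is preserved.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("balancing requires at least 2 non-empty classes")
    if np.any(counts == 0):
        raise ValueError("every class must be non-empty")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in classes:  # deterministic class order
        idx = np.flatnonzero(y == cls)
        if idx.size > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    return X[sel], y[sel], sel


class SleepStageClassifier(ClassifierMixin, BaseEstimator):
    """Linear-kernel SVM with seeded class balancing of the training pool.

    Parameters
    ----------
    C : float, default 1.0
        SVM regularization (library default).
    balance : bool, default True
        Down-sample majority classes before fitting.
    random_state : int, default 1
        Seed of the balancing subsample.
    standardize : bool, default False
        If True, z-score features on the (balanced) training pool first.
        Off by default: features enter the model raw.

    Attributes
    ----------
    classes_ : ndarray of class labels seen in training.
    estimator_ : the fitted SVC.
    balanced_indices_ : rows of the training set actually used.
    """

    def __init__(self, C: float = 1.0, balance: bool = True,
                 random_state: int = 1, standardize: bool = False):
        self.C = C
        self.balance = balance
        self.random_state = random_state
        self.standardize = standardize

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=str))
        self.classes_ = unique_labels(y)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        if self.balance:
            Xb, yb, idx = balance_downsample(X, y, self.random_state)
        else:
            counts = np.unique(y, return_counts=True)[1]
            if counts.min() != counts.max():
                warnings.warn(
                    "training classes are imbalanced and balance=False",
                    stacklevel=2,
                )
            Xb, yb, idx = X, y, np.arange(len(y))
        if self.standardize:
            self.scale_mean_ = Xb.mean(axis=0)
            sd = Xb.std(axis=0)
            self.scale_sd_ = np.where(sd > 0, sd, 1.0)
            Xb = (Xb - self.scale_mean_) / self.scale_sd_
        self.balanced_indices_ = idx
        self.estimator_ = SVC(kernel="linear", C=self.C,
                              decision_function_shape="ovo")
        self.estimator_.fit(Xb, yb)
        self.n_features_in_ = X.shape[1]
        return self

    def _prepare(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != {self.n_features_in_} "
                "seen in training"
            )
        if self.standardize:
            X = (X - self.scale_mean_) / self.scale_sd_
        return X

    def predict(self, X) -> np.ndarray:
        return self.estimator_.predict(self._prepare(X))

    def decision_function(self, X) -> np.ndarray:
        """Signed distances to the separating hyperplane(s).

        Binary tasks yield one score per row (positive toward the
        lexicographically larger class, sklearn convention), used for
        ROC/AUC.
        """
        return self.estimator_.decision_function(self._prepare(X))
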