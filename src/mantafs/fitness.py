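"""Wrapper objective: KNN error on a feature subset plus a subset-size penalty.

The fitness of a candidate bit mask is

    fitness = omega * E + (1 - omega) * d / D

where ``E`` is the classification error of a k-nearest-neighbour classifier
restricted to the masked features, ``d`` the number of selected features and
``D`` the total.  With the conventional ``omega = 0.99`` the error term
dominates and the size term breaks ties among equally accurate subsets.

The split used to measure ``E`` is frozen once per optimizer run (a
stratified 80/20 holdout of the data handed to the optimizer), so fitness is
a deterministic, memoizable function of the mask and personal/global-best
comparisons are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import min_max_scale, stratified_split_indices

__all__ = [
    "FitnessRecord",
    "fitness_value",
    "knn_classify",
    "subset_error",
    "MaskEvaluator",
    "evaluate_mask",
]

#: Sentinel fitness for the empty subset, strictly worse than any valid mask.
EMPTY_MASK_FITNESS = 1.0


@dataclass(frozen=True)
class FitnessRecord:
    """Result of evaluating one feature mask.

    ``error`` is NaN for the empty mask, whose fitness is pinned at the
    sentinel value 1.0 without calling the classifier.
    """

    fitness: float
    error: float
    n_selected: int
    n_features: int


def fitness_value(error: float, n_selected: int, n_features: int, omega: float = 0.99) -> float:
    """The weighted objective ``omega * E + (1 - omega) * d / D``."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    if not 0.0 <= error <= 1.0:
        raise ValueError("error must lie in [0, 1]")
    if not 1 <= n_selected <= n_features:
        raise ValueError("require 1 <= n_selected <= n_features (empty masks are handled upstream)")
    return omega * error + (1.0 - omega) * n_selected / n_features


def knn_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Deterministic k-nearest-neighbour labels for each query row.

    Euclidean distances; distance ties broken by lower training-row index and
    vote ties by the smallest label value, so predictions are reproducible
    bit-for-bit regardless of backend sort order.  If fewer than ``k``
    training rows exist, ``k`` is reduced with a warning.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    n_train = train_X.shape[0]
    if k > n_train:
        warnings.warn(f"reducing k from {k} to {n_train} available training rows", stacklevel=2)
        k = n_train
    d = cdist(query_X, train_X)
    idx = np.arange(n_train)
    n_labels = train_y.max() + 1
    out = np.empty(query_X.shape[0], dtype=int)
    for q in range(query_X.shape[0]):
        order = np.lexsort((idx, d[q]))  # distance first, then train index
        votes = np.bincount(train_y[order[:k]], minlength=n_labels)
        out[q] = int(np.argmax(votes))  # argmax tie -> smallest label
    return out


def subset_error(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    mask: np.ndarray,
    k: int = 5,
) -> float:
    """Misclassified fraction of the test rows using only the masked columns."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask selects no features")
    pred = knn_classify(train_X[:, mask], train_y, test_X[:, mask], k=k)
    return float(np.mean(pred != np.asarray(test_y)))


class MaskEvaluator:
    """Fitness oracle over bit masks with a frozen internal split.

    The constructor draws one stratified holdout (default 80/20) of ``(X, y)``
    and, when ``scale`` is on, min-max scales both sides using training
    statistics.  Scaling is column-wise, so it commutes with masking and is
    done once up front.  Each call evaluates one mask and returns a
    :class:`FitnessRecord`; calls are counted in :attr:`n_calls` (and
    :attr:`n_distinct` when memoization is on).

    Parameters
    ----------
    X, y : array-likes
        Data available to the optimizer (any unseen outer test data is split
        off by the caller beforehand).
    omega : float
        Error-vs-size weight of the objective.
    k : int
        KNN neighbour count.
    test_fraction : float
        Fraction held out internally for measuring ``E``.
    scale : bool
        Min-max scale features on training statistics.
    memoize : bool
        Cache records by mask; repeated masks then cost a dictionary lookup
        but still increment :attr:`n_calls`.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        omega: float = 0.99,
        k: int = 5,
        test_fraction: float = 0.2,
        scale: bool = True,
        memoize: bool = False,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("fitness evaluation needs at least 2 classes")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        tr, te = stratified_split_indices(y, test_fraction, rng)
        self.train_X, self.test_X = X[tr], X[te]
        self.train_y, self.test_y = y[tr], y[te]
        if scale:
            self.train_X, self.test_X = min_max_scale(self.train_X, self.test_X)
        self.omega = omega
        self.k = k
        self.n_features = X.shape[1]
        self.memoize = memoize
        self.n_calls = 0
        self.n_distinct = 0
        self._cache: dict[bytes, FitnessRecord] = {}

    def __call__(self, mask: np.ndarray) -> FitnessRecord:
        mask = np.asarray(mask).astype(bool)
        if mask.shape[0] != self.n_features:
            raise ValueError("mask length does not match the feature count")
        self.n_calls += 1
        if self.memoize:
            key = np.packbits(mask).tobytes()
            hit = self._cache.get(key)
            if hit is not None:
                return hit
        record = self._evaluate(mask)
        if self.memoize:
            self._cache[key] = record
            self.n_distinct = len(self._cache)
        return record

    def _evaluate(self, mask: np.ndarray) -> FitnessRecord:
        d = int(mask.sum())
        if d == 0:
            return FitnessRecord(EMPTY_MASK_FITNESS, float("nan"), 0, self.n_features)
        err = subset_error(self.train_X, self.train_y, self.test_X, self.test_y, mask, k=self.k)
        return FitnessRecord(fitness_value(err, d, self.n_features, self.omega), err, d, self.n_features)


def evaluate_mask(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    omega: float = 0.99,
    k: int = 5,
    test_fraction: float = 0.2,
    scale: bool = True,
    rng: np.random.Generator | int | None = None,
) -> FitnessRecord:
    """One-shot mask evaluation (builds a fresh :class:`MaskEvaluator`)."""
    return MaskEvaluator(
        X, y, omega=omega, k=k, test_fraction=test_fraction, scale=scale, rng=rng
    )(mask)
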