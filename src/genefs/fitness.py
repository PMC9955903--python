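"""Wrapper fitness for binary feature-subset optimization.

The objective every metaheuristic maximizes blends cross-validated
classification accuracy with subset parsimony:

    fitness(mask) = w * mean_cv_accuracy(mask) + (1 - w) * (1 - |mask| / n)

with ``w`` in [0, 1] (default 0.9) and a 5-nearest-neighbor wrapper
classifier under stratified 5-fold internal cross-validation by default.
The CV folds are unshuffled, so a fitness value depends only on
(X, y, classifier, folds, weight) and can be memoized per mask — including
across optimizer runs on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "FitnessConfig",
    "FitnessEvaluator",
    "evaluate_fitness",
    "exhaustive_search",
    "exhaustive_best",
]


@dataclass
class FitnessConfig:
    """Configuration of the subset objective (maximized).

    weight : trade-off between accuracy (weight) and parsimony (1 - weight).
    estimator : wrapper classifier; ``None`` means 5-nearest-neighbors.
    cv : stratified internal CV folds (>= 2).
    seed : recorded for provenance; the objective itself is deterministic.
    """

    weight: float = 0.9
    estimator: object = None
    cv: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if self.cv < 2:
            raise ValueError("cv must be at least 2")


class FitnessEvaluator:
    """Callable mask -> fitness with per-mask memoization.

    Parameters
    ----------
    X, y : training data over the candidate gene pool.
    config : FitnessConfig
    cache : dict, optional
        Shared ``mask bytes -> cv accuracy`` cache; pass one dict to several
        evaluators over the same (X, y, config) to pool work.
    """

    def __init__(self, X, y, config: FitnessConfig = None, cache: dict = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.config = config or FitnessConfig()
        classes, counts = np.unique(self.y, return_counts=True)
        if classes.size < 2:
            raise ValueError("fitness evaluation needs two classes")
        if counts.min() < self.config.cv:
            raise ValueError(
                f"minority class ({counts.min()} samples) too small for "
                f"{self.config.cv}-fold stratified CV; a fold would be single-class"
            )
        splitter = StratifiedKFold(n_splits=self.config.cv, shuffle=False)
        self._splits = list(splitter.split(self.X, self.y))
        self._estimator = (
            self.config.estimator
            if self.config.estimator is not None
            else KNeighborsClassifier(n_neighbors=5)
        )
        self._cache = cache if cache is not None else {}
        self.n_evaluations = 0

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def cv_accuracy(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask length must equal the candidate-pool size")
        if not mask.any():
            raise ValueError("cannot evaluate an empty feature mask")
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        Xm = self.X[:, mask]
        scores = []
        for train, test in self._splits:
            est = clone(self._estimator)
            est.fit(Xm[train], self.y[train])
            scores.append(np.mean(est.predict(Xm[test]) == self.y[test]))
        acc = float(np.mean(scores))
        self._cache[key] = acc
        self.n_evaluations += 1
        return acc

    def __call__(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        acc = self.cv_accuracy(mask)
        w = self.config.weight
        parsimony = 1.0 - mask.sum() / self.n_features
        return w * acc + (1.0 - w) * parsimony


def evaluate_fitness(mask, dataset, config: FitnessConfig = None) -> float:
    """One-shot fitness of ``mask`` on a dataset (see module docstring)."""
    evaluator = FitnessEvaluator(dataset.values, dataset.labels, config)
    return evaluator(mask)


def exhaustive_search(evaluator, n_features: int):
    """Evaluate all 2^n - 1 non-empty masks; return the argmax mask.

    Ties break toward the smaller subset, then the lexicographically
    smallest tuple of selected column indices. ``evaluator`` is any
    callable mask -> fitness.
    """
    best_mask = None
    best_key = None
    for code in range(1, 2 ** n_features):
        mask = np.array(
            [(code >> j) & 1 for j in range(n_features)], dtype=bool
        )
        fit = evaluator(mask)
        key = (-fit, int(mask.sum()), tuple(np.flatnonzero(mask)))
        if best_key is None or key < best_key:
            best_key = key
            best_mask = mask
    return best_mask


def exhaustive_best(X, y, config: FitnessConfig = None, max_pool: int = 15,
                    cache: dict = None):
    """Brute-force optimum of the wrapper fitness over a small gene pool."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] > max_pool:
        raise ValueError(
            f"candidate pool of {X.shape[1]} exceeds max_pool={max_pool}"
        )
    evaluator = FitnessEvaluator(X, y, config, cache=cache)
    return exhaustive_search(evaluator, X.shape[1])
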