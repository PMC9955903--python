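"""Quasi-constant filtering, SMOTE oversampling, and stratified splitting.

Estimator classes follow scikit-learn conventions (fit/transform or
fit_resample, fitted attributes with a trailing underscore); the
module-level functions are thin dataset-aware wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datasets import ExpressionDataset

__all__ = [
    "QuasiConstantFilter",
    "SMOTEOversampler",
    "SplitResult",
    "quasi_constant_filter",
    "smote_balance",
    "stratified_split",
    "stratified_split_indices",
]


class QuasiConstantFilter(SelectorMixin, BaseEstimator):
    """Remove genes whose sample variance falls below ``threshold``.

    The variance estimator is the unbiased sample variance (denominator
    n - 1) and the removal rule is strict (``variance < threshold``), so a
    threshold of 0 retains every gene. The filter is idempotent.
    """

    def __init__(self, threshold: float = 0.01):
        self.threshold = threshold

    def fit(self, X, y=None):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        X = check_array(X, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        self.variances_ = X.var(axis=0, ddof=1)
        self.support_ = self.variances_ >= self.threshold
        if not self.support_.any():
            raise ValueError(
                "quasi-constant filter removed every gene; "
                "downstream stages need at least one"
            )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class SMOTEOversampler(BaseEstimator):
    """Synthetic Minority Oversampling: raise the minority class count to
    the majority count by linear interpolation toward minority nearest
    neighbors.

    Each synthetic sample is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``,
    ``x`` a uniformly chosen minority sample and ``x_nn`` one of its
    ``k_neighbors`` nearest minority neighbors under the Euclidean metric
    over all genes (ties broken by lower sample index). Original rows are
    never altered; synthetic rows are appended after them. For each
    synthetic sample the RNG is consumed in the order: sample choice,
    neighbor choice, interpolation coefficient.
    """

    def __init__(self, k_neighbors: int = 5, random_state=None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X, y = check_X_y(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("SMOTE requires both classes to be present")
        if classes.size > 2:
            raise ValueError("only two-class problems are supported")
        if counts[0] == counts[1]:
            return X.copy(), y.copy()

        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min < 2:
            raise ValueError("minority class needs at least 2 samples for SMOTE")
        k = min(self.k_neighbors, n_min - 1)

        minority_idx = np.flatnonzero(y == minority)
        Xm = X[minority_idx]
        # deterministic k-NN: stable sort on (distance, index), self excluded
        d2 = cdist(Xm, Xm, metric="sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        order = np.argsort(d2, axis=1, kind="stable")
        neighbors = order[:, :k]

        rng = np.random.default_rng(self.random_state)
        synthetic = np.empty((n_maj - n_min, X.shape[1]))
        for t in range(n_maj - n_min):
            i = int(rng.integers(n_min))
            j = neighbors[i, int(rng.integers(k))]
            u = rng.random()
            synthetic[t] = Xm[i] + u * (Xm[j] - Xm[i])

        X_out = np.vstack([X, synthetic])
        y_out = np.concatenate([y, np.full(n_maj - n_min, minority, dtype=y.dtype)])
        return X_out, y_out


@dataclass
class SplitResult:
    """A stratified train/test partition of an :class:`ExpressionDataset`."""

    train: ExpressionDataset
    test: ExpressionDataset
    test_fraction: float
    seed: int


def stratified_split_indices(y, test_fraction: float = 0.2, seed=None):
    """Per-class index split: test count per class is
    ``round(test_fraction * class size)`` (half-up), with a guard of at
    least one test sample per class whenever ``test_fraction > 0``.
    Returns ``(train_idx, test_idx)`` in ascending order.
    """
    y = np.asarray(y)
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValueError(
                f"class {cls} has {members.size} sample(s); cannot stratify"
            )
        n_test = int(np.floor(test_fraction * members.size + 0.5))
        if test_fraction > 0:
            n_test = max(n_test, 1)
        if n_test >= members.size:
            raise ValueError(
                f"class {cls} too small for test_fraction={test_fraction}"
            )
        perm = rng.permutation(members)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts)) if test_fraction > 0 else np.array([], dtype=int)
    return train_idx, test_idx


# --- dataset-level wrappers -------------------------------------------------

def quasi_constant_filter(dataset: ExpressionDataset, threshold: float = 0.01):
    """Filter quasi-constant genes; returns ``(filtered, removed_gene_ids)``."""
    selector = QuasiConstantFilter(threshold=threshold).fit(dataset.values)
    keep = np.flatnonzero(selector.support_)
    removed = [g for g, ok in zip(dataset.gene_ids, selector.support_) if not ok]
    filtered = ExpressionDataset(
        sample_ids=list(dataset.sample_ids),
        gene_ids=[dataset.gene_ids[i] for i in keep],
        values=dataset.values[:, keep].copy(),
        labels=dataset.labels.copy(),
    )
    return filtered, removed


def smote_balance(dataset: ExpressionDataset, k_neighbors: int = 5, seed=None) -> ExpressionDataset:
    """Balance the dataset with SMOTE; synthetic samples get ids
    ``synthetic_1, synthetic_2, ...`` appended after the originals."""
    sampler = SMOTEOversampler(k_neighbors=k_neighbors, random_state=seed)
    X, y = sampler.fit_resample(dataset.values, dataset.labels)
    n_new = X.shape[0] - dataset.n_samples
    sample_ids = list(dataset.sample_ids) + [f"synthetic_{i + 1}" for i in range(n_new)]
    return ExpressionDataset(
        sample_ids=sample_ids,
        gene_ids=list(dataset.gene_ids),
        values=X,
        labels=y,
    )


def stratified_split(dataset: ExpressionDataset, test_fraction: float = 0.2, seed=None) -> SplitResult:
    train_idx, test_idx = stratified_split_indices(
        dataset.labels, test_fraction=test_fraction, seed=seed
    )
    return SplitResult(
        train=dataset.subset_samples(train_idx),
        test=dataset.subset_samples(test_idx)
        if test_idx.size
        else dataset.subset_samples(np.array([], dtype=int)),
        test_fraction=test_fraction,
        seed=seed,
    )
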