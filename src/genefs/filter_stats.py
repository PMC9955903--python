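"""mRMR feature selection with the FCQ criterion and unpaired t-test screening.

Relevance is the one-way ANOVA F-statistic between a gene and the class
label (for two classes F = t^2 with the pooled t), redundancy the mean
absolute Pearson correlation with already-selected genes, and the greedy
criterion their quotient (FCQ). The t-test screen keeps genes whose
two-tailed unpaired p-value falls below alpha, with no multiplicity
correction (a per-gene 5% level by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .datasets import ExpressionDataset

__all__ = [
    "MRMRResult",
    "TTestRow",
    "MRMRSelector",
    "TTestScreen",
    "f_statistic",
    "pearson",
    "mrmr_select_fcq",
    "ttest_two_tailed",
    "ttest_from_summary",
    "ttest_screen",
    "ttest_rows_to_frame",
]

#: Floor on the mean absolute correlation in the FCQ denominator. This is
#: the configured minimum correlation of the filter stage and also guards
#: against division by zero for (near-)orthogonal or degenerate partners.
CORRELATION_FLOOR = 1e-5


def f_statistic(gene_values, labels) -> float:
    """One-way ANOVA F-statistic of one gene against the class labels.

    F = [sum_k n_k (m_k - m)^2 / (K - 1)] / s2 where s2 is the pooled
    within-class variance. Requires at least two classes, each non-empty,
    and a strictly positive pooled variance.
    """
    x = np.asarray(gene_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("F-statistic needs at least two classes")
    n = x.size
    grand = x.mean()
    between = 0.0
    within = 0.0
    for cls in classes:
        xc = x[y == cls]
        between += xc.size * (xc.mean() - grand) ** 2
        if xc.size > 1:
            within += (xc.size - 1) * xc.var(ddof=1)
    k = classes.size
    if n - k <= 0:
        raise ValueError("not enough samples for a pooled variance")
    pooled = within / (n - k)
    if pooled <= 0:
        raise ValueError("zero pooled within-class variance")
    return float((between / (k - 1)) / pooled)


def pearson(x, y) -> float:
    """Pearson correlation coefficient; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("zero-variance vector in Pearson correlation")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


@dataclass
class MRMRResult:
    """Ordered mRMR selection with per-gene relevance and greedy step scores."""

    selected: list
    relevance: np.ndarray
    step_scores: np.ndarray


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy minimum-redundancy maximum-relevance selection (FCQ variant).

    Step 1 picks the gene with maximal F-statistic relevance; step m+1
    picks, among unselected genes, the maximizer of
    F(i, h) / max(mean_{j in S} |c(i, j)|, floor). Ties break toward the
    lower column index. Genes with zero variance get relevance 0 (with a
    warning); the upstream quasi-constant filter is expected to have
    removed them.

    Parameters
    ----------
    k : int
        Number of genes to select (all genes if fewer are available).
    corr_floor : float
        Lower bound on the FCQ denominator.
    """

    def __init__(self, k: int = 20, corr_floor: float = CORRELATION_FLOOR):
        self.k = k
        self.corr_floor = corr_floor

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError("k must be at least 1")
        X, y = check_X_y(X, y)
        if np.unique(y).size < 2:
            raise ValueError("mRMR relevance is undefined for single-class labels")
        self.n_features_in_ = n_genes = X.shape[1]
        k = min(self.k, n_genes)

        sds = X.std(axis=0, ddof=1)
        relevance = np.zeros(n_genes)
        for j in range(n_genes):
            if sds[j] == 0:
                warnings.warn(
                    f"gene column {j} is constant; relevance set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
            else:
                relevance[j] = f_statistic(X[:, j], y)

        centered = X - X.mean(axis=0)
        norms = np.sqrt((centered ** 2).sum(axis=0))

        selected = [int(np.argmax(relevance))]
        step_scores = [float(relevance[selected[0]])]
        abs_corr_sum = np.zeros(n_genes)
        for _ in range(1, k):
            last = selected[-1]
            if norms[last] > 0:
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = (centered.T @ centered[:, last]) / (norms * norms[last])
                corr[norms == 0] = 0.0
                abs_corr_sum += np.abs(np.clip(corr, -1.0, 1.0))
            mean_redundancy = np.maximum(abs_corr_sum / len(selected), self.corr_floor)
            score = relevance / mean_redundancy
            score[selected] = -np.inf
            best = int(np.argmax(score))
            selected.append(best)
            step_scores.append(float(score[best]))

        self.selected_idx_ = np.array(selected, dtype=int)
        self.relevance_ = relevance
        self.step_scores_ = np.array(step_scores)
        self.support_ = np.zeros(n_genes, dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def mrmr_select_fcq(dataset: ExpressionDataset, k: int = 20) -> MRMRResult:
    """Run mRMR-FCQ on a dataset and return gene ids in selection order."""
    selector = MRMRSelector(k=k).fit(dataset.values, dataset.labels)
    order = selector.selected_idx_
    return MRMRResult(
        selected=[dataset.gene_ids[i] for i in order],
        relevance=selector.relevance_[order].copy(),
        step_scores=selector.step_scores_.copy(),
    )


def ttest_from_summary(m1, s1, n1, m0, s0, n0, variant: str = "student"):
    """Two-tailed unpaired t-test from sufficient statistics.

    Returns ``(t, df, p)``. The ``student`` variant pools the variance with
    df = n1 + n0 - 2; ``welch`` uses the Satterthwaite approximation. Two
    constant, equal groups give (0, df, 1); zero variance with unequal
    means is an error.
    """
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")
    if s1 < 0 or s0 < 0:
        raise ValueError("standard deviations must be non-negative")
    diff = m1 - m0
    if variant == "student":
        df = n1 + n0 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n0 - 1) * s0 ** 2) / df
        se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    elif variant == "welch":
        a, b = s1 ** 2 / n1, s0 ** 2 / n0
        se2 = a + b
        if se2 > 0:
            df = se2 ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n0 - 1))
        else:
            df = n1 + n0 - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se2 == 0:
        if diff == 0:
            return 0.0, float(df), 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def ttest_two_tailed(x1, x0, variant: str = "student"):
    """Two-tailed unpaired t-test on raw samples; returns ``(t, df, p)``."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if x1.size < 2 or x0.size < 2:
        raise ValueError("each group needs at least 2 samples")
    return ttest_from_summary(
        x1.mean(), x1.std(ddof=1), x1.size,
        x0.mean(), x0.std(ddof=1), x0.size,
        variant=variant,
    )


@dataclass
class TTestRow:
    """Per-gene group statistics and test outcome (one table row)."""

    gene_id: str
    mean_class1: float
    sd_class1: float
    n_class1: int
    mean_class0: float
    sd_class0: float
    n_class0: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool


class TTestScreen(SelectorMixin, BaseEstimator):
    """Keep genes whose two-tailed unpaired t-test p-value is below alpha."""

    def __init__(self, alpha: float = 0.05, variant: str = "student"):
        self.alpha = alpha
        self.variant = variant

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.unique(y).size != 2:
            raise ValueError("t-test screen needs exactly two classes")
        self.n_features_in_ = X.shape[1]
        pvalues = np.empty(X.shape[1])
        tstats = np.empty(X.shape[1])
        dfs = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            t, df, p = ttest_two_tailed(X[y == 1, j], X[y == 0, j], variant=self.variant)
            tstats[j], dfs[j], pvalues[j] = t, df, p
        self.t_statistic_ = tstats
        self.df_ = dfs
        self.p_values_ = pvalues
        self.support_ = pvalues < self.alpha
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def ttest_screen(dataset: ExpressionDataset, gene_ids=None, alpha: float = 0.05,
                 variant: str = "student"):
    """Screen genes by two-tailed unpaired t-test at level ``alpha``.

    Returns ``(rows, selected_gene_ids)`` with rows in input gene order.
    """
    subset = dataset if gene_ids is None else dataset.select_genes(gene_ids)
    screen = TTestScreen(alpha=alpha, variant=variant).fit(subset.values, subset.labels)
    x1 = subset.values[subset.labels == 1]
    x0 = subset.values[subset.labels == 0]
    rows = [
        TTestRow(
            gene_id=g,
            mean_class1=float(x1[:, j].mean()),
            sd_class1=float(x1[:, j].std(ddof=1)),
            n_class1=int(x1.shape[0]),
            mean_class0=float(x0[:, j].mean()),
            sd_class0=float(x0[:, j].std(ddof=1)),
            n_class0=int(x0.shape[0]),
            t_statistic=float(screen.t_statistic_[j]),
            degrees_of_freedom=float(screen.df_[j]),
            p_value=float(screen.p_values_[j]),
            significant=bool(screen.support_[j]),
        )
        for j, g in enumerate(subset.gene_ids)
    ]
    selected = [r.gene_id for r in rows if r.significant]
    return rows, selected


def ttest_rows_to_frame(rows) -> pd.DataFrame:
    """Tabulate screen rows (gene, per-class mean/SD/n, t, df, p, flag)."""
    return pd.DataFrame([row.__dict__ for row in rows])
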