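"""Classification metrics and the multi-classifier evaluation harness.

The metric primitives (confusion counts, accuracy, F1, TPR/FPR, ROC-AUC)
are authored here from their definitions; the classifiers themselves are
delegated to scikit-learn and XGBoost with the reported hyperparameter
settings. The harness scores every (feature subset x classifier) pair
under stratified k-fold cross-validation on the training partition, the
same CV protocol repeated on the held-out test partition, and additionally
a conventional single fit-on-train / score-on-test evaluation with
confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .preprocessing import SplitResult

__all__ = [
    "ConfusionCounts",
    "ClassifierSpec",
    "EvaluationReport",
    "DEFAULT_CLASSIFIERS",
    "confusion_counts",
    "accuracy",
    "f1",
    "tpr",
    "fpr",
    "roc_auc",
    "make_classifier",
    "cross_validate_models",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    """Count TP/TN/FP/FN with configurable positive class (default 1 = tumor)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int((pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("no samples")
    return (c.tp + c.tn) / c.total


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when undefined."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def tpr(c: ConfusionCounts) -> float:
    """True positive rate TP / (TP + FN)."""
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0


def fpr(c: ConfusionCounts) -> float:
    """False positive rate FP / (FP + TN)."""
    return c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else 0.0


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve via the rank statistic (ties count 1/2).

    Equivalent to trapezoidal integration of the ROC curve over all score
    thresholds.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined for single-class truth")
    ranks = rankdata(scores, method="average")
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ClassifierSpec:
    """A named classifier with its (reported-default) hyperparameters."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = None


DEFAULT_CLASSIFIERS = ("LR", "XGBoost", "GaussianNB", "DecisionTree", "KNN",
                       "SVM", "RandomForest")


def make_classifier(name: str, seed=None, **overrides):
    """Instantiate a classifier by registry name with its default settings.

    LR: lbfgs, L2, C=1, tol=1e-4, 100 iterations. XGBoost: depth 4,
    learning rate 0.2, lambda 1, 150 rounds, subsample 0.9,
    colsample_bytree 0.9, random_state 1. DecisionTree/RandomForest: Gini,
    depth 4 (RF: 100 estimators). KNN: k=5. SVM: linear, squared hinge,
    C=1 (AUC from its decision margin — it has no native probabilities).
    """
    if name == "LR":
        # L2 penalty (the solver default), C=1, per the reported settings
        params = dict(solver="lbfgs", C=1.0, tol=1e-4, dual=False,
                      max_iter=100, intercept_scaling=1)
    elif name == "XGBoost":
        params = dict(max_depth=4, learning_rate=0.2, reg_lambda=1,
                      n_estimators=150, subsample=0.9, colsample_bytree=0.9,
                      random_state=1, eval_metric="logloss")
    elif name == "GaussianNB":
        params = dict(priors=None, var_smoothing=1e-9)
    elif name == "DecisionTree":
        params = dict(criterion="gini", splitter="best", max_depth=4,
                      min_samples_split=2, min_samples_leaf=1,
                      random_state=seed)
    elif name == "KNN":
        params = dict(n_neighbors=5, weights="uniform", algorithm="auto",
                      leaf_size=30, p=2)
    elif name == "SVM":
        params = dict(penalty="l2", loss="squared_hinge", tol=1e-4, C=1.0,
                      fit_intercept=True, intercept_scaling=1)
    elif name == "RandomForest":
        params = dict(criterion="gini", n_estimators=100, max_depth=4,
                      min_samples_split=2, min_samples_leaf=1,
                      bootstrap=True, oob_score=False, random_state=seed)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    params.update(overrides)
    factory = {
        "LR": LogisticRegression,
        "XGBoost": XGBClassifier,
        "GaussianNB": GaussianNB,
        "DecisionTree": DecisionTreeClassifier,
        "KNN": KNeighborsClassifier,
        "SVM": LinearSVC,
        "RandomForest": RandomForestClassifier,
    }[name]
    return factory(**params)


def _scores_for_auc(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _cv_metrics(model, X, y, folds, seed):
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, f1s, aucs = [], [], []
    for train, test in splitter.split(X, y):
        est = clone(model)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        counts = confusion_counts(y[test], pred)
        accs.append(accuracy(counts))
        f1s.append(f1(counts))
        aucs.append(roc_auc(y[test], _scores_for_auc(est, X[test])))
    return (
        float(np.mean(accs)), float(np.std(accs)),
        float(np.mean(f1s)), float(np.std(f1s)),
        float(np.mean(aucs)), float(np.std(aucs)),
    )


@dataclass
class ReportRow:
    subset: str
    classifier: str
    genes: list
    train_cv: dict
    test_cv: dict
    holdout: dict
    confusion: ConfusionCounts


@dataclass
class EvaluationReport:
    """Per (subset x classifier) metric table plus hold-out confusions."""

    rows: list
    folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {"subset": row.subset, "classifier": row.classifier,
                   "n_genes": len(row.genes)}
            for block, stats in (("train_cv", row.train_cv),
                                 ("test_cv", row.test_cv),
                                 ("holdout", row.holdout)):
                for key, value in stats.items():
                    rec[f"{block}_{key}"] = value
            rec.update(tp=row.confusion.tp, tn=row.confusion.tn,
                       fp=row.confusion.fp, fn=row.confusion.fn)
            records.append(rec)
        return pd.DataFrame(records)

    def to_json_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seed": self.seed,
            "rows": [
                {
                    "subset": row.subset,
                    "classifier": row.classifier,
                    "genes": list(row.genes),
                    "train_cv": row.train_cv,
                    "test_cv": row.test_cv,
                    "holdout": row.holdout,
                    "confusion": {"tp": row.confusion.tp, "tn": row.confusion.tn,
                                  "fp": row.confusion.fp, "fn": row.confusion.fn},
                }
                for row in self.rows
            ],
        }

    def metric_table(self, metric: str = "accuracy", block: str = "test_cv") -> pd.DataFrame:
        """Pivot one metric into a subsets-by-classifiers table of mean +/- SD."""
        frame = self.to_frame()
        mean = frame.pivot(index="subset", columns="classifier",
                           values=f"{block}_{metric}_mean")
        sd = frame.pivot(index="subset", columns="classifier",
                         values=f"{block}_{metric}_sd")
        return mean.round(3).astype(str) + " ± " + sd.round(3).astype(str)

    def best_row(self, metric: str = "accuracy", block: str = "test_cv"):
        key = f"{metric}_mean"
        return max(self.rows, key=lambda row: getattr(row, block)[key]
                   if isinstance(getattr(row, block), dict) else -np.inf)


def _metric_dict(acc_m, acc_s, f1_m, f1_s, auc_m, auc_s) -> dict:
    return {"accuracy_mean": acc_m, "accuracy_sd": acc_s,
            "f1_mean": f1_m, "f1_sd": f1_s,
            "auc_mean": auc_m, "auc_sd": auc_s}


def cross_validate_models(split: SplitResult, masks: dict, specs=None,
                          folds: int = 10, seed: int = 0) -> EvaluationReport:
    """Evaluate every (named subset x classifier) pair.

    Parameters
    ----------
    split : SplitResult
        Stratified train/test partition.
    masks : dict
        Subset name -> list of gene ids (must be non-empty and present in
        the split's gene pool).
    specs : iterable of str or ClassifierSpec, optional
        Defaults to the seven-classifier roster.
    folds, seed : CV protocol (stratified, shuffled with ``seed``).

    Returns a report holding, per pair: train-CV mean/SD, the same CV
    protocol applied to the test partition, and a conventional
    fit-on-train / score-on-test evaluation with confusion counts.
    """
    specs = list(specs) if specs is not None else list(DEFAULT_CLASSIFIERS)
    rows = []
    for subset_name, gene_ids in masks.items():
        if not list(gene_ids):
            raise ValueError(f"subset {subset_name!r} is empty")
        train = split.train.select_genes(gene_ids)
        test = split.test.select_genes(gene_ids)
        for spec in specs:
            if isinstance(spec, ClassifierSpec):
                name, params, clf_seed = spec.name, spec.params, spec.seed
            else:
                name, params, clf_seed = spec, {}, seed
            model = make_classifier(name, seed=clf_seed, **params)
            try:
                train_cv = _metric_dict(*_cv_metrics(model, train.values,
                                                     train.labels, folds, seed))
                test_cv = _metric_dict(*_cv_metrics(model, test.values,
                                                    test.labels, folds, seed))
                fitted = clone(model).fit(train.values, train.labels)
                pred = fitted.predict(test.values)
                counts = confusion_counts(test.labels, pred)
                holdout = {
                    "accuracy": accuracy(counts),
                    "f1": f1(counts),
                    "auc": roc_auc(test.labels, _scores_for_auc(fitted, test.values)),
                    "tpr": tpr(counts),
                    "fpr": fpr(counts),
                }
            except Exception as exc:
                raise RuntimeError(
                    f"evaluation failed for subset {subset_name!r} with "
                    f"classifier {name!r}: {exc}"
                ) from exc
            rows.append(ReportRow(subset=subset_name, classifier=name,
                                  genes=list(gene_ids), train_cv=train_cv,
                                  test_cv=test_cv, holdout=holdout,
                                  confusion=counts))
    return EvaluationReport(rows=rows, folds=folds, seed=seed)
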