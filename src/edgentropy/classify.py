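"""Nodal-entropy classifiers: RFE feature selection + linear SVM.

Two tasks mirror the study design: HC vs MDD (both patient groups pooled)
and MDDNSI vs MDDSI.  Features are per-region nodal entropies; recursive
feature elimination (squared linear-SVM coefficients, one feature dropped
per iteration) reduces them to a fixed subset inside each training fold,
then the SVM's C is tuned by an inner grid search, and metrics are taken on
the held-out fold.  Feature stability is summarized by how often each
region survives selection across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             precision_score, recall_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class FoldResult:
    accuracy: float  # percent
    precision: float
    recall: float
    f1: float
    selected_features: np.ndarray  # indices into the feature columns
    coef: np.ndarray  # |SVM coefficient| per selected feature
    best_c: float
    confusion: np.ndarray  # 2x2 counts
    roc_points: tuple[np.ndarray, np.ndarray]  # (scores, true labels)


@dataclass
class ClassifierReport:
    folds: list[FoldResult]
    accuracy: float
    precision: float
    recall: float
    f1: float
    n_features: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "n_features": self.n_features,
            "fold_accuracy": [f.accuracy for f in self.folds],
            "fold_best_c": [f.best_c for f in self.folds],
            "fold_selected": [f.selected_features.tolist() for f in self.folds],
            "confusion_total": np.sum([f.confusion for f in self.folds],
                                      axis=0).tolist(),
        }


def rfe_select(
    X: np.ndarray, y: np.ndarray, n_features: int, C: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Recursive feature elimination with a linear SVM, step = 1.

    Returns (selected indices in ascending order, elimination ranking where
    1 marks the surviving features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    if n_features > X.shape[1]:
        raise ValueError("n_features exceeds available features")
    if n_features == X.shape[1]:
        return np.arange(X.shape[1]), np.ones(X.shape[1], dtype=int)
    rfe = RFE(SVC(kernel="linear", C=C), n_features_to_select=n_features,
              step=1).fit(X, y)
    return np.where(rfe.support_)[0], rfe.ranking_


def train_eval_svm_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    n_features: int = 60,
    seed: int | None = None,
    rfe_scope: str = "fold",
    class_weight: str | None = None,
) -> ClassifierReport:
    """Stratified k-fold CV with in-fold RFE and inner C grid search.

    All feature selection and hyperparameter tuning happen inside each
    training fold; the held-out fold is touched only for scoring.
    ``rfe_scope="global"`` instead runs a single RFE on the full data before
    CV (optimistic; kept for comparison with single-selection protocols).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if counts.min() < n_folds:
        raise ValueError(f"fold count {n_folds} exceeds smallest class size "
                         f"({counts.min()})")
    if rfe_scope not in ("fold", "global"):
        raise ValueError(f"unknown rfe_scope: {rfe_scope!r}")
    pos = classes[1]
    y01 = (y == pos).astype(int)

    global_sel = None
    if rfe_scope == "global":
        global_sel, _ = rfe_select(X, y01, n_features)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for train, test in skf.split(X, y01):
        Xtr, ytr = X[train], y01[train]
        sel = global_sel if global_sel is not None \
            else rfe_select(Xtr, ytr, n_features)[0]
        inner = min(3, np.bincount(ytr).min())
        gs = GridSearchCV(SVC(kernel="linear", class_weight=class_weight),
                          {"C": list(c_grid)}, cv=inner, scoring="accuracy")
        gs.fit(Xtr[:, sel], ytr)
        clf = gs.best_estimator_
        pred = clf.predict(X[test][:, sel])
        ytt = y01[test]
        folds.append(FoldResult(
            accuracy=100 * accuracy_score(ytt, pred),
            precision=100 * precision_score(ytt, pred, zero_division=0),
            recall=100 * recall_score(ytt, pred, zero_division=0),
            f1=100 * f1_score(ytt, pred, zero_division=0),
            selected_features=sel,
            coef=np.abs(clf.coef_.ravel()),
            best_c=float(gs.best_params_["C"]),
            confusion=confusion_matrix(ytt, pred, labels=[0, 1]),
            roc_points=(clf.decision_function(X[test][:, sel]), ytt),
        ))
    return ClassifierReport(
        folds=folds,
        accuracy=float(np.mean([f.accuracy for f in folds])),
        precision=float(np.mean([f.precision for f in folds])),
        recall=float(np.mean([f.recall for f in folds])),
        f1=float(np.mean([f.f1 for f in folds])),
        n_features=n_features,
        seed=seed,
        extra={"positive_class": pos, "rfe_scope": rfe_scope},
    )


def feature_frequency(
    report: ClassifierReport, top_n: int = 10
) -> tuple[list[int], bool]:
    """Rank features by how often they were selected across folds.

    Ties are broken by the mean absolute SVM coefficient over the folds
    where the feature was selected, then by ascending feature index.
    Returns (ranked indices, truncated_flag) — the flag warns when fewer
    than ``top_n`` distinct features were ever selected.
    """
    if not report.folds:
        raise ValueError("report holds no folds")
    counts: dict[int, int] = {}
    coefs: dict[int, list[float]] = {}
    for f in report.folds:
        for idx, c in zip(f.selected_features, f.coef):
            counts[idx] = counts.get(idx, 0) + 1
            coefs.setdefault(idx, []).append(float(c))
    ranked = sorted(
        counts,
        key=lambda i: (-counts[i], -float(np.mean(coefs[i])), i),
    )
    truncated = len(ranked) < top_n
    return ranked[:top_n], truncated
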