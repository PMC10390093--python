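"""Cross-validated SVM grade classification.

Feature subsets are classified with support-vector machines (linear,
polynomial, RBF kernels).  The default resampling scheme is five repeated
stratified 70/30 train/test splits; plain stratified 5-fold is available via
``cv_mode='kfold'``.  Features are standardized using training-fold
statistics only.  The high-grade class is the positive class for
sensitivity/specificity, and AUC is computed from decision-function scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassificationReport",
    "cross_validated_svm",
    "select_best_kernel",
    "roc_auc",
]

KERNELS = ("linear", "poly", "rbf")
POSITIVE_LABEL = "HGG"


@dataclass
class FoldMetrics:
    fold: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_train: int
    n_test: int


@dataclass
class ClassificationReport:
    feature_set: str
    kernel: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_folds: int
    seed: int
    cv_mode: str
    fold_metrics: List[FoldMetrics] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "feature_set": self.feature_set,
            "kernel": self.kernel,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "cv_mode": self.cv_mode,
            "folds": [vars(f) for f in self.fold_metrics],
        }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _binary_labels(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == POSITIVE_LABEL).astype(int)
    return labels.astype(int)


def _splitter(cv_mode: str, n_folds: int, seed: int):
    if cv_mode == "shuffle":
        return StratifiedShuffleSplit(n_splits=n_folds, test_size=0.3,
                                      random_state=seed)
    if cv_mode == "kfold":
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    raise ValueError(f"unknown cv_mode: {cv_mode}")


def cross_validated_svm(features: np.ndarray, labels: Sequence,
                        kernel: str = "linear", seed: int = 0,
                        n_folds: int = 5, cv_mode: str = "shuffle",
                        feature_set: str = "", C: float = 1.0
                        ) -> ClassificationReport:
    """Stratified resampling; per-fold accuracy/sensitivity/specificity/AUC
    averaged over folds.  Rows with missing features are dropped."""
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _binary_labels(labels)
    keep = np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")

    folds: List[FoldMetrics] = []
    for i, (tr, te) in enumerate(_splitter(cv_mode, n_folds, seed).split(X, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            continue  # degenerate fold: a class vanished from train or test
        clf = make_pipeline(StandardScaler(),
                            SVC(kernel=kernel, C=C, gamma="scale"))
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        score = clf.decision_function(X[te])
        tp = int(np.sum((pred == 1) & (y[te] == 1)))
        tn = int(np.sum((pred == 0) & (y[te] == 0)))
        fp = int(np.sum((pred == 1) & (y[te] == 0)))
        fn = int(np.sum((pred == 0) & (y[te] == 1)))
        folds.append(FoldMetrics(
            fold=i,
            accuracy=(tp + tn) / len(te),
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            auc=roc_auc(score, y[te]),
            n_train=len(tr),
            n_test=len(te),
        ))
    if not folds:
        raise ValueError("no valid folds")

    def mean(attr: str) -> float:
        vals = [getattr(f, attr) for f in folds]
        return float(np.nanmean(vals)) * 100.0

    return ClassificationReport(
        feature_set=feature_set,
        kernel=kernel,
        accuracy=mean("accuracy"),
        sensitivity=mean("sensitivity"),
        specificity=mean("specificity"),
        auc=mean("auc"),
        n_folds=len(folds),
        seed=seed,
        cv_mode=cv_mode,
        fold_metrics=folds,
    )


def select_best_kernel(features: np.ndarray, labels: Sequence, seed: int = 0,
                       n_folds: int = 5, cv_mode: str = "shuffle",
                       feature_set: str = "") -> ClassificationReport:
    """Run all three kernels on identical folds and keep the best by AUC
    (ties: accuracy, then simplicity — linear before poly before rbf)."""
    reports = [
        cross_validated_svm(features, labels, kernel=k, seed=seed,
                            n_folds=n_folds, cv_mode=cv_mode,
                            feature_set=feature_set)
        for k in KERNELS
    ]
    return max(
        reports,
        key=lambda r: (r.auc, r.accuracy, -KERNELS.index(r.kernel)),
    )
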