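"""Subnetwork-index classification.

Each subject's *subnetwork connectivity index* is the mean of their raw
(unthresholded) correlations over the edges of an NBS-identified
component.  Diagnostic discrimination of that single index is evaluated
by k-fold cross-validated logistic regression: stratified random folds,
per-fold unregularized fits, predictions pooled over held-out folds for
accuracy, the confusion matrix and the ROC/AUC.

Note on circularity: when the component was selected on the *same*
subjects that are then cross-validated, the resulting accuracy/AUC is
optimistically biased — the selection step leaks group information.  The
index is reproduced this way by design for comparability; per-fold AUCs
are also reported so the spread across folds is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .connectome import ConnectivityMatrix
from .nbs import SubnetworkComponent

__all__ = [
    "ClassifierReport",
    "subnetwork_connectivity_index",
    "crossval_logistic",
]


@dataclass(frozen=True)
class ClassifierReport:
    accuracy: float
    accuracy_by_fold: tuple
    auc: float
    auc_by_fold: tuple
    confusion: np.ndarray  # rows = true class, cols = predicted
    fold_assignments: np.ndarray
    coefficients: tuple  # per-fold (intercept, slope)
    probabilities: np.ndarray  # pooled out-of-fold P(class 1)

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_by_fold": list(self.accuracy_by_fold),
            "auc": self.auc,
            "auc_by_fold": [None if np.isnan(a) else a for a in self.auc_by_fold],
            "confusion": self.confusion.tolist(),
            "coefficients": [list(c) for c in self.coefficients],
        }


def subnetwork_connectivity_index(
    c: ConnectivityMatrix, component: SubnetworkComponent
) -> float:
    """Mean raw correlation over the component's edges."""
    if component.size == 0:
        raise ValueError("component has no edges")
    n = c.n_parcels
    vals = []
    for i, j in component.edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"component edge ({i}, {j}) out of range for N={n}")
        vals.append(c.values[i, j])
    return float(np.mean(vals))


def crossval_logistic(
    index: np.ndarray,
    labels: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold cross-validated logistic regression on one index.

    Accuracy is pooled over all held-out predictions at the 0.5
    probability cutoff; AUC is computed from the pooled out-of-fold
    predicted probabilities (per-fold values also reported).
    """
    x = np.asarray(index, dtype=float).reshape(-1, 1)
    y = np.asarray(labels).astype(int)
    n = len(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly 2 classes")
    if not np.array_equal(classes, [0, 1]):
        y = (y == classes[1]).astype(int)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n < 2 * k_folds:
        raise ValueError("need at least 2 subjects per fold")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    prob = np.empty(n)
    pred = np.empty(n, dtype=int)
    folds = np.empty(n, dtype=int)
    coefs = []
    acc_fold = []
    auc_fold = []
    for f, (train, test) in enumerate(skf.split(x, y)):
        if np.unique(y[train]).size < 2:
            raise ValueError(
                "a training fold contains a single class; use more subjects "
                "or fewer folds"
            )
        # C=inf: unregularized maximum-likelihood fit
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        model.fit(x[train], y[train])
        p = model.predict_proba(x[test])[:, 1]
        prob[test] = p
        pred[test] = (p >= 0.5).astype(int)
        folds[test] = f
        coefs.append((float(model.intercept_[0]), float(model.coef_[0, 0])))
        acc_fold.append(float((pred[test] == y[test]).mean()))
        if np.unique(y[test]).size == 2:
            auc_fold.append(float(roc_auc_score(y[test], p)))
        else:
            auc_fold.append(float("nan"))

    confusion = np.zeros((2, 2), dtype=int)
    for truth, guess in zip(y, pred):
        confusion[truth, guess] += 1
    return ClassifierReport(
        accuracy=float((pred == y).mean()),
        accuracy_by_fold=tuple(acc_fold),
        auc=float(roc_auc_score(y, prob)),
        auc_by_fold=tuple(auc_fold),
        confusion=confusion,
        fold_assignments=folds,
        coefficients=tuple(coefs),
        probabilities=prob,
    )
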