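"""Patient-vs-control classification: Fisher-score ranking, linear SVM, LOOCV.

The classifier mirrors a standard FC-based diagnosis workflow: edges are
ranked by the two-class Fisher criterion, a linear SVM (label +1 = patient,
-1 = control) is trained on the top-k edges under leave-one-out
cross-validation, and the accuracy curve over k, ROC/AUC from held-out
decision values, and a label-permutation null of the AUC are reported.

Feature ranking and per-fold z-scoring use training subjects only when
``ranking_scope='fold'`` (leakage-safe default); ``'global'`` ranks once on
the full sample, mirroring the common published variant, and is documented
as optimistically biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics
from sklearn.svm import SVC


@dataclass
class ClassificationResult:
    accuracy_by_k: dict[int, float]
    best_k: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc: tuple[np.ndarray, np.ndarray]      # (FPR, TPR)
    auc: float
    ranking_scope: str
    C: float
    permutation_p: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    decision_values: np.ndarray = field(default=None, repr=False)
    predictions: np.ndarray = field(default=None, repr=False)


def fisher_score(x, labels) -> np.ndarray:
    """Two-class Fisher criterion per feature.

    F = ((m+ - m)^2 + (m- - m)^2) / (s+^2 + s-^2) with unbiased within-class
    variances; a zero denominator with separated means yields +inf (ranked
    first).  ``x`` may be a vector (one feature) or subjects x features.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    labels = np.asarray(labels)
    pos, neg = x[labels == 1], x[labels == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    grand = x.mean(axis=0)
    num = (pos.mean(axis=0) - grand) ** 2 + (neg.mean(axis=0) - grand) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return float(f[0]) if one_d else f


def _rank(x, y) -> np.ndarray:
    """Feature indices sorted by descending Fisher score (stable)."""
    f = fisher_score(x, y)
    return np.argsort(-f, kind="stable")


def _standardize(train, test):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv_svm(features, labels, k: int, ranking_scope: str = "fold",
              C: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out predictions and decision values using the top-k edges.

    Per fold: rank features (on training subjects for ``fold`` scope, once
    globally for ``global``), z-score with training statistics, train a
    linear SVM, and score the held-out subject.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, m = x.shape
    if n < 4 or (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need n >= 4 with at least two subjects per class")
    if not (1 <= k <= m):
        raise ValueError(f"k = {k} outside [1, {m}]")
    if ranking_scope not in ("fold", "global"):
        raise ValueError(f"unknown ranking_scope {ranking_scope!r}")
    global_order = _rank(x, y) if ranking_scope == "global" else None
    preds = np.empty(n)
    decisions = np.empty(n)
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        xt, yt = x[train_idx], y[train_idx]
        order = global_order if global_order is not None else _rank(xt, yt)
        cols = order[:k]
        xtr, xte = _standardize(xt[:, cols], x[i:i + 1, cols])
        clf = SVC(kernel="linear", C=C)
        clf.fit(xtr, yt)
        decisions[i] = clf.decision_function(xte)[0]
        preds[i] = clf.predict(xte)[0]
    return preds, decisions


def roc_auc(decision_values, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points by threshold sweep and AUC (concordant pairs, ties half-weight)."""
    y = np.asarray(labels)
    d = np.asarray(decision_values, dtype=float)
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _skmetrics.roc_curve(y, d, pos_label=1)
    auc = float(_skmetrics.roc_auc_score(y == 1, d))
    return (fpr, tpr), auc


def accuracy_curve(features, labels, ranking_scope: str = "fold", C: float = 1.0,
                   k_max: int | None = None) -> ClassificationResult:
    """LOOCV accuracy for k = 1..K; metrics and ROC/AUC at the best k.

    Ties on best accuracy resolve to the smallest k (parsimony).
    Sensitivity = correctly classified patients / patients; specificity the
    control analogue.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, m = x.shape
    k_max = m if k_max is None else min(k_max, m)
    global_order = _rank(x, y) if ranking_scope == "global" else None

    # one ranking + standardisation + k SVM fits per fold
    acc = {}
    preds_by_k = {k: np.empty(n) for k in range(1, k_max + 1)}
    dec_by_k = {k: np.empty(n) for k in range(1, k_max + 1)}
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        xt, yt = x[train_idx], y[train_idx]
        order = global_order if global_order is not None else _rank(xt, yt)
        xtr_all, xte_all = _standardize(xt[:, order], x[i:i + 1, order])
        for k in range(1, k_max + 1):
            clf = SVC(kernel="linear", C=C)
            clf.fit(xtr_all[:, :k], yt)
            dec_by_k[k][i] = clf.decision_function(xte_all[:, :k])[0]
            preds_by_k[k][i] = clf.predict(xte_all[:, :k])[0]
    for k in range(1, k_max + 1):
        acc[k] = float((preds_by_k[k] == y).mean())
    best_k = min(acc, key=lambda k: (-acc[k], k))
    preds, decisions = preds_by_k[best_k], dec_by_k[best_k]
    sens = float((preds[y == 1] == 1).mean())
    spec = float((preds[y == -1] == -1).mean())
    roc, auc = roc_auc(decisions, y)
    return ClassificationResult(
        accuracy_by_k=acc, best_k=best_k, accuracy=acc[best_k],
        sensitivity=sens, specificity=spec, roc=roc, auc=auc,
        ranking_scope=ranking_scope, C=C,
        decision_values=decisions, predictions=preds,
    )


def permutation_test_auc(features, labels, k: int, n_perm: int = 5000,
                         seed: int = 0, ranking_scope: str = "fold",
                         C: float = 1.0, plus_one: bool = False) -> tuple[float, np.ndarray]:
    """Label-permutation p-value for the LOOCV AUC at a fixed k.

    p = #{permuted AUC >= observed AUC} / n_perm (the literal proportion, so
    p = 0 is possible; ``plus_one`` switches to (b+1)/(n+1)).  Returns the p
    and the null AUC distribution.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    _, obs_dec = loocv_svm(features, y, k, ranking_scope, C)
    _, obs_auc = roc_auc(obs_dec, y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        _, dec = loocv_svm(features, yp, k, ranking_scope, C)
        _, null[b] = roc_auc(dec, yp)
    exceed = int((null >= obs_auc).sum())
    p = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    return float(p), null
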