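"""Pairwise group classification from differential edge features.

Mirrors the common neuroimaging recipe: continuous edge features ranked by
mutual information (MI) with the binary label, a linear support vector
machine, and leave-one-out cross-validation (LOOCV) scored by pooled
out-of-fold decision values (ROC/AUC, and accuracy / sensitivity /
specificity at the zero-margin threshold).

MI for a continuous feature against a binary label is estimated by
equal-frequency binning of the feature (default 8 bins, quantile edges from
the data at hand) followed by the plug-in contingency estimate with the
Miller-Madow bias correction, clipped at zero; values are in nats.  Feature
ranking and per-feature standardization are recomputed inside every LOOCV
fold from the training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "FeatureRanking",
    "ClassificationResult",
    "mi_rank_features",
    "loocv_linear_svm",
    "roc_metrics",
]


@dataclass
class FeatureRanking:
    mi: np.ndarray  # nats, >= 0
    ranks: np.ndarray  # 1 = most informative; permutation of 1..m
    n_bins: int


@dataclass
class ClassificationResult:
    auc: float  # percent
    accuracy: float  # percent
    sensitivity: float  # percent
    specificity: float  # percent
    roc_points: np.ndarray  # (FPR, TPR) pairs
    scores: np.ndarray  # out-of-fold decision values
    predicted: np.ndarray
    labels: np.ndarray
    positive_class: object
    degenerate: bool = False


def _binned_mi(x: np.ndarray, y01: np.ndarray, n_bins: int) -> float:
    n = len(x)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(qs, x, side="right")
    joint = np.zeros((n_bins, 2))
    for b, c in zip(bins, y01):
        joint[b, c] += 1
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    # Miller-Madow: H_mm = H + (K-1)/(2n)  =>  MI_mm = MI + (Kx + Ky - Kxy - 1)/(2n)
    kx, ky, kxy = (px > 0).sum(), (py > 0).sum(), nz.sum()
    mi += (kx + ky - kxy - 1) / (2.0 * n)
    return max(mi, 0.0)


def mi_rank_features(
    features: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 8,
) -> FeatureRanking:
    """Mutual information of each continuous feature with a binary label."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"labels must be binary, got classes {classes}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    y01 = (y == classes[1]).astype(int)
    mi = np.array([_binned_mi(X[:, j], y01, n_bins) for j in range(X.shape[1])])
    # descending MI; ties broken by feature index (stable sort on -mi)
    order = np.argsort(-mi, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(mi) + 1)
    return FeatureRanking(mi=mi, ranks=ranks, n_bins=n_bins)


def roc_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_class,
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC (percent) from decision scores.

    Ties are handled properly (one ROC step per distinct score), so the AUC
    equals the normalized Mann-Whitney U statistic,
    ``(#{pos > neg} + 0.5 * #{pos == neg}) / (n_pos * n_neg)``.
    Constant scores give AUC = 50% with a degeneracy flag via NaN-free output.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    is_pos = pos[order].astype(float)
    tp = np.cumsum(is_pos)
    fp = np.cumsum(1.0 - is_pos)
    # keep only the last index of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), 100.0 * auc


def loocv_linear_svm(
    features: np.ndarray,
    labels: np.ndarray,
    positive_class=None,
    n_features: int | None = None,
    C: float = 1.0,
    n_bins: int = 8,
) -> ClassificationResult:
    """Leave-one-out linear-SVM classification with in-fold MI ranking.

    Per fold: features are z-scored by training statistics, ranked by MI on
    the training subjects, the top ``n_features`` kept (default: all), and a
    linear SVM (regularization ``C``) scores the held-out subject.  Metrics
    come from the pooled out-of-fold decision values; accuracy, sensitivity
    and specificity use the zero decision threshold with ``positive_class``
    (default: the first label encountered) as the positive class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if min((y == c).sum() for c in classes) < 3:
        raise ValueError("need at least 3 subjects per class")
    if positive_class is None:
        positive_class = y[0]
    n = len(y)
    scores = np.empty(n)
    for k in range(n):
        tr = np.arange(n) != k
        Xtr, ytr = X[tr], y[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr_s = (Xtr - mu) / sd
        xk = (X[k] - mu) / sd
        if n_features is not None and n_features < X.shape[1]:
            ranking = mi_rank_features(Xtr_s, ytr, n_bins=n_bins)
            keep = ranking.ranks <= n_features
        else:
            keep = np.ones(X.shape[1], dtype=bool)
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr_s[:, keep], (ytr == positive_class).astype(int))
        scores[k] = clf.decision_function(xk[keep][None, :])[0]
    degenerate = bool(np.ptp(scores) == 0)
    roc, auc = roc_metrics(scores, y, positive_class)
    if degenerate:
        auc = 50.0
    predicted = np.where(scores > 0, positive_class, classes[classes != positive_class][0])
    pos = y == positive_class
    tp = int(np.sum((scores > 0) & pos))
    tn = int(np.sum((scores <= 0) & ~pos))
    return ClassificationResult(
        auc=auc,
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / int(pos.sum()),
        specificity=100.0 * tn / int((~pos).sum()),
        roc_points=roc,
        scores=scores,
        predicted=predicted,
        labels=y,
        positive_class=positive_class,
        degenerate=degenerate,
    )
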