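"""Segmentation and classification evaluation.

Segmentation agreement is scored by two normalized partition metrics
computed from the joint segment-overlap distribution p_ij of a candidate
segmentation S against a ground truth T:

* ``v_rand = 2 * sum p_ij^2 / (sum s_i^2 + sum t_j^2)`` — the F-score
  form of the Rand index over pixel pairs; 1 iff the partitions agree.
* ``v_info = 2 * I(S;T) / (H(S) + H(T))`` — normalized mutual
  information; 1 for identical partitions, 0 for independent ones.

Segments are 4-connected components of equal-label regions.  An optional
border-thinning mode skeletonizes the ground-truth boundary class to a
1-px skeleton and excludes it from the counted pixels, so thick
hand-drawn borders do not dominate the score.

Classification metrics are the usual one-vs-rest rates plus ROC and
precision-recall areas, reported per class and as support-weighted
means, with stratified k-fold cross-validation on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize
from sklearn.metrics import confusion_matrix, precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .feature_selection import FeatureTable
from .learning import ClassifierSpec, predict, predict_proba, train

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "contingency",
    "v_rand",
    "v_info",
    "classification_metrics",
    "cross_validate",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ContingencyTable:
    """Joint segment-overlap probabilities with marginals."""

    p: np.ndarray  # K_S x K_T

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if np.any(p < 0):
            raise ValueError("joint probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"joint probabilities must sum to 1, got {p.sum()}")
        self.p = p

    @property
    def s(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def t(self) -> np.ndarray:
        return self.p.sum(axis=0)


def _segments(labels: np.ndarray) -> np.ndarray:
    """4-connected components of equal-label regions, all labels treated alike."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=np.int64)
    next_id = 1
    for val in np.unique(labels):
        comp, n = ndimage.label(labels == val, structure=_FOUR_CONN)
        out[comp > 0] = comp[comp > 0] + next_id - 1
        next_id += n
    return out


def contingency(
    seg: np.ndarray,
    truth: np.ndarray,
    thin_borders: bool = False,
    boundary_label: int = 0,
    restrict_foreground: bool = False,
) -> ContingencyTable:
    """Joint overlap table of the segment partitions of ``seg`` and ``truth``.

    With ``thin_borders`` the ground-truth boundary class is reduced to a
    1-px skeleton and the remaining (non-skeleton) boundary pixels are
    excluded from the count.  With ``restrict_foreground`` only pixels
    whose truth label differs from ``boundary_label`` are counted.
    """
    seg = np.asarray(seg)
    truth = np.asarray(truth)
    if seg.shape != truth.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {truth.shape}")
    counted = np.ones(seg.shape, dtype=bool)
    if thin_borders:
        border = truth == boundary_label
        if border.any():
            skel = skeletonize(border)
            counted &= ~(border & ~skel)
    if restrict_foreground:
        counted &= truth != boundary_label
    if not counted.any():
        raise ValueError("no pixels left to count after thinning/restriction")
    s_ids = _segments(seg)[counted]
    t_ids = _segments(truth)[counted]
    s_codes = np.unique(s_ids, return_inverse=True)[1]
    t_codes = np.unique(t_ids, return_inverse=True)[1]
    k_s, k_t = s_codes.max() + 1, t_codes.max() + 1
    joint = np.bincount(s_codes * k_t + t_codes, minlength=k_s * k_t)
    p = joint.reshape(k_s, k_t).astype(np.float64)
    return ContingencyTable(p / p.sum())


def v_rand(ct: ContingencyTable) -> float:
    """F-score form of the Rand index: 2*sum p^2 / (sum s^2 + sum t^2).

    Sums are accumulated with ``math.fsum`` so a permutation-diagonal
    table scores exactly 1.0 (the marginal and joint reductions would
    otherwise round differently).
    """
    num = 2.0 * math.fsum((ct.p**2).ravel())
    den = math.fsum(ct.s**2) + math.fsum(ct.t**2)
    return num / den


def _plogp(p: np.ndarray) -> float:
    p = p[p > 0]
    return math.fsum(p * np.log(p))


def v_info(ct: ContingencyTable) -> float:
    """Normalized mutual information 2*I(S;T) / (H(S) + H(T)).

    Natural logarithms (the ratio is base-free).  Undefined when both
    partitions are single-segment (H(S) + H(T) = 0).
    """
    h_s = -_plogp(ct.s)
    h_t = -_plogp(ct.t)
    if h_s + h_t <= 0:
        raise ValueError("v_info undefined: both partitions are single-segment")
    mutual = _plogp(ct.p.ravel()) - _plogp(ct.s) - _plogp(ct.t)
    return float(np.clip(2.0 * mutual / (h_s + h_t), 0.0, 1.0))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest rates with support-weighted means."""

    classes: List
    per_class: pd.DataFrame       # rows per class: tp_rate..pr_area, support
    confusion: np.ndarray
    means: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.means:
            w = self.per_class["support"].to_numpy(dtype=float)
            w = w / w.sum()
            self.means = {
                c: float(np.sum(self.per_class[c].to_numpy() * w))
                for c in self.per_class.columns
                if c != "support"
            }


def _trapezoid_pr_area(y_true: np.ndarray, score: np.ndarray) -> float:
    """Trapezoidal area under the precision-recall curve.

    Tied recall values (score ties) keep their best precision, so the
    degenerate all-positive operating point does not drag the curve down
    at recall 1.
    """
    precision, recall, _ = precision_recall_curve(y_true, score)
    best: Dict[float, float] = {}
    for p, r in zip(precision, recall):
        best[r] = max(best.get(r, 0.0), p)
    rs = np.array(sorted(best))
    ps = np.array([best[r] for r in rs])
    return float(np.trapezoid(ps, rs))


def classification_metrics(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: Optional[np.ndarray] = None,
    classes: Optional[Sequence] = None,
) -> MetricsReport:
    """TP/FP rates, precision, recall, F1, ROC and PR areas per class.

    ``scores`` is an instances x classes matrix of class scores (e.g.
    probabilities) used for the ROC/PR areas; when omitted, one-hot
    scores derived from the predicted labels are used.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    if scores is None:
        scores = np.stack([(y_pred == c).astype(float) for c in classes], axis=1)
    scores = np.asarray(scores, dtype=np.float64)
    rows = []
    for i, c in enumerate(classes):
        pos = y_true == c
        tp = float(cm[i, i])
        fn = float(cm[i].sum() - cm[i, i])
        fp = float(cm[:, i].sum() - cm[i, i])
        tn = float(cm.sum() - tp - fn - fp)
        tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
        fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tpr
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        if pos.all() or not pos.any():
            roc = pr = 0.0
        else:
            roc = float(roc_auc_score(pos, scores[:, i]))
            pr = _trapezoid_pr_area(pos.astype(int), scores[:, i])
        rows.append(
            {"tp_rate": tpr, "fp_rate": fpr, "precision": prec, "recall": rec,
             "f1": f1, "roc_area": roc, "pr_area": pr, "support": int(pos.sum())}
        )
    per_class = pd.DataFrame(rows, index=[str(c) for c in classes])
    return MetricsReport(classes=classes, per_class=per_class, confusion=cm)


def cross_validate(
    table: FeatureTable,
    spec: ClassifierSpec | None = None,
    k_folds: int = 10,
    seed: int = 0,
) -> Dict[str, object]:
    """Stratified k-fold cross-validation; mean metrics plus per-fold reports."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    spec = spec or ClassifierSpec()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    X = table.matrix
    y = table.labels
    classes = list(table.classes)
    fold_reports: List[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        sub_train = FeatureTable(table.data.iloc[train_idx].reset_index(drop=True),
                                 y[train_idx])
        sub_test = FeatureTable(table.data.iloc[test_idx].reset_index(drop=True),
                                y[test_idx])
        model = train(sub_train, spec)
        pred = predict(model, sub_test)
        proba = predict_proba(model, sub_test)
        fold_reports.append(
            classification_metrics(y[test_idx], pred, proba, classes=model.classes)
        )
    mean_metrics = {
        key: float(np.mean([r.means[key] for r in fold_reports]))
        for key in fold_reports[0].means
    }
    return {"mean": mean_metrics, "folds": fold_reports, "classes": classes}
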