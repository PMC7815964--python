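"""Performance measurements for binary classifiers, with explicit tie and
degenerate-case handling.

All metrics are implemented here rather than delegated, so that tie
handling and degenerate cases are pinned down exactly:

* AUROC is the concordance probability — the chance a random positive is
  scored above a random negative, ties credited 1/2.  Computed from
  mid-ranks; equivalent to the trapezoid rule on the tie-grouped ROC curve.
* prAUC is the average-precision summation sum_k (R_k - R_{k-1}) * P_k over
  descending score thresholds.  Trapezoidal interpolation of the PR curve
  is biased, so it is deliberately not used.
* Degenerate cases (no positive predictions, a single observed class, ...)
  yield an explicit ``None`` ("undefined") rather than a silent 0, so that
  rankings can sort them last deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import BioAutoMLError

#: epsilon used to clamp probabilities before taking logs
LOGLOSS_EPS = 1e-15

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "f1",
    "auroc",
    "prauc",
    "logloss",
)


@dataclass
class MetricSet:
    """A bundle of classification metrics; ``None`` marks an undefined value."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    auroc: float | None = None
    prauc: float | None = None
    logloss: float | None = None
    positive_class: str | None = None
    n_positive: int = 0
    n_negative: int = 0

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def get(self, name: str) -> float | None:
        if name not in METRIC_NAMES:
            raise BioAutoMLError(f"unknown metric {name!r}")
        return getattr(self, name)


def mean_metric_sets(sets: list[MetricSet]) -> tuple[MetricSet, MetricSet]:
    """Average a list of MetricSets, ignoring undefined entries per metric.

    Returns (mean, standard deviation); a metric undefined in every input
    stays undefined in both.
    """
    if not sets:
        raise BioAutoMLError("cannot average an empty list of metric sets")
    mean = MetricSet(positive_class=sets[0].positive_class)
    sd = MetricSet(positive_class=sets[0].positive_class)
    for name in METRIC_NAMES:
        vals = [s.get(name) for s in sets if s.get(name) is not None]
        if vals:
            setattr(mean, name, float(np.mean(vals)))
            setattr(sd, name, float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    mean.n_positive = int(np.mean([s.n_positive for s in sets]))
    mean.n_negative = int(np.mean([s.n_negative for s in sets]))
    return mean, sd


def _binary(true_labels, positive_class) -> np.ndarray:
    labels = np.asarray(true_labels)
    y = (labels == positive_class).astype(int)
    return y


def confusion_metrics(predicted_labels, true_labels, positive_class):
    """Accuracy, sensitivity, specificity, precision and F1 from hard labels.

    Precision is undefined when there are no positive predictions;
    specificity is undefined when there are no actual negatives; sensitivity
    is undefined when there are no actual positives.
    """
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size < 1:
        raise BioAutoMLError("predicted and true labels must have equal length >= 1")
    observed = set(true.tolist()) | set(pred.tolist())
    if len(observed - {positive_class}) > 1:
        extra = sorted(str(x) for x in observed)
        raise BioAutoMLError(f"labels outside the two classes: {extra}")
    yp = pred == positive_class
    yt = true == positive_class
    tp = int(np.sum(yp & yt))
    fp = int(np.sum(yp & ~yt))
    fn = int(np.sum(~yp & yt))
    tn = int(np.sum(~yp & ~yt))
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return accuracy, sensitivity, specificity, precision, f1


def roc_auc(scores, true_labels, positive_class):
    """ROC curve points and AUROC (concordance with half-credit for ties).

    Returns ``(points, auroc)`` where points is a list of (threshold, FPR,
    TPR) swept over distinct score values in descending order, bracketed by
    the (inf, 0, 0) origin.  With only one observed class the AUROC is
    undefined (``None``).
    """
    s = np.asarray(scores, dtype=float)
    y = _binary(true_labels, positive_class)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return [], None
    ranks = rankdata(s)  # mid-ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    points = [(math.inf, 0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[order[j]] == s[order[i]]:
            tp += int(y[order[j]] == 1)
            fp += int(y[order[j]] == 0)
            j += 1
        points.append((float(s[order[i]]), fp / n_neg, tp / n_pos))
        i = j
    return points, float(auc)


def pr_auc(scores, true_labels, positive_class):
    """Precision-recall curve points and area by average-precision summation.

    The area is sum over thresholds of (recall gain) x (precision at that
    threshold), which equals the mean precision at the rank of each positive
    (tie groups evaluated jointly).  Undefined when there are no positives.
    A constant-score classifier yields exactly the prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary(true_labels, positive_class)
    n_pos = int(y.sum())
    if n_pos == 0:
        return [], None
    order = np.argsort(-s, kind="stable")
    points = []
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[order[j]] == s[order[i]]:
            tp += int(y[order[j]] == 1)
            fp += int(y[order[j]] == 0)
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        points.append((float(s[order[i]]), recall, precision))
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return points, float(ap)


def log_loss(scores, true_labels, positive_class, clamp: float = LOGLOSS_EPS):
    """Negative mean log-likelihood of the positive-class probabilities.

    Probabilities are clamped to [clamp, 1-clamp] so that hard 0/1 scores do
    not produce infinities.
    """
    p = np.asarray(scores, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise BioAutoMLError("scores must be probabilities in [0, 1]")
    y = _binary(true_labels, positive_class)
    p = np.clip(p, clamp, 1 - clamp)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def score_metrics(
    scores,
    true_labels,
    positive_class: str,
    negative_class: str,
    threshold: float = 0.5,
) -> MetricSet:
    """Full MetricSet from positive-class probabilities.

    Hard labels are derived at the given probability threshold; ranking
    metrics use the probabilities directly.
    """
    s = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels)
    pred = np.where(s >= threshold, positive_class, negative_class)
    accuracy, sensitivity, specificity, precision, f1 = confusion_metrics(
        pred, true, positive_class
    )
    _, auroc = roc_auc(s, true, positive_class)
    _, prauc = pr_auc(s, true, positive_class)
    ll = log_loss(s, true, positive_class)
    y = _binary(true, positive_class)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        recall=sensitivity,
        f1=f1,
        auroc=auroc,
        prauc=prauc,
        logloss=ll,
        positive_class=str(positive_class),
        n_positive=int(y.sum()),
        n_negative=int(y.size - y.sum()),
    )


def curve_points_table(points, x_name: str, y_name: str):
    """Curve points as rows of (threshold, x, y) dicts for TSV export."""
    return [
        {"threshold": t, x_name: x, y_name: y}
        for (t, x, y) in points
    ]
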