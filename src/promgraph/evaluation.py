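"""Binary-classification metric suite.

All metrics are computed literally from the 2x2 confusion tally (class 1 =
promoter = positive):

    Sen = TP/(TP+FN)            Spe = TN/(TN+FP)
    Acc = (TP+TN)/total         Pre = TP/(TP+FP)
    F1  = 2TP/(2TP+FP+FN)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

AUC is the rank-based Mann-Whitney statistic with midranks for ties
(identical to the trapezoidal ROC area); Cohen's kappa is implemented in
its multi-class form (Acc - p_e)/(1 - p_e) with the chance-agreement term
p_e = sum_m a_m b_m / n^2 over actual/predicted class counts a_m, b_m.
Degenerate denominators (an empty margin) yield 0 with a warning rather
than an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """The seven headline metrics plus kappa for one evaluation run."""

    sen: float
    spe: float
    acc: float
    mcc: float
    pre: float
    f1: float
    auc: float
    kappa: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def _check_pair(y_true, y_other) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=int)
    y_other = np.asarray(y_other)
    if y_true.shape != y_other.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_other.shape}")
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_other


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true, y_pred = _check_pair(y_true, y_pred)
    y_pred = y_pred.astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: degenerate zero denominator, returning 0", stacklevel=3)
        return 0.0
    return num / den


def binary_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sen, Spe, Acc, MCC, Pre, F1 from a confusion tally."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    mcc_den = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    return {
        "sen": _safe_div(tp, tp + fn, "Sen"),
        "spe": _safe_div(tn, tn + fp, "Spe"),
        "acc": (tp + tn) / counts.total,
        "mcc": _safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
        "pre": _safe_div(tp, tp + fp, "Pre"),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn, "F1"),
    }


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney AUC with midranks; equals the trapezoidal ROC area."""
    y_true, scores = _check_pair(y_true, scores)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores.astype(float), method="average")
    rank_sum_pos = float(ranks[y_true == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def pr_curve(y_true, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision/recall at every distinct threshold, threshold-descending.

    Returns (thresholds, recall, precision); the first point is the
    recall-0 anchor at precision 1 (threshold +inf by convention).
    """
    y_true, scores = _check_pair(y_true, scores)
    scores = scores.astype(float)
    n_pos = int(np.sum(y_true == 1))
    if n_pos == 0:
        raise ValueError("PR curve undefined without positives")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp_cum = np.cumsum(y_true[order] == 1)
    pred_cum = np.arange(1, len(scores) + 1)
    # keep only the last row of each tied-score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    recall = np.r_[0.0, tp_cum[distinct] / n_pos]
    precision = np.r_[1.0, tp_cum[distinct] / pred_cum[distinct]]
    # truncate after full recall is first reached (standard construction)
    stop = int(np.argmax(recall >= 1.0)) + 1 if recall.max() >= 1.0 else len(recall)
    return thresholds[:stop], recall[:stop], precision[:stop]


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement, multi-class form: (Acc - p_e)/(1 - p_e)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    y_pred = y_pred.astype(int)
    n = y_true.size
    acc = float(np.mean(y_true == y_pred))
    classes = np.union1d(y_true, y_pred)
    p_e = sum(
        float(np.sum(y_true == c)) * float(np.sum(y_pred == c)) for c in classes
    ) / (n * n)
    if p_e == 1.0:
        warnings.warn("kappa: chance agreement is 1; defined as 1 iff identical",
                      stacklevel=2)
        return 1.0 if np.array_equal(y_true, y_pred) else 0.0
    return (acc - p_e) / (1.0 - p_e)


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold the scores, tally, and compute all metrics."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    counts = confusion_counts(y_true, y_pred)
    base = binary_metrics(counts)
    return MetricsReport(
        **base,
        auc=roc_auc(y_true, scores),
        kappa=cohen_kappa(y_true, y_pred),
        counts=counts,
    )
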