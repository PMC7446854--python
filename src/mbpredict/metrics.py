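"""Predictive metrics: error rate, baseline error rate, R²_ER, AUC, AUPRC.

The error rate is the fraction of wrongly predicted cases under the
argmax rule.  The baseline error rate ER⁽⁰⁾ = 1 − max_k f_k is what a
predictor that always answers the majority class achieves; the relative
reduction R²_ER = (ER⁽⁰⁾ − ER)/ER⁽⁰⁾ plays the role of R² for
classification.  AUC is computed rank-based (Mann–Whitney, ties ½),
which equals the trapezoidal area under the empirical ROC curve; AUPRC
uses step-wise (right-continuous) interpolation of precision over
recall, which avoids the optimistic bias of linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsReport:
    er: float
    er0: float
    rer2: float
    auc: float
    auprc: float
    class_frequencies: dict
    n: int


def error_rate(yhat: np.ndarray, y: np.ndarray) -> float:
    """Proportion of wrongly predicted cases, mean of I(yhat != y)."""
    yhat = np.asarray(yhat)
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    if yhat.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.mean(yhat != y))


def baseline_error_rate(y: np.ndarray) -> float:
    """ER of always predicting the majority class: 1 − max_k f_k."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(y, return_counts=True)
    return float(1.0 - counts.max() / y.size)


def rer2(er: float, er0: float) -> float:
    """Relative ER reduction (ER⁽⁰⁾ − ER)/ER⁽⁰⁾; negative when worse than baseline."""
    if er0 <= 0:
        raise ValueError("baseline error rate must be positive")
    return (er0 - er) / er0


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC of `scores` for the positive class (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the precision-recall curve, step-wise interpolation.

    Thresholds sweep the distinct score values from high to low;
    the area is sum over steps of (recall increment) × precision.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive samples")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # evaluate only at the last index of each tied score block
    distinct = np.flatnonzero(np.append(np.diff(s_sorted) != 0, True))
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def confusion_metrics(yhat: np.ndarray, y: np.ndarray, positive_class) -> dict:
    """Sensitivity, specificity, precision and recall at a fixed decision.

    Sensitivity (= recall) is TP/(TP+FN); specificity TN/(TN+FP);
    precision TP/(TP+FP).  Undefined ratios (empty denominators) are
    returned as NaN rather than raising.
    """
    yhat = np.asarray(yhat)
    y = np.asarray(y)
    pos_hat = yhat == positive_class
    pos = y == positive_class
    tp = int(np.sum(pos_hat & pos))
    tn = int(np.sum(~pos_hat & ~pos))
    fp = int(np.sum(pos_hat & ~pos))
    fn = int(np.sum(~pos_hat & pos))

    def _ratio(a, b):
        return a / b if b > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "precision": _ratio(tp, tp + fp),
        "recall": _ratio(tp, tp + fn),
    }


def argmax_predict(proba: np.ndarray, classes: np.ndarray, majority_first: int | None = None) -> np.ndarray:
    """Point prediction by argmax over class probabilities.

    Ties are broken toward the majority training class when
    ``majority_first`` (its column index) is given, else toward the
    lower class index.
    """
    proba = np.asarray(proba, dtype=float)
    if majority_first is not None:
        # nudge the majority column so exact ties resolve toward it
        proba = proba.copy()
        proba[:, majority_first] += 1e-12
    return np.asarray(classes)[np.argmax(proba, axis=1)]


def report(
    proba: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    positive_class=None,
    majority_first: int | None = None,
) -> MetricsReport:
    """Full metrics report from class probabilities and observed labels.

    ``positive_class`` defaults to the second level in sorted order.
    """
    classes = np.asarray(classes)
    y = np.asarray(y)
    if positive_class is None:
        positive_class = np.sort(classes)[1]
    pos_col = int(np.flatnonzero(classes == positive_class)[0])
    yhat = argmax_predict(proba, classes, majority_first)
    er = error_rate(yhat, y)
    er0 = baseline_error_rate(y)
    levels, counts = np.unique(y, return_counts=True)
    freq = {lev: c / y.size for lev, c in zip(levels.tolist(), counts.tolist())}
    scores = np.asarray(proba, dtype=float)[:, pos_col]
    y_bin = y == positive_class
    return MetricsReport(
        er=er,
        er0=er0,
        rer2=rer2(er, er0) if er0 > 0 else float("nan"),
        auc=auc(scores, y_bin),
        auprc=auprc(scores, y_bin),
        class_frequencies=freq,
        n=int(y.size),
    )
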