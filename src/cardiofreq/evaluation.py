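"""Confusion matrix, accuracy/recall/precision/F-measure and one-vs-rest ROC.

Class order everywhere is (normal, control, noise).  Accuracy for the
3-class task is trace/total, the standard multi-class generalization of
(TP+TN)/(TP+FN+FP+TN) which it reproduces in the binary case.  Recall,
precision and F are computed per class by one-vs-rest marginalization of
the matrix, with macro averages on top; an undefined metric (empty row
or column) raises :class:`UndefinedMetricError` rather than silently
returning zero, because silent zeros corrupt parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cardiofreq.synthetic_ecg import CLASS_LABELS

N_CLASSES = len(CLASS_LABELS)
_LABEL_TO_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (no relevant examples)."""


def _label_index(label: str | int) -> int:
    if isinstance(label, str):
        try:
            return _LABEL_TO_INDEX[label]
        except KeyError:
            raise ValueError(f"unknown class label {label!r}; expected one of {CLASS_LABELS}") from None
    i = int(label)
    if not 0 <= i < N_CLASSES:
        raise ValueError(f"class index out of range: {i}")
    return i


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts: rows = true condition, columns = predicted label."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"counts must be {N_CLASSES}x{N_CLASSES}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str | int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against the rest."""
        i = _label_index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


@dataclass(frozen=True)
class Metrics:
    """Per-class and macro-averaged classification metrics, all in [0, 1]."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f_measure: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f: float


@dataclass(frozen=True)
class RocCurve:
    """One-vs-rest ROC: (fpr, tpr) steps from (0,0) to (1,1), trapezoidal AUC."""

    cls: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Tally counts[i][j] = #{k : true = i, predicted = j}."""
    t = [_label_index(x) for x in true_labels]
    p = [_label_index(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    c = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(c, (t, p), 1)
    return ConfusionMatrix(c)


def accuracy(matrix: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    if matrix.total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty matrix")
    return float(np.trace(matrix.counts)) / matrix.total


def recall(matrix: ConfusionMatrix, cls: str | int) -> float:
    """TP / (TP + FN): diagonal count over the class's true-condition row."""
    i = _label_index(cls)
    row = matrix.counts[i].sum()
    if row == 0:
        raise UndefinedMetricError(f"recall undefined: no true examples of {CLASS_LABELS[i]!r}")
    return float(matrix.counts[i, i]) / float(row)


def precision(matrix: ConfusionMatrix, cls: str | int) -> float:
    """TP / (TP + FP): diagonal count over the class's prediction column."""
    i = _label_index(cls)
    col = matrix.counts[:, i].sum()
    if col == 0:
        raise UndefinedMetricError(f"precision undefined: no predictions of {CLASS_LABELS[i]!r}")
    return float(matrix.counts[i, i]) / float(col)


def f_measure(p: float, r: float) -> float:
    """Harmonic mean 2PR / (P + R)."""
    if p < 0 or r < 0:
        raise ValueError("precision and recall must be non-negative")
    if p + r == 0:
        raise UndefinedMetricError("F-measure undefined when precision = recall = 0")
    return 2.0 * p * r / (p + r)


def compute_metrics(matrix: ConfusionMatrix, strict: bool = True) -> Metrics:
    """All headline metrics from one confusion matrix.

    With ``strict=False`` an undefined per-class metric becomes NaN
    (which propagates into the macro averages) instead of raising —
    useful inside parameter sweeps where an early-training model may not
    predict every class yet.  NaN is deliberate: it cannot be mistaken
    for a genuinely bad-but-defined score the way a silent 0 can.
    """

    def _maybe(fn, *args):
        if strict:
            return fn(*args)
        try:
            return fn(*args)
        except UndefinedMetricError:
            return float("nan")

    prec = {c: _maybe(precision, matrix, c) for c in CLASS_LABELS}
    rec = {c: _maybe(recall, matrix, c) for c in CLASS_LABELS}
    f = {c: _maybe(f_measure, prec[c], rec[c]) for c in CLASS_LABELS}
    return Metrics(
        accuracy=accuracy(matrix),
        precision=prec,
        recall=rec,
        f_measure=f,
        macro_precision=float(np.mean(list(prec.values()))),
        macro_recall=float(np.mean(list(rec.values()))),
        macro_f=float(np.mean(list(f.values()))),
    )


def roc_one_vs_rest(scores: np.ndarray, true_labels: Sequence, cls: str | int) -> RocCurve:
    """ROC for one class treated as positive, swept over its activation.

    ``scores`` is (n_examples, 3) output activations.  Equal scores are
    grouped into a single threshold step; AUC is the trapezoidal area.
    """
    i = _label_index(cls)
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] != N_CLASSES:
        raise ValueError(f"scores must have shape (n, {N_CLASSES}), got {s.shape}")
    y = np.array([_label_index(t) == i for t in true_labels])
    if len(y) != s.shape[0]:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"ROC undefined: need both positive and negative examples of {CLASS_LABELS[i]!r}"
        )
    sc = s[:, i]
    order = np.argsort(-sc, kind="stable")
    sc_sorted = sc[order]
    y_sorted = y[order]
    # cumulative counts at each distinct score (ties collapsed to one step)
    distinct = np.r_[np.flatnonzero(np.diff(sc_sorted)), len(sc_sorted) - 1]
    tp_cum = np.cumsum(y_sorted)[distinct]
    fp_cum = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, sc_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(cls=CLASS_LABELS[i], fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
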