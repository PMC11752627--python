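"""Multiclass one-vs-rest evaluation: confusion matrix, six metrics, ROC, PR.

For each class the K-class confusion matrix is reduced to binary counts
(Tp, Fn, Tn, Fp) and six statistics are computed:

    Acc = (Tp + Tn) / (Tp + Tn + Fp + Fn)
    Se  = Tp / (Tp + Fn)                      (sensitivity / recall)
    Sp  = Tn / (Tn + Fp)                      (specificity)
    Pre = Tp / (Tp + Fp)                      (precision)
    F1  = 2 * Se * Pre / (Se + Pre)
    MCC = (Tp*Tn - Fp*Fn) / sqrt((Tp+Fp)(Tp+Fn)(Tn+Fp)(Tn+Fn))

A metric whose denominator is zero is reported as 0 and flagged as
degenerate rather than NaN, so batch evaluation stays stable. Macro
averages are unweighted arithmetic means over classes. ROC and
precision-recall curves are computed over the empirical threshold set
(score ties grouped) with trapezoidal areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from afwave.errors import InputError, ParameterError

METRIC_NAMES = ("acc", "se", "sp", "pre", "f1", "mcc")


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ClassMetrics:
    """The six one-vs-rest statistics for one class.

    ``degenerate`` names the metrics whose denominator was zero (their
    value is reported as 0).
    """

    acc: float
    se: float
    sp: float
    pre: float
    f1: float
    mcc: float
    degenerate: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics plus curve summaries."""

    confusion: ConfusionMatrix
    per_class: dict
    macro: ClassMetrics
    auc_roc: dict = field(default_factory=dict)
    auc_pr: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "classes": [str(c) for c in self.confusion.class_names],
            "confusion": self.confusion.counts.tolist(),
            "per_class": {str(c): m.as_dict() for c, m in self.per_class.items()},
            "macro": self.macro.as_dict(),
        }
        if self.auc_roc:
            out["auc_roc"] = {str(c): v for c, v in self.auc_roc.items()}
        if self.auc_pr:
            out["auc_pr"] = {str(c): v for c, v in self.auc_pr.items()}
        return out


def confusion_matrix(true_labels, predicted_labels, class_names) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a K x K matrix."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise InputError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise InputError(f"label outside class_names: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> BinaryCounts:
    """Reduce a K-class matrix to binary counts for one class."""
    k = cm.counts.shape[0]
    if not 0 <= class_index < k:
        raise ParameterError(f"class_index {class_index} out of range for {k} classes")
    tp = int(cm.counts[class_index, class_index])
    fn = int(cm.counts[class_index].sum()) - tp
    fp = int(cm.counts[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _ratio(num: float, den: float, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def class_metrics(c: BinaryCounts) -> ClassMetrics:
    """Evaluate the six statistics for one class's binary counts."""
    if c.total == 0:
        raise InputError("all-zero counts")
    flags: set = set()
    acc = (c.tp + c.tn) / c.total
    se = _ratio(c.tp, c.tp + c.fn, "se", flags)
    sp = _ratio(c.tn, c.tn + c.fp, "sp", flags)
    pre = _ratio(c.tp, c.tp + c.fp, "pre", flags)
    f1 = _ratio(2.0 * se * pre, se + pre, "f1", flags)
    denom = math.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if denom == 0:
        flags.add("mcc")
        mcc = 0.0
    else:
        mcc = (float(c.tp) * c.tn - float(c.fp) * c.fn) / denom
    return ClassMetrics(acc=acc, se=se, sp=sp, pre=pre, f1=f1, mcc=mcc, degenerate=flags)


def macro_average(per_class_records: list[ClassMetrics]) -> ClassMetrics:
    """Unweighted arithmetic mean of each metric over classes."""
    if not per_class_records:
        raise InputError("need at least one class record")
    means = {
        name: float(np.mean([getattr(r, name) for r in per_class_records]))
        for name in METRIC_NAMES
    }
    degenerate = set().union(*(r.degenerate for r in per_class_records))
    return ClassMetrics(**means, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class PrCurve:
    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auc: float

    def recall_at_precision(self, p: float) -> float:
        """Maximal recall among thresholds whose precision is >= p."""
        ok = self.precision >= p
        return float(self.recall[ok].max()) if ok.any() else 0.0


def _validate_scores(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(truth).ravel().astype(bool)
    if s.size != y.size or s.size == 0:
        raise InputError("scores and truth must be equal-length and non-empty")
    if np.any(s < 0) or np.any(s > 1) or not np.all(np.isfinite(s)):
        raise InputError("scores must lie in [0, 1]")
    return s, y


def _threshold_counts(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative (tp, fp) at every distinct threshold, descending.

    An item is predicted positive when its score >= threshold; tied
    scores enter together.
    """
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.where(np.diff(s_sorted))[0]
    last = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[last].astype(float)
    fp = np.cumsum(~y_sorted)[last].astype(float)
    return s_sorted[last], tp, fp


def roc_points_and_auc(scores_for_class, binary_truth) -> RocCurve:
    """ROC curve over all score thresholds with trapezoidal AUC."""
    s, y = _validate_scores(scores_for_class, binary_truth)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both truth values must be present for a ROC curve")
    thr, tp, fp = _threshold_counts(s, y)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def pr_points_and_auc(scores_for_class, binary_truth) -> PrCurve:
    """Precision-recall curve with trapezoidal area over recall."""
    s, y = _validate_scores(scores_for_class, binary_truth)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise InputError("no positives in truth; PR curve undefined")
    thr, tp, fp = _threshold_counts(s, y)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    # anchor at recall 0 with the precision of the strictest threshold
    r = np.r_[0.0, recall]
    p = np.r_[precision[0], precision]
    auc = float(np.trapezoid(p, r))
    return PrCurve(thresholds=thr, recall=r, precision=p, auc=auc)


def evaluate(
    true_labels,
    predicted_labels,
    class_names,
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """Full evaluation battery for one prediction run.

    ``scores`` (items x classes probability matrix, column order matching
    ``class_names``) enables per-class AUC-ROC / AUC-PR; classes whose
    one-vs-rest truth is single-valued get no curve entry.
    """
    cm = confusion_matrix(true_labels, predicted_labels, class_names)
    per_class = {c: class_metrics(one_vs_rest_counts(cm, i)) for i, c in enumerate(class_names)}
    macro = macro_average(list(per_class.values()))
    report = MetricsReport(confusion=cm, per_class=per_class, macro=macro)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        truth = np.asarray(list(true_labels))
        for i, c in enumerate(class_names):
            binary = truth == np.asarray(c)
            if binary.all() or not binary.any():
                continue
            report.auc_roc[c] = roc_points_and_auc(scores[:, i], binary).auc
            report.auc_pr[c] = pr_points_and_auc(scores[:, i], binary).auc
    return report
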