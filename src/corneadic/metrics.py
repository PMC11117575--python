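"""Evaluation arithmetic for binary screening studies.

Confusion-matrix metrics (accuracy, precision, recall/sensitivity, F1,
specificity), ROC analysis with trapezoidal AUC and a Youden-index optimal
cut-off, two-sample pooled t statistics and Pearson chi-square from summary
data, and a brute-force reconstruction of integer confusion matrices from
rounded published metrics.

All metric formulas use the standard confusion-matrix definitions::

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)            (= sensitivity)
    F1        = 2 * precision * recall / (precision + recall)
    specificity = TN / (TN + FP)

A metric whose denominator is zero is reported as ``None`` (missing), never
propagated as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "ConfusionMatrix",
    "ClassifierReport",
    "RocResult",
    "TTestResult",
    "Chi2Result",
    "confusion_metrics",
    "f1_from_precision_recall",
    "roc_auc",
    "reconstruct_confusion",
    "two_sample_t",
    "chi_square_2x2",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary decision: positives = disease class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def f1_from_precision_recall(precision: float, recall: float) -> float | None:
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """All scalar metrics derivable from a confusion matrix.

    Returns a dict with keys ``accuracy, precision, recall, f1, sensitivity,
    specificity``; undefined ratios are ``None``.
    """
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "precision": precision,
        "recall": recall,
        "f1": f1_from_precision_recall(precision, recall)
        if precision is not None and recall is not None
        else None,
        "sensitivity": recall,
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
    }


@dataclass
class RocResult:
    """ROC curve with trapezoidal AUC and Youden-J optimal operating point.

    ``orientation`` is +1 when larger scores indicate the positive class and
    -1 when the sweep direction was flipped so that AUC >= 0.5.
    """

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    optimal_cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    orientation: int = 1


def _roc_sweep(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold sweep over unique scores (descending); rule: score >= thr -> positive."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # indices of the last element of each tied block
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct].astype(float)
    fps = (distinct + 1) - tps
    p = labels.sum()
    n = labels.size - p
    tpr = np.r_[0.0, tps / p]
    fpr = np.r_[0.0, fps / n]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(scores, labels, auto_orient: bool = True) -> RocResult:
    """ROC points, trapezoidal AUC and the Youden-J optimal cut-off.

    Tied scores are grouped into a single sweep step, so ties contribute half
    a concordance each (the trapezoid crosses the tie block diagonally).  With
    ``auto_orient`` the score direction is flipped when AUC < 0.5 so that the
    reported AUC is >= 0.5 (useful for raw device parameters whose polarity is
    unknown); the cut-off is always reported on the original score scale.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present for ROC analysis")

    sign = 1
    fpr, tpr, thr = _roc_sweep(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    if auto_orient and auc < 0.5:
        sign = -1
        fpr, tpr, thr = _roc_sweep(-scores, labels)
        auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    i = int(np.argmax(j))
    # cut-off as the midpoint between the weakest accepted score and the next
    # distinct score below it (between the classes when they separate cleanly)
    d = thr[1:]  # distinct scores, descending (on the oriented scale)
    if i == 0:
        cutoff = d[0] + 1.0
    elif i < d.size:
        cutoff = 0.5 * (d[i - 1] + d[i])
    else:
        cutoff = d[-1] - 1.0
    if sign < 0:
        cutoff = -cutoff
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=sign * thr,
        optimal_cutoff=float(cutoff),
        youden_j=float(j[i]),
        sensitivity=float(tpr[i]),
        specificity=float(1.0 - fpr[i]),
        orientation=sign,
    )


@dataclass
class ClassifierReport:
    """Per-model, per-dataset evaluation record (one printed table row)."""

    model: str
    dataset: str
    cm: ConfusionMatrix
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None = None
    roc: RocResult | None = None

    @classmethod
    def from_confusion(
        cls,
        cm: ConfusionMatrix,
        model: str = "",
        dataset: str = "",
        roc: RocResult | None = None,
        auc: float | None = None,
    ) -> "ClassifierReport":
        m = confusion_metrics(cm)
        if roc is not None and auc is None:
            auc = roc.auc
        return cls(model=model, dataset=dataset, cm=cm, auc=auc, roc=roc, **m)

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "dataset": self.dataset,
            "confusion_matrix": self.cm.to_dict(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }
        if self.roc is not None:
            out["optimal_cutoff"] = self.roc.optimal_cutoff
            out["youden_j"] = self.roc.youden_j
        return out


def reconstruct_confusion(
    total: int,
    precision: float | None = None,
    recall: float | None = None,
    specificity: float | None = None,
    accuracy: float | None = None,
    f1: float | None = None,
    ndigits: int = 2,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices of size ``total`` matching rounded metrics.

    Exhaustively enumerates (TP, FP, TN, FN) compositions of ``total`` and keeps
    those whose metrics round (half-up, ``ndigits``) to the given values.  A
    metric whose denominator is zero for a candidate never matches.  An empty
    result flags the printed metrics as internally inconsistent.
    """
    if total < 1 or total > 10_000:
        raise ValueError("total must be in [1, 10000]")
    targets = {
        k: round_half_up(v, ndigits)
        for k, v in {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "accuracy": accuracy,
            "f1": f1,
        }.items()
        if v is not None
    }
    if not targets:
        raise ValueError("at least one target metric is required")

    out: list[ConfusionMatrix] = []
    for tp in range(total + 1):
        for fp in range(total + 1 - tp):
            for tn in range(total + 1 - tp - fp):
                fn = total - tp - fp - tn
                cm = ConfusionMatrix(tp, fp, tn, fn)
                m = confusion_metrics(cm)
                if all(
                    m[k] is not None and round_half_up(m[k], ndigits) == v
                    for k, v in targets.items()
                ):
                    out.append(cm)
    return out


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    p_value: float
    infinite: bool = False


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance (Student) two-sample t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, infinite=True)
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * _sstats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def chi_square_2x2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]] without continuity correction."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("all row/column marginals must be positive")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return Chi2Result(float(stat), 1, float(_sstats.chi2.sf(stat, 1)))
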