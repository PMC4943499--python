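"""Binary-classification metrics, ROC curves and AUC.

Metrics follow the usual confusion-table definitions: recall TP/(TP+FN),
precision TP/(TP+FP), accuracy (TP+TN)/total, F the harmonic mean of
precision and recall, and the Matthews correlation coefficient.  A metric
whose denominator is zero is reported as undefined with a reason rather
than coerced to 0.  ROC points sweep the unique score values with a strict
"score > threshold" positive rule, and AUC is the trapezoidal area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_points",
    "auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    rec: float | None
    pre: float | None
    acc: float
    f: float | None
    mcc: float | None
    undefined: dict[str, str] = field(default_factory=dict)
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "rec": self.rec, "pre": self.pre, "acc": self.acc,
            "f": self.f, "mcc": self.mcc, "auc": self.auc,
            "undefined": self.undefined,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Recall, precision, accuracy, F-measure and MCC from one table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    undefined: dict[str, str] = {}

    def ratio(num: int, den: int, name: str, reason: str) -> float | None:
        if den == 0:
            undefined[name] = reason
            return None
        return num / den

    rec = ratio(c.tp, c.tp + c.fn, "rec", "no positive samples (TP+FN=0)")
    pre = ratio(c.tp, c.tp + c.fp, "pre", "no positive predictions (TP+FP=0)")
    acc = (c.tp + c.tn) / c.total
    if rec is None or pre is None or pre + rec == 0:
        undefined["f"] = "precision+recall is zero or undefined"
        f = None
    else:
        f = 2 * pre * rec / (pre + rec)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        undefined["mcc"] = "a confusion-table margin is zero"
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(rec=rec, pre=pre, acc=acc, f=f, mcc=mcc,
                         undefined=undefined)


def roc_points(y_true, scores) -> list[tuple[float, float]]:
    """(FPR, TPR) points over all unique score thresholds.

    Positive prediction when score > threshold (strict, matching the vote
    tie-break).  The curve is anchored at (0,0) and (1,1) and is monotone
    non-decreasing in both coordinates.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"ROC undefined: no {missing} samples")
    # Descending unique thresholds; "> t" admits progressively more samples.
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_true = y_true[order]
    tps = np.cumsum(sorted_true == 1)
    fps = np.cumsum(sorted_true == 0)
    # Last index of each unique score value marks one threshold.
    last_of_value = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    points = [(0.0, 0.0)]
    for i in last_of_value:
        points.append((fps[i] / n_neg, tps[i] / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC curve sorted by FPR."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    if np.any(np.diff(fpr) < 0):
        raise ValueError("ROC points must be sorted by FPR")
    return float(np.trapezoid(tpr, fpr))
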