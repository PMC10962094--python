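"""Evaluation metrics for binary conserved-site classification.

Sensitivity, specificity, overall accuracy and the Matthews correlation
coefficient are evaluated exactly from integer confusion counts:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The ROC curve is traced over all distinct score thresholds (sensitivity
against 1-specificity) and integrated with the trapezoidal rule.  With
tied scores collapsed into single threshold steps, the trapezoidal area
equals the rank statistic: the fraction of positive-negative pairs whose
scores are correctly ordered, with 0.5 credit per tie.

Conventions fixed for reproducibility:

* a site is called positive when its score is >= the threshold
  (closed on the positive side);
* MCC is defined as 0 whenever any factor under the radical vanishes
  (the quotient is otherwise undefined);
* Sn/Sp are 0 when their denominator is 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Integer confusion counts at a fixed decision threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative confusion count: {name}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Sn/Sp/ACC/MCC/AUROC bundle with the ROC points that produced it."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auroc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "Sn": self.sn,
            "Sp": self.sp,
            "ACC": self.acc,
            "MCC": self.mcc,
            "AUROC": self.auroc,
            "roc_points": [[float(x), float(y)] for x, y in self.roc_points],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.ndim != 1 or y.ndim != 1 or s.shape[0] != y.shape[0]:
        raise ValueError(
            f"scores and labels must be equal-length 1-D sequences "
            f"(got {s.shape} vs {y.shape})"
        )
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return s, y


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tally confusion counts; positive call iff score >= threshold."""
    s, y = _check_scores_labels(scores, labels)
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, ACC and MCC from confusion counts.

    Raises on an all-zero tally; any zero factor under the MCC radical
    yields MCC = 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"Sn": sn, "Sp": sp, "ACC": acc, "MCC": mcc}


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUROC by trapezoidal integration over all score thresholds.

    Returns ``(auroc, roc_points)`` where the points are
    (1-specificity, sensitivity) pairs starting at (0, 0), one step per
    distinct score value.  Requires both classes to be present.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices of the last occurrence of each distinct score value
    boundary = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[boundary]
    fps = boundary + 1 - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full evaluation report: thresholded metrics plus the ROC curve."""
    counts = confusion(scores, labels, threshold=threshold)
    m = metrics(counts)
    auc, points = roc_auc(scores, labels)
    return EvalReport(
        sn=m["Sn"], sp=m["Sp"], acc=m["ACC"], mcc=m["MCC"],
        auroc=auc, roc_points=points,
    )
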