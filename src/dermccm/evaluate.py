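"""Classification metrics: sensitivity, specificity, accuracy, PPV and
ROC/AUC by threshold variation, for the 7-way multilabel pattern task and
the binary BCC / non-BCC diagnosis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .palette import PATTERN_CLASSES

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "confusion",
    "metrics_from_counts",
    "roc_auc",
    "multilabel_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has an empty denominator (e.g. specificity with
    no negative cases). Raised instead of silently returning 0, which
    would corrupt macro averages over rare patterns."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: Sequence[bool], y_pred: Sequence[bool]) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape or t.size == 0:
        raise ValueError(f"need equal-length non-empty vectors, got {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
    )


def _ratio(num, den, name):
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined (empty denominator)")
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """sens = tp/(tp+fn), spec = tn/(tn+fp), acc = (tp+tn)/total,
    ppv = tp/(tp+fp)."""
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "ppv": _ratio(c.tp, c.tp + c.fp, "ppv"),
    }


def roc_auc(scores: Sequence[float], y_true: Sequence[bool]) -> dict:
    """Empirical ROC by sweeping the threshold over the unique scores (equal
    scores grouped) and trapezoidal AUC; equivalent to the Mann-Whitney
    statistic with ties counted 1/2."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present in y_true")
    fpr, tpr, _ = _roc_curve(y, s)
    return {"auc": float(_auc(fpr, tpr)), "roc": list(zip(fpr.tolist(), tpr.tolist()))}


def multilabel_report(
    prob_table: np.ndarray,
    label_table: np.ndarray,
    thresholds=None,
) -> dict:
    """Per-pattern sensitivity/specificity/accuracy/PPV/AUC plus unweighted
    macro averages.

    ``prob_table``: (N, 7) scores; ``label_table``: (N, 7) binary truth;
    ``thresholds``: pattern -> threshold map (default 0.5 each).
    """
    P = np.asarray(prob_table, dtype=float)
    Y = np.asarray(label_table) > 0.5
    if P.shape != Y.shape or P.shape[1] != len(PATTERN_CLASSES):
        raise ValueError(f"need aligned (N, 7) tables, got {P.shape} vs {Y.shape}")
    thresholds = thresholds or {k: 0.5 for k in PATTERN_CLASSES}
    per = {}
    for k, pattern in enumerate(PATTERN_CLASSES):
        pred = P[:, k] >= thresholds[pattern]
        c = confusion(Y[:, k], pred)
        row = {}
        for name in ("sensitivity", "specificity", "accuracy", "ppv"):
            try:
                row[name] = metrics_from_counts(c)[name]
            except UndefinedMetricError:
                row[name] = None
        try:
            row["auc"] = roc_auc(P[:, k], Y[:, k])["auc"]
        except ValueError:
            row["auc"] = None
        per[pattern] = row
    macro = {}
    for name in ("sensitivity", "specificity", "accuracy", "ppv", "auc"):
        vals = [per[p][name] for p in PATTERN_CLASSES if per[p][name] is not None]
        macro[name] = float(np.mean(vals)) if vals else None
    return {"per_pattern": per, "macro": macro}
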