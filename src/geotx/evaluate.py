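"""Evaluation metrics for site-level classifiers.

AUC is the rank statistic under the ROC curve; AP is the step-weighted mean
of precision over thresholds with the recall increments as weights, which
does not reward true negatives and is therefore the metric of choice for
the 1:10 imbalanced test settings.  Accuracy, F1 and MCC are thresholded at
0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MetricReport", "evaluate", "average_precision_stepwise"]


@dataclass
class MetricReport:
    accuracy: float
    f1: float
    mcc: float
    auc: float
    ap: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1, "mcc": self.mcc,
                "auc": self.auc, "ap": self.ap}

    @staticmethod
    def aggregate(reports: Sequence["MetricReport"]) -> dict:
        """Per-metric mean and standard deviation across folds."""
        keys = ("accuracy", "f1", "mcc", "auc", "ap")
        out = {}
        for k in keys:
            vals = np.array([getattr(r, k) for r in reports], dtype=np.float64)
            out[k] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out


def average_precision_stepwise(labels: np.ndarray, scores: np.ndarray) -> float:
    """AP = sum_k (R_k - R_{k-1}) * P_k over descending score thresholds.

    Reference implementation written out from the definition; used as the
    independent check against the library AP in the test suite.
    """
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(labels, dtype=np.float64)[order]
    tp = np.cumsum(y)
    n_pos = y.sum()
    if n_pos == 0:
        return float("nan")
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / n_pos
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(precision, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate(scores: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> MetricReport:
    """Accuracy/F1/MCC at the threshold plus AUC and AP.

    AUC and AP are reported as NaN (missing) when only one class is present.
    """
    from sklearn.metrics import (
        accuracy_score, average_precision_score, f1_score,
        matthews_corrcoef, roc_auc_score,
    )

    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).reshape(-1).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = (scores >= threshold).astype(int)
    acc = float(accuracy_score(labels, pred))
    f1 = float(f1_score(labels, pred, zero_division=0))
    mcc = float(matthews_corrcoef(labels, pred))
    if len(np.unique(labels)) < 2:
        auc = ap = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
        ap = float(average_precision_score(labels, scores))
    return MetricReport(accuracy=acc, f1=f1, mcc=mcc, auc=auc, ap=ap)
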