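"""Confusion-matrix metrics, ROC and AUC, with abnormal as the positive class."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .trace_model import ABNORMAL, NORMAL


@dataclass
class EvaluationReport:
    """Binary classification metrics against expert truth.

    ``accuracy``, ``sensitivity`` (true-abnormal rate) and ``specificity``
    (true-normal rate) are percentages; ROC points and AUC are present only
    when decision scores were supplied and both classes occur in the truth.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: Optional[np.ndarray] = None
    roc_tpr: Optional[np.ndarray] = None
    auc: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "auc": self.auc,
        }

    def to_json(self) -> str:
        def _clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v
        return json.dumps({k: _clean(v) for k, v in self.as_dict().items()},
                          indent=2)

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}  (TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn})",
            f"accuracy    {self.accuracy:5.1f} %",
            f"sensitivity {self.sensitivity:5.1f} %",
            f"specificity {self.specificity:5.1f} %",
        ]
        if self.auc is not None:
            lines.append(f"AUC         {self.auc:6.3f}")
        return "\n".join(lines)


def _to_binary(values) -> np.ndarray:
    """Map labels (strings or 0/1) to 1=abnormal, 0=normal."""
    arr = np.asarray(values)
    if arr.dtype.kind in "ifb":
        out = arr.astype(int)
        if not np.isin(out, (0, 1)).all():
            raise ValueError("numeric labels must be 0 (normal) or 1 (abnormal)")
        return out
    out = np.empty(arr.shape, dtype=int)
    for i, v in enumerate(arr.ravel()):
        s = str(v).strip().lower()
        if s == ABNORMAL:
            out.ravel()[i] = 1
        elif s == NORMAL:
            out.ravel()[i] = 0
        else:
            raise ValueError(f"unknown label {v!r}")
    return out


def _align(predictions, truth, scores):
    """Align by index when pandas Series are given; error on key mismatch."""
    if isinstance(predictions, pd.Series) and isinstance(truth, pd.Series):
        if set(predictions.index) != set(truth.index):
            raise ValueError("prediction and truth keys do not match")
        truth = truth.loc[predictions.index]
        if isinstance(scores, pd.Series):
            if set(scores.index) != set(predictions.index):
                raise ValueError("score keys do not match predictions")
            scores = scores.loc[predictions.index]
    pred = _to_binary(predictions)
    true = _to_binary(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth differ in length")
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != pred.shape:
            raise ValueError("scores and predictions differ in length")
    return pred, true, scores


def evaluate(
    predictions: Union[Sequence, pd.Series],
    truth: Union[Sequence, pd.Series],
    scores: Optional[Union[Sequence, pd.Series]] = None,
) -> EvaluationReport:
    """Compute confusion counts, accuracy/sensitivity/specificity and,
    when ``scores`` are given, the ROC curve and trapezoidal AUC.

    The AUC equals the probability that a randomly chosen abnormal instance
    receives a higher score than a randomly chosen normal one (ties counted
    half).  With single-class truth the ROC/AUC are reported as missing.
    """
    pred, true, scores = _align(predictions, truth, scores)
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("cannot evaluate an empty prediction set")

    accuracy = 100.0 * (tp + tn) / n
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")

    roc_fpr = roc_tpr = auc = None
    if scores is not None and 0 < true.sum() < n:
        roc_fpr, roc_tpr, _ = roc_curve(true, scores, drop_intermediate=False)
        auc = float(np.trapezoid(roc_tpr, roc_fpr))

    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        roc_fpr=roc_fpr, roc_tpr=roc_tpr, auc=auc,
    )


def roc_points_frame(report: EvaluationReport) -> pd.DataFrame:
    if report.roc_fpr is None:
        raise ValueError("report carries no ROC curve")
    return pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr})


def plot_roc(report: EvaluationReport, path, title: str = "ROC") -> None:
    """Save the ROC curve to PNG."""
    if report.roc_fpr is None:
        raise ValueError("report carries no ROC curve")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(report.roc_fpr, report.roc_tpr, color="tab:blue",
            label=f"AUC = {report.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
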