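"""Classification metrics (AC, SE, SP, G-mean, AUC) and the two
cost-sensitive fitness functions.

The positive class is fracture (the minority).  All arithmetic is on the
fraction scale in [0, 1]; percentage formatting belongs to the report layer.

The two objectives maximised by the wrapper are

* ``OB1 = AC - |SE - SP|`` — accuracy penalised by the sensitivity–
  specificity gap, pushing models toward SE ≈ SP on balanced data;
* ``OB2 = AUC`` — the area under the ROC curve of the continuous decision
  values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

OBJECTIVES = ("OB1", "OB2")


@dataclass(frozen=True)
class MetricSet:
    """Metrics of one model on one dataset, with the confusion counts."""

    ac: float
    se: float
    sp: float
    gmean: float
    auc: float | None
    counts: tuple[int, int, int, int]  # (TP, FN, TN, FP)

    def as_dict(self) -> dict[str, float | None]:
        return {"AC": self.ac, "SE": self.se, "SP": self.sp,
                "Gmean": self.gmean, "AUC": self.auc}


def g_mean(se: float, sp: float) -> float:
    """Geometric mean sqrt(SE * SP) of sensitivity and specificity."""
    if se < 0 or sp < 0:
        raise ValueError("sensitivity and specificity must be non-negative")
    return math.sqrt(se * sp)


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    bad = np.setdiff1d(np.unique(arr), [0, 1])
    if bad.size:
        raise ValueError(f"{name} must be binary 0/1; found {bad.tolist()}")
    return arr.astype(np.int64)


def confusion_metrics(labels, predictions, scores=None) -> MetricSet:
    """Compute AC/SE/SP/G-mean (and AUC when ``scores`` given) from binary
    labels and predictions.

    SE requires at least one positive label and SP at least one negative;
    a single-class label vector is an error, not a silent zero.
    """
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if y.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y == 1) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    if tp + fn == 0:
        raise ValueError("no positive labels: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative labels: specificity undefined")
    ac = (tp + tn) / y.size
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    auc = auc_score(y, scores) if scores is not None else None
    return MetricSet(ac=ac, se=se, sp=sp, gmean=g_mean(se, sp), auc=auc,
                     counts=(tp, fn, tn, fp))


def auc_score(labels, scores) -> float:
    """Area under the ROC curve of continuous scores.

    Equals the probability that a random positive outscores a random
    negative, ties counted 1/2 (the rank / Mann-Whitney statistic).
    """
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if y.min() == y.max():
        raise ValueError("both classes must be present for AUC")
    return float(roc_auc_score(y, s))


def objective_value(metrics: MetricSet, objective: str) -> float:
    """Value of a fitness function on a MetricSet; higher is better."""
    name = objective.upper()
    if name == "OB1":
        return metrics.ac - abs(metrics.se - metrics.sp)
    if name == "OB2":
        if metrics.auc is None:
            raise ValueError("OB2 requires an AUC; pass decision scores")
        return metrics.auc
    raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
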