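"""Confusion-matrix metrics and rank-based AUC for toxicity classifiers.

The report carries the eight headline metrics in the conventional order
ACC, SE, SP, MCC, P, F1, BA, AUC.  Any metric whose denominator is zero is
reported as 0 and listed under ``flags`` instead of propagating NaN, so
summary tables over many models never break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "compute_metrics", "rank_auc", "METRIC_ORDER"]

METRIC_ORDER = ("ACC", "SE", "SP", "MCC", "P", "F1", "BA", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    ACC: float
    SE: float
    SP: float
    MCC: float
    P: float
    F1: float
    BA: float
    AUC: float | None = None
    flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_ORDER}
        return d


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count the confusion matrix with class 1 as positive."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1D arrays")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def rank_auc(y_true, scores) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outranks a random negative,
    with ties counted half.
    """
    yt = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)  # average ranks handle ties
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def compute_metrics(c: ConfusionCounts, y_true=None, scores=None) -> MetricsReport:
    """The eight-metric report from confusion counts (plus scores for AUC).

    ACC=(TP+TN)/N, SE=TP/(TP+FN), SP=TN/(TN+FP), P=TP/(TP+FP),
    F1=2*P*SE/(P+SE), BA=(SE+SP)/2, and
    MCC=(TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Zero denominators yield 0 and a flag.  AUC is computed from ``scores``
    against ``y_true`` when both are given, else omitted (None).
    """
    if c.total < 1:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (c.TP + c.TN) / c.total
    se = ratio(c.TP, c.TP + c.FN, "SE")
    sp = ratio(c.TN, c.TN + c.FP, "SP")
    p = ratio(c.TP, c.TP + c.FP, "P")
    f1 = ratio(2 * p * se, p + se, "F1")
    ba = (se + sp) / 2
    mcc_den = np.sqrt(float(c.TP + c.FP) * (c.TP + c.FN)
                      * (c.TN + c.FP) * (c.TN + c.FN))
    if mcc_den == 0:
        flags.append("MCC")
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / mcc_den
    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true alongside scores")
        auc = rank_auc(y_true, scores)
    return MetricsReport(ACC=acc, SE=se, SP=sp, MCC=mcc, P=p, F1=f1, BA=ba,
                         AUC=auc, flags=tuple(flags))
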