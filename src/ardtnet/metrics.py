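"""Binary-classification evaluation: confusion counts at a threshold,
sensitivity/specificity/accuracy, trapezoidal ROC AUC and average precision."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N, plus ranking
    metrics. A metric whose denominator is empty is ``None`` (undefined),
    never silently zero."""

    se: float | None
    sp: float | None
    acc: float | None
    auc: float | None
    ap: float | None

    def to_dict(self) -> dict:
        def enc(v):
            return "undefined" if v is None else float(v)
        return {"SE": enc(self.se), "SP": enc(self.sp), "ACC": enc(self.acc),
                "AUC": enc(self.auc), "AP": enc(self.ap)}


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError(f"scores and labels length mismatch: {scores.shape} vs {labels.shape}")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Counts from thresholding scores; ties at the threshold are positive."""
    scores, labels = _check(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)), fn=int(np.sum(~pred & pos)))


def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve by trapezoidal integration over all
    score thresholds."""
    scores, labels = _check(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative TP/FP after each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def average_precision(scores, labels) -> float:
    """Area under the precision-recall step curve:
    AP = sum_n (R_n - R_{n-1}) * P_n over descending score thresholds."""
    scores, labels = _check(scores, labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("AP undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y == 1)[distinct].astype(float)
    ranks = (distinct + 1).astype(float)
    precision = tps / ranks
    recall = tps / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def metrics(counts: ConfusionCounts, scores=None, labels=None) -> MetricsReport:
    """Full report from confusion counts plus (optionally) ranking metrics
    from the raw scores."""
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    acc = (counts.tp + counts.tn) / counts.total if counts.total else None
    auc = ap = None
    if scores is not None and labels is not None:
        try:
            auc = roc_auc(scores, labels)
        except ValueError:
            auc = None
        try:
            ap = average_precision(scores, labels)
        except ValueError:
            ap = None
    return MetricsReport(se=se, sp=sp, acc=acc, auc=auc, ap=ap)
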