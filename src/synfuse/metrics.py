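"""The nine-metric evaluation suite for binary synergy prediction:
ACC, BACC, Prec, Rec, F1, ROC-AUC, MCC, Cohen's kappa and average
precision, plus the confusion counts behind them.

Conventions for degenerate folds (which leave-one-entity-out splitting can
produce): precision, recall and F1 fall back to 0 when their denominator is
0; MCC falls back to 0 when any factor under its root is 0. ROC-AUC is the
Mann-Whitney pair statistic (ties count 1/2), which is exact and
tie-robust; average precision is the uninterpolated step sum
sum_n (R_n - R_{n-1}) P_n over descending-score thresholds.

Kappa uses chance agreement P_e = (a_1 b_1 + a_0 b_0) / n^2 from the actual
and predicted class counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

METRIC_ORDER = ["ACC", "BACC", "Prec", "Rec", "F1", "ROC_AUC", "MCC", "Kappa", "AP"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    ACC: float
    BACC: float
    Prec: float
    Rec: float
    F1: float
    ROC_AUC: float
    MCC: float
    Kappa: float
    AP: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_ORDER}
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def table(self) -> str:
        """Fixed-order one-row table (benchmark-table column order)."""
        header = "  ".join(f"{k:>8s}" for k in METRIC_ORDER)
        values = "  ".join(f"{getattr(self, k):8.4f}" for k in METRIC_ORDER)
        return header + "\n" + values


def _check_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-d array")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(np.int64)


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = _check_binary(y_true, "y_true")
    p = _check_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float, fallback: float = 0.0) -> float:
    return num / den if den != 0 else fallback


def threshold_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The seven confusion-derived metrics (all but ROC-AUC and AP)."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    n = c.n
    if n < 1:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / n
    prec = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    tpr = _safe_div(tp, tp + fn)
    tnr = _safe_div(tn, tn + fp)
    bacc = 0.5 * (tpr + tnr)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, np.sqrt(mcc_den)) if mcc_den > 0 else 0.0
    # chance agreement from actual (a) and predicted (b) class counts
    a1, a0 = tp + fn, tn + fp
    b1, b0 = tp + fp, tn + fn
    p_o = acc
    p_e = (a1 * b1 + a0 * b0) / (n * n)
    kappa = _safe_div(p_o - p_e, 1.0 - p_e)
    return {"ACC": acc, "BACC": bacc, "Prec": prec, "Rec": rec, "F1": f1,
            "MCC": float(mcc), "Kappa": kappa}


def roc_auc(y_true, probs) -> float:
    """Probability that a random positive outscores a random negative
    (Mann-Whitney U / n_pos n_neg), ties counted one half."""
    t = _check_binary(y_true, "y_true")
    s = np.asarray(probs, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC is undefined with a single class")
    # midranks handle ties exactly
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(t.size, dtype=np.float64)
    sorted_s = s[order]
    i = 0
    while i < t.size:
        j = i
        while j + 1 < t.size and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_precision(y_true, probs) -> float:
    """Uninterpolated AP: sum over descending-score cutoffs of
    (recall step) x (precision at the cutoff); ties enter as one block."""
    t = _check_binary(y_true, "y_true")
    s = np.asarray(probs, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined without positives")
    order = np.argsort(-s, kind="mergesort")
    t_sorted = t[order]
    s_sorted = s[order]
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    while i < t.size:
        j = i
        while j + 1 < t.size and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        block_pos = int(t_sorted[i : j + 1].sum())
        prev_recall = tp / n_pos
        tp += block_pos
        seen = j + 1
        precision = tp / seen
        ap += (tp / n_pos - prev_recall) * precision
        i = j + 1
    return float(ap)


def evaluate_predictions(y_true, probs, threshold: float = 0.5) -> MetricReport:
    """Full nine-metric report from labels and predicted probabilities."""
    from .losses import binarize

    t = _check_binary(y_true, "y_true")
    y_pred = binarize(probs, threshold)
    c = confusion(t, y_pred)
    m = threshold_metrics(c)
    return MetricReport(
        ACC=m["ACC"], BACC=m["BACC"], Prec=m["Prec"], Rec=m["Rec"], F1=m["F1"],
        ROC_AUC=roc_auc(t, probs), MCC=m["MCC"], Kappa=m["Kappa"],
        AP=average_precision(t, probs), counts=c,
    )
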