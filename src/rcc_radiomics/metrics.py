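"""Evaluation statistics: confusion matrices, per-class metrics, ROC/AUC,
and the DeLong test for correlated AUCs.

Confusion matrix orientation is rows = predicted class, columns =
pathology (true) class, class order (ccRCC, pRCC, cRCC).  Per-class
sensitivity/specificity/precision/NPV/f1 and overall accuracy follow the
usual one-vs-rest reductions of the 3x3 matrix.  AUC is the Mann-Whitney
pair statistic (ties counted 1/2); the DeLong test uses the structural
placement-value covariance estimate for paired ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

CLASS_ORDER = ("ccRCC", "pRCC", "cRCC")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (display rule)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_matrix(predicted, pathology, classes=CLASS_ORDER) -> pd.DataFrame:
    """Counts[i, j] = #(predicted == classes[i] and pathology == classes[j])."""
    predicted = np.asarray(predicted)
    pathology = np.asarray(pathology)
    if predicted.shape != pathology.shape:
        raise ValueError("label vectors differ in length")
    unknown = set(predicted) | set(pathology)
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(map(str, unknown))}")
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for p, t in zip(predicted, pathology):
        cm[index[p], index[t]] += 1
    return pd.DataFrame(cm, index=list(classes), columns=list(classes))


def per_class_metrics(cm: pd.DataFrame | np.ndarray, classes=CLASS_ORDER) -> pd.DataFrame:
    """Per-class sensitivity/specificity/precision/NPV/f1 + accuracy.

    Returns a DataFrame indexed by class with an ``accuracy`` attribute
    column repeated on each row (trace / total).  Zero-denominator cells
    are reported as NaN.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    accuracy = np.trace(cm) / total
    for i, c in enumerate(classes):
        tp = cm[i, i]
        col = cm[:, i].sum()          # pathology-positive
        row = cm[i, :].sum()          # predicted-positive
        fn = col - tp
        fp = row - tp
        tn = total - col - fp
        sens = tp / col if col > 0 else np.nan
        spec = tn / (total - col) if total - col > 0 else np.nan
        prec = tp / row if row > 0 else np.nan
        npv = tn / (tn + fn) if tn + fn > 0 else np.nan
        f1 = (
            2 * prec * sens / (prec + sens)
            if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
            else np.nan
        )
        rows[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "npv": npv,
            "f1": f1,
            "accuracy": accuracy,
        }
    return pd.DataFrame(rows).T


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class ROCComparison:
    """Paired AUC comparison of two models on the same subjects."""

    auc_a: float
    auc_b: float
    z: float
    p: float
    se_diff: float
    degenerate: bool = False


def _placements(scores, pos):
    """DeLong structural components V10 (per positive), V01 (per negative)."""
    x = scores[pos]
    y = scores[~pos]
    # psi(x, y) = 1 if x > y, 1/2 if equal
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (
        x[:, None] == y[None, :]
    )
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_test(scores_a, scores_b, labels) -> ROCComparison:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same subjects with the
    same binary labels.  A zero-variance difference (e.g. identical
    scores) yields p = 1.0 with the ``degenerate`` flag set.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores and labels must share one shape")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10_a, v01_a = _placements(scores_a, pos)
    v10_b, v01_b = _placements(scores_b, pos)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())

    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        return ROCComparison(auc_a=auc_a, auc_b=auc_b, z=0.0, p=1.0,
                             se_diff=0.0, degenerate=True)
    se = float(np.sqrt(var))
    z = (auc_a - auc_b) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return ROCComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p=p, se_diff=se)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR pairs at every score threshold (for CSV export)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    tps = np.cumsum(l)
    fps = np.cumsum(1 - l)
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = tps[distinct] / max(l.sum(), 1)
    fpr = fps[distinct] / max((1 - l).sum(), 1)
    return pd.DataFrame({"threshold": s[distinct], "fpr": fpr, "tpr": tpr})
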