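"""Ranking metrics for causal-SNP recovery (imbalanced binary classification).

Stability-selection frequencies are treated as scores for the binary label
"causal"; with ~15 positives among ~2000 SNPs the precision-recall curve is
the informative summary (the ROC curve is dominated by the huge
true-negative count).  Curves are evaluated only at distinct score values
(ties share a threshold), and PR-AUC is the trapezoid over the achievable
curve with the recall = 0 endpoint carried at the first point's precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankingEvaluation",
    "confusion_at_threshold",
    "pr_curve",
    "pr_auc",
    "roc_auc",
    "evaluate_grid",
]


@dataclass
class RankingEvaluation:
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    pr_auc: float
    roc_auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "precision": self.precision,
                "recall": self.recall,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return labels


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, t: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with 'predicted positive' meaning score >= t."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    labels = _check_labels(labels)
    pred = scores >= t
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return tp, fp, tn, fn


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> RankingEvaluation:
    """Confusion quantities, PR and ROC points at every distinct score."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    thresholds = np.unique(scores)[::-1]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    # cumulative counts over thresholds, descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(~sorted_labels)
    # index of the last element with score >= t for each distinct threshold
    last = len(scores) - 1 - np.searchsorted(sorted_scores[::-1], thresholds, side="left")
    tp = cum_tp[last]
    fp = cum_fp[last]
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    recall = tp / n_pos
    sensitivity = recall
    specificity = tn / n_neg
    ev = RankingEvaluation(
        thresholds=thresholds,
        tp=tp.astype(int),
        fp=fp.astype(int),
        tn=tn.astype(int),
        fn=fn.astype(int),
        precision=precision,
        recall=recall,
        sensitivity=sensitivity,
        specificity=specificity,
        pr_auc=0.0,
        roc_auc=0.0,
    )
    ev.pr_auc = pr_auc(ev)
    fpr = 1.0 - specificity
    ev.roc_auc = float(np.trapezoid(np.r_[0.0, sensitivity, 1.0], np.r_[0.0, fpr, 1.0]))
    return ev


def pr_auc(curve: RankingEvaluation) -> float:
    """Trapezoidal area under the achievable PR points.

    The curve is anchored at (recall=0, precision of the highest-score
    point); no average-precision style interpolation is applied.
    """
    order = np.argsort(curve.recall, kind="stable")
    rec = curve.recall[order]
    prec = curve.precision[order]
    rec = np.r_[0.0, rec]
    prec = np.r_[prec[0], prec]
    return float(np.trapezoid(prec, rec))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    return pr_curve(scores, labels).roc_auc


def evaluate_grid(results: list[dict]) -> pd.DataFrame:
    """Aggregate per-dataset PR-AUCs into a (sigma_sig, sigma_pop, method) table.

    ``results`` rows need keys sigma_sig, sigma_pop, method and either
    'pr_auc' or ('scores', 'labels') to compute it.  Returns a long-format
    table with per-cell mean/sd and n; a singleton cell reports sd = NaN.
    """
    rows = []
    for r in results:
        auc = r["pr_auc"] if "pr_auc" in r else pr_curve(r["scores"], r["labels"]).pr_auc
        rows.append(
            {
                "sigma_sig": r["sigma_sig"],
                "sigma_pop": r["sigma_pop"],
                "method": r.get("method", "sgl-lmm"),
                "pr_auc": auc,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["method", "sigma_sig", "sigma_pop"])["pr_auc"]
        .agg(mean_pr_auc="mean", sd_pr_auc="std", n="count")
        .reset_index()
    )
    return out
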