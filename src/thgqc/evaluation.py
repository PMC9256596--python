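"""Threshold-free and threshold-calibrated classifier evaluation.

ROC and precision-recall curves are swept over the unique score values
(plus the two degenerate endpoints), with the decision rule fixed as
"score >= threshold -> positive". The operating point is calibrated with
Youden's J statistic (J = sensitivity + specificity - 1 = TPR - FPR),
maximized over the ROC thresholds with ties broken toward the lowest
qualifying threshold. Ensembles of models trained on different
Monte-Carlo splits are summarized by vertical curve averaging on a common
abscissa grid; the ensemble scalar (AUC or AP) is the mean of the member
scalars, not the area of the mean curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class UndefinedMetricError(ValueError):
    """Raised when a curve requires a class that is absent."""


@dataclass
class ScoredSet:
    """Scores in [0,1] with binary labels (1 = tumor) and optional ids."""

    scores: np.ndarray
    labels: np.ndarray
    image_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class RocResult:
    """ROC points in threshold order (descending threshold) plus AUC."""

    thresholds: np.ndarray  # descending; +inf first
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class PrResult:
    """Precision-recall points in threshold order plus average precision."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    average_precision: float


@dataclass
class MetricsSummary:
    """Confusion-matrix metrics at one decision threshold."""

    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class CurveBundle:
    """Vertically averaged ensemble of curves on a common abscissa grid."""

    grid: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    member_curves: list[tuple[np.ndarray, np.ndarray]]
    mean_scalar: float  # mean of member AUC/AP values


def _counts_at_thresholds(scored: ScoredSet
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For descending unique thresholds: cumulative (thresholds, TP, FP).

    Tied scores enter simultaneously; an implicit +inf threshold
    contributes the (0, 0) point.
    """
    order = np.argsort(-scored.scores, kind="stable")
    scores = scored.scores[order]
    labels = scored.labels[order]
    uniq_mask = np.r_[np.diff(scores) != 0, True]
    tp = np.cumsum(labels)[uniq_mask]
    fp = np.cumsum(1 - labels)[uniq_mask]
    thresholds = scores[uniq_mask]
    return (np.r_[np.inf, thresholds],
            np.r_[0, tp].astype(float),
            np.r_[0, fp].astype(float))


def roc_auc(scored: ScoredSet) -> RocResult:
    """ROC curve and trapezoidal AUC over the unique-score threshold sweep."""
    p, n = scored.n_positive, scored.n_negative
    if p == 0 or n == 0:
        raise UndefinedMetricError(
            "ROC needs both classes present in the labels"
        )
    thr, tp, fp = _counts_at_thresholds(scored)
    tpr = tp / p
    fpr = fp / n
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def pr_ap(scored: ScoredSet) -> PrResult:
    """Precision-recall curve and step-interpolated average precision.

    AP = sum_k (R_k - R_{k-1}) * P_k over the descending-threshold sweep;
    its no-skill baseline equals the positive-class prevalence.
    """
    p = scored.n_positive
    if p == 0:
        raise UndefinedMetricError("average precision needs >= 1 positive")
    thr, tp, fp = _counts_at_thresholds(scored)
    # drop the +inf point where precision is undefined (0/0)
    tp, fp, thr = tp[1:], fp[1:], thr[1:]
    recall = tp / p
    precision = tp / np.maximum(tp + fp, 1)
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PrResult(thresholds=thr, recall=recall, precision=precision,
                    average_precision=ap)


def no_skill_ap(n_positive: int, n_total: int) -> float:
    """The prevalence baseline of average precision."""
    return n_positive / n_total


def youden_threshold(roc: RocResult) -> float:
    """Threshold maximizing J = TPR - FPR; lowest qualifying on ties.

    The +inf endpoint is not a usable operating point; if the maximum J is
    0 (uninformative or anti-correlated ranking) the lowest finite
    candidate is returned with a warning.
    """
    j = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    j_max = j[finite].max()
    candidates = roc.thresholds[finite & (j == j_max)]
    if j_max <= 0:
        warnings.warn(
            "Youden's J is non-positive at every threshold; the score "
            "ranking carries no (or inverted) class signal",
            stacklevel=2,
        )
    return float(candidates.min())


def metrics_at_threshold(scored: ScoredSet, threshold: float
                         ) -> MetricsSummary:
    """Accuracy/sensitivity/specificity with score >= threshold -> positive."""
    pred = scored.scores >= threshold
    pos = scored.labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    n = len(scored.labels)
    return MetricsSummary(
        threshold=float(threshold),
        accuracy=(tp + tn) / n if n else float("nan"),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def aggregate_curves(curves: Sequence[tuple[np.ndarray, np.ndarray]],
                     scalars: Sequence[float],
                     grid_size: int = 101,
                     variance_ddof: int = 0) -> CurveBundle:
    """Vertical averaging of member curves onto a common abscissa grid.

    Each member (x, y) curve is linearly interpolated onto ``grid_size``
    evenly spaced abscissa points; the bundle reports pointwise mean and
    (by default population-) variance, plus the mean of the member scalar
    summaries.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 member curves to aggregate")
    if len(scalars) != len(curves):
        raise ValueError("one scalar summary per member curve required")
    grid = np.linspace(0.0, 1.0, grid_size)
    stack = []
    members = []
    for x, y in curves:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        order = np.argsort(x, kind="stable")
        xi, yi = x[order], y[order]
        stack.append(np.interp(grid, xi, yi))
        members.append((x, y))
    stack = np.array(stack)
    return CurveBundle(
        grid=grid,
        mean=stack.mean(axis=0),
        variance=stack.var(axis=0, ddof=variance_ddof),
        member_curves=members,
        mean_scalar=float(np.mean(scalars)),
    )


def evaluate_ensemble(scored_sets: Sequence[ScoredSet],
                      threshold_mode: str = "youden-test"
                      ) -> dict:
    """Per-model Youden-calibrated metrics plus ensemble curve bundles.

    ``threshold_mode`` "youden-test" derives each model's threshold from
    its own test-set ROC (mirroring how the reference results were
    produced — optimistic, since the operating point sees the test
    labels); "fixed-0.5" uses the raw 0.5 cut as the deployment-honest
    alternative.
    """
    per_model = []
    roc_curves, prc_curves = [], []
    aucs, aps = [], []
    for scored in scored_sets:
        roc = roc_auc(scored)
        prc = pr_ap(scored)
        if threshold_mode == "youden-test":
            thr = youden_threshold(roc)
        elif threshold_mode == "fixed-0.5":
            thr = 0.5
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        summary = metrics_at_threshold(scored, thr)
        per_model.append({
            "auc": roc.auc,
            "average_precision": prc.average_precision,
            "youden_threshold": thr,
            "accuracy": summary.accuracy,
            "sensitivity": summary.sensitivity,
            "specificity": summary.specificity,
        })
        roc_curves.append((roc.fpr, roc.tpr))
        prc_curves.append((prc.recall, prc.precision))
        aucs.append(roc.auc)
        aps.append(prc.average_precision)
    out = {"per_model": per_model, "threshold_mode": threshold_mode}
    keys = ("auc", "average_precision", "accuracy", "sensitivity",
            "specificity", "youden_threshold")
    out["mean"] = {k: float(np.mean([m[k] for m in per_model])) for k in keys}
    out["std"] = {k: float(np.std([m[k] for m in per_model])) for k in keys}
    if len(scored_sets) >= 2:
        out["roc_bundle"] = aggregate_curves(roc_curves, aucs)
        out["pr_bundle"] = aggregate_curves(prc_curves, aps)
    return out
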