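"""Thresholded classification metrics, AUPRC, reliability diagrams and ECE.

Conventions fixed here and used everywhere else in the package:

* classification rule: ``score >= threshold`` predicts the positive class,
  applied to every threshold, not just the default 0.5;
* metrics whose defining denominator is zero are the NA sentinel
  (``float("nan")``), rendered as the literal token ``NA`` in reports;
* AUPRC is step-wise average precision (no interpolation), a pure rank
  statistic that is exactly invariant under strictly increasing score maps;
* reliability bins are ``((z-1)/Z, z/Z]`` for ``z = 1..Z`` with score 0
  assigned to bin 1; empty bins contribute zero weight to ECE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .exceptions import DegenerateLabelsError

#: NA sentinel for undefined metrics (zero denominator).
NA = float("nan")


def is_na(value: float) -> bool:
    """True if ``value`` is the NA sentinel."""
    return isinstance(value, float) and math.isnan(value)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts at a threshold under the ``>=`` rule."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Eqs-style summary metrics at one threshold, optionally with AUPRC and CIs."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    mcc: float
    counts: ConfusionCounts
    auprc: float | None = None
    ci: dict = field(default_factory=dict)


@dataclass
class ReliabilityTable:
    """Per-bin reliability diagram data and the resulting ECE."""

    n_bins: int
    edges: np.ndarray
    counts: np.ndarray
    mean_pred: np.ndarray  # mean predicted probability (or confidence) per bin
    accuracy: np.ndarray  # empirical positive fraction (or correctness) per bin
    mode: str
    ece: float
    m: int


@dataclass
class ThresholdResult:
    """PR-curve sweep with the F-maximizing threshold."""

    optimal_threshold: float
    f_at_optimum: float
    curve: list[tuple[float, float, float, float]]  # (threshold, precision, recall, f)


def _validated(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {scores.shape} scores")
    return labels, scores


def confusion(labels, scores, threshold: float) -> ConfusionCounts:
    """Exact confusion counts with ``score >= threshold`` predicting positive."""
    labels, scores = _validated(labels, scores)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        threshold=float(threshold),
    )


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F-score and MCC from confusion counts.

    Any metric with a zero denominator is NA, matching how degenerate cells
    are reported (a value, not an error).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.n
    if n < 1:
        raise ValueError("classification_metrics needs at least one sample")
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp > 0 else NA
    recall = tp / (tp + fn) if tp + fn > 0 else NA
    if is_na(precision) or is_na(recall) or precision + recall == 0:
        f_score = NA
    else:
        f_score = 2.0 * precision * recall / (precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else NA
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_score=f_score,
        mcc=mcc,
        counts=counts,
    )


def auprc(labels, scores) -> float:
    """Step-wise average precision; ties are grouped at equal scores."""
    labels, scores = _validated(labels, scores)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("auprc requires both classes")
    return float(average_precision_score(labels, scores))


def reliability(labels, scores, n_bins: int = 10, mode: str = "positive_fraction") -> ReliabilityTable:
    """Bin predictions into ``n_bins`` equal-width bins and compute ECE.

    ``positive_fraction`` mode compares the empirical positive fraction to the
    mean positive-class score per bin (the reliability-diagram axes for a
    binary disease classifier).  ``confidence`` mode bins by the argmax-class
    confidence ``max(s, 1-s)`` and compares it to argmax correctness.
    """
    labels, scores = _validated(labels, scores)
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if mode not in ("positive_fraction", "confidence"):
        raise ValueError(f"unknown reliability mode {mode!r}")
    m = len(labels)
    if m == 0:
        raise ValueError("reliability needs at least one sample")
    if mode == "positive_fraction":
        binned_on = scores
        outcome = (labels == 1).astype(float)
    else:
        pred = (scores >= 0.5).astype(int)
        binned_on = np.where(pred == 1, scores, 1.0 - scores)
        outcome = (pred == labels).astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.digitize(binned_on, edges, right=True)
    idx = np.clip(idx, 1, n_bins)  # score 0 joins bin 1
    counts = np.zeros(n_bins, dtype=int)
    mean_pred = np.full(n_bins, NA)
    acc = np.full(n_bins, NA)
    ece = 0.0
    for z in range(1, n_bins + 1):
        members = idx == z
        c = int(np.sum(members))
        counts[z - 1] = c
        if c:
            mean_pred[z - 1] = float(np.mean(binned_on[members]))
            acc[z - 1] = float(np.mean(outcome[members]))
            ece += (c / m) * abs(acc[z - 1] - mean_pred[z - 1])
    return ReliabilityTable(
        n_bins=n_bins,
        edges=edges,
        counts=counts,
        mean_pred=mean_pred,
        accuracy=acc,
        mode=mode,
        ece=float(ece),
        m=m,
    )


def ece(labels, scores, n_bins: int = 10, mode: str = "positive_fraction") -> float:
    """Convenience wrapper returning only the expected calibration error."""
    return reliability(labels, scores, n_bins=n_bins, mode=mode).ece


def pr_optimal_threshold(labels, scores) -> ThresholdResult:
    """F-maximizing threshold over the observed scores (0.5 always a candidate).

    The ``>=`` rule is applied at every candidate; ties in F are broken by the
    smallest threshold.  Exact and deterministic.
    """
    labels, scores = _validated(labels, scores)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("pr_optimal_threshold requires both classes")
    thresholds = np.unique(np.concatenate([scores, [0.5]]))
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = np.cumsum(labels[order] == 1)
    n = len(labels)
    n_pos = int(sorted_pos[-1])
    # counts of samples / positives with score >= t, vectorized over thresholds
    lo_idx = np.searchsorted(sorted_scores, thresholds, side="left")
    ge = n - lo_idx
    pos_below = np.where(lo_idx > 0, sorted_pos[lo_idx - 1], 0)
    tp = n_pos - pos_below
    fp = ge - tp
    fn = n_pos - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), NA)
        rec = tp / n_pos
        denom = prec + rec
        f = np.where(np.isnan(prec) | (denom == 0), NA, 2.0 * prec * rec / np.maximum(denom, 1e-300))
    curve = [
        (float(t), float(p), float(r), float(fv))
        for t, p, r, fv in zip(thresholds, prec, rec, f)
    ]
    f_filled = np.where(np.isnan(f), -np.inf, f)
    best_f = float(np.max(f_filled))
    best_t = float(np.min(thresholds[f_filled == best_f]))
    return ThresholdResult(optimal_threshold=best_t, f_at_optimum=best_f, curve=curve)


def metrics_at(labels, scores, threshold: float, with_auprc: bool = True) -> MetricsReport:
    """Full metrics report at one threshold (confusion + Eqs metrics + AUPRC)."""
    report = classification_metrics(confusion(labels, scores, threshold))
    if with_auprc:
        report.auprc = auprc(labels, scores)
    return report
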