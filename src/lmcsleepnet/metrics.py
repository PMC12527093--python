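"""Agreement statistics for 5-stage sleep scoring.

Confusion matrices are 5x5 with rows = true stage, columns = predicted stage,
both in W, N1, N2, N3, REM order.  Per-class precision/recall/F1 follow the
usual one-vs-rest definitions; overall metrics are pooled accuracy
(trace / N), macro-F1 (unweighted mean of per-class F1) and Cohen's kappa
with expected agreement p_e = sum_i row_i * col_i / N^2.

Zero-division convention: a class with an empty row or column gets
PR = RE = F1 = 0 and is flagged ``degenerate`` so macro-F1 stays defined on
small validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_edf import StageLabel

__all__ = [
    "STAGE_NAMES",
    "ConfusionMatrix",
    "ClassMetrics",
    "SummaryMetrics",
    "confusion_matrix",
    "per_class_metrics",
    "summary_metrics",
    "REFERENCE_CONFUSION_SLEEPEDF20",
    "reference_report",
]

STAGE_NAMES = tuple(s.name for s in StageLabel)
N_STAGES = len(STAGE_NAMES)

# Pooled 10-fold confusion matrix reported for the original LMCSleepNet
# evaluation on SleepEDF-20 (rows true, columns predicted, W/N1/N2/N3/REM).
REFERENCE_CONFUSION_SLEEPEDF20 = np.array([
    [7844, 276, 87, 14, 68],
    [387, 1131, 614, 12, 405],
    [109, 241, 14858, 514, 459],
    [17, 0, 461, 4706, 1],
    [106, 257, 582, 2, 6068],
], dtype=np.int64)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"confusion matrix must be {N_STAGES}x{N_STAGES}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1, each a length-5 array in stage order."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    degenerate: np.ndarray  # True where a zero denominator forced a 0


@dataclass
class SummaryMetrics:
    accuracy: float
    macro_f1: float
    kappa: float  # NaN when expected agreement is 1 (single-class degenerate)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= N_STAGES
                        or y_pred.min() < 0 or y_pred.max() >= N_STAGES):
        raise ValueError(f"labels must lie in 0..{N_STAGES - 1}")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    counts = cm.counts.astype(np.float64)
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    degenerate = (tp + fp == 0) | (tp + fn == 0)
    return ClassMetrics(precision=precision, recall=recall, f1=f1,
                        degenerate=degenerate)


def summary_metrics(cm: ConfusionMatrix) -> SummaryMetrics:
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / n ** 2)
    kappa = np.nan if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    macro_f1 = float(per_class_metrics(cm).f1.mean())
    return SummaryMetrics(accuracy=float(p_o), macro_f1=macro_f1, kappa=float(kappa))


def reference_report() -> dict:
    """Recompute every matrix-derived statistic of the packaged reference
    confusion matrix, formatted as the original evaluation prints them
    (percentages to one decimal, kappa to two)."""
    cm = ConfusionMatrix(REFERENCE_CONFUSION_SLEEPEDF20)
    cls = per_class_metrics(cm)
    summary = summary_metrics(cm)
    report = {
        "ACC": round(100 * summary.accuracy, 1),
        "MF1": round(100 * summary.macro_f1, 1),
        "kappa": round(summary.kappa, 2),
        "N": cm.total,
    }
    for i, name in enumerate(STAGE_NAMES):
        report[f"PR_{name}"] = round(float(100 * cls.precision[i]), 1)
        report[f"RE_{name}"] = round(float(100 * cls.recall[i]), 1)
        report[f"F1_{name}"] = round(float(100 * cls.f1[i]), 1)
    return report
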