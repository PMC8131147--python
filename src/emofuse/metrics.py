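"""Evaluation statistics: recognition accuracy, F1, and R-squared.

Recognition accuracy RA = N_TP / N_data and the confusion-count form
F1 = 2 N_TP / (2 N_TP + N_FP + N_FN).  For single-label multiclass
problems the counts are aggregated over classes (micro), in which case
every misclassification is simultaneously one FP and one FN and micro-F1
equals RA; a macro (per-class averaged) variant is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    n_tp: int
    n_fp: int
    n_fn: int
    n_data: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_fn, self.n_data) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_tp > self.n_data:
            raise ValueError("N_TP cannot exceed N_data")


def micro_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Class-aggregated counts: each error is both one FP and one FN."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    tp = int((y_true == y_pred).sum())
    err = int(y_true.size - tp)
    return ConfusionCounts(tp, err, err, int(y_true.size))


def recognition_accuracy(counts: ConfusionCounts) -> float:
    if counts.n_data == 0:
        raise ValueError("RA undefined for an empty test set")
    return counts.n_tp / counts.n_data


def f1_score(counts: ConfusionCounts) -> float:
    denom = 2 * counts.n_tp + counts.n_fp + counts.n_fn
    if denom == 0:
        raise ValueError("F1 undefined: all confusion counts are zero")
    return 2 * counts.n_tp / denom


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None) -> float:
    """Per-class F1 averaged over classes (one-vs-rest counts)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    scores = []
    for c in range(n_classes):
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        denom = 2 * tp + fp + fn
        scores.append(0.0 if denom == 0 else 2 * tp / denom)
    return float(np.mean(scores))


def r_squared(y_act: np.ndarray, y_pre: np.ndarray) -> float:
    """R^2 = 1 - sum (y_act - y_pre)^2 / sum (y_act - mean)^2."""
    y_act, y_pre = np.asarray(y_act, float), np.asarray(y_pre, float)
    if y_act.shape != y_pre.shape:
        raise ValueError("series must have equal length")
    ss_tot = float(((y_act - y_act.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: true series has zero variance")
    ss_res = float(((y_act - y_pre) ** 2).sum())
    return 1.0 - ss_res / ss_tot
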