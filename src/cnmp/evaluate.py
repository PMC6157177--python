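"""Evaluation: accuracy, annotated confusion matrix, ROC/AUC, and a
leakage-safe stratified cross-validation harness.

The confusion matrix uses rows = true class, columns = predicted class;
per-class recall (sensitivity) is the diagonal over the row sum and
precision the diagonal over the column sum.  A class absent from the truth
(empty row) or never predicted (empty column) yields NaN for the affected
metric rather than a silent zero.

The ROC curve sweeps a threshold over the positive-class scores
(TPR = TP/(TP+FN) against FPR = FP/(FP+TN)); AUC is the trapezoidal area,
which equals the concordant-(positive, negative)-pair fraction with ties
counted one half.

Cross-validation folds are stratified over *source image ids*, never over
patches: all patches cut from one image share a fold, because patch
predictions of one image are averaged and are not independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledImageSet

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "confusion_matrix",
    "roc_curve",
    "auc",
    "cross_validate",
]


@dataclass
class ConfusionMatrix:
    """k x k count matrix with per-class precision/recall and accuracy."""

    counts: np.ndarray
    precision: np.ndarray  # NaN where the class was never predicted
    recall: np.ndarray     # NaN where the class has no true instances
    accuracy: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        """Annotated pandas DataFrame mirroring the standard layout:
        count block, recall column, precision row, accuracy corner."""
        import pandas as pd

        k = self.counts.shape[0]
        labels = [f"true_{c + 1}" for c in range(k)]
        cols = [f"pred_{c + 1}" for c in range(k)]
        frame = pd.DataFrame(self.counts, index=labels, columns=cols, dtype=float)
        frame["recall"] = self.recall
        precision_row = list(self.precision) + [self.accuracy]
        frame.loc["precision"] = precision_row
        return frame


def confusion_matrix(y_true, y_pred, k: int | None = None) -> ConfusionMatrix:
    """Exact tally of 1-based labels into a k x k confusion matrix."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if k is None:
        k = int(max(y_true.max(), y_pred.max()))
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.min() < 1 or arr.max() > k:
            raise ValueError(f"{name} labels must lie in [1, {k}]")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    diag = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, np.nan)
    return ConfusionMatrix(
        counts=counts,
        precision=precision,
        recall=recall,
        accuracy=float(diag.sum() / counts.sum()),
    )


@dataclass
class ROCCurve:
    """Threshold-swept (FPR, TPR) points from (0,0) to (1,1), non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    positive_label: int = 1


def roc_curve(scores, y_true, positive_label: int = 1) -> ROCCurve:
    """ROC points at every distinct score threshold (descending).

    ``scores`` are positive-class probabilities (or any monotone score);
    raises if only one class is present, since TPR or FPR is then undefined.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = y_true == positive_label
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs both a positive and a negative class present")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn always ends at (1,1)
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, positive_label=positive_label)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def cross_validate(
    ds: LabeledImageSet,
    run_fold: Callable[[LabeledImageSet, LabeledImageSet, int], dict],
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV over source images.

    ``run_fold(train_set, test_set, fold_seed) -> dict of metrics`` is called
    once per fold with disjoint test sets that partition the image ids.
    Returns per-fold metric dicts plus mean/std per metric key.
    """
    if folds < 2:
        raise ValueError(f"need at least 2 folds, got {folds}")
    labels, counts = np.unique(ds.labels, return_counts=True)
    small = labels[counts < folds]
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer images than folds={folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: list[dict] = []
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(ds)), ds.labels)):
        metrics = run_fold(ds.subset(train_idx), ds.subset(test_idx), seed + f)
        fold_metrics.append(metrics)
    keys = fold_metrics[0].keys()
    summary = {
        key: {
            "mean": float(np.mean([m[key] for m in fold_metrics])),
            "std": float(np.std([m[key] for m in fold_metrics])),
        }
        for key in keys
        if np.isscalar(fold_metrics[0][key])
    }
    return {"folds": fold_metrics, "summary": summary}
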