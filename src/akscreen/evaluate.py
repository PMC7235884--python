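"""Confusion-matrix metrics, ROC/AUC, and the 10-fold evaluation protocol.

Metric definitions (positive class = actinic keratosis):

    Acc  = (TP + TN) / (TP + TN + FP + FN)
    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Prec = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any metric whose denominator is zero is reported as NaN with a warning flag
rather than silently coerced to 0.  AUC comes from a threshold sweep over
the unique scores (ties grouped) with trapezoidal integration, which equals
the tie-corrected Mann-Whitney rank statistic.

Cross-validation is stratified by default and, crucially, applies minority
-class augmentation *inside* each fold to the training split only, so no
flipped/rotated derivative of a test image ever reaches the training set.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from math import sqrt
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .datasets import LabeledImageSet
from .preprocess import PreprocessPlan, augment_set, base_image_id

__all__ = [
    "ConfusionCounts", "BinaryMetrics", "FoldPlan", "MetricReport",
    "confusion_counts", "binary_metrics", "roc_auc", "make_folds",
    "cross_validate",
]

METRIC_COLUMNS = ["Acc", "Sens", "Spec", "Prec", "MCC", "AUC"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN as counts (positive class = AK)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class BinaryMetrics:
    acc: float
    sens: float
    spec: float
    prec: float
    mcc: float
    undefined: tuple[str, ...] = ()  # metrics with a zero denominator

    def as_dict(self) -> dict[str, float]:
        return {"Acc": self.acc, "Sens": self.sens, "Spec": self.spec,
                "Prec": self.prec, "MCC": self.mcc}


def confusion_counts(labels, predicted) -> ConfusionCounts:
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if y.size == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if y.shape != p.shape:
        raise TypeError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (np.isin(y, [0, 1]).all() and np.isin(p, [0, 1]).all()):
        raise TypeError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Accuracy, sensitivity, specificity, precision and MCC from counts."""
    if c.total == 0:
        raise ValueError("confusion matrix is empty")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = (c.tp + c.tn) / c.total
    sens = ratio(c.tp, c.tp + c.fn, "Sens")
    spec = ratio(c.tn, c.tn + c.fp, "Spec")
    prec = ratio(c.tp, c.tp + c.fp, "Prec")
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        undefined.append("MCC")
        mcc = float("nan")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / sqrt(den)
    return BinaryMetrics(acc, sens, spec, prec, mcc, tuple(undefined))


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC.

    Returns ``(curve, auc)`` where ``curve`` has rows (fpr, tpr, threshold),
    one step per unique score value (ties grouped).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise TypeError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresh = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr, thresh]), auc


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint partition of sample indices into k folds."""

    k: int
    assignments: np.ndarray  # fold index per sample
    seed: int = 0
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels, k: int = 10, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Seeded (optionally stratified) k-fold partition; sizes differ by <= 1."""
    y = np.asarray(labels)
    n = y.size
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if stratified and np.bincount(y.astype(int), minlength=2).min() < k:
        raise ValueError(f"stratified {k}-fold split needs >= {k} members per class")
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=stratified)


def _fold_scores(estimator, X) -> np.ndarray:
    if hasattr(estimator, "score_samples"):
        return np.asarray(estimator.score_samples(X), dtype=float)
    if hasattr(estimator, "predict_proba"):
        proba = np.asarray(estimator.predict_proba(X), dtype=float)
        pos = int(np.where(np.asarray(estimator.classes_) == 1)[0][0])
        return proba[:, pos]
    return np.asarray(estimator.decision_function(X), dtype=float)


@dataclass
class MetricReport:
    """Per-fold metrics plus their arithmetic means."""

    per_fold: pd.DataFrame
    fold_details: list[dict] = field(default_factory=list)

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in METRIC_COLUMNS}

    def summary_row(self, model: str) -> dict:
        row = {"model": model}
        row.update(self.means)
        row["train_seconds"] = float(self.per_fold["train_seconds"].sum())
        return row


def cross_validate(model_recipe: Callable[[], object], dataset: LabeledImageSet,
                   plan: FoldPlan, augment: PreprocessPlan | None = None) -> MetricReport:
    """Run the k-fold protocol over an image dataset.

    ``model_recipe`` is a zero-argument factory returning a fresh estimator
    (a pipeline over raw uint8 images) per fold.  When ``augment`` is given,
    the training split of each fold is expanded with
    :func:`akscreen.preprocess.augment_set` before fitting; the test split is
    never augmented, and provenance of every augmented identifier is recorded
    in ``fold_details`` so leakage can be audited.

    Held-out predictions use the estimator's own ``predict`` (the 0.5
    threshold on the positive-class probability for probabilistic models);
    AUC uses ``score_samples``/``predict_proba``/``decision_function``, in
    that order of preference.
    """
    if plan.assignments.size != len(dataset):
        raise ValueError("fold plan does not match dataset size")
    rows = []
    details = []
    for fold in range(plan.k):
        train_set = dataset.subset(plan.train_indices(fold))
        test_set = dataset.subset(plan.test_indices(fold))
        if augment is not None:
            train_set = augment_set(train_set, augment)
        est = model_recipe()
        t0 = time.perf_counter()
        est.fit(train_set.images, train_set.labels)
        train_seconds = time.perf_counter() - t0
        y_true = test_set.labels
        y_pred = np.asarray(est.predict(test_set.images))
        scores = _fold_scores(est, test_set.images)
        m = binary_metrics(confusion_counts(y_true, y_pred))
        _, auc = roc_auc(scores, y_true)
        row = {"fold": fold}
        row.update(m.as_dict())
        row["AUC"] = auc
        row["n_test"] = len(test_set)
        row["train_seconds"] = train_seconds
        rows.append(row)
        details.append({
            "fold": fold,
            "train_ids": train_set.image_ids,
            "train_base_ids": sorted({base_image_id(i) for i in train_set.image_ids}),
            "test_ids": test_set.image_ids,
            "scores": scores.tolist(),
            "y_true": y_true.tolist(),
            "y_pred": y_pred.tolist(),
            "undefined_metrics": list(m.undefined),
        })
    return MetricReport(per_fold=pd.DataFrame(rows), fold_details=details)
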