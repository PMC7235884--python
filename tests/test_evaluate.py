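"""Confusion metrics, ROC/AUC, fold construction, and the CV harness."""

import math

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, matthews_corrcoef, precision_score, recall_score

import akscreen as ak
from akscreen.datasets import LabeledImageSet, Sample
from akscreen.evaluate import BinaryMetrics
from akscreen.preprocess import base_image_id
from conftest import random_rgb


# ---------------------------------------------------------------------------
# confusion counts

def test_confusion_enumeration_example():
    c = ak.confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


def test_all_correct_has_no_errors():
    c = ak.confusion_counts([1, 0, 1], [1, 0, 1])
    assert c.fp == c.fn == 0 and c.total == 3


@pytest.mark.parametrize("labels, preds, exc", [
    ([], [], ValueError),
    ([1, 0], [1], TypeError),
    ([1, 2], [1, 0], TypeError),
])
def test_confusion_rejects_bad_inputs(labels, preds, exc):
    with pytest.raises(exc):
        ak.confusion_counts(labels, preds)


# ---------------------------------------------------------------------------
# metric formulas

def test_symmetric_table_metrics():
    m = ak.binary_metrics(ak.ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
    assert m.acc == m.sens == m.spec == m.prec == 0.5
    assert m.mcc == 0.0
    assert m.undefined == ()


def test_perfect_classifier_metrics():
    m = ak.binary_metrics(ak.ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
    assert (m.acc, m.sens, m.spec, m.prec, m.mcc) == (1, 1, 1, 1, 1)


def test_zero_denominator_flags_nan():
    m = ak.binary_metrics(ak.ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
    assert math.isnan(m.prec) and math.isnan(m.mcc)
    assert "Prec" in m.undefined and "MCC" in m.undefined
    assert m.acc == 5 / 8


def test_metrics_match_sklearn_on_random_predictions(rng):
    for _ in range(200):
        n = int(rng.integers(4, 40))
        y = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        m = ak.binary_metrics(ak.confusion_counts(y, p))
        assert m.acc == pytest.approx(accuracy_score(y, p))
        if not math.isnan(m.sens):
            assert m.sens == pytest.approx(recall_score(y, p, zero_division=np.nan))
        if not math.isnan(m.prec):
            assert m.prec == pytest.approx(precision_score(y, p, zero_division=np.nan))
        if not math.isnan(m.mcc):
            assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


def test_mcc_properties_over_random_tables(rng):
    for _ in range(1000):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 30, 4))
        if tp + fp + tn + fn == 0:
            continue
        m = ak.binary_metrics(ak.ConfusionCounts(tp, fp, tn, fn))
        if not math.isnan(m.mcc):
            assert -1 <= m.mcc <= 1
            # swap classes: MCC is symmetric
            sw = ak.binary_metrics(ak.ConfusionCounts(tn, fn, tp, fp))
            if not math.isnan(sw.mcc):
                assert m.mcc == pytest.approx(sw.mcc, abs=1e-12)
            # invert all predictions: MCC negates
            inv = ak.binary_metrics(ak.ConfusionCounts(fn, tn, fp, tp))
            if not math.isnan(inv.mcc):
                assert inv.mcc == pytest.approx(-m.mcc, abs=1e-12)


def test_trivial_all_positive_classifier():
    y = np.array([1, 1, 0, 0, 0, 1])
    m = ak.binary_metrics(ak.confusion_counts(y, np.ones_like(y)))
    assert m.sens == 1.0 and m.spec == 0.0


# ---------------------------------------------------------------------------
# ROC / AUC

def test_perfect_and_inverted_ranking():
    _, auc = ak.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    _, auc = ak.roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
    assert auc == 0.0


def test_auc_equals_mann_whitney_rank_statistic(rng):
    """Trapezoidal AUC with grouped ties == tie-corrected rank statistic."""
    for _ in range(20):
        n = 200
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.normal(size=n), 1)  # coarse scores force ties
        _, auc = ak.roc_auc(s, y)
        r = rankdata(s)
        n1, n0 = int((y == 1).sum()), int((y == 0).sum())
        u = r[y == 1].sum() - n1 * (n1 + 1) / 2
        assert abs(auc - u / (n1 * n0)) < 1e-10


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    s = rng.normal(size=100)
    _, auc1 = ak.roc_auc(s, y)
    _, auc2 = ak.roc_auc(np.exp(3 * s) + 7, y)
    assert auc1 == pytest.approx(auc2, abs=1e-12)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        ak.roc_auc([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# folds

def test_even_fold_sizes():
    plan = ak.make_folds(np.repeat([0, 1], 50), k=10, seed=0)
    sizes = [len(plan.test_indices(f)) for f in range(10)]
    assert sizes == [10] * 10


def test_stratification_within_one():
    y = np.array([1] * 60 + [0] * 40)
    plan = ak.make_folds(y, k=10, seed=1, stratified=True)
    for f in range(10):
        test_y = y[plan.test_indices(f)]
        assert abs(int(test_y.sum()) - 6) <= 1
        assert abs(int((test_y == 0).sum()) - 4) <= 1


def test_folds_partition_all_indices():
    y = np.repeat([0, 1], 26)
    plan = ak.make_folds(y, k=10, seed=3)
    all_test = np.concatenate([plan.test_indices(f) for f in range(10)])
    assert sorted(all_test.tolist()) == list(range(52))
    for f in range(3):
        assert set(plan.train_indices(f)).isdisjoint(plan.test_indices(f))


def test_fold_plan_is_seeded():
    y = np.repeat([0, 1], 30)
    a = ak.make_folds(y, k=5, seed=9)
    b = ak.make_folds(y, k=5, seed=9)
    c = ak.make_folds(y, k=5, seed=10)
    assert np.array_equal(a.assignments, b.assignments)
    assert not np.array_equal(a.assignments, c.assignments)


def test_fold_preconditions():
    with pytest.raises(ValueError):
        ak.make_folds([0, 1, 0, 1], k=10)
    with pytest.raises(ValueError):
        ak.make_folds(np.array([0] * 30 + [1] * 5), k=10, stratified=True)


# ---------------------------------------------------------------------------
# cross-validation harness

class RednessClassifier(BaseEstimator, ClassifierMixin):
    """Cheap image classifier: thresholds mean redness (R - (G+B)/2)."""

    def fit(self, X, y):
        scores = self._redness(X)
        y = np.asarray(y)
        self.threshold_ = (scores[y == 1].mean() + scores[y == 0].mean()) / 2
        self.classes_ = np.array([0, 1])
        return self

    @staticmethod
    def _redness(X):
        return np.array([im[:, :, 0].mean() - (im[:, :, 1].mean() + im[:, :, 2].mean()) / 2
                         for im in X], dtype=float)

    def predict(self, X):
        return (self._redness(X) >= self.threshold_).astype(int)

    def score_samples(self, X):
        return self._redness(X)


def _imbalanced_set(rng, n_pos=8, n_neg=24, size=16):
    samples = []
    for i in range(n_neg):
        samples.append(Sample(f"neg{i:03d}", random_rgb(rng, size), 0))
    for i in range(n_pos):
        img = random_rgb(rng, size).astype(np.int16)
        img[:, :, 0] += 60  # positives are redder
        samples.append(Sample(f"pos{i:03d}", np.clip(img, 0, 255).astype(np.uint8), 1))
    return LabeledImageSet(samples)


def test_cross_validate_report_structure(rng):
    data = _imbalanced_set(rng)
    plan = ak.make_folds(data.labels, k=4, seed=0)
    report = ak.cross_validate(RednessClassifier, data, plan)
    assert len(report.per_fold) == 4
    for m in ("Acc", "Sens", "Spec", "Prec", "MCC", "AUC"):
        assert report.means[m] == pytest.approx(report.per_fold[m].mean(), abs=1e-12)
    assert report.per_fold["n_test"].sum() == len(data)


def test_separable_redness_task_is_learned(rng):
    data = _imbalanced_set(rng)
    plan = ak.make_folds(data.labels, k=4, seed=0)
    report = ak.cross_validate(RednessClassifier, data, plan)
    assert report.means["Acc"] >= 0.95
    assert report.means["AUC"] >= 0.95


def test_augmentation_stays_inside_training_folds(rng):
    """No flipped/rotated copy of any held-out image reaches training."""
    data = _imbalanced_set(rng)  # positives are the minority -> get augmented
    plan = ak.make_folds(data.labels, k=4, seed=1)
    report = ak.cross_validate(RednessClassifier, data, plan,
                               augment=ak.PreprocessPlan())
    saw_augmented = False
    for detail in report.fold_details:
        train_ids = detail["train_ids"]
        test_ids = set(detail["test_ids"])
        saw_augmented |= any(base_image_id(t) != t for t in train_ids)
        for tid in train_ids:
            assert base_image_id(tid) not in test_ids
        assert all(base_image_id(t) == t for t in test_ids)  # tests are originals
    assert saw_augmented


def test_cross_validate_rejects_mismatched_plan(rng):
    data = _imbalanced_set(rng)
    plan = ak.make_folds(np.repeat([0, 1], 8), k=4, seed=0)
    with pytest.raises(ValueError):
        ak.cross_validate(RednessClassifier, data, plan)


def test_metric_report_summary_row(rng):
    data = _imbalanced_set(rng)
    plan = ak.make_folds(data.labels, k=4, seed=0)
    report = ak.cross_validate(RednessClassifier, data, plan)
    row = report.summary_row("redness")
    assert row["model"] == "redness"
    assert row["Acc"] == pytest.approx(report.means["Acc"])
    assert isinstance(BinaryMetrics(0.5, 0.5, 0.5, 0.5, 0.0), BinaryMetrics)
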