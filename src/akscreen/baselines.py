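"""Classical classifiers (SVM / random forest / k-NN) over HOG features.

A thin, uniform wrapper around scikit-learn estimators that adds the
``score_samples`` contract used by the ROC machinery: a real score per
sample, larger = more actinic-keratosis-like.  For the SVM that is the
signed decision value; for the forest the positive-class vote fraction; for
k-NN the positive-neighbor fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = ["BaselineSpec", "ClassicalBaseline", "fit_baseline", "score_samples"]

_KINDS = ("svm", "rf", "knn")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineSpec:
    """Which classical classifier to run, and how.

    ``hyperparameters`` override the conventional defaults (svm: RBF kernel,
    C=1; rf: 100 trees; knn: k=5).  ``tuning`` optionally maps parameter
    names to candidate grids, selected by internal cross-validation.
    """

    kind: str = "svm"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    tuning: dict[str, list] | None = None
    tuning_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"kind must be one of {_KINDS}, got {self.kind!r}")


def _base_estimator(spec: BaselineSpec):
    if spec.kind == "svm":
        params = {"kernel": "rbf", "C": 1.0, "random_state": spec.seed}
    elif spec.kind == "rf":
        params = {"n_estimators": 100, "random_state": spec.seed}
    else:
        params = {"n_neighbors": 5}
    params.update(spec.hyperparameters)
    cls = {"svm": SVC, "rf": RandomForestClassifier, "knn": KNeighborsClassifier}[spec.kind]
    return cls(**params)


class ClassicalBaseline(BaseEstimator, ClassifierMixin):
    """Sklearn estimator facade over the three classical baselines."""

    def __init__(self, kind: str = "svm", hyperparameters: dict | None = None,
                 tuning: dict | None = None, tuning_folds: int = 3, seed: int = 0):
        self.kind = kind
        self.hyperparameters = hyperparameters
        self.tuning = tuning
        self.tuning_folds = tuning_folds
        self.seed = seed

    def _spec(self) -> BaselineSpec:
        return BaselineSpec(kind=self.kind, hyperparameters=self.hyperparameters or {},
                            tuning=self.tuning, tuning_folds=self.tuning_folds,
                            seed=self.seed)

    def fit(self, X, y) -> "ClassicalBaseline":
        spec = self._spec()
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        counts = np.bincount(y.astype(int), minlength=2)
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        est = _base_estimator(spec)
        if spec.tuning:
            search = GridSearchCV(est, spec.tuning, cv=spec.tuning_folds, n_jobs=1)
            search.fit(X, y)
            self.estimator_ = search.best_estimator_
            self.best_params_ = search.best_params_
        else:
            self.estimator_ = clone(est).fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def score_samples(self, X) -> np.ndarray:
        """Real-valued AK-likeness score (larger = more likely positive)."""
        if not hasattr(self, "estimator_"):
            raise NotFittedError("baseline is not fitted; call fit first")
        if self.kind == "svm":
            return np.asarray(self.estimator_.decision_function(X), dtype=float)
        pos = int(np.where(self.estimator_.classes_ == 1)[0][0])
        return self.estimator_.predict_proba(X)[:, pos]


def fit_baseline(features: np.ndarray, labels, spec: BaselineSpec) -> ClassicalBaseline:
    """Train the requested classical classifier on a feature matrix."""
    model = ClassicalBaseline(kind=spec.kind, hyperparameters=spec.hyperparameters,
                              tuning=spec.tuning, tuning_folds=spec.tuning_folds,
                              seed=spec.seed)
    return model.fit(np.asarray(features), np.asarray(labels))


def score_samples(classifier: ClassicalBaseline, features: np.ndarray) -> np.ndarray:
    return classifier.score_samples(np.asarray(features))
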