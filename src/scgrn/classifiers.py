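"""The nine classifier configurations behind a uniform train/score contract.

Methods: three SVM kernels (``svm_linear``, ``svm_poly``, ``svm_rbf``),
random forest (``rf``), Gaussian naive Bayes (``nb``), gradient-boosted
trees (``gbdt``), logistic regression (``lr``), CART decision tree (``dt``)
and k-nearest neighbours (``knn``).  Model fitting is delegated to
scikit-learn; every method emits a positive-class score in [0, 1] so scores
are comparable when pooled across TFs.  The kernel functions and the Gini
impurity used by CART are also exposed directly as testable utilities.

Features are z-scored per column (per cell) inside the fitted pipeline, so
standardisation statistics always come from the training fold alone;
constant columns pass through as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "METHODS",
    "ClassifierConfig",
    "TrainedModel",
    "kernel_value",
    "gini_impurity",
    "train_classifier",
    "score_samples",
]

METHODS = (
    "svm_linear",
    "svm_poly",
    "svm_rbf",
    "rf",
    "nb",
    "gbdt",
    "lr",
    "dt",
    "knn",
)


def kernel_value(x, y, kind: str, d: int = 3, gamma: float = 1.0) -> float:
    """Evaluate an SVM kernel on a pair of vectors.

    linear: x·y; polynomial: ((x·y) + 1)^d; rbf: exp(-gamma * ||x - y||^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if kind == "linear":
        return float(x @ y)
    if kind == "polynomial":
        if d < 1:
            raise ValueError(f"polynomial degree must be >= 1, got {d}")
        return float((x @ y + 1.0) ** d)
    if kind == "rbf":
        if gamma <= 0:
            raise ValueError(f"rbf gamma must be > 0, got {gamma}")
        diff = x - y
        return float(np.exp(-gamma * (diff @ diff)))
    raise ValueError(f"unknown kernel {kind!r}")


def gini_impurity(class_counts) -> float:
    """Gini index 1 - sum(p_i^2) of a class-count vector.

    The probability that two samples drawn from the counted set carry
    different class labels; 0 for a pure set, at most 1 - 1/n for n classes.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("class_counts must be a 1-D vector")
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("class_counts must sum to at least 1")
    p = counts / total
    return float(1.0 - (p @ p))


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration for one of the nine methods.

    Fields irrelevant to ``method`` are ignored.  Hyperparameter defaults
    are the conventional ones: C=1, degree=3, gamma="scale", 100 trees,
    K=5 neighbours, library-default depths.
    """

    method: str
    C: float = 1.0
    degree: int = 3
    gamma: float | str = "scale"
    n_trees: int = 100
    k_neighbors: int = 5
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.gamma != "scale" and float(self.gamma) <= 0:
            raise ValueError("gamma must be > 0 or 'scale'")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TrainedModel:
    """Fitted pipeline plus the config that produced it."""

    config: ClassifierConfig
    pipeline: Pipeline
    n_features: int


class _PlattSVC(ClassifierMixin, BaseEstimator):
    """SVC whose decision values are mapped to [0,1] probabilities by a
    logistic curve fitted on the training data (Platt-style calibration).

    The mapping is monotone increasing in the decision value, so rankings
    are those of the raw margin while the emitted scores are probabilities
    comparable across TF problems.
    """

    def __init__(self, svc_kwargs=None):
        self.svc_kwargs = svc_kwargs or {}

    def fit(self, X, y):
        self._svc = SVC(**self.svc_kwargs)
        self._platt = LogisticRegression(C=1e6)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        decision = self._svc.decision_function(X).reshape(-1, 1)
        self._platt.fit(decision, y)
        if self._platt.coef_[0, 0] < 0:  # guard: keep score monotone in margin
            self._platt.coef_[0, 0] = abs(self._platt.coef_[0, 0])
        return self

    def predict_proba(self, X):
        decision = self._svc.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(decision)

    def predict(self, X):
        return self._svc.predict(X)


class _AdaptiveKNN(KNeighborsClassifier):
    """KNN whose neighbourhood size shrinks to the training-set size when a
    fold is smaller than K; the score is the fraction of positive
    neighbours."""

    def fit(self, X, y):
        self.n_neighbors = min(self.n_neighbors, len(y))
        return super().fit(X, y)


def _build_estimator(config: ClassifierConfig):
    m = config.method
    if m == "svm_linear":
        return _PlattSVC({"kernel": "linear", "C": config.C})
    if m == "svm_poly":
        return _PlattSVC(
            {
                "kernel": "poly",
                "degree": config.degree,
                "gamma": config.gamma,
                "coef0": 1.0,
                "C": config.C,
            }
        )
    if m == "svm_rbf":
        return _PlattSVC({"kernel": "rbf", "gamma": config.gamma, "C": config.C})
    if m == "rf":
        return RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed
        )
    if m == "nb":
        return GaussianNB()
    if m == "gbdt":
        return GradientBoostingClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth or 3,
            random_state=config.seed,
        )
    if m == "lr":
        return LogisticRegression(C=config.C, max_iter=1000)
    if m == "dt":
        return DecisionTreeClassifier(
            criterion="gini", max_depth=config.max_depth, random_state=config.seed
        )
    if m == "knn":
        return _AdaptiveKNN(n_neighbors=config.k_neighbors)
    raise AssertionError(m)


def train_classifier(
    config: ClassifierConfig, features: np.ndarray, labels: np.ndarray
) -> TrainedModel:
    """Fit one configured classifier on a ±1-labeled feature matrix.

    Raises if the labels contain a single class (the caller must apply the
    zero-positive rule first) or if features contain NaN.  Training is
    deterministic given the config (including its seed).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    if not np.isfinite(features).all():
        raise ValueError("features contain NaN or infinite values")
    classes = np.unique(labels)
    if not set(classes) <= {-1, 1}:
        raise ValueError("labels must be ±1")
    if len(classes) < 2:
        raise ValueError(
            "single-class labels: apply the zero-positive rule instead of training"
        )
    pipeline = Pipeline(
        [("scale", StandardScaler()), ("clf", _build_estimator(config))]
    )
    pipeline.fit(features, labels)
    return TrainedModel(config, pipeline, features.shape[1])


def score_samples(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Positive-class probability in [0,1] for each feature row."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be 2-D")
    if features.shape[0] == 0:
        return np.empty(0, dtype=float)
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {features.shape[1]} != trained {model.n_features}"
        )
    clf = model.pipeline.named_steps["clf"]
    proba = model.pipeline.predict_proba(features)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    scores = proba[:, pos_col]
    return np.clip(scores, 0.0, 1.0)
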