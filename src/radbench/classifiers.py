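"""The five benchmark classifiers behind a uniform train/score contract.

k-nearest neighbors, logistic regression, Gaussian naive Bayes, random
forest (250 trees), and an RBF-kernel SVM whose kernel width gamma is set
to the inverse of the mean pairwise Euclidean distance between training
samples. Regularization grids are powers of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import FeatureTable
from .errors import ConfigError, DataError

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "rbf_gamma",
    "train",
    "score",
    "classifier_grid",
    "C_GRID",
    "KNN_K_GRID",
    "CLASSIFIER_NAMES",
]

#: even powers of two from 2^-10 to 2^10 (11 values, including 2^0 = 1)
C_GRID: tuple[float, ...] = tuple(2.0 ** p for p in range(-10, 11, 2))
KNN_K_GRID: tuple[int, ...] = (1, 3, 5, 7, 9)
CLASSIFIER_NAMES = ("knn", "logistic", "naive_bayes", "random_forest", "rbf_svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration: name, hyperparameters, seed."""

    name: str
    hyper: tuple[tuple[str, Any], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigError(f"unknown classifier {self.name!r}")
        h = dict(self.hyper)
        if self.name == "knn" and "k" in h and h["k"] not in KNN_K_GRID:
            raise ConfigError(f"knn k must be in {KNN_K_GRID}")
        if self.name in ("logistic", "rbf_svm") and "C" in h and h["C"] <= 0:
            raise ConfigError("C must be positive")

    @property
    def hyper_dict(self) -> dict:
        return dict(self.hyper)

    @property
    def label(self) -> str:
        h = self.hyper_dict
        if not h:
            return self.name
        inner = ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                         for k, v in sorted(h.items()))
        return f"{self.name}({inner})"


@dataclass
class TrainedModel:
    """A fitted classifier bound to the exact feature set it was trained on."""

    spec: ClassifierSpec
    estimator: Any
    feature_names: list[str]
    #: "probability" -> scores in [0, 1]; "decision" -> unbounded margin
    score_kind: str = "probability"

    @property
    def default_threshold(self) -> float:
        return 0.5 if self.score_kind == "probability" else 0.0


def rbf_gamma(table: FeatureTable | np.ndarray) -> float:
    """gamma = 1 / mean Euclidean distance over all unordered sample pairs."""
    X = table.X if isinstance(table, FeatureTable) else np.asarray(table, float)
    if len(X) < 2:
        raise DataError("rbf_gamma needs at least 2 samples")
    mean_dist = float(pdist(X).mean())
    if mean_dist == 0:
        raise ConfigError("all samples identical: mean pairwise distance is 0")
    return 1.0 / mean_dist


def train(table: FeatureTable, spec: ClassifierSpec) -> TrainedModel:
    """Fit one classifier; deterministic given (table, spec)."""
    if len(np.unique(table.y)) < 2:
        raise DataError("training table has a single class "
                        "(can happen after aggressive undersampling)")
    if np.isnan(table.X).any():
        raise DataError("training table contains missing values")
    h = spec.hyper_dict
    score_kind = "probability"
    if spec.name == "knn":
        est = KNeighborsClassifier(n_neighbors=h.get("k", 5))
    elif spec.name == "logistic":
        est = LogisticRegression(C=h.get("C", 1.0), max_iter=2000)
    elif spec.name == "naive_bayes":
        est = GaussianNB(var_smoothing=h.get("var_smoothing", 1e-9))
    elif spec.name == "random_forest":
        est = RandomForestClassifier(n_estimators=h.get("n_trees", 250),
                                     random_state=spec.seed, n_jobs=1)
    elif spec.name == "rbf_svm":
        est = SVC(C=h.get("C", 1.0), kernel="rbf", gamma=rbf_gamma(table),
                  random_state=spec.seed)
        score_kind = "decision"
    else:  # pragma: no cover - guarded by spec validation
        raise ConfigError(f"unknown classifier {spec.name!r}")
    est.fit(table.X, table.y)
    return TrainedModel(spec, est, list(table.feature_names), score_kind)


def score(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Continuous positive-class score per sample.

    Probability of the positive class where the estimator supports it,
    otherwise the decision-function margin; either way the score is
    monotone in the model's estimated positive-class probability.
    """
    if list(table.feature_names) != model.feature_names:
        raise DataError("feature mismatch between model and table")
    if model.score_kind == "probability":
        proba = model.estimator.predict_proba(table.X)
        pos_col = list(model.estimator.classes_).index(1)
        return proba[:, pos_col]
    return model.estimator.decision_function(table.X)


def classifier_grid(seed: int = 0) -> list[ClassifierSpec]:
    """All benchmark classifier configurations (5 + 11 + 1 + 1 + 11 = 29)."""
    grid: list[ClassifierSpec] = []
    grid += [ClassifierSpec("knn", (("k", k),), seed) for k in KNN_K_GRID]
    grid += [ClassifierSpec("logistic", (("C", c),), seed) for c in C_GRID]
    grid += [ClassifierSpec("naive_bayes", (), seed)]
    grid += [ClassifierSpec("random_forest", (("n_trees", 250),), seed)]
    grid += [ClassifierSpec("rbf_svm", (("C", c),), seed) for c in C_GRID]
    return grid
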