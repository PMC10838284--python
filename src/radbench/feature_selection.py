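"""Filter feature scorers and top-N extraction.

Four univariate-to-multivariate relevance scorers (ANOVA F, Gaussian
Bhattacharyya distance, extremely-randomized-tree importance, L1-logistic
coefficient magnitude) score every feature; the top N by score are kept,
with N drawn from a logarithmic grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression

from .datasets import FeatureTable
from .errors import ConfigError, DataError

__all__ = [
    "FeatureScores",
    "FeatureSet",
    "anova_f",
    "bhattacharyya",
    "extratrees_importance",
    "lasso_scores",
    "select_top",
    "score_features",
    "DEFAULT_N_GRID",
    "SELECTORS",
]

#: logarithmic grid of selected-feature counts
DEFAULT_N_GRID: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64)

SELECTORS = ("anova", "bhattacharyya", "extratrees", "lasso")

_VAR_FLOOR = 1e-8


@dataclass
class FeatureScores:
    """Per-feature relevance scores; higher means more relevant."""

    scores: np.ndarray
    method: str
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.scores.shape != self.valid_mask.shape:
            raise DataError("scores / valid_mask shape mismatch")


@dataclass(frozen=True)
class FeatureSet:
    """An ordered list of selected feature names."""

    names: tuple[str, ...]
    N: int

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise DataError("duplicate names in FeatureSet")

    def as_set(self) -> frozenset[str]:
        return frozenset(self.names)


def _split_classes(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    g0, g1 = table.X[table.y == 0], table.X[table.y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise DataError("both classes need at least 2 samples for scoring")
    return g0, g1


def anova_f(table: FeatureTable) -> FeatureScores:
    """One-way F statistic between the two classes, per feature.

    ``F = MS_between / MS_within``. A feature with zero within-class
    variance but a nonzero class shift gets ``+inf`` so it ranks above any
    finite score; zero shift with zero variance scores 0.
    """
    g0, g1 = _split_classes(table)
    n0, n1 = len(g0), len(g1)
    n = n0 + n1
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    grand = table.X.mean(axis=0)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_within = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    ms_between = ss_between / 1.0
    ms_within = ss_within / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f = np.where((ms_within == 0) & (ms_between > 0), np.inf, f)
    f = np.where((ms_within == 0) & (ms_between == 0), 0.0, f)
    return FeatureScores(f, "anova", np.isfinite(f) | np.isinf(f))


def bhattacharyya(table: FeatureTable) -> FeatureScores:
    """Gaussian Bhattacharyya distance between the class distributions.

    ``D = (mu1 - mu2)^2 / (4 (s1^2 + s2^2)) + 0.5 ln((s1^2 + s2^2) / (2 s1 s2))``.
    Zero class variances are floored at 1e-8 with a warning.
    """
    g0, g1 = _split_classes(table)
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    v0 = g0.var(axis=0, ddof=1)
    v1 = g1.var(axis=0, ddof=1)
    if (v0 < _VAR_FLOOR).any() or (v1 < _VAR_FLOOR).any():
        warnings.warn("bhattacharyya: zero class variance floored", stacklevel=2)
    v0 = np.maximum(v0, _VAR_FLOOR)
    v1 = np.maximum(v1, _VAR_FLOOR)
    d = 0.25 * (m0 - m1) ** 2 / (v0 + v1) + 0.5 * np.log(
        (v0 + v1) / (2.0 * np.sqrt(v0 * v1))
    )
    return FeatureScores(d, "bhattacharyya", np.ones(table.d, dtype=bool))


def extratrees_importance(
    table: FeatureTable, n_trees: int = 250, seed: int = 0
) -> FeatureScores:
    """Mean impurity-decrease importance of an extra-trees ensemble.

    Scores are nonnegative and sum to 1 (sklearn normalization).
    """
    est = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(table.X, table.y)
    imp = est.feature_importances_
    return FeatureScores(imp, "extratrees", np.ones(table.d, dtype=bool))


def lasso_scores(
    table: FeatureTable, regularization: float = 1.0, max_iter: int = 2000
) -> FeatureScores:
    """Absolute coefficients of an L1-penalized logistic model.

    ``regularization`` is sklearn's inverse penalty C. Non-convergence
    triggers one retry with a 5x iteration budget, then a warning with the
    partial result.
    """
    for budget in (max_iter, 5 * max_iter):
        model = LogisticRegression(
            penalty="l1", solver="liblinear", C=regularization,
            max_iter=budget, tol=1e-8, random_state=0,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(table.X, table.y)
        converged = not any("onverge" in str(w.message) for w in caught)
        if converged:
            break
    if not converged:
        warnings.warn("lasso_scores: optimizer did not converge; returning "
                      "partial result", stacklevel=2)
    coefs = np.abs(model.coef_.ravel())
    return FeatureScores(coefs, "lasso", np.ones(table.d, dtype=bool))


def select_top(scores: FeatureScores, N: int, feature_names: list[str]) -> FeatureSet:
    """The N highest-scoring valid features; ties break toward lower index."""
    if N < 1:
        raise ConfigError("N must be >= 1")
    d = len(scores.scores)
    if len(feature_names) != d:
        raise DataError("feature_names length mismatch")
    key = np.where(scores.valid_mask, scores.scores, -np.inf)
    order = np.argsort(-key, kind="stable")  # stable: ties keep ascending index
    take = order[: min(N, d)]
    return FeatureSet(tuple(feature_names[j] for j in take), N=N)


def score_features(table: FeatureTable, method: str, seed: int = 0,
                   **kwargs) -> FeatureScores:
    """Dispatch to one of the four scorers by name."""
    if method == "anova":
        return anova_f(table)
    if method == "bhattacharyya":
        return bhattacharyya(table)
    if method == "extratrees":
        return extratrees_importance(table, seed=seed, **kwargs)
    if method == "lasso":
        return lasso_scores(table, **kwargs)
    raise ConfigError(f"unknown selector {method!r}; known: {SELECTORS}")
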