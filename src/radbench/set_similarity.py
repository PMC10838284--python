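"""Feature-set agreement and correlation-aware similarity.

Two selected feature sets can disagree completely (Jaccard 0) yet carry the
same information because the features are strongly correlated. Agreement is
measured set-theoretically (Jaccard, Ochiai); similarity additionally uses
the feature correlation matrix: the symmetrized mean of each feature's best
absolute correlation in the other set, and the Zucknick measure, a
correlation-corrected Jaccard index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .datasets import FeatureTable
from .errors import ConfigError, DataError
from .feature_selection import FeatureSet

__all__ = [
    "CorrelationMatrix",
    "correlation_matrix",
    "jaccard",
    "ochiai",
    "max_corr_similarity",
    "zucknick",
    "pairwise_agreement",
]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Pearson feature correlations."""

    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        d = len(self.feature_names)
        if self.matrix.shape != (d, d):
            raise DataError("correlation matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise DataError("correlation matrix not symmetric")
        self._index = {f: j for j, f in enumerate(self.feature_names)}

    def lookup(self, names: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[f] for f in names], dtype=int)
        except KeyError as exc:
            raise DataError(f"feature {exc.args[0]!r} not in correlation "
                            "matrix") from exc


def correlation_matrix(table: FeatureTable) -> CorrelationMatrix:
    """Pearson correlations of the table's features (constant columns -> 0)."""
    if np.isnan(table.X).any():
        raise DataError("correlation matrix requires complete data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.corrcoef(table.X, rowvar=False)
    R = np.atleast_2d(R)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R, list(table.feature_names))


def _names(s: FeatureSet | Iterable[str]) -> frozenset[str]:
    if isinstance(s, FeatureSet):
        return s.as_set()
    return frozenset(s)


def jaccard(A: FeatureSet | Iterable[str], B: FeatureSet | Iterable[str]) -> float:
    """|A n B| / |A u B|; two empty sets agree perfectly (1.0, with warning)."""
    a, b = _names(A), _names(B)
    if not a and not b:
        warnings.warn("jaccard of two empty sets defined as 1.0", stacklevel=2)
        return 1.0
    return len(a & b) / len(a | b)


def ochiai(A: FeatureSet | Iterable[str], B: FeatureSet | Iterable[str]) -> float:
    """|A n B| / sqrt(|A| |B|), the cosine-type set agreement."""
    a, b = _names(A), _names(B)
    if not a or not b:
        raise DataError("ochiai requires nonempty sets")
    return len(a & b) / float(np.sqrt(len(a) * len(b)))


def max_corr_similarity(
    A: FeatureSet | Iterable[str],
    B: FeatureSet | Iterable[str],
    R: CorrelationMatrix,
) -> float:
    """Symmetrized mean best absolute correlation between the two sets.

    ``s(A->B) = mean over a in A of max over b in B of |R(a, b)|``; the
    similarity is ``(s(A->B) + s(B->A)) / 2``, in [0, 1], and equals 1
    whenever A = B.
    """
    a, b = _names(A), _names(B)
    if not a or not b:
        raise DataError("max_corr_similarity requires nonempty sets")
    ia, ib = R.lookup(sorted(a)), R.lookup(sorted(b))
    sub = np.abs(R.matrix[np.ix_(ia, ib)])
    s_ab = sub.max(axis=1).mean()
    s_ba = sub.max(axis=0).mean()
    return float(0.5 * (s_ab + s_ba))


def zucknick(
    A: FeatureSet | Iterable[str],
    B: FeatureSet | Iterable[str],
    R: CorrelationMatrix,
    threshold: float = 0.8,
) -> float:
    """Correlation-corrected Jaccard index.

    ``S = (|A n B| + C(A, B) + C(B, A)) / |A u B|`` where
    ``C(X, Y) = (1/|Y|) * sum over x in X\\Y, y in Y of |R(x, y)|`` counting
    only entries with ``|R| >= threshold``; clipped to [0, 1].
    """
    if not (0 < threshold <= 1):
        raise ConfigError("threshold must be in (0, 1]")
    a, b = _names(A), _names(B)
    if not a or not b:
        raise DataError("zucknick requires nonempty sets")

    def corr_credit(x_set: frozenset[str], y_set: frozenset[str]) -> float:
        extra = sorted(x_set - y_set)
        if not extra:
            return 0.0
        ix = R.lookup(extra)
        iy = R.lookup(sorted(y_set))
        sub = np.abs(R.matrix[np.ix_(ix, iy)])
        sub = np.where(sub >= threshold, sub, 0.0)
        return float(sub.sum() / len(y_set))

    s = (len(a & b) + corr_credit(a, b) + corr_credit(b, a)) / len(a | b)
    return float(np.clip(s, 0.0, 1.0))


def pairwise_agreement(
    feature_sets: Mapping[tuple[str, object], FeatureSet],
    metric: str = "jaccard",
    R: CorrelationMatrix | Mapping[object, CorrelationMatrix] | None = None,
    zucknick_threshold: float = 0.8,
) -> tuple[list[str], np.ndarray]:
    """Mean pairwise agreement of methods' selected sets across folds.

    ``feature_sets`` maps ``(method, fold_key)`` to the FeatureSet the
    method's best model selected on that fold. All methods must cover the
    same fold keys. ``R`` is a single correlation matrix or a per-fold-key
    mapping; it is required for the correlation-aware metrics. Returns the
    sorted method list and the symmetric matrix of fold-averaged values
    (unit diagonal).
    """
    methods = sorted({m for m, _ in feature_sets})
    folds_per_method = {
        m: {f for mm, f in feature_sets if mm == m} for m in methods
    }
    folds = folds_per_method[methods[0]]
    for m in methods[1:]:
        if folds_per_method[m] != folds:
            raise DataError(f"method {m!r} does not cover the same folds")
    fold_keys = sorted(folds, key=repr)

    def metric_fn(A, B, fold_key):
        if metric == "jaccard":
            return jaccard(A, B)
        if metric == "ochiai":
            return ochiai(A, B)
        Rf = R[fold_key] if isinstance(R, Mapping) else R
        if Rf is None:
            raise ConfigError(f"metric {metric!r} needs a correlation matrix")
        if metric == "maxcorr":
            return max_corr_similarity(A, B, Rf)
        if metric == "zucknick":
            return zucknick(A, B, Rf, zucknick_threshold)
        raise ConfigError(f"unknown metric {metric!r}")

    k = len(methods)
    M = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals = [
                metric_fn(feature_sets[(methods[i], f)],
                          feature_sets[(methods[j], f)], f)
                for f in fold_keys
            ]
            M[i, j] = M[j, i] = float(np.mean(vals))
    return methods, M
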