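"""Cross-dataset comparison statistics for resampling methods.

Works on a method-by-dataset matrix of best-model scores (rows = datasets,
columns = methods): gains against a baseline, mean ranks with mid-rank
ties, pairwise win-loss counts with half-point draws, the Friedman rank
test with tie correction, and the Nemenyi post hoc on the Studentized
range distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, studentized_range

from .errors import ConfigError, DataError

__all__ = [
    "gains_vs_baseline",
    "rank_matrix",
    "win_loss",
    "friedman",
    "nemenyi",
]


def _as_frame(M) -> pd.DataFrame:
    df = pd.DataFrame(M)
    if df.isna().any().any():
        raise DataError("method-by-dataset matrix has missing entries")
    return df.astype(float)


def gains_vs_baseline(M: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Per method: mean and maximum (over datasets) gain vs. the baseline.

    The mean gain is the average of ``method - baseline`` across datasets;
    the max gain is the largest such difference seen on any single dataset.
    """
    df = _as_frame(M)
    if baseline not in df.columns:
        raise ConfigError(f"baseline {baseline!r} not a column of the matrix")
    diffs = df.sub(df[baseline], axis=0)
    return pd.DataFrame({
        "mean_gain": diffs.mean(axis=0),
        "max_gain": diffs.max(axis=0),
    })


def rank_matrix(M: pd.DataFrame) -> pd.DataFrame:
    """Within-dataset ranks, 1 = best (highest score); ties get mid-ranks."""
    df = _as_frame(M)
    ranks = df.rank(axis=1, ascending=False, method="average")
    return ranks


def win_loss(M: pd.DataFrame) -> pd.DataFrame:
    """Pairwise wins across datasets; a draw contributes 0.5 to both sides.

    Entry (i, j) counts datasets where method i strictly beats method j,
    plus half the exact draws, so (i, j) + (j, i) equals the number of
    datasets for every pair. The diagonal is n/2 (a method always draws
    with itself).
    """
    df = _as_frame(M)
    cols = list(df.columns)
    n = len(df)
    W = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            wins = (df[ci] > df[cj]).sum()
            draws = (df[ci] == df[cj]).sum()
            W.iloc[i, j] = wins + 0.5 * draws
    return W


def _mean_ranks(df: pd.DataFrame) -> tuple[np.ndarray, float]:
    """(column mean ranks, tie-correction factor C)."""
    n, k = df.shape
    ranks = np.vstack([rankdata(-row) for row in df.to_numpy()])
    tie_sum = 0.0
    for row in df.to_numpy():
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    C = 1.0 - tie_sum / (n * k * (k**2 - 1))
    return ranks.mean(axis=0), C


def friedman(M: pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square test across datasets (blocks) and methods.

    ``chi2_F = 12 n / (k (k + 1)) * sum_j (Rbar_j - (k + 1) / 2)^2``,
    divided by the mid-rank tie correction
    ``C = 1 - sum(t^3 - t) / (n k (k^2 - 1))``. Completely tied data
    (every row constant) degenerates to statistic 0, p = 1.
    """
    df = _as_frame(M)
    n, k = df.shape
    if n < 2 or k < 2:
        raise DataError("friedman needs >= 2 datasets and >= 2 methods")
    mean_ranks, C = _mean_ranks(df)
    stat = 12.0 * n / (k * (k + 1)) * float(
        ((mean_ranks - (k + 1) / 2.0) ** 2).sum()
    )
    if C == 0.0:
        return 0.0, 1.0
    stat /= C
    p = float(chi2.sf(stat, k - 1))
    return float(stat), p


def nemenyi(M: pd.DataFrame) -> pd.DataFrame:
    """Pairwise post hoc p-values after Friedman.

    For methods i, j the standardized mean-rank difference
    ``q = |Rbar_i - Rbar_j| / sqrt(k (k + 1) / (12 n))`` is referred to the
    Studentized range distribution with k groups and infinite degrees of
    freedom. Symmetric with a unit diagonal.
    """
    df = _as_frame(M)
    n, k = df.shape
    if n < 2 or k < 2:
        raise DataError("nemenyi needs >= 2 datasets and >= 2 methods")
    mean_ranks, _ = _mean_ranks(df)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    cols = list(df.columns)
    P = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(np.clip(studentized_range.sf(q, k, np.inf), 0.0, 1.0))
            P.iloc[i, j] = P.iloc[j, i] = p
    return P
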