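"""Independent brute-force oracles for the neighbor-based resamplers.

Deliberately naive O(n^2)/O(n^3) enumerations that share no code with the
package implementation; used only to verify removal sets on tiny instances.
"""

from __future__ import annotations

import numpy as np


def _neighbors_bruteforce(X: np.ndarray, i: int, k: int) -> list[int]:
    """Indices of the k nearest samples to i (self excluded), ties by index."""
    order = sorted(
        (float(np.sqrt(((X[i] - X[j]) ** 2).sum())), j)
        for j in range(len(X)) if j != i
    )
    return [j for _, j in order[:k]]


def _enn_vote_removals(X: np.ndarray, y: np.ndarray, maj: int, k: int) -> set[int]:
    """Raw edit set: majority rows whose k-NN vote disagrees with their label."""
    removals = set()
    for i in range(len(X)):
        if y[i] != maj:
            continue
        nb = _neighbors_bruteforce(X, i, k)
        disagree = sum(1 for j in nb if y[j] != maj)
        if 2 * disagree > k:
            removals.add(i)
    return removals


def enn_removals_oracle(X: np.ndarray, y: np.ndarray, maj: int, k: int) -> set[int]:
    """Single-pass ENN with its guard: the edit never empties the majority
    class — the highest-index candidate survives."""
    removals = _enn_vote_removals(X, y, maj, k)
    n_maj = sum(1 for v in y if v == maj)
    if len(removals) == n_maj:
        removals.discard(max(removals))
    return removals


def all_knn_kept_oracle(X: np.ndarray, y: np.ndarray, maj: int,
                        k_max: int) -> list[int]:
    """Sequential ENN for k = 1..k_max on the shrinking instance."""
    kept = list(range(len(X)))
    for k in range(1, k_max + 1):
        Xc, yc = X[kept], y[kept]
        rem_local = _enn_vote_removals(Xc, yc, maj, k)
        n_maj = sum(1 for v in yc if v == maj)
        if len(rem_local) >= n_maj:
            break
        kept = [g for pos, g in enumerate(kept) if pos not in rem_local]
    return kept


def tomek_removals_oracle(X: np.ndarray, y: np.ndarray, maj: int) -> set[int]:
    """Majority members of cross-class mutual-nearest-neighbor pairs."""
    n = len(X)
    nn = [_neighbors_bruteforce(X, i, 1)[0] for i in range(n)]
    removals = set()
    for a in range(n):
        b = nn[a]
        if nn[b] == a and y[a] != y[b]:
            removals.add(a if y[a] == maj else b)
    return removals


def auc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordant-pair count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def majority_label(y: np.ndarray) -> int:
    n_pos = int((np.asarray(y) == 1).sum())
    n_neg = len(y) - n_pos
    return 1 if n_pos > n_neg else 0
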