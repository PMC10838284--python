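"""Class-balancing resamplers implemented from first principles.

Nine methods, three families:

* oversampling — random oversampling, SMOTE, SVM-SMOTE — grow the minority
  class until the classes are equal;
* undersampling — random undersampling, Edited Nearest Neighbours (ENN),
  All k-NN, Tomek links — shrink or clean the majority class;
* combined — SMOTE + ENN, SMOTE + Tomek — oversample first, then clean.

All distances are Euclidean (the pipeline feeds z-scored features), all
nearest-neighbour ties break toward the lower sample index, and every
method is a pure function of ``(table, spec)``: the same inputs produce
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.svm import SVC

from .datasets import FeatureTable
from .errors import ConfigError, DataError

__all__ = [
    "ResamplerSpec",
    "ResampleResult",
    "resample",
    "resampler_grid",
    "random_undersample",
    "random_oversample",
    "smote",
    "svm_smote",
    "edited_nn",
    "all_knn",
    "tomek_links",
]

#: methods that take a neighborhood size k
_K_METHODS = {"smote", "svm_smote", "all_knn", "smote_tomek", "smote_enn"}
VALID_METHODS = (
    "none", "random_under", "random_over", "smote", "svm_smote",
    "enn", "all_knn", "tomek", "smote_enn", "smote_tomek",
)


@dataclass(frozen=True)
class ResamplerSpec:
    """One resampling configuration: method name, neighborhood size, seed."""

    method: str
    k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ConfigError(f"unknown resampling method {self.method!r}")
        if self.method in _K_METHODS:
            if self.k not in (3, 5, 7):
                raise ConfigError(f"{self.method} requires k in {{3, 5, 7}}")
        elif self.method == "enn":
            if self.k not in (None, 3):
                raise ConfigError("enn uses a fixed neighborhood of 3")
        elif self.k is not None:
            raise ConfigError(f"{self.method} takes no k parameter")

    @property
    def label(self) -> str:
        if self.method == "enn":
            return "enn(k=3)"
        if self.method in _K_METHODS:
            return f"{self.method}(k={self.k})"
        return self.method


@dataclass
class ResampleResult:
    """Output of one resampling step.

    ``kept_indices`` are positions (into the input table) of the original
    rows retained, in their output order; synthetic rows are appended after
    them with fresh sample ids.
    """

    table: FeatureTable
    kept_indices: np.ndarray
    n_synthetic: int
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _class_split(y: np.ndarray) -> tuple[int, int]:
    """(majority_label, minority_label); a tie makes 0 the majority."""
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("resampling requires both classes present")
    return (1, 0) if n_pos > n_neg else (0, 1)


def _check_input(table: FeatureTable) -> None:
    if np.isnan(table.X).any():
        raise DataError("resampling requires a table without missing values")


def _neighbor_order(dists: np.ndarray) -> np.ndarray:
    """Indices sorted by (distance, index) — stable sort breaks ties low."""
    return np.argsort(dists, kind="stable")


def _result_from_rows(
    table: FeatureTable,
    kept: np.ndarray,
    synth_X: np.ndarray | None,
    synth_label: int | None,
    log: list[str],
) -> ResampleResult:
    kept = np.asarray(sorted(kept), dtype=int)
    X = table.X[kept]
    y = table.y[kept]
    ids = [table.sample_ids[i] for i in kept]
    n_syn = 0
    if synth_X is not None and len(synth_X):
        n_syn = len(synth_X)
        X = np.vstack([X, synth_X])
        y = np.concatenate([y, np.full(n_syn, synth_label, dtype=int)])
        ids = ids + [f"syn_{i:05d}" for i in range(n_syn)]
    out = FeatureTable(X, y, list(table.feature_names), ids, table.provenance)
    return ResampleResult(out, kept, n_syn, log)


def _identity(table: FeatureTable, log: list[str]) -> ResampleResult:
    return _result_from_rows(table, np.arange(table.n), None, None, log)


# ---------------------------------------------------------------------------
# random under/over
# ---------------------------------------------------------------------------

def random_undersample(table: FeatureTable, seed: int = 0) -> ResampleResult:
    """Drop majority rows uniformly at random until the classes are equal."""
    _check_input(table)
    maj, mino = _class_split(table.y)
    maj_idx = np.flatnonzero(table.y == maj)
    min_idx = np.flatnonzero(table.y == mino)
    if len(maj_idx) == len(min_idx):
        return _identity(table, ["random_under: already balanced"])
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
    kept = np.concatenate([keep_maj, min_idx])
    return _result_from_rows(
        table, kept, None, None,
        [f"random_under: removed {len(maj_idx) - len(min_idx)} majority rows"],
    )


def random_oversample(table: FeatureTable, seed: int = 0) -> ResampleResult:
    """Duplicate minority rows (sampled with replacement) until equal counts."""
    _check_input(table)
    maj, mino = _class_split(table.y)
    maj_idx = np.flatnonzero(table.y == maj)
    min_idx = np.flatnonzero(table.y == mino)
    need = len(maj_idx) - len(min_idx)
    if need == 0:
        return _identity(table, ["random_over: already balanced"])
    rng = np.random.default_rng(seed)
    picks = rng.choice(min_idx, size=need, replace=True)
    synth = table.X[picks].copy()
    return _result_from_rows(
        table, np.arange(table.n), synth, mino,
        [f"random_over: duplicated {need} minority rows"],
    )


# ---------------------------------------------------------------------------
# SMOTE family
# ---------------------------------------------------------------------------

def _smote_points(
    X_min: np.ndarray,
    seeds_order: np.ndarray,
    k: int,
    need: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``need`` interpolated points.

    ``seeds_order`` is a permuted list of row indices into ``X_min`` cycled
    round-robin, so each minority point contributes floor(need/m) or
    ceil(need/m) synthetics. A neighbor is drawn uniformly from the seed's
    k nearest minority neighbors (excluding itself, k capped at m - 1) and
    the point is ``x + u * (x' - x)`` with u ~ Uniform(0, 1).
    """
    m = len(X_min)
    k_eff = min(k, m - 1)
    D = squareform(pdist(X_min))
    np.fill_diagonal(D, np.inf)
    nn = np.stack([_neighbor_order(D[i])[:k_eff] for i in range(m)])
    out = np.empty((need, X_min.shape[1]))
    for t in range(need):
        i = seeds_order[t % m]
        j = nn[i, rng.integers(k_eff)]
        u = rng.uniform()
        out[t] = X_min[i] + u * (X_min[j] - X_min[i])
    return out


def smote(table: FeatureTable, k: int = 5, seed: int = 0) -> ResampleResult:
    """Synthetic Minority Oversampling: interpolate between minority neighbors."""
    _check_input(table)
    maj, mino = _class_split(table.y)
    maj_idx = np.flatnonzero(table.y == maj)
    min_idx = np.flatnonzero(table.y == mino)
    need = len(maj_idx) - len(min_idx)
    if need == 0:
        return _identity(table, ["smote: already balanced"])
    if len(min_idx) < 2:
        warnings.warn("smote: minority class of size 1; falling back to "
                      "random oversampling", stacklevel=2)
        res = random_oversample(table, seed)
        res.log.insert(0, "smote: fallback to random_over (minority size 1)")
        return res
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(min_idx))
    synth = _smote_points(table.X[min_idx], order, k, need, rng)
    return _result_from_rows(
        table, np.arange(table.n), synth, mino,
        [f"smote: k={k}, generated {need} synthetic minority rows"],
    )


def svm_smote(
    table: FeatureTable,
    k: int = 5,
    seed: int = 0,
    m_neighbors: int = 10,
    C: float = 1.0,
) -> ResampleResult:
    """SMOTE seeded at the minority support vectors of a soft-margin RBF SVM.

    For each support-vector seed, its ``m_neighbors`` nearest neighbors
    among all samples decide the branch: a majority-dominated neighborhood
    ("danger") interpolates toward a nearby minority neighbor, otherwise
    the point extrapolates outward beyond the seed, away from the neighbor.
    """
    from .classifiers import rbf_gamma  # local import avoids a cycle

    _check_input(table)
    maj, mino = _class_split(table.y)
    maj_idx = np.flatnonzero(table.y == maj)
    min_idx = np.flatnonzero(table.y == mino)
    need = len(maj_idx) - len(min_idx)
    if need == 0:
        return _identity(table, ["svm_smote: already balanced"])
    if len(min_idx) < 2:
        warnings.warn("svm_smote: minority class of size 1; falling back to "
                      "random oversampling", stacklevel=2)
        res = random_oversample(table, seed)
        res.log.insert(0, "svm_smote: fallback to random_over (minority size 1)")
        return res

    gamma = rbf_gamma(table)
    svc = SVC(C=C, kernel="rbf", gamma=gamma, random_state=0)
    svc.fit(table.X, table.y)
    sv_rows = np.asarray(svc.support_, dtype=int)
    sv_min = np.array([i for i in sv_rows if table.y[i] == mino], dtype=int)
    if sv_min.size == 0:
        warnings.warn("svm_smote: no minority support vectors; falling back "
                      "to smote", stacklevel=2)
        res = smote(table, k=k, seed=seed)
        res.log.insert(0, "svm_smote: fallback to smote (no minority SVs)")
        return res

    rng = np.random.default_rng(seed)
    X = table.X
    X_min = X[min_idx]
    m_eff = min(m_neighbors, table.n - 1)
    k_eff = min(k, len(min_idx) - 1)

    # per-seed nearest minority neighbors (excluding the seed itself)
    D_min = cdist(X[sv_min], X_min)
    min_pos = {int(g): p for p, g in enumerate(min_idx)}
    for r, i in enumerate(sv_min):
        D_min[r, min_pos[int(i)]] = np.inf
    nn_min = np.stack([_neighbor_order(D_min[r])[:k_eff] for r in range(len(sv_min))])

    # danger flag: more than half of the m nearest overall neighbors are majority
    D_all = cdist(X[sv_min], X)
    for r, i in enumerate(sv_min):
        D_all[r, i] = np.inf
    danger = np.empty(len(sv_min), dtype=bool)
    for r in range(len(sv_min)):
        nb = _neighbor_order(D_all[r])[:m_eff]
        danger[r] = (table.y[nb] == maj).sum() * 2 > m_eff

    order = rng.permutation(len(sv_min))
    synth = np.empty((need, table.d))
    n_interp = 0
    for t in range(need):
        r = order[t % len(sv_min)]
        x = X[sv_min[r]]
        xn = X_min[nn_min[r, rng.integers(k_eff)]]
        u = rng.uniform()
        if danger[r]:
            synth[t] = x + u * (xn - x)
            n_interp += 1
        else:
            synth[t] = x + u * (x - xn)
    return _result_from_rows(
        table, np.arange(table.n), synth, mino,
        [f"svm_smote: k={k}, seeds={len(sv_min)} minority SVs, "
         f"interpolated={n_interp}, extrapolated={need - n_interp}"],
    )


# ---------------------------------------------------------------------------
# cleaning undersamplers
# ---------------------------------------------------------------------------

def _enn_removals(X: np.ndarray, y: np.ndarray, maj: int, k: int) -> np.ndarray:
    """Majority rows whose k nearest neighbors vote against their label."""
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    removals = []
    for i in np.flatnonzero(y == maj):
        nb = _neighbor_order(D[i])[:k]
        disagree = int((y[nb] != maj).sum())
        if 2 * disagree > k:
            removals.append(i)
    return np.asarray(removals, dtype=int)


def edited_nn(table: FeatureTable, k: int = 3) -> ResampleResult:
    """Edited Nearest Neighbours: one cleaning pass over the majority class.

    A majority sample is removed when the majority vote of its k nearest
    neighbors (any class, Euclidean) disagrees with its label. Minority
    samples are never touched. If the pass would empty the majority class,
    the highest-index majority sample is kept and a warning emitted.
    """
    _check_input(table)
    if table.n <= k:
        raise DataError(f"edited_nn requires n > k (n={table.n}, k={k})")
    maj, _ = _class_split(table.y)
    removals = _enn_removals(table.X, table.y, maj, k)
    maj_idx = np.flatnonzero(table.y == maj)
    if len(removals) == len(maj_idx):
        warnings.warn("edited_nn would remove the entire majority class; "
                      "keeping one sample", stacklevel=2)
        removals = removals[:-1]
    kept = np.setdiff1d(np.arange(table.n), removals)
    return _result_from_rows(
        table, kept, None, None,
        [f"enn: k={k}, removed {len(removals)} majority rows"],
    )


def all_knn(table: FeatureTable, k_max: int = 3) -> ResampleResult:
    """Iterated ENN for k = 1, 2, ..., k_max on the shrinking table.

    The majority label is fixed at entry. An iteration whose edit would
    remove every remaining majority sample is skipped and the procedure
    stops early.
    """
    _check_input(table)
    if table.n <= k_max:
        raise DataError(f"all_knn requires n > k_max (n={table.n}, k_max={k_max})")
    maj, _ = _class_split(table.y)
    kept = np.arange(table.n)
    log: list[str] = []
    for k in range(1, k_max + 1):
        X, y = table.X[kept], table.y[kept]
        removals_local = _enn_removals(X, y, maj, k)
        n_maj = int((y == maj).sum())
        if len(removals_local) >= n_maj:
            log.append(f"all_knn: k={k} would empty the majority class; stopped")
            break
        kept = np.delete(kept, removals_local)
        log.append(f"all_knn: k={k}, removed {len(removals_local)} rows")
    return _result_from_rows(table, kept, None, None, log)


def tomek_links(table: FeatureTable) -> ResampleResult:
    """Remove the majority member of every cross-class mutual-NN pair."""
    _check_input(table)
    maj, _ = _class_split(table.y)
    D = squareform(pdist(table.X))
    np.fill_diagonal(D, np.inf)
    nn = np.array([_neighbor_order(D[i])[0] for i in range(table.n)])
    removals = set()
    for a in range(table.n):
        b = nn[a]
        if b > a and nn[b] == a and table.y[a] != table.y[b]:
            removals.add(a if table.y[a] == maj else int(b))
    kept = np.setdiff1d(np.arange(table.n), sorted(removals))
    return _result_from_rows(
        table, kept, None, None,
        [f"tomek: removed {len(removals)} majority rows from links"],
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def resample(table: FeatureTable, spec: ResamplerSpec) -> ResampleResult:
    """Apply one resampling method; combined methods run SMOTE then cleaning."""
    _check_input(table)
    if spec.method == "none":
        return _identity(table, ["none"])
    if spec.method == "random_under":
        return random_undersample(table, spec.seed)
    if spec.method == "random_over":
        return random_oversample(table, spec.seed)
    if spec.method == "smote":
        return smote(table, k=spec.k, seed=spec.seed)
    if spec.method == "svm_smote":
        return svm_smote(table, k=spec.k, seed=spec.seed)
    if spec.method == "enn":
        return edited_nn(table, k=3)
    if spec.method == "all_knn":
        return all_knn(table, k_max=spec.k)
    if spec.method == "tomek":
        return tomek_links(table)
    if spec.method in ("smote_enn", "smote_tomek"):
        stage1 = smote(table, k=spec.k, seed=spec.seed)
        clean = edited_nn if spec.method == "smote_enn" else tomek_links
        stage2 = clean(stage1.table) if spec.method == "smote_tomek" \
            else edited_nn(stage1.table, k=3)
        # map stage-2 kept positions back through stage 1
        kept2 = stage2.kept_indices
        orig_kept = np.array(
            [stage1.kept_indices[i] for i in kept2 if i < len(stage1.kept_indices)],
            dtype=int,
        )
        n_syn = int((kept2 >= len(stage1.kept_indices)).sum())
        return ResampleResult(stage2.table, orig_kept, n_syn,
                              stage1.log + stage2.log)
    raise ConfigError(f"unknown resampling method {spec.method!r}")


def resampler_grid(
    smote_enn_ks: tuple[int, ...] = (3, 5),
    seed: int = 0,
) -> list[ResamplerSpec]:
    """The benchmark's full resampler grid (19 method variants).

    The SMOTE-stage neighborhood of SMOTE+ENN defaults to {3, 5} while all
    other SMOTE-based methods use {3, 5, 7}; ENN-based cleaning always uses
    a neighborhood of 3, which avoids wiping out small minority classes.
    """
    grid: list[ResamplerSpec] = [
        ResamplerSpec("none", seed=seed),
        ResamplerSpec("random_under", seed=seed),
        ResamplerSpec("random_over", seed=seed),
    ]
    grid += [ResamplerSpec("smote", k=k, seed=seed) for k in (3, 5, 7)]
    grid += [ResamplerSpec("svm_smote", k=k, seed=seed) for k in (3, 5, 7)]
    grid += [ResamplerSpec("enn", k=3, seed=seed)]
    grid += [ResamplerSpec("all_knn", k=k, seed=seed) for k in (3, 5, 7)]
    grid += [ResamplerSpec("tomek", seed=seed)]
    grid += [ResamplerSpec("smote_enn", k=k, seed=seed) for k in smote_enn_ks]
    grid += [ResamplerSpec("smote_tomek", k=k, seed=seed) for k in (3, 5, 7)]
    return grid
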