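"""Synthetic radiomics-like data: imbalanced, high-dimensional, block-correlated.

Real radiomic feature tables are high-dimensional (often more features than
samples), strongly inter-correlated in groups (many texture features measure
overlapping image properties), class-imbalanced, and occasionally carry a
sprinkle of missing cells. The generator here reproduces exactly those
statistical traits with a tractable analytic oracle:

* features come in consecutive equicorrelated Gaussian blocks
  (pairwise correlation ``rho`` within a block, independence across blocks),
* a small number of *informative* features — by default one per block —
  carry a class-conditional mean shift ``delta`` in standardized units
  (Cohen's d scale),
* class sizes are fixed counts taken from a :class:`DatasetProfile`,
* a fraction of cells is deleted completely at random.

Because the marginal distribution of each informative feature is
``N(0, 1)`` vs ``N(delta, 1)``, the AUC attainable from the informative
coordinates alone has the closed form ``Phi(delta * sqrt(k) / sqrt(2))``,
which serves as the recovery oracle for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .datasets import DatasetProfile, FeatureTable
from .errors import ConfigError, DataError

__all__ = [
    "SynthSpec",
    "table1_profiles",
    "get_profile",
    "balance_ratio",
    "generate",
    "bayes_auc",
]

# Built-in benchmark dataset profiles: (name, n, d, n_pos, n_neg, B, modality).
# Shapes of fifteen public radiomic datasets spanning n in [51, 922],
# d in [118, 7106] and majority/minority balance B in [1.0, 4.0].
_PROFILE_ROWS: tuple[tuple[str, int, int, int, int, float, str], ...] = (
    ("Arita2018", 168, 685, 111, 57, 1.9, "MRI"),
    ("Carvalho2018", 262, 118, 154, 108, 1.4, "FDG+PET"),
    ("Hosny2018A", 293, 985, 159, 134, 1.2, "CT"),
    ("Hosny2018B", 211, 1005, 60, 151, 2.5, "CT"),
    ("Hosny2018C", 183, 1005, 133, 50, 2.7, "CT"),
    ("Ramella2018", 91, 243, 50, 41, 1.2, "CT"),
    ("Saha2018", 922, 530, 327, 595, 1.8, "DCE-MRI"),
    ("Lu2019", 213, 658, 91, 122, 1.3, "CT"),
    ("Sasaki2019", 138, 588, 68, 70, 1.0, "MRI"),
    ("Toivonen2019", 100, 7106, 80, 20, 4.0, "MRI"),
    ("Keek2020", 273, 1323, 119, 154, 1.3, "CT"),
    ("Li2020", 51, 397, 32, 19, 1.7, "MRI"),
    ("Park2020", 768, 941, 183, 585, 3.2, "US"),
    ("Song2020", 260, 265, 127, 133, 1.0, "MRI"),
    ("Veeraraghavan2020", 150, 201, 47, 103, 2.2, "DCE-MRI"),
)


def table1_profiles() -> list[DatasetProfile]:
    """The 15 built-in benchmark dataset profiles."""
    return [
        DatasetProfile(name=r[0], n=r[1], d=r[2], n_pos=r[3], n_neg=r[4],
                       balance=r[5], modality=r[6])
        for r in _PROFILE_ROWS
    ]


def get_profile(name: str) -> DatasetProfile:
    for p in table1_profiles():
        if p.name == name:
            return p
    raise ConfigError(f"unknown profile {name!r}; known: "
                      f"{[r[0] for r in _PROFILE_ROWS]}")


def balance_ratio(profile: DatasetProfile) -> float:
    """Majority/minority class-size ratio B = max/min >= 1."""
    if min(profile.n_pos, profile.n_neg) < 1:
        raise DataError(f"{profile.name}: zero class count")
    return max(profile.n_pos, profile.n_neg) / min(profile.n_pos, profile.n_neg)


@dataclass(frozen=True)
class SynthSpec:
    """Full specification of one synthetic dataset.

    Defaults reflect what is typical for radiomic tables: strong
    within-block correlation (``rho = 0.8`` over blocks of 10 features),
    a handful of informative features with a moderate standardized shift,
    and sparse (< 1%) missingness.
    """

    profile: DatasetProfile
    n_informative: int = 1
    effect_size: float = 2.0
    block_size: int = 10
    within_block_corr: float = 0.8
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_informative <= self.profile.d):
            raise ConfigError("n_informative must be in [0, d]")
        if not (0 <= self.missing_rate < 0.05):
            raise ConfigError("missing_rate must be in [0, 0.05)")
        if not (0 <= self.within_block_corr < 1):
            raise ConfigError("within_block_corr must be in [0, 1)")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")


def informative_indices(spec: SynthSpec) -> np.ndarray:
    """Column indices of the class-associated features.

    One per distinct block (the block's first column) while blocks last;
    any surplus informative features fill the remaining columns of the
    first block, then the second, and so on.
    """
    d, bs = spec.profile.d, spec.block_size
    n_blocks = int(np.ceil(d / bs))
    starts = [b * bs for b in range(n_blocks)]
    idx: list[int] = starts[: spec.n_informative]
    if len(idx) < spec.n_informative:
        rest = [j for j in range(d) if j not in set(starts)]
        idx.extend(rest[: spec.n_informative - len(idx)])
    return np.asarray(sorted(idx), dtype=int)


def generate(spec: SynthSpec) -> FeatureTable:
    """Draw one synthetic feature table.

    Within a block of size ``m``, features share a latent factor:
    ``x_j = sqrt(rho) * g + sqrt(1 - rho) * e_j`` with independent standard
    normal ``g`` and ``e_j``, so every marginal is N(0,1) and every
    within-block pair has correlation ``rho``; blocks are independent.
    Positive-class rows get ``+delta`` added to the informative columns.
    Class counts match the profile exactly; rows are shuffled so label
    order carries no information. ``missing_rate`` of cells (rounded to the
    nearest count) is deleted uniformly at random.
    """
    p = spec.profile
    rng = np.random.default_rng(spec.seed)
    n, d, bs = p.n, p.d, spec.block_size
    rho = spec.within_block_corr

    n_blocks = int(np.ceil(d / bs))
    X = np.empty((n, d))
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, d)
        m = hi - lo
        g = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, m))
        X[:, lo:hi] = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e

    y = np.concatenate([np.ones(p.n_pos, dtype=int), np.zeros(p.n_neg, dtype=int)])
    order = rng.permutation(n)
    y = y[order]

    info = informative_indices(spec)
    if info.size:
        X[np.ix_(y == 1, info)] += spec.effect_size

    if spec.missing_rate > 0:
        n_missing = int(round(spec.missing_rate * n * d))
        flat = rng.choice(n * d, size=n_missing, replace=False)
        X.flat[flat] = np.nan

    names = [f"f{j:05d}" for j in range(d)]
    ids = [f"s{i:05d}" for i in range(n)]
    return FeatureTable(X, y, names, ids,
                        provenance=f"synth:{p.name}:seed={spec.seed}")


def bayes_auc(spec: SynthSpec) -> float:
    """Analytic AUC of the optimal rule on the informative coordinates.

    With ``k`` informative features, each shifted by ``delta`` with unit
    marginal variance and placed in distinct blocks (hence mutually
    independent), the optimal score is their sum and
    ``AUC = Phi(delta * sqrt(k) / sqrt(2))``. With ``k = 0`` or
    ``delta = 0`` this is 0.5. Correlated block-mates could in principle
    denoise the signal further; this oracle deliberately scores only the
    informative coordinates, matching what a filter-then-classify pipeline
    can use.
    """
    k = spec.n_informative
    if k == 0 or spec.effect_size == 0:
        return 0.5
    return float(norm.cdf(spec.effect_size * np.sqrt(k) / np.sqrt(2.0)))
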