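"""Leakage-safe repeated stratified cross-validation harness.

The protocol: split the data into stratified folds; for each fold, the
training part alone is (optionally re-preprocessed,) resampled, scored for
feature relevance, reduced to the top-N features, and used to fit the
classifier; the held-out fold is only ever transformed and scored. The
macro-averaged AUC over all validation folds of all repeats identifies the
best model per resampling method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from . import feature_selection as fs
from . import resampling as rs
from .datasets import FeatureTable, preprocess
from .errors import ConfigError, DataError

__all__ = [
    "ModelConfig",
    "FoldRecord",
    "CVResult",
    "stratified_folds",
    "auc",
    "sensitivity_specificity",
    "run_single_fold",
    "run_config",
    "best_model",
    "derive_seed",
]


def derive_seed(*parts: int) -> int:
    """A reproducible 31-bit seed from a tuple of integers.

    Routed through ``numpy.random.SeedSequence`` so that per-repeat,
    per-fold, and per-stage streams never collide.
    """
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ModelConfig:
    """One point of the model space: resampler x selector x N x classifier."""

    resampler: rs.ResamplerSpec
    selector: str
    n_features: int
    classifier: clf.ClassifierSpec

    def __post_init__(self) -> None:
        if self.selector not in fs.SELECTORS:
            raise ConfigError(f"unknown selector {self.selector!r}")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")

    @property
    def method_label(self) -> str:
        """The resampling-method label used for grouping and ranking."""
        return self.resampler.label

    @property
    def label(self) -> str:
        return (f"{self.resampler.label}|{self.selector}"
                f"|N={self.n_features}|{self.classifier.label}")


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    train_ids: list[str]
    val_ids: list[str]
    feature_set: fs.FeatureSet
    val_scores: np.ndarray
    auc: float
    sensitivity: float
    specificity: float


@dataclass
class CVResult:
    config: ModelConfig
    fold_records: list[FoldRecord]
    macro_auc: float
    mean_sensitivity: float
    mean_specificity: float


# ---------------------------------------------------------------------------
# folds & metrics
# ---------------------------------------------------------------------------

def stratified_folds(
    y: np.ndarray, folds: int = 5, repeats: int = 30, seed: int = 0
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per repeat, a stratified partition into ``folds`` validation sets.

    Stratification keeps each fold's class proportions within one sample
    of the global proportions. Repeats differ through derived seeds.
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise DataError(
            f"smallest class ({counts.min()}) has fewer members than folds={folds}"
        )
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=derive_seed(seed, r))
        out.append([(tr.copy(), va.copy())
                    for tr, va in skf.split(np.zeros(len(y)), y)])
    return out


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative; ties count 1/2.

    The Mann-Whitney form: ``(R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg)``
    with mid-ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined with a single class")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) with ``score >= threshold`` predicting positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & neg).sum())
    fp = int((pred & neg).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens, spec


# ---------------------------------------------------------------------------
# the protocol
# ---------------------------------------------------------------------------

def run_single_fold(
    table: FeatureTable,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: ModelConfig,
    fold_seed: int,
    repeat: int = 0,
    fold: int = 0,
    preprocess_mode: str = "global",
) -> FoldRecord:
    """Resample -> select -> train on the training rows; score the held-out rows.

    Validation rows are never passed to the resampler, the scorer, or the
    classifier fit; with ``preprocess_mode='per_fold'`` imputation and
    scaling are additionally refitted on the training rows only.
    """
    train_tab = table.subset_rows(train_idx)
    val_tab = table.subset_rows(val_idx)
    if preprocess_mode == "per_fold":
        train_tab, state = preprocess(train_tab, drop=())
        val_tab, _ = preprocess(val_tab, drop=(), state=state)
    elif preprocess_mode != "global":
        raise ConfigError("preprocess_mode must be 'global' or 'per_fold'")

    res_spec = rs.ResamplerSpec(
        config.resampler.method, k=config.resampler.k,
        seed=derive_seed(fold_seed, 1),
    )
    resampled = rs.resample(train_tab, res_spec).table

    scores = fs.score_features(resampled, config.selector,
                               seed=derive_seed(fold_seed, 2))
    feature_set = fs.select_top(scores, config.n_features,
                                resampled.feature_names)
    sel_names = list(feature_set.names)

    model = clf.train(
        resampled.subset_features(sel_names),
        clf.ClassifierSpec(config.classifier.name, config.classifier.hyper,
                           seed=derive_seed(fold_seed, 3)),
    )
    val_scores = clf.score(model, val_tab.subset_features(sel_names))
    thr = model.default_threshold
    fold_auc = auc(val_scores, val_tab.y)
    sens, spec = sensitivity_specificity(val_scores, val_tab.y, thr)
    return FoldRecord(
        repeat=repeat, fold=fold,
        train_ids=list(train_tab.sample_ids), val_ids=list(val_tab.sample_ids),
        feature_set=feature_set, val_scores=val_scores,
        auc=fold_auc, sensitivity=sens, specificity=spec,
    )


def run_config(
    table: FeatureTable,
    config: ModelConfig,
    folds: int = 5,
    repeats: int = 30,
    master_seed: int = 0,
    preprocess_mode: str = "global",
) -> CVResult:
    """Evaluate one model configuration under repeated stratified CV."""
    partitions = stratified_folds(table.y, folds, repeats, master_seed)
    records: list[FoldRecord] = []
    for r, partition in enumerate(partitions):
        for f, (tr, va) in enumerate(partition):
            records.append(run_single_fold(
                table, tr, va, config,
                fold_seed=derive_seed(master_seed, r, f),
                repeat=r, fold=f, preprocess_mode=preprocess_mode,
            ))
    return CVResult(
        config=config,
        fold_records=records,
        macro_auc=float(np.mean([rec.auc for rec in records])),
        mean_sensitivity=float(np.mean([rec.sensitivity for rec in records])),
        mean_specificity=float(np.mean([rec.specificity for rec in records])),
    )


def best_model(results: list[CVResult]) -> dict[str, CVResult]:
    """Best configuration per resampling method by macro-AUC.

    Ties break toward higher mean sensitivity, then toward the
    lexicographically smaller configuration label.
    """
    if not results:
        raise ConfigError("best_model needs at least one CVResult")
    groups: dict[str, list[CVResult]] = {}
    for res in results:
        groups.setdefault(res.config.method_label, []).append(res)
    out: dict[str, CVResult] = {}
    for method, group in groups.items():
        out[method] = max(
            sorted(group, key=lambda r: r.config.label),
            key=lambda r: (r.macro_auc, r.mean_sensitivity),
        )
    return out
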