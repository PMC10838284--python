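"""Feature-table data model, CSV/manifest I/O, and preprocessing.

The universal currency of the pipeline is the :class:`FeatureTable`: an
``n x d`` matrix of real-valued radiomic features together with a binary
label vector. Preprocessing follows the standard radiomics recipe for
already-extracted feature tables: drop named problem features, impute
missing cells with feature means, and z-score each feature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "FeatureTable",
    "DatasetProfile",
    "PreprocessorState",
    "read_feature_table",
    "write_feature_table",
    "read_manifest",
    "drop_named_features",
    "impute_means",
    "zscore",
    "preprocess",
]

#: CSV tokens treated as missing cells, plus the empty cell.
NA_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")


@dataclass
class FeatureTable:
    """A numeric feature matrix with binary labels and names.

    Parameters
    ----------
    X
        ``(n, d)`` float array; missing values are ``NaN``.
    y
        Length-``n`` integer vector with values in ``{0, 1}``
        (1 = positive class).
    feature_names
        ``d`` unique column names.
    sample_ids
        ``n`` unique row identifiers.
    provenance
        Free-text source tag (file path, generator spec, ...).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.feature_names = list(self.feature_names)
        self.sample_ids = list(self.sample_ids)
        if self.X.ndim != 2:
            raise DataError("X must be a 2-D matrix")
        n, d = self.X.shape
        if n < 2:
            raise DataError("a feature table needs at least 2 samples")
        if d < 1:
            raise DataError("a feature table needs at least 1 feature")
        if self.y.shape != (n,):
            raise DataError("y length does not match number of rows")
        if not np.isin(self.y, (0, 1)).all():
            raise DataError("labels must be coded 0/1")
        if len(self.feature_names) != d:
            raise DataError("feature_names length does not match X columns")
        if len(set(self.feature_names)) != d:
            raise FormatError("duplicate feature names")
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length does not match X rows")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids")

    # -- basic shape accessors -------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.X).sum())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.X.copy(), self.y.copy(), list(self.feature_names),
            list(self.sample_ids), self.provenance,
        )

    def subset_rows(self, idx: np.ndarray, provenance: str | None = None) -> "FeatureTable":
        """Row-subset table; ``idx`` is an integer index array."""
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            self.X[idx], self.y[idx], list(self.feature_names),
            [self.sample_ids[i] for i in idx],
            self.provenance if provenance is None else provenance,
        )

    def subset_features(self, names: list[str]) -> "FeatureTable":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise DataError(f"unknown features: {missing}")
        cols = [pos[f] for f in names]
        return FeatureTable(self.X[:, cols], self.y, list(names),
                            list(self.sample_ids), self.provenance)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, label_column, self.y)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass(frozen=True)
class DatasetProfile:
    """Shape metadata of one benchmark dataset.

    ``balance`` is the majority/minority class-size ratio B >= 1, as
    conventionally printed to one decimal.
    """

    name: str
    n: int
    d: int
    n_pos: int
    n_neg: int
    balance: float
    modality: str = ""

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg != self.n:
            raise DataError(f"{self.name}: n_pos + n_neg != n")
        if min(self.n_pos, self.n_neg) < 1:
            raise DataError(f"{self.name}: empty class")
        if self.balance < 1.0:
            raise DataError(f"{self.name}: balance must be >= 1")


@dataclass
class PreprocessorState:
    """Fitted imputation/scaling parameters, reusable in transform mode."""

    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    dropped_features: list[str] = field(default_factory=list)
    zero_sd_mask: np.ndarray | None = None
    sd_ddof: int = 1
    #: raw-scale means used for imputation (differ from feature_means only
    #: when the table had missing cells)
    impute_means: np.ndarray | None = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path,
    label_column: str,
    sample_id_column: str | None = None,
    positive_label: object | None = None,
) -> FeatureTable:
    """Read a CSV feature table.

    The CSV must have a header row and a label column with exactly two
    distinct values. Empty cells and common NA tokens are read as missing.
    ``positive_label`` names the label value mapped to 1; when omitted the
    larger of the two values (after string sort) is positive.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=list(NA_TOKENS), keep_default_na=False)
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path}")
    if df.columns.duplicated().any():
        raise FormatError(f"duplicate column names in {path}")
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 samples")

    labels_raw = df[label_column]
    if labels_raw.isna().any():
        raise FormatError(f"{path}: missing values in label column")
    distinct = sorted(map(str, labels_raw.unique()))
    if len(distinct) != 2:
        raise FormatError(
            f"{path}: label column must have exactly 2 distinct values, "
            f"got {distinct}"
        )
    if positive_label is None:
        positive = distinct[1]
    else:
        positive = str(positive_label)
        if positive not in distinct:
            raise FormatError(f"{path}: positive label {positive!r} not present")
    y = (labels_raw.astype(str) == positive).to_numpy().astype(int)

    if sample_id_column is not None and sample_id_column in df.columns:
        sample_ids = [str(s) for s in df[sample_id_column]]
        df = df.drop(columns=[sample_id_column])
    elif "sample_id" in df.columns:
        sample_ids = [str(s) for s in df["sample_id"]]
        df = df.drop(columns=["sample_id"])
    else:
        sample_ids = [f"s{i:05d}" for i in range(len(df))]

    feat = df.drop(columns=[label_column])
    non_numeric = [
        c for c in feat.columns
        if not pd.api.types.is_numeric_dtype(pd.to_numeric(feat[c], errors="coerce"))
        or pd.to_numeric(feat[c], errors="coerce").isna().sum() > feat[c].isna().sum()
    ]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric feature columns {non_numeric}")
    X = feat.apply(pd.to_numeric).to_numpy(dtype=float)
    return FeatureTable(X, y, list(feat.columns), sample_ids, provenance=str(path))


def write_feature_table(table: FeatureTable, path: str | Path,
                        label_column: str = "label") -> None:
    """Write a feature table as CSV (missing cells become empty)."""
    table.to_frame(label_column).to_csv(path, index=False, na_rep="")


def read_manifest(path: str | Path) -> list[dict]:
    """Read a JSON manifest: list of {name, path, label_column, positive_label}."""
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise FormatError("manifest must be a JSON list")
    for e in entries:
        for key in ("name", "path", "label_column"):
            if key not in e:
                raise FormatError(f"manifest entry missing {key!r}: {e}")
    return entries


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

#: Features dropped by default: the two exponential-filter texture features
#: whose values overflow and go missing in several public datasets.
DEFAULT_DROP_FEATURES = (
    "exponential_ngtdm_contrast",
    "exponential_glcm_correlation",
)


def drop_named_features(table: FeatureTable, names: list[str]) -> FeatureTable:
    """Remove the named feature columns; absent names are ignored with a warning."""
    present = [f for f in names if f in table.feature_names]
    absent = [f for f in names if f not in table.feature_names]
    if absent:
        warnings.warn(f"features not present, ignored: {absent}", stacklevel=2)
    if not present:
        return table.copy()
    keep = [f for f in table.feature_names if f not in set(present)]
    out = table.subset_features(keep)
    return out


def impute_means(table: FeatureTable) -> tuple[FeatureTable, PreprocessorState]:
    """Replace missing cells with the per-feature mean over observed values."""
    X = table.X.copy()
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [table.feature_names[j] for j in np.flatnonzero(all_missing)]
        raise DataError(f"features with no observed values: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X, axis=0)
    miss = np.isnan(X)
    X[miss] = np.broadcast_to(means, X.shape)[miss]
    state = PreprocessorState(feature_means=means)
    out = replace(table.copy(), X=X)
    return out, state


def zscore(
    table: FeatureTable,
    state: PreprocessorState | None = None,
    ddof: int = 1,
) -> tuple[FeatureTable, PreprocessorState]:
    """Standardize every feature to mean 0, sd 1.

    In fit mode (``state is None``) means and sample standard deviations
    (``ddof=1`` denominator by default) are estimated from the input.
    In transform mode the supplied state's parameters are applied
    unchanged. Zero-sd features map to all-zero columns, preserving the
    column layout.
    """
    if np.isnan(table.X).any():
        raise DataError("zscore requires a table without missing values")
    if state is None or state.feature_means is None or state.feature_sds is None:
        means = table.X.mean(axis=0)
        sds = table.X.std(axis=0, ddof=ddof)
        zero = sds == 0
        state = PreprocessorState(
            feature_means=means, feature_sds=sds, zero_sd_mask=zero, sd_ddof=ddof,
        )
    else:
        if len(state.feature_means) != table.d or len(state.feature_sds) != table.d:
            raise DataError("preprocessor state dimension mismatch")
        means, sds = state.feature_means, state.feature_sds
        zero = sds == 0 if state.zero_sd_mask is None else state.zero_sd_mask
    safe_sds = np.where(sds == 0, 1.0, sds)
    Z = (table.X - means) / safe_sds
    Z[:, np.asarray(zero, dtype=bool)] = 0.0
    out = replace(table.copy(), X=Z)
    return out, state


def preprocess(
    table: FeatureTable,
    drop: tuple[str, ...] | list[str] = DEFAULT_DROP_FEATURES,
    state: PreprocessorState | None = None,
) -> tuple[FeatureTable, PreprocessorState]:
    """Full pipeline: drop named features -> mean imputation -> z-score.

    With ``state`` supplied, imputation means and scaling parameters come
    from the state (transform mode, for per-fold preprocessing of
    validation data).
    """
    dropped = [f for f in drop if f in table.feature_names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = drop_named_features(table, list(drop)) if drop else table.copy()
    if state is None:
        t, imp_state = impute_means(t)
        t, z_state = zscore(t)
        out_state = PreprocessorState(
            feature_means=z_state.feature_means,
            feature_sds=z_state.feature_sds,
            dropped_features=dropped,
            zero_sd_mask=z_state.zero_sd_mask,
            sd_ddof=z_state.sd_ddof,
            impute_means=imp_state.feature_means,
        )
        return t, out_state
    # transform mode
    X = t.X.copy()
    imp = state.impute_means if state.impute_means is not None else state.feature_means
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(imp, X.shape)[miss]
    t = replace(t, X=X)
    t, _ = zscore(t, state)
    return t, state
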