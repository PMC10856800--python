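"""Feature/trait table ingestion, preprocessing and sample QC.

The canonical in-memory layout is samples-in-rows: ``FeatureTable.abundance``
is a pandas DataFrame with sample IDs as the index and feature IDs as the
columns.  MSDIAL-style exports (features in rows) are transposed on read,
since all downstream correlations run across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: metadata columns recognised (case-insensitively) at the front of a feature table
META_COLUMNS = ("feature_id", "mz", "rt", "annotation")

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}


@dataclass(frozen=True)
class PreprocessConfig:
    """Missingness filtering, imputation and transform settings.

    max_missing_fraction
        Features missing in more than this fraction of samples are dropped.
    impute_method
        ``half_minimum`` (half the feature's observed minimum), ``zero``, or
        ``none`` (missing entries must not survive preprocessing; ``none``
        raises if any remain).
    transform
        Elementwise transform applied after imputation: ``none``, ``log2``
        or ``log10``.
    """

    max_missing_fraction: float = 0.5
    impute_method: str = "half_minimum"
    transform: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.impute_method not in {"half_minimum", "zero", "none"}:
            raise ValueError(f"unknown impute_method {self.impute_method!r}")
        if self.transform not in {"none", "log2", "log10"}:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class FeatureTable:
    """Samples × features abundance matrix plus per-feature metadata.

    ``abundance``: DataFrame (index = sample IDs, columns = feature IDs),
    peak areas; NaN marks a missing measurement.
    ``meta``: DataFrame indexed by feature ID with columns ``mz`` (Th),
    ``rt`` (minutes) and ``annotation`` (compound name; empty string or
    "unknown" means unidentified).
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"mz": np.nan, "rt": np.nan, "annotation": ""},
                index=self.abundance.columns,
            )
        if not self.abundance.columns.equals(self.meta.index):
            self.meta = self.meta.reindex(self.abundance.columns)
        if self.abundance.index.has_duplicates:
            dups = self.abundance.index[self.abundance.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.abundance.columns.has_duplicates:
            dups = self.abundance.columns[self.abundance.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        mz = self.meta.get("mz")
        if mz is not None and (pd.to_numeric(mz, errors="coerce") <= 0).any():
            raise ValueError("mz values must be positive where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def values(self) -> np.ndarray:
        """Abundance matrix as float ndarray (samples × features)."""
        return self.abundance.to_numpy(dtype=float)

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(self.abundance[ids], self.meta.loc[ids])


@dataclass
class TraitTable:
    """Samples × traits numeric table; binary traits are 0/1 encoded."""

    traits: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def vector(self, name: str) -> pd.Series:
        return self.traits[name]


@dataclass
class SampleTree:
    """Average-linkage clustering of samples with optional outlier flags."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    cut_height: float | None = None
    outliers: list[str] = field(default_factory=list)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _to_float(cell: str, row_label, col_label) -> float:
    text = cell.strip()
    if text.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric abundance cell {cell!r} at feature {row_label!r}, "
            f"sample {col_label!r}"
        ) from None


def read_feature_table(path, orientation: str = "features_in_rows") -> FeatureTable:
    """Read a CSV/TSV feature table into the canonical samples × features layout.

    ``orientation="features_in_rows"`` expects the MSDIAL-style export: one
    row per molecular feature, leading metadata columns (feature_id, mz, rt,
    annotation — matched case-insensitively; all but feature_id optional),
    remaining columns one per sample.  ``samples_in_rows`` expects the
    transpose with a leading sample_id column and feature IDs as headers
    (no per-feature metadata in that dialect).

    Empty cells and NA-like tokens are recorded as missing; a literal 0 is a
    measured zero.
    """
    if orientation not in {"features_in_rows", "samples_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_delimited(path)

    if orientation == "samples_in_rows":
        sample_col = raw.columns[0]
        abundance = raw.set_index(sample_col)
        abundance.index.name = None
        values = np.array(
            [
                [_to_float(abundance.iat[i, j], abundance.columns[j], abundance.index[i])
                 for j in range(abundance.shape[1])]
                for i in range(abundance.shape[0])
            ]
        ) if abundance.size else np.empty(abundance.shape)
        table = pd.DataFrame(values, index=abundance.index.astype(str),
                             columns=abundance.columns.astype(str))
        return FeatureTable(table, None)

    lower = {c.lower().strip(): c for c in raw.columns}
    if "feature_id" not in lower:
        # fall back: first column is the feature identifier
        id_col = raw.columns[0]
    else:
        id_col = lower["feature_id"]
    meta_cols = {name: lower[name] for name in ("mz", "rt", "annotation")
                 if name in lower}
    feature_ids = raw[id_col].astype(str).str.strip()
    if feature_ids.duplicated().any():
        dups = sorted(feature_ids[feature_ids.duplicated()].unique())
        raise ValueError(f"duplicate feature IDs: {dups}")

    meta = pd.DataFrame(index=pd.Index(feature_ids, name=None))
    for name in ("mz", "rt"):
        if name in meta_cols:
            meta[name] = pd.to_numeric(
                raw[meta_cols[name]].replace("", np.nan).values, errors="coerce")
        else:
            meta[name] = np.nan
    if "annotation" in meta_cols:
        ann = raw[meta_cols["annotation"]].astype(str).str.strip()
        ann = ann.where(~ann.str.lower().isin({"unknown", "na", "nan"}), "")
        meta["annotation"] = ann.values
    else:
        meta["annotation"] = ""

    sample_cols = [c for c in raw.columns
                   if c != id_col and c not in meta_cols.values()]
    values = np.array(
        [
            [_to_float(raw[c].iat[i], feature_ids.iat[i], c) for c in sample_cols]
            for i in range(len(raw))
        ]
    ) if len(raw) else np.empty((0, len(sample_cols)))
    abundance = pd.DataFrame(values.T, index=[str(c) for c in sample_cols],
                             columns=feature_ids.tolist())
    return FeatureTable(abundance, meta)


def read_trait_table(path, binary_encodings: dict | None = None) -> TraitTable:
    """Read a CSV/TSV trait table (first column sample_id, rest traits).

    ``binary_encodings`` maps trait name → {level: 0/1} for categorical
    columns; numeric columns pass through.  A column declared binary with
    more than two observed levels is an error.  Categorical columns without
    a declared mapping are encoded reference level → 0, alternative → 1 in
    sorted level order.
    """
    raw = _read_delimited(path)
    sample_col = raw.columns[0]
    df = raw.set_index(sample_col)
    df.index = df.index.astype(str)
    df.index.name = None
    binary_encodings = binary_encodings or {}

    out = {}
    for col in df.columns:
        series = df[col].astype(str).str.strip()
        numeric = pd.to_numeric(series, errors="coerce")
        if col in binary_encodings:
            mapping = binary_encodings[col]
            levels = sorted(series.unique())
            if len(levels) > 2:
                raise ValueError(
                    f"trait {col!r} declared binary but has levels {levels}")
            unmapped = [lv for lv in levels if lv not in {str(k) for k in mapping}]
            if unmapped:
                raise ValueError(f"trait {col!r}: no encoding for {unmapped}")
            out[col] = series.map({str(k): v for k, v in mapping.items()}).astype(float)
        elif numeric.notna().all():
            out[col] = numeric.astype(float)
        else:
            levels = sorted(series.unique())
            if len(levels) != 2:
                raise ValueError(
                    f"trait {col!r} is non-numeric with levels {levels}; "
                    "declare an encoding via binary_encodings")
            out[col] = series.map({levels[0]: 0.0, levels[1]: 1.0})
            logger.info("trait %r encoded %s->0, %s->1", col, levels[0], levels[1])
    return TraitTable(pd.DataFrame(out, index=df.index))


def preprocess(table: FeatureTable, config: PreprocessConfig | None = None) -> FeatureTable:
    """Drop high-missingness features, impute the rest, apply the transform.

    Features missing in more than ``max_missing_fraction`` of samples (or
    entirely missing) are dropped; remaining missing cells are imputed
    (``half_minimum`` = half the feature's observed minimum); the transform
    is applied elementwise afterwards.  Idempotent for a fixed config.
    """
    config = config or PreprocessConfig()
    X = table.abundance
    frac_missing = X.isna().mean(axis=0)
    keep = frac_missing <= config.max_missing_fraction
    all_missing = frac_missing == 1.0
    keep &= ~all_missing
    dropped = X.columns[~keep]
    if len(dropped):
        logger.warning("preprocess: dropping %d features above missingness "
                       "threshold %.2f", len(dropped), config.max_missing_fraction)
    X = X.loc[:, keep].copy()
    meta = table.meta.loc[X.columns]

    if X.isna().any().any():
        if config.impute_method == "half_minimum":
            fill = X.min(axis=0, skipna=True) / 2.0
            X = X.fillna(fill)
        elif config.impute_method == "zero":
            X = X.fillna(0.0)
        else:
            raise ValueError("missing entries remain with impute_method='none'")

    if config.transform == "log2":
        X = np.log2(X)
    elif config.transform == "log10":
        X = np.log10(X)
    return FeatureTable(X, meta)


def sample_dendrogram(table: FeatureTable, cut_height: float | None = None) -> SampleTree:
    """Average-linkage sample tree on Euclidean distance of z-scored features.

    Each feature is standardized across samples (zero mean, unit variance)
    before computing pairwise Euclidean distances between samples.  With a
    ``cut_height``, samples that sit in singleton clusters after cutting the
    tree at that height are flagged as outliers; without one, no samples are
    flagged.
    """
    if table.n_samples < 3:
        raise ValueError("sample_dendrogram requires at least 3 samples")
    X = table.values()
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    lm = linkage(pdist(Z, metric="euclidean"), method="average")
    outliers: list[str] = []
    if cut_height is not None:
        labels = fcluster(lm, t=cut_height, criterion="distance")
        sizes = pd.Series(labels).value_counts()
        singles = set(sizes[sizes == 1].index)
        outliers = [sid for sid, lab in zip(table.sample_ids, labels)
                    if lab in singles]
        if outliers:
            logger.warning("sample_dendrogram: flagged outliers %s", outliers)
    return SampleTree(lm, table.sample_ids, cut_height, outliers)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in the features-in-rows dialect."""
    out = table.meta.copy()
    out.insert(0, "feature_id", out.index)
    out = pd.concat([out.reset_index(drop=True),
                     table.abundance.T.reset_index(drop=True)], axis=1)
    out.columns = ["feature_id", "mz", "rt", "annotation"] + table.sample_ids
    out.to_csv(path, sep="\t", index=False)


def write_trait_table(traits: TraitTable, path) -> None:
    out = traits.traits.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)
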