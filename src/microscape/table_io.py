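"""Abundance tables and sample metadata.

The universal input of the landscape analysis is a sample × feature
matrix of non-negative abundances — counts or relative frequencies of
predicted functions (KEGG orthologs, GO terms) or taxa — plus an
optional per-sample metadata table carrying the grouping variables
(generation, time point, subject, treatment, birth mode).

Tables are stored samples × features internally; every downstream
dissimilarity is computed between sample rows.  Features present in no
sample are retained: they contribute nothing to the Jensen–Shannon
divergence and dropping them would silently reindex the feature axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative_abundance",
    "read_metadata",
    "write_metadata",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class CommunityTable:
    """Sample × feature non-negative abundance matrix with aligned ids.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows).
    feature_ids : list of str
        Ordered, unique feature identifiers (columns).
    values : ndarray of shape (n_samples, n_features)
        Non-negative abundances; counts or relative frequencies.
    is_relative : bool
        If True, every row sums to 1 (within 1e-9).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    is_relative: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite abundance values")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(
                    f"is_relative set but row {self.sample_ids[i]!r} sums to {sums[i]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_relative: bool = False) -> "CommunityTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            values=df.to_numpy(dtype=float),
            is_relative=is_relative,
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample attribute map (group, generation, timepoint, subject, ...).

    Backed by a DataFrame indexed by sample_id.  All attributes are
    optional; unknown columns are preserved as text.  A metadata table
    may reference samples absent from an abundance table — the join
    step downstream warns rather than fails.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample_id(s) in metadata: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    def get(self, sample_id: str, key: str):
        return self.table.loc[sample_id, key]

    def subset(self, sample_ids) -> "SampleMetadata":
        present = [s for s in sample_ids if s in self.table.index]
        return SampleMetadata(self.table.loc[present])


def read_abundance_table(path, orientation: str = "samples-in-rows") -> CommunityTable:
    """Read a tab-separated abundance table.

    Parameters
    ----------
    path : path-like
        TSV file with one header row and one leading id column.
    orientation : {"samples-in-rows", "features-in-rows"}
        How the file is laid out; the returned table is always
        samples × features.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path}: {dups}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                ) from None
        raise
    if orientation == "features-in-rows":
        numeric = numeric.T
    return CommunityTable.from_dataframe(numeric)


def write_abundance_table(table: CommunityTable, path) -> None:
    """Write a table as TSV, samples in rows, full float precision."""
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def to_relative_abundance(table: CommunityTable) -> CommunityTable:
    """Divide each sample row by its row sum.

    Idempotent; raises if any sample has no positive entry (its
    frequency profile would be undefined).
    """
    sums = table.values.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.argmax(sums <= 0))
        raise ValueError(
            f"sample {table.sample_ids[i]!r} has zero total abundance; "
            "cannot normalize to relative abundance"
        )
    return replace(table, values=table.values / sums[:, None], is_relative=True)


def read_metadata(path) -> SampleMetadata:
    """Read a TSV metadata table; requires a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"metadata file {path} has no 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    # integer-like attribute columns come back as ints, everything else as text
    for col in df.columns:
        if col in ("generation", "timepoint"):
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.notna().all():
                df[col] = converted.astype(int)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
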