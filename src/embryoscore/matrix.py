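"""Expression-matrix container and delimited-text I/O.

The canonical in-memory layout is features x samples (genes or probes as
rows), the orientation in which microarray matrices are usually published.
Estimators in this package follow the scikit-learn convention instead
(samples x features); :meth:`ExpressionMatrix.to_sklearn` bridges the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_SPACES = ("probe", "gene")


class MatrixParseError(ValueError):
    """Raised when a delimited expression file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Non-negative expression values with labelled features and samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Features x samples; index holds feature ids, columns sample ids.
    feature_space : {"probe", "gene"}
        Namespace of the row identifiers.
    metadata : pandas.DataFrame, optional
        Per-sample records indexed by sample id.  Recognised columns are
        ``class_label``, ``group_id`` and ``platform``; extra columns pass
        through untouched.
    """

    values: pd.DataFrame
    feature_space: str = "gene"
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.feature_space not in FEATURE_SPACES:
            raise ValueError(f"feature_space must be one of {FEATURE_SPACES}, got {self.feature_space!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        dup_f = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_f):
            raise MatrixParseError(f"duplicate feature ids: {list(dup_f[:5])}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise MatrixParseError(f"duplicate sample ids: {list(dup_s[:5])}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise MatrixParseError("expression values must be finite")
        if self.metadata is not None:
            unknown = self.metadata.index.difference(self.values.columns)
            if len(unknown):
                raise ValueError(f"metadata rows for unknown samples: {list(unknown[:5])}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_sklearn(self) -> pd.DataFrame:
        """Samples x features view for scikit-learn style estimators."""
        return self.values.T

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        meta = None
        if self.metadata is not None:
            keep = self.metadata.index.intersection(values.columns)
            meta = self.metadata.loc[keep]
        return ExpressionMatrix(values=values, feature_space=self.feature_space, metadata=meta)


def read_expression_matrix(
    path,
    orientation: str = "features_by_samples",
    feature_space: str = "gene",
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a delimited (TSV/CSV, gzip-transparent) expression matrix.

    ``orientation`` is ``"features_by_samples"`` (rows are features) or
    ``"samples_by_features"`` (rows are samples; the matrix is transposed on
    load).  Duplicate identifiers and non-numeric cells raise
    :class:`MatrixParseError` naming the offender.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise MatrixParseError(f"{path}: no data columns found (malformed header?)")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        for col in bad:
            nonnum = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(nonnum):
                raise MatrixParseError(
                    f"non-numeric cell in column {col!r}, row {nonnum.index[0]!r}: {nonnum.iloc[0]!r}"
                )
        df = df.apply(pd.to_numeric)
    if orientation == "samples_by_features":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, feature_space=feature_space, metadata=metadata)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write the matrix as features x samples TSV (header = sample ids)."""
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    m.values.to_csv(path, sep=sep)


def read_probe_annotation(path) -> pd.Series:
    """Read a 2-column probe_id -> gene_symbol table.

    Returns a Series indexed by probe id.  A probe listed twice with
    conflicting gene symbols is rejected; empty gene symbols are rejected.
    """
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: annotation needs 2 columns (probe_id, gene_symbol)")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "gene_symbol"]
    df = df.dropna()
    if (df["gene_symbol"].str.len() == 0).any():
        raise MatrixParseError("empty gene symbol in annotation")
    dedup = df.drop_duplicates()
    counts = dedup["probe_id"].value_counts()
    conflicting = counts[counts > 1]
    if len(conflicting):
        raise MatrixParseError(
            f"probes mapped to multiple genes: {list(conflicting.index[:5])}"
        )
    return dedup.set_index("probe_id")["gene_symbol"]


def read_labels(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, class, group[, platform])."""
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    rename = {}
    for col in df.columns:
        low = col.lower()
        if low in ("class", "label", "class_label"):
            rename[col] = "class_label"
        elif low in ("group", "dataset", "group_id"):
            rename[col] = "group_id"
    return df.rename(columns=rename)
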