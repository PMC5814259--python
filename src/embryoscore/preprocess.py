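"""Frozen-reference expression preprocessing.

Three stages take a raw probe- or gene-level matrix to the classifier's
input space:

1. probe -> gene aggregation (geometric mean over probes of a gene),
2. background masking against a fluorescence floor (default 130 RFU on
   Illumina BeadArrays),
3. quantile normalization against a *frozen* reference: the target
   quantiles are the rank-wise mean of the sorted training columns, stored
   once and re-applied to every later sample, so a single new transcriptome
   lands in exactly the distribution the classifiers were trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# probe aggregation and background masking
# ---------------------------------------------------------------------------

def aggregate_probes(
    m: ExpressionMatrix,
    annotation: pd.Series,
    pseudo_floor: float | None = None,
) -> ExpressionMatrix:
    """Collapse probe rows to genes by geometric mean.

    Probes absent from ``annotation`` are dropped (count logged).  A
    non-positive value under a multi-probe gene makes the geometric mean
    undefined and raises, unless ``pseudo_floor`` is given, in which case
    values are clipped up to it first (logged).
    """
    if m.feature_space != "probe":
        raise ValueError("aggregate_probes expects a probe-space matrix")
    ann = annotation.astype(str)
    present = m.values.index.intersection(ann.index)
    dropped = m.n_features - len(present)
    if dropped:
        logger.info("aggregate_probes: dropped %d unannotated probes", dropped)
    if len(present) == 0:
        raise ValueError("no probes in the matrix are covered by the annotation")
    vals = m.values.loc[present]
    genes = ann.loc[present]
    multi = genes.value_counts()
    multi_genes = set(multi[multi > 1].index)
    mask_multi = genes.isin(multi_genes).to_numpy()
    arr = vals.to_numpy(dtype=float)
    if (arr[mask_multi] <= 0).any():
        if pseudo_floor is None:
            bad_probe = vals.index[mask_multi][np.argwhere((arr[mask_multi] <= 0).any(axis=1))[0][0]]
            raise ValueError(
                f"non-positive value under multi-probe gene (probe {bad_probe!r}); "
                "geometric mean undefined — pass pseudo_floor to clip"
            )
        n_clipped = int((arr <= 0).sum())
        logger.warning("aggregate_probes: clipping %d non-positive values to %g", n_clipped, pseudo_floor)
        arr = np.clip(arr, pseudo_floor, None)
        vals = pd.DataFrame(arr, index=vals.index, columns=vals.columns)
    # geometric mean = exp(mean(log x)); single-probe genes pass through
    logvals = np.log(vals.where(vals > 0, np.nan))
    out = np.exp(logvals.groupby(genes).mean())
    single = vals.groupby(genes).size() == 1
    # restore exact values for single-probe genes (avoid exp(log()) rounding)
    direct = vals.groupby(genes).first()
    out.loc[single[single].index] = direct.loc[single[single].index]
    out = out.sort_index()
    return ExpressionMatrix(values=out, feature_space="gene", metadata=m.metadata)


@dataclass(frozen=True)
class BackgroundPolicy:
    """Treatment of sub-background intensities.

    ``threshold`` defaults to 130 relative fluorescence units, under which
    BeadArray signal is nonspecific background.  ``floor`` replaces values
    strictly below the threshold by the threshold; ``drop`` removes features
    whose values are below it in every sample.
    """

    threshold: float = 130.0
    mode: str = "floor"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.mode not in ("floor", "drop"):
            raise ValueError(f"mode must be 'floor' or 'drop', got {self.mode!r}")


def mask_background(m: ExpressionMatrix, policy: BackgroundPolicy = BackgroundPolicy()) -> ExpressionMatrix:
    """Apply a :class:`BackgroundPolicy`; values equal to the threshold are kept."""
    vals = m.values
    if policy.mode == "floor":
        return m.with_values(vals.clip(lower=policy.threshold))
    keep = (vals >= policy.threshold).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("mask_background: dropped %d all-background features", n_dropped)
    return m.with_values(vals.loc[keep])


# ---------------------------------------------------------------------------
# frozen quantile normalization
# ---------------------------------------------------------------------------

class QuantileReferenceNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization with a frozen target distribution.

    ``fit`` records the rank-wise mean of the sorted training columns as the
    target quantiles; ``transform`` maps each sample's values onto those
    quantiles by rank, averaging tied target quantiles, so transform of any
    permutation of the reference yields that permutation exactly.

    Follows the scikit-learn transformer contract: X is samples x features.

    Parameters
    ----------
    log2_transform : bool
        Apply log2(x+1) before ranking (for count-scale RNA-seq inputs fed
        through a reference fit on intensities).  Default off.
    missing_policy : {"error", "median_impute"}
        At transform time, features of the reference absent from the input
        either raise (default) or are imputed with the reference median
        before ranking.

    Attributes
    ----------
    quantiles_ : ndarray of shape (n_features,)
        Non-decreasing target quantiles.
    feature_names_in_ : ndarray of str
        Gene ids of the training matrix, in training order.
    """

    def __init__(self, log2_transform: bool = False, missing_policy: str = "error"):
        self.log2_transform = log2_transform
        self.missing_policy = missing_policy

    def fit(self, X, y=None):
        if self.missing_policy not in ("error", "median_impute"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        X = self._as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("quantile reference needs >= 2 training samples")
        if X.isna().to_numpy().any():
            raise ValueError("training matrix contains missing values")
        arr = X.to_numpy(dtype=float)
        if self.log2_transform:
            arr = np.log2(arr + 1.0)
        # mean over samples of each sample's sorted values
        self.quantiles_ = np.sort(arr, axis=1).mean(axis=0)
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "quantiles_")
        if not isinstance(X, pd.DataFrame):
            # unlabeled arrays are taken to be in reference gene order
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.shape[1] != len(self.feature_names_in_):
                raise ValueError(
                    f"unlabeled input has {arr.shape[1]} features; "
                    f"reference expects {len(self.feature_names_in_)}"
                )
            X = pd.DataFrame(arr, columns=list(self.feature_names_in_))
        genes = pd.Index(self.feature_names_in_)
        missing = genes.difference(X.columns)
        if len(genes.intersection(X.columns)) == 0:
            raise ValueError("no overlap between input features and the reference gene list")
        if len(missing):
            if self.missing_policy == "error":
                raise ValueError(
                    f"{len(missing)} reference genes missing from input "
                    f"(e.g. {list(missing[:5])}); use missing_policy='median_impute' to fill"
                )
            logger.warning("imputing %d missing genes with the reference median", len(missing))
            X = X.reindex(columns=X.columns.union(missing))
            X.loc[:, list(missing)] = float(np.median(self.quantiles_))
        X = X.loc[:, genes]
        arr = X.to_numpy(dtype=float)
        if self.log2_transform:
            arr = np.log2(arr + 1.0)
        out = np.empty_like(arr)
        g = len(self.quantiles_)
        positions = np.arange(1, g + 1, dtype=float)
        for i in range(arr.shape[0]):
            ranks = rankdata(arr[i], method="average")
            # average ranks land between integer positions; linear
            # interpolation yields the mean of the tied target quantiles
            out[i] = np.interp(ranks, positions, self.quantiles_)
        return pd.DataFrame(out, index=X.index, columns=genes)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return pd.DataFrame(X, columns=[str(i) for i in range(X.shape[1])])


@dataclass
class QuantileReference:
    """Frozen target quantiles plus the training gene list (serializable)."""

    quantiles: np.ndarray
    gene_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        if len(self.quantiles) != len(self.gene_ids):
            raise ValueError("quantiles and gene_ids must have equal length")
        if np.any(np.diff(np.sort(self.quantiles)) < 0):  # pragma: no cover
            raise ValueError("quantiles must be sortable")

    def to_normalizer(self, log2_transform: bool = False, missing_policy: str = "error") -> QuantileReferenceNormalizer:
        norm = QuantileReferenceNormalizer(log2_transform=log2_transform, missing_policy=missing_policy)
        norm.quantiles_ = np.asarray(self.quantiles, dtype=float)
        norm.feature_names_in_ = np.asarray(self.gene_ids, dtype=object)
        norm.n_features_in_ = len(self.gene_ids)
        return norm

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for line in self.provenance.splitlines():
                fh.write(f"# {line}\n")
            fh.write("gene_id\tquantile\n")
            for gid, q in zip(self.gene_ids, self.quantiles):
                fh.write(f"{gid}\t{float(q):.17g}\n")

    @classmethod
    def load(cls, path) -> "QuantileReference":
        prov, genes, quants = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    prov.append(line[1:].strip())
                    continue
                if line.startswith("gene_id\t") or not line:
                    continue
                gid, q = line.split("\t")
                genes.append(gid)
                quants.append(float(q))
        return cls(quantiles=np.asarray(quants), gene_ids=genes, provenance="\n".join(prov))


def fit_quantile_reference(training: ExpressionMatrix, log2_transform: bool = False, provenance: str = "") -> QuantileReference:
    """Freeze the training corpus quantiles (features x samples input)."""
    norm = QuantileReferenceNormalizer(log2_transform=log2_transform).fit(training.to_sklearn())
    prov = provenance or f"n_samples={training.n_samples} feature_space={training.feature_space}"
    # quantiles indexed by rank; gene_ids record the training feature set
    return QuantileReference(
        quantiles=norm.quantiles_,
        gene_ids=[str(g) for g in norm.feature_names_in_],
        provenance=prov,
    )


def apply_quantile_reference(
    m: ExpressionMatrix,
    ref: QuantileReference,
    missing_policy: str = "error",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Rank-map every sample of ``m`` onto the frozen reference quantiles."""
    norm = ref.to_normalizer(log2_transform=log2_transform, missing_policy=missing_policy)
    out = norm.transform(m.to_sklearn())
    return m.with_values(out.T)
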