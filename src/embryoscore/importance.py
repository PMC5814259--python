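"""Feature importance: network weight propagation and GBM split counts.

For a dense network the importance of input gene g is the magnitude with
which it propagates through every layer to the output: row g of
|W1| @ |W2| @ ... @ W_out|, summed over output units (biases, dropout and
activations are ignored).  For a boosted-tree model the f-score counts how
many times a feature is used to split a tree.  Ensemble importance averages
the per-network propagation scores after normalizing each network's scores
to sum 1, so no single network's weight scale dominates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ensemble import OvoEnsembleClassifier
from .nn import DenseNetwork

logger = logging.getLogger(__name__)


def _rank_table(scores: np.ndarray, gene_ids, method: str) -> pd.DataFrame:
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any():
        raise ValueError("importance scores must be non-negative")
    ranks = rankdata(-scores, method="min").astype(int)
    if len(np.unique(scores)) < len(scores):
        logger.info("importance ties present; tied genes share the min rank")
    table = pd.DataFrame({
        "gene_id": list(gene_ids),
        "score": scores,
        "rank": ranks,
        "method": method,
    })
    return table.sort_values(["rank", "gene_id"], kind="stable").reset_index(drop=True)


def weight_propagation_scores(weights: list[np.ndarray]) -> np.ndarray:
    """Row sums of the product of element-wise absolute weight matrices."""
    prod = np.abs(np.asarray(weights[0], dtype=float))
    for w in weights[1:]:
        prod = prod @ np.abs(np.asarray(w, dtype=float))
    return prod.sum(axis=1)


def dnn_weight_importance(network, gene_ids=None) -> pd.DataFrame:
    """Importance table for one trained dense network.

    ``network`` is a :class:`~embryoscore.nn.DenseNetwork`, an estimator
    exposing ``network_`` (e.g. :class:`~embryoscore.classifiers.DNNClassifier`),
    or a plain list of weight matrices.
    """
    if isinstance(network, DenseNetwork):
        weights = network.get_weights()
    elif hasattr(network, "network_"):
        weights = network.network_.get_weights()
    else:
        weights = [np.asarray(w, dtype=float) for w in network]
        for w in weights:
            if w.ndim == 1:
                raise ValueError("weight matrices must be 2-D (fan_in x fan_out)")
    scores = weight_propagation_scores(weights)
    if gene_ids is None:
        gene_ids = getattr(network, "feature_names_in_", None)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(len(scores))]
    return _rank_table(scores, gene_ids, "dnn_weight_propagation")


def ensemble_importance(model: OvoEnsembleClassifier) -> pd.DataFrame:
    """Mean of per-network weight-propagation scores, each normalized to sum 1."""
    acc = None
    for pair in sorted(model.networks_, key=lambda p: (p.positive, p.negative)):
        scores = weight_propagation_scores(model.networks_[pair].get_weights())
        total = scores.sum()
        if total > 0:
            scores = scores / total
        acc = scores if acc is None else acc + scores
    acc = acc / len(model.networks_)
    return _rank_table(acc, list(model.feature_names_in_), "dnn_weight_propagation")


def gbm_split_importance(model, gene_ids=None) -> pd.DataFrame:
    """f-score table: how many times each feature splits a tree.

    Accepts a fitted ``xgboost.XGBClassifier`` or a
    :class:`~embryoscore.classifiers.TrainedClassifier` of the gbm family.
    Features never used to split score 0.
    """
    if hasattr(model, "family"):
        if model.family != "gbm":
            raise ValueError(f"expected a gbm model, got family {model.family!r}")
        gene_ids = gene_ids or model.training_gene_ids
        booster = model.model.get_booster()
    else:
        booster = model.get_booster()
    fmap = booster.get_score(importance_type="weight")
    if gene_ids is None:
        n = booster.num_features()
        gene_ids = [str(i) for i in range(n)]
    scores = np.zeros(len(gene_ids))
    for key, count in fmap.items():
        idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else list(gene_ids).index(key)
        scores[idx] = count
    return _rank_table(scores, gene_ids, "gbm_fscore")
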