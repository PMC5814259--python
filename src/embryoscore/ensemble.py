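"""Directional one-vs-one deep-network ensemble and the Embryonic Score.

For K cell classes, K*(K-1) ordered (positive, negative) class pairs each
train one binary sigmoid network; the ensemble vote for class i is the sum
of the K-1 sigmoid outputs of the networks in which i is the positive
class, so each vote lies in [0, K-1].  For the canonical five classes
(ESC, iPSC, EPC, ASC, AC) this yields 20 networks and votes in [0, 4].

The Embryonic Score places a transcriptome on the embryonic -> adult axis:

    ES = sum_i Class_i * w_i / sum_i Class_i

a vote-mass-weighted average of per-class degrees of embryonic development
w_ESC=1.0, w_iPSC=0.9, w_EPC=0.7, w_ASC=0.5, w_AC=0.0, so a pure-ESC vote
scores 1 (embryonic) and a pure-AC vote scores 0 (adult).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classifiers import DnnSpec
from .nn import DenseNetwork

logger = logging.getLogger(__name__)

#: Canonical class order: embryonic stem cells, induced pluripotent stem
#: cells, embryonic progenitors, adult stem cells, adult cells.  The order
#: is also the tie-break authority for argmax class prediction.
CANONICAL_CLASSES = ("ESC", "iPSC", "EPC", "ASC", "AC")

#: Default per-class degrees of embryonic development (w_i).
DEFAULT_ESCORE_WEIGHTS = {"ESC": 1.0, "iPSC": 0.9, "EPC": 0.7, "ASC": 0.5, "AC": 0.0}


@dataclass(frozen=True)
class PairSpec:
    """One ordered class pair: the binary network targets positive=1."""

    positive: str
    negative: str

    def __post_init__(self) -> None:
        if self.positive == self.negative:
            raise ValueError("positive and negative classes must differ")


def build_pair_specs(classes) -> list[PairSpec]:
    """All K*(K-1) ordered pairs, lexicographic in the given class order."""
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes for one-vs-one pairs")
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate class labels")
    return [PairSpec(pos, neg) for pos in classes for neg in classes if pos != neg]


def check_escore_weights(weights: dict, classes) -> dict:
    w = dict(weights)
    if set(w) != set(classes):
        raise ValueError(f"weight keys {sorted(w)} must equal the class set {sorted(classes)}")
    for cls, val in w.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"weight for {cls} must be in [0, 1], got {val}")
    return w


def embryonic_score(votes, weights: dict | None = None, classes=CANONICAL_CLASSES) -> float:
    """Vote-mass-weighted average of the class weights.

    ``votes`` is a mapping class -> vote or a vector in ``classes`` order.
    Raises on an all-zero vote vector (the score is undefined).
    """
    if isinstance(votes, dict):
        classes = list(votes.keys())
        vec = np.asarray([votes[c] for c in classes], dtype=float)
    else:
        vec = np.asarray(votes, dtype=float)
        classes = list(classes)[: len(vec)]
    w = check_escore_weights(weights or {c: DEFAULT_ESCORE_WEIGHTS[c] for c in classes}, classes)
    if (vec < 0).any():
        raise ValueError("votes must be non-negative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("all-zero vote vector: Embryonic Score undefined")
    wv = np.asarray([w[c] for c in classes], dtype=float)
    return float(vec @ wv / total)


def predict_class(votes: dict) -> str:
    """Argmax vote; exact ties go to the earliest class in vote order."""
    best = max(votes.values())
    tied = [c for c, v in votes.items() if v == best]
    if len(tied) > 1:
        logger.info("vote tie between %s; breaking by canonical order", tied)
    return tied[0]


class OvoEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of directional one-vs-one binary dense networks.

    Each ordered class pair (p, n) trains one sigmoid-output network on the
    samples of those two classes only (target 1 for p, 0 for n), with the
    architecture shared by all members (default 2 x 200 ReLU, dropout 0.2,
    L2 0.03, 200 epochs of Adam).  Per-network seeds are derived from
    ``random_state`` XOR the pair index and recorded in ``seed_ledger_``.

    ``decision_function`` returns the per-class vote vector; ``predict`` is
    its argmax with canonical-order tie-break; ``embryonic_score`` reduces
    the votes to the [0, 1] embryonic -> adult score.
    """

    def __init__(
        self,
        hidden_layers: int = 2,
        neurons_per_layer: int = 200,
        activation: str = "relu",
        dropout: float = 0.2,
        l2_strength: float = 0.03,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        class_order: tuple = CANONICAL_CLASSES,
        escore_weights: dict | None = None,
        random_state: int = 0,
    ):
        self.hidden_layers = hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.activation = activation
        self.dropout = dropout
        self.l2_strength = l2_strength
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.class_order = class_order
        self.escore_weights = escore_weights
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray([str(i) for i in range(arr.shape[1])], dtype=object)
        y = np.asarray([str(v) for v in y], dtype=object)
        present = set(y)
        self.classes_ = np.asarray(
            [c for c in self.class_order if c in present]
            + sorted(present - set(self.class_order)),
            dtype=object,
        )
        if len(self.classes_) < 2:
            raise ValueError("need samples of >= 2 classes")
        counts = pd.Series(y).value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(f"classes with < 2 samples: {list(thin.index)}")
        self._weights = check_escore_weights(
            self.escore_weights or {c: DEFAULT_ESCORE_WEIGHTS.get(c, 0.0) for c in self.classes_},
            self.classes_,
        )
        pairs = build_pair_specs(self.classes_)
        self.pair_specs_ = pairs
        self.networks_ = {}
        self.seed_ledger_ = {}
        for idx, pair in enumerate(pairs):
            seed = (int(self.random_state) ^ idx) % (2**31)
            mask = (y == pair.positive) | (y == pair.negative)
            target = (y[mask] == pair.positive).astype(float)
            net = DenseNetwork(
                n_inputs=arr.shape[1],
                n_outputs=1,
                hidden_layers=self.hidden_layers,
                neurons_per_layer=self.neurons_per_layer,
                activation=self.activation,
                dropout=self.dropout,
                l2_strength=self.l2_strength,
                epochs=self.epochs,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size,
                output="sigmoid",
                seed=seed,
            ).fit(arr[mask], target)
            self.networks_[pair] = net
            self.seed_ledger_[pair] = seed
        self.n_features_in_ = arr.shape[1]
        return self

    # ------------------------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "networks_")
        if isinstance(X, pd.DataFrame):
            got = [str(c) for c in X.columns]
            want = list(self.feature_names_in_)
            if got != want:
                sym = set(got) ^ set(want)
                if sym:
                    raise ValueError(f"feature mismatch with training genes: {sorted(sym)[:10]}")
                X = X.loc[:, want]
            return X.to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {arr.shape[1]}")
        return arr

    def decision_function(self, X) -> pd.DataFrame:
        """Per-class ensemble votes (samples x classes DataFrame).

        vote(c) = sum of sigmoid outputs of the K-1 networks whose positive
        class is c; each entry lies in [0, K-1].
        """
        arr = self._check_X(X)
        votes = pd.DataFrame(
            0.0,
            index=X.index if isinstance(X, pd.DataFrame) else range(arr.shape[0]),
            columns=list(self.classes_),
        )
        for pair, net in self.networks_.items():
            votes[pair.positive] += net.forward(arr)[:, 0]
        return votes

    def ensemble_votes(self, x) -> dict:
        """Votes for a single expression vector, as class -> vote."""
        votes = self.decision_function(np.atleast_2d(np.asarray(x, dtype=float)) if not isinstance(x, pd.DataFrame) else x)
        return votes.iloc[0].to_dict()

    def predict(self, X) -> np.ndarray:
        votes = self.decision_function(X)
        return np.asarray([predict_class(row.to_dict()) for _, row in votes.iterrows()], dtype=object)

    def predict_proba(self, X) -> np.ndarray:
        """Votes normalized to sum 1 per sample (soft, not calibrated)."""
        votes = self.decision_function(X).to_numpy()
        total = votes.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return votes / total

    def embryonic_score(self, X) -> np.ndarray:
        """Embryonic Score per sample, in [min(w), max(w)] ⊆ [0, 1]."""
        votes = self.decision_function(X)
        return np.asarray(
            [embryonic_score(row.to_dict(), self._weights) for _, row in votes.iterrows()]
        )

    # ------------------------------------------------------------------
    def save(self, directory) -> None:
        """Serialize: manifest.json + one weight file per ordered pair."""
        check_is_fitted(self, "networks_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "class_order": list(self.classes_),
            "escore_weights": self._weights,
            "gene_ids": list(self.feature_names_in_),
            "spec": {
                "hidden_layers": self.hidden_layers,
                "neurons_per_layer": self.neurons_per_layer,
                "activation": self.activation,
                "dropout": self.dropout,
                "l2_strength": self.l2_strength,
                "epochs": self.epochs,
                "learning_rate": self.learning_rate,
                "batch_size": self.batch_size,
            },
            "seeds": {f"{p.positive}__{p.negative}": s for p, s in self.seed_ledger_.items()},
            "random_state": self.random_state,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for pair, net in self.networks_.items():
            state = net.state_dict()
            arrays = {k: v for k, v in state.items() if k != "config"}
            np.savez(directory / f"{pair.positive}__{pair.negative}.npz",
                     config=json.dumps(state["config"]), **arrays)

    @classmethod
    def load(cls, directory) -> "OvoEnsembleClassifier":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        spec = manifest["spec"]
        model = cls(random_state=manifest.get("random_state", 0),
                    class_order=tuple(manifest["class_order"]),
                    escore_weights=manifest["escore_weights"], **spec)
        model.classes_ = np.asarray(manifest["class_order"], dtype=object)
        model._weights = {k: float(v) for k, v in manifest["escore_weights"].items()}
        model.feature_names_in_ = np.asarray(manifest["gene_ids"], dtype=object)
        model.n_features_in_ = len(manifest["gene_ids"])
        model.pair_specs_ = build_pair_specs(model.classes_)
        model.networks_ = {}
        model.seed_ledger_ = {}
        for pair in model.pair_specs_:
            name = f"{pair.positive}__{pair.negative}"
            with np.load(directory / f"{name}.npz") as data:
                state = {k: data[k] for k in data.files if k != "config"}
                state["config"] = json.loads(str(data["config"]))
                model.networks_[pair] = DenseNetwork.from_state_dict(state)
            model.seed_ledger_[pair] = manifest["seeds"][name]
        return model


def train_ensemble(X, y, spec: DnnSpec | None = None, base_seed: int = 0, **kwargs) -> OvoEnsembleClassifier:
    """Convenience wrapper: fit an :class:`OvoEnsembleClassifier`.

    ``X`` is samples x features; ``spec`` overrides the member architecture.
    """
    spec = spec or DnnSpec()
    model = OvoEnsembleClassifier(
        hidden_layers=spec.hidden_layers,
        neurons_per_layer=spec.neurons_per_layer,
        activation=spec.activation,
        dropout=spec.dropout,
        l2_strength=spec.l2_strength,
        epochs=spec.epochs,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        random_state=base_seed,
        **kwargs,
    )
    return model.fit(X, y)
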