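"""Baseline classifier families and their hyperparameter search spaces.

Five families are provided — kNN, PCA-whitened logistic regression (LR),
SVM, gradient-boosted trees (GBM, via xgboost) and a multiclass deep
network (DNN) — each with the default search ranges used when tuning on
microarray corpora.  The multiclass DNN's optimum (2 x 200 ReLU, dropout
0.2, L2 0.03) seeds the one-vs-one ensemble in :mod:`embryoscore.ensemble`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .nn import DenseNetwork

FAMILIES = ("knn", "lr", "svm", "gbm", "dnn")

#: Default hyperparameter search spaces per family.  Each parameter is
#: ("int", lo, hi), ("float", lo, hi), ("logfloat", lo, hi) or
#: ("cat", [choices]).
DEFAULT_SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "knn": {
        "n_neighbors": ("int", 5, 20),
        "weights": ("cat", ["uniform", "distance"]),
        "metric": ("cat", ["manhattan", "euclidean", "minkowski3"]),
    },
    "lr": {
        "n_components": ("int", 100, 500),
        "C": ("logfloat", 0.1, 100.0),
    },
    "svm": {
        "kernel": ("cat", ["linear", "sigmoid", "poly", "rbf"]),
        "C": ("logfloat", 0.1, 100.0),
    },
    "gbm": {
        "n_estimators": ("int", 10, 100),
        "max_depth": ("int", 3, 8),
        "subsample": ("float", 0.5, 1.0),
        "gamma": ("float", 0.5, 1.0),
        "min_child_weight": ("int", 1, 5),
        "learning_rate": ("float", 0.005, 0.05),
    },
    "dnn": {
        "hidden_layers": ("int", 2, 4),
        "neurons_per_layer": ("int", 100, 500),
        "activation": ("cat", ["relu", "sigmoid", "tanh"]),
        "l2_strength": ("float", 0.01, 0.05),
        "dropout": ("float", 0.0, 0.5),
    },
}


def validate_params(family: str, params: dict) -> None:
    """Check a concrete parameter point against the family's search space."""
    if family not in DEFAULT_SEARCH_SPACES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    space = DEFAULT_SEARCH_SPACES[family]
    for name, value in params.items():
        if name not in space:
            continue  # fixed extras (epochs, batch size) pass through
        kind = space[name][0]
        if kind == "cat":
            if value not in space[name][1]:
                raise ValueError(f"{family}.{name}: {value!r} not in {space[name][1]}")
        else:
            lo, hi = space[name][1], space[name][2]
            if not lo <= value <= hi:
                raise ValueError(f"{family}.{name}: {value} outside [{lo}, {hi}]")


@dataclass
class DnnSpec:
    """Architecture and training schedule of one dense network.

    Defaults are the ensemble member settings: 2 hidden layers of 200 ReLU
    neurons, dropout 0.2, L2 0.03, trained 200 epochs with Adam.  Batch
    size 64 and the Adam default learning rate 1e-3 are package choices.
    """

    hidden_layers: int = 2
    neurons_per_layer: int = 200
    activation: str = "relu"
    dropout: float = 0.2
    l2_strength: float = 0.03
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class DNNClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass dense network with softmax output (scikit-learn API)."""

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
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        if len(self.classes_) < 2:
            raise ValueError("need samples of >= 2 classes")
        codes = self._encoder.transform(y)
        self.network_ = DenseNetwork(
            n_inputs=X.shape[1],
            n_outputs=len(self.classes_),
            hidden_layers=self.hidden_layers,
            neurons_per_layer=self.neurons_per_layer,
            activation=self.activation,
            dropout=self.dropout,
            l2_strength=self.l2_strength,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            output="softmax",
            seed=self.random_state,
        ).fit(X, codes)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty((0, len(self.classes_)))
        return self.network_.forward(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def _build_estimator(family: str, params: dict, seed: int, n_classes: int):
    p = dict(params)
    if family == "knn":
        metric = p.pop("metric", "euclidean")
        kw = {"metric": metric}
        if metric == "minkowski3":
            kw = {"metric": "minkowski", "p": 3}
        return KNeighborsClassifier(
            n_neighbors=p.pop("n_neighbors", 5), weights=p.pop("weights", "uniform"), **kw
        )
    if family == "lr":
        return Pipeline([
            ("pca", PCA(n_components=p.pop("n_components", 100), whiten=True, random_state=seed)),
            ("logreg", LogisticRegression(C=p.pop("C", 1.0), penalty="l2", max_iter=2000, random_state=seed)),
        ])
    if family == "svm":
        kernel = p.pop("kernel", "rbf")
        kw = {"degree": 3} if kernel == "poly" else {}
        return SVC(kernel=kernel, C=p.pop("C", 1.0), probability=True, random_state=seed, **kw)
    if family == "gbm":
        return XGBClassifier(
            n_estimators=p.pop("n_estimators", 50),
            max_depth=p.pop("max_depth", 4),
            subsample=p.pop("subsample", 1.0),
            gamma=p.pop("gamma", 0.5),
            min_child_weight=p.pop("min_child_weight", 1),
            learning_rate=p.pop("learning_rate", 0.05),
            objective="multi:softprob" if n_classes > 2 else "binary:logistic",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if family == "dnn":
        return DNNClassifier(random_state=seed, **p)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class TrainedClassifier:
    """A fitted family model bound to its training feature namespace."""

    family: str
    model: object
    class_order: list[str]
    training_gene_ids: list[str]
    params: dict = field(default_factory=dict)
    label_codes: object = None  # LabelEncoder for xgboost integer targets

    def _check_features(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            got = [str(c) for c in X.columns]
            if got != list(self.training_gene_ids):
                missing = set(self.training_gene_ids) - set(got)
                extra = set(got) - set(self.training_gene_ids)
                if missing or extra:
                    raise ValueError(
                        f"feature mismatch: missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}"
                    )
                X = X.loc[:, self.training_gene_ids]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.training_gene_ids):
            raise ValueError(
                f"expected {len(self.training_gene_ids)} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        arr = self._check_features(X)
        if arr.shape[0] == 0:
            return np.empty((0, len(self.class_order)))
        proba = self.model.predict_proba(arr)
        # reorder model classes into the declared class order
        model_classes = [str(c) for c in getattr(self.model, "classes_", self.class_order)]
        if self.label_codes is not None:
            model_classes = [str(c) for c in self.label_codes.inverse_transform(
                np.asarray(getattr(self.model, "classes_", range(len(self.class_order))), dtype=int))]
        order = [model_classes.index(c) for c in self.class_order]
        return proba[:, order]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.class_order, dtype=object)[np.argmax(proba, axis=1)]


def train_classifier(
    X,
    y,
    family: str,
    params: dict | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one family at a concrete hyperparameter point.

    ``X`` is samples x features (DataFrame preferred: column names become
    the bound feature namespace).  Deterministic for fixed (data, params,
    seed).
    """
    params = dict(params or {})
    validate_params(family, params)
    if isinstance(X, pd.DataFrame):
        gene_ids = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        gene_ids = [str(i) for i in range(arr.shape[1])]
    y = np.asarray(y, dtype=object)
    classes = sorted({str(c) for c in y})
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if family == "lr":
        n_comp = params.get("n_components", 100)
        if n_comp > min(arr.shape):
            raise ValueError(
                f"n_components={n_comp} exceeds min(n_samples, n_features)={min(arr.shape)}"
            )
    model = _build_estimator(family, params, seed, n_classes=len(classes))
    label_codes = None
    if family == "gbm":
        label_codes = LabelEncoder().fit(y.astype(str))
        model.fit(arr, label_codes.transform(y.astype(str)))
    else:
        model.fit(arr, y.astype(str))
    return TrainedClassifier(
        family=family,
        model=model,
        class_order=classes,
        training_gene_ids=gene_ids,
        params=params,
        label_codes=label_codes,
    )


def macro_f1(y_true, y_pred, class_order=None) -> float:
    """Unweighted mean of per-class F1 over ``class_order``.

    A class absent from both truth and prediction contributes 0 by
    convention.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if class_order is None:
        class_order = sorted({str(v) for v in y_true} | {str(v) for v in y_pred})
    return float(
        f1_score(y_true.astype(str), y_pred.astype(str), labels=list(class_order),
                 average="macro", zero_division=0)
    )
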