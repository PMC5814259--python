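"""Dataset-aware (group-aware) stratified nested cross-validation.

Public expression corpora come in batches (GEO series, array runs); a
classifier evaluated with folds that split a batch across training and
validation can memorize the batch instead of the biology, and its
performance is greatly overestimated.  The splitter here therefore keeps
every source dataset (group) intact on one side of each split, and the
nested loop tunes hyperparameters (TPE) strictly inside the outer training
portion, reporting three scores per fold:

* ``Training`` — inner-loop training-side score of the selected point,
* ``Int. validation`` — inner-loop mean validation score (the TPE target),
* ``Ext. validation`` — the unbiased score on the held-out outer fold.

``naive_cv`` deliberately ignores the group structure (class-stratified
folds only) to expose the overestimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import tpe
from .classifiers import DEFAULT_SEARCH_SPACES, macro_f1, train_classifier
from .ensemble import CANONICAL_CLASSES

logger = logging.getLogger(__name__)


def _class_order(labels: pd.Series) -> list[str]:
    present = set(labels.astype(str))
    ordered = [c for c in CANONICAL_CLASSES if c in present]
    return ordered + sorted(present - set(ordered))


@dataclass
class FoldPlan:
    """k folds of group ids partitioning the corpus (no group split)."""

    folds: list[list]
    group_of: pd.Series  # sample_id -> group_id

    def __post_init__(self) -> None:
        seen = [g for fold in self.folds for g in fold]
        if len(seen) != len(set(seen)):
            raise ValueError("a group appears in more than one fold")

    def test_mask(self, fold: int) -> np.ndarray:
        groups = set(self.folds[fold])
        return self.group_of.isin(groups).to_numpy()


def make_group_stratified_folds(labels: pd.DataFrame, k: int = 3, seed: int = 0) -> FoldPlan:
    """Assign whole groups to k folds, balancing per-class sample counts.

    ``labels`` has columns ``class_label`` and ``group_id`` indexed by
    sample id.  Groups are placed greedily, largest first (ties randomized
    by ``seed``), each into the fold where the resulting per-class counts
    stay most balanced.  Raises if there are fewer groups than folds; warns
    when a class lives entirely inside one group (it becomes untestable in
    the folds that train on that group).
    """
    if not {"class_label", "group_id"} <= set(labels.columns):
        raise ValueError("labels need 'class_label' and 'group_id' columns")
    classes = _class_order(labels["class_label"])
    groups = labels["group_id"].unique().tolist()
    if len(groups) < k:
        raise ValueError(f"need >= {k} groups for {k}-fold splitting, got {len(groups)}")
    for cls, sub in labels.groupby("class_label", observed=True):
        if sub["group_id"].nunique() == 1:
            warnings.warn(
                f"class {cls!r} occurs in a single group; it is untestable in some folds",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    sizes = labels.groupby("group_id", observed=True).size()
    order = sorted(groups, key=lambda g: (-sizes[g], rng.random()))
    comp = {
        g: labels.loc[labels["group_id"] == g, "class_label"].value_counts()
        for g in groups
    }
    fold_counts = [pd.Series(0, index=classes, dtype=float) for _ in range(k)]
    folds: list[list] = [[] for _ in range(k)]
    for g in order:
        add = comp[g].reindex(classes, fill_value=0)
        # imbalance after adding g to fold f: sum of squared per-class counts
        costs = [float(((fold_counts[f] + add) ** 2).sum()) for f in range(k)]
        f = int(np.argmin(costs))
        folds[f].append(g)
        fold_counts[f] += add
    return FoldPlan(folds=folds, group_of=labels["group_id"])


@dataclass
class CvReport:
    """Cross-validation outcome: per-fold records plus pooled confusion."""

    family: str
    class_order: list[str]
    fold_records: list[dict] = field(default_factory=list)
    confusion: pd.DataFrame | None = None

    def score(self, role: str) -> float:
        """Mean score over folds for role 'Training' / 'Int. validation' / 'Ext. validation'."""
        vals = [r[role] for r in self.fold_records if role in r and r[role] is not None]
        if not vals:
            raise KeyError(f"no {role!r} scores recorded")
        return float(np.mean(vals))

    def pooled_macro_f1(self) -> float:
        """Macro-F1 from the pooled held-out confusion matrix.

        Pooling tests every sample exactly once, so classes that are
        untestable in individual folds (all their groups on the training
        side) still contribute.
        """
        cm = self.confusion.to_numpy(dtype=float)
        f1s = []
        for i in range(cm.shape[0]):
            tp = cm[i, i]
            prec = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
            rec = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        return float(np.mean(f1s))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "class_order": self.class_order,
            "folds": self.fold_records,
            "scores": {
                role: self.score(role)
                for role in ("Training", "Int. validation", "Ext. validation")
                if any(role in r for r in self.fold_records)
            },
            "confusion": None if self.confusion is None else self.confusion.to_dict(),
        }


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[str(i) for i in range(X.shape[1])])


def _confusion(y_true, y_pred, classes) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[str(t), str(p)] += 1
    return cm


def _inner_scores(X, labels, family, point, k, seed):
    """Group-aware k-fold of one concrete point; returns (train_mean, val_mean)."""
    plan = make_group_stratified_folds(labels, k=k, seed=seed)
    train_scores, val_scores = [], []
    for f in range(k):
        test_mask = plan.test_mask(f)
        clf = train_classifier(X.loc[~test_mask], labels.loc[~test_mask, "class_label"],
                               family, point, seed=seed + f)
        order = clf.class_order
        train_scores.append(macro_f1(labels.loc[~test_mask, "class_label"],
                                     clf.predict(X.loc[~test_mask]), order))
        val_scores.append(macro_f1(labels.loc[test_mask, "class_label"],
                                   clf.predict(X.loc[test_mask]), order))
    return float(np.mean(train_scores)), float(np.mean(val_scores))


def nested_cv(
    X,
    labels: pd.DataFrame,
    family: str,
    space: dict | None = None,
    budget: int = 50,
    k: int = 3,
    seed: int = 0,
    fixed_params: dict | None = None,
) -> CvReport:
    """Group-aware nested cross-validation with inner TPE tuning.

    The outer loop holds out one group-fold; the inner loop tunes the
    family's hyperparameters by TPE for ``budget`` evaluations, each scored
    as the mean validation macro-F1 of an inner group-aware ``k``-fold.
    The selected point is refit on the whole outer-training portion and
    scored once on the held-out fold ("Ext. validation").  With
    ``fixed_params`` and ``budget=1`` this reduces to plain group-aware
    k-fold of that point.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X = _as_frame(X)
    labels = labels.loc[X.index] if X.index.equals(labels.index) or set(X.index) <= set(labels.index) else labels
    if len(labels) != len(X):
        raise ValueError("labels and X disagree in length")
    space = space if space is not None else DEFAULT_SEARCH_SPACES[family]
    classes = _class_order(labels["class_label"])
    plan = make_group_stratified_folds(labels, k=k, seed=seed)
    report = CvReport(family=family, class_order=classes)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for f in range(k):
        test_mask = plan.test_mask(f)
        X_tr, lab_tr = X.loc[~test_mask], labels.loc[~test_mask]
        X_te, lab_te = X.loc[test_mask], labels.loc[test_mask]
        assert not set(X_tr.index) & set(X_te.index), "train/test sample leakage"

        if fixed_params is not None and budget == 1:
            best_point = dict(fixed_params)
        else:
            def objective(point):
                _, val = _inner_scores(X_tr, lab_tr, family, point, k, seed + 1000 * (f + 1))
                return -val
            best_point, _ = tpe.minimize(objective, space, budget, seed=seed + f)
        train_score, int_val = _inner_scores(X_tr, lab_tr, family, best_point, k,
                                             seed + 1000 * (f + 1))
        clf = train_classifier(X_tr, lab_tr["class_label"], family, best_point, seed=seed + f)
        y_pred = clf.predict(X_te)
        ext = macro_f1(lab_te["class_label"], y_pred, classes)
        confusion += _confusion(lab_te["class_label"], y_pred, classes)
        report.fold_records.append({
            "fold": f,
            "test_groups": list(plan.folds[f]),
            "best_params": best_point,
            "Training": train_score,
            "Int. validation": int_val,
            "Ext. validation": ext,
        })
    report.confusion = confusion
    assert int(confusion.to_numpy().sum()) == len(X)
    return report


def grouped_cv_ensemble(
    X,
    labels: pd.DataFrame,
    spec=None,
    k: int = 3,
    seed: int = 0,
) -> CvReport:
    """Group-aware k-fold evaluation of the one-vs-one DNN ensemble.

    Ensemble hyperparameters are fixed (the multiclass optimum), so there
    is no inner tuning loop; each fold holds out whole groups, trains the
    ensemble on the rest, and the pooled confusion matrix covers every
    sample once.
    """
    from .ensemble import train_ensemble

    X = _as_frame(X)
    classes = _class_order(labels["class_label"])
    plan = make_group_stratified_folds(labels, k=k, seed=seed)
    report = CvReport(family="dnn_ensemble", class_order=classes)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for f in range(k):
        test_mask = plan.test_mask(f)
        model = train_ensemble(
            X.loc[~test_mask], labels.loc[~test_mask, "class_label"], spec=spec,
            base_seed=seed + f,
        )
        y_pred = model.predict(X.loc[test_mask])
        y_true = labels.loc[test_mask, "class_label"]
        confusion += _confusion(y_true, y_pred, classes)
        report.fold_records.append({
            "fold": f,
            "test_groups": list(plan.folds[f]),
            "Ext. validation": macro_f1(y_true, y_pred, classes),
        })
    report.confusion = confusion
    return report


def naive_cv(
    X,
    labels: pd.DataFrame,
    family: str,
    point: dict,
    k: int = 3,
    seed: int = 0,
) -> CvReport:
    """Class-stratified k-fold that ignores group structure (for contrast).

    Same scoring machinery as :func:`nested_cv` at a fixed point, but folds
    stratify on class only, so samples of one source dataset can sit on
    both sides of a split — the leakage the group-aware splitter prevents.
    """
    X = _as_frame(X)
    classes = _class_order(labels["class_label"])
    report = CvReport(family=family, class_order=classes)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = labels["class_label"].astype(str).to_numpy()
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        clf = train_classifier(X.iloc[tr], y[tr], family, point, seed=seed + f)
        y_pred = clf.predict(X.iloc[te])
        ext = macro_f1(y[te], y_pred, classes)
        confusion += _confusion(y[te], y_pred, classes)
        report.fold_records.append({
            "fold": f,
            "best_params": dict(point),
            "Training": macro_f1(y[tr], clf.predict(X.iloc[tr]), classes),
            "Ext. validation": ext,
        })
    report.confusion = confusion
    return report
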