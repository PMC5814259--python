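"""Synthetic multiclass expression corpora with batch structure.

The generator emulates, at desk scale, a curated multi-dataset microarray
corpus of five developmental classes (ESC, iPSC, EPC, ASC, AC).  On log2
scale each value is

    base + class_offset(class, gene) + batch_offset(group, gene) + noise

with the class offsets drawn once per class per gene (SD ``class_signal_sd``),
additive per-(group, gene) batch effects (SD ``batch_sd``) emulating
source-dataset technical variation, and i.i.d. per-sample noise.  The iPSC
signature is a weighted copy of the ESC signature
(``esc_ipsc_similarity``), because well-reprogrammed iPSCs are nearly
indistinguishable from ESCs at the transcriptome level.  Marker genes with
chosen per-class means can be planted (e.g. an adult-high / embryonic-low
COX7A1-like gene and its embryonic-high LIN28B-like mirror) to give
importance methods a known recovery target.  Output is exponentiated to
linear intensity scale so it flows through the same preprocessing path as
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import CANONICAL_CLASSES
from .matrix import ExpressionMatrix


@dataclass
class SimConfig:
    """Study-condition knobs of the corpus generator.

    Defaults describe a well-separated five-class corpus spread over 12
    source datasets: 2,000 genes, 40 samples per class, class signal and
    batch effects of comparable scale (1.0 and 0.5 log2 units), mild sample
    noise, and iPSC sharing 95% of the ESC signature.
    """

    n_genes: int = 2000
    classes: tuple = CANONICAL_CLASSES
    samples_per_class: int = 40
    n_groups: int = 12
    class_signal_sd: float = 1.0
    batch_sd: float = 0.5
    noise_sd: float = 0.3
    esc_ipsc_similarity: float = 0.95
    planted_markers: tuple = ()  # of (gene_id, {class: log2 mean})
    base_expression: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("class_signal_sd", "batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0.0 <= self.esc_ipsc_similarity <= 1.0:
            raise ValueError("esc_ipsc_similarity must be in [0, 1]")
        marker_ids = [m[0] for m in self.planted_markers]
        if len(marker_ids) != len(set(marker_ids)):
            raise ValueError("planted marker gene_ids must be distinct")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")


@dataclass
class SimOutput:
    """Simulated corpus plus its ground truth."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame  # sample_id -> class_label, group_id
    signature_table: pd.DataFrame  # genes x classes, true log2 means

    def sklearn_xy(self):
        """(X samples x features, y class labels) view."""
        return self.matrix.to_sklearn(), self.truth["class_label"]


def _gene_ids(cfg: SimConfig) -> list[str]:
    ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    for j, (gid, _) in enumerate(cfg.planted_markers):
        ids[j] = str(gid)  # markers occupy the leading rows under their own names
    return ids


def _signatures(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    offsets = {}
    esc_offset = None
    for cls in cfg.classes:
        draw = rng.normal(0.0, cfg.class_signal_sd, size=cfg.n_genes)
        if cls == "ESC":
            esc_offset = draw
        if cls == "iPSC" and esc_offset is not None:
            s = cfg.esc_ipsc_similarity
            draw = s * esc_offset + (1.0 - s) * draw
        offsets[cls] = draw
    sig = pd.DataFrame(offsets, index=_gene_ids(cfg)) + cfg.base_expression
    for gid, means in cfg.planted_markers:
        for cls, mu in means.items():
            sig.loc[str(gid), cls] = float(mu)
    return sig


def simulate_corpus(cfg: SimConfig) -> SimOutput:
    """Draw a full corpus; bit-reproducible for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sig = _signatures(cfg, rng)
    batch = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_groups, cfg.n_genes))
    n = len(cfg.classes) * cfg.samples_per_class
    labels = np.repeat(list(cfg.classes), cfg.samples_per_class)
    # source datasets are class-linked, as in real corpora: a GEO series
    # contributes samples of (mostly) one class, which is what confounds
    # batch with biology and makes naive CV leak
    n_classes = len(cfg.classes)
    if cfg.n_groups < n_classes:
        raise ValueError(
            f"n_groups={cfg.n_groups} must be >= the number of classes ({n_classes}) "
            "so every class spans at least one source dataset"
        )
    groups_of_class = {
        cls: [g + 1 for g in range(cfg.n_groups) if g % n_classes == i]
        for i, cls in enumerate(cfg.classes)
    }
    group_ids = np.empty(n, dtype=int)
    for i, cls in enumerate(cfg.classes):
        own = groups_of_class[cls]
        idx = np.where(labels == cls)[0]
        group_ids[idx] = [own[j % len(own)] for j in range(len(idx))]
    cols, names = [], []
    for i, (cls, grp) in enumerate(zip(labels, group_ids)):
        log2 = (
            sig[cls].to_numpy()
            + batch[grp - 1]
            + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        )
        cols.append(2.0 ** log2)
        names.append(f"S{i:04d}")
    values = pd.DataFrame(np.column_stack(cols), index=sig.index, columns=names)
    truth = pd.DataFrame(
        {"class_label": labels, "group_id": [f"D{g:02d}" for g in group_ids]},
        index=names,
    )
    matrix = ExpressionMatrix(values=values, feature_space="gene", metadata=truth)
    return SimOutput(matrix=matrix, truth=truth, signature_table=sig)


def make_differentiation_series(
    cfg: SimConfig,
    n_steps: int,
    samples_per_step: int = 5,
) -> ExpressionMatrix:
    """Samples interpolating from the ESC signature to the AC signature.

    Step t of ``n_steps`` has true log2 signature
    ``(1 - t/(n-1)) * ESC + t/(n-1) * AC`` plus sample noise — a stylized
    differentiation time course on which the Embryonic Score should decay
    monotonically in expectation.  Metadata records the step index.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not {"ESC", "AC"} <= set(cfg.classes):
        raise ValueError("config must contain both ESC and AC classes")
    rng = np.random.default_rng(cfg.seed)
    sig = _signatures(cfg, rng)
    esc, ac = sig["ESC"].to_numpy(), sig["AC"].to_numpy()
    cols, names, steps = [], [], []
    for t in range(n_steps):
        alpha = t / (n_steps - 1)
        mean = (1.0 - alpha) * esc + alpha * ac
        for r in range(samples_per_step):
            log2 = mean + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            cols.append(2.0 ** log2)
            names.append(f"T{t:02d}_{r:02d}")
            steps.append(t)
    values = pd.DataFrame(np.column_stack(cols), index=sig.index, columns=names)
    meta = pd.DataFrame({"step": steps}, index=names)
    return ExpressionMatrix(values=values, feature_space="gene", metadata=meta)
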