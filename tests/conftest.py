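"""Shared fixtures: simulated corpora and trained ensembles.

Heavy artifacts (trained one-vs-one ensembles) are session-scoped and use
a documented scaled-down member architecture (2 x 50 neurons, 50 epochs)
so the whole suite runs on one CPU in minutes.
"""

import warnings

import numpy as np
import pytest

from embryoscore import DnnSpec, SimConfig, simulate_corpus, train_ensemble
from embryoscore.evaluation import grouped_cv_ensemble

SCALED = dict(neurons_per_layer=50, epochs=50)

#: Planted anti-correlated marker pair: an adult-high / embryonic-low gene
#: (COX7A1-like) and its embryonic-high mirror (LIN28B-like), log2 means.
MARKER_PAIR = (
    ("COX7A1like", {"ESC": 5.0, "iPSC": 5.3, "EPC": 6.5, "ASC": 8.0, "AC": 11.0}),
    ("LIN28Blike", {"ESC": 11.0, "iPSC": 10.7, "EPC": 9.5, "ASC": 8.0, "AC": 5.0}),
)


def log2_xy(sim):
    X, y = sim.sklearn_xy()
    return np.log2(X + 1), y


@pytest.fixture(scope="session")
def separable_cfg():
    # distinguishable iPSC residual; all other knobs at generator defaults
    return SimConfig(seed=11, esc_ipsc_similarity=0.5)


@pytest.fixture(scope="session")
def separable_sim(separable_cfg):
    return simulate_corpus(separable_cfg)


@pytest.fixture(scope="session")
def separable_ensemble(separable_sim):
    X, y = log2_xy(separable_sim)
    return train_ensemble(X, y, spec=DnnSpec(**SCALED), base_seed=7)


@pytest.fixture(scope="session")
def separable_cv_report(separable_sim):
    X, y = log2_xy(separable_sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return grouped_cv_ensemble(X, separable_sim.truth, spec=DnnSpec(**SCALED), k=3, seed=7)


@pytest.fixture(scope="session")
def confusable_cv_report():
    sim = simulate_corpus(SimConfig(seed=11, esc_ipsc_similarity=1.0))
    X, y = log2_xy(sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return grouped_cv_ensemble(X, sim.truth, spec=DnnSpec(**SCALED), k=3, seed=7)
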