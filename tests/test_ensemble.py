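import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryoscore import DnnSpec, SimConfig, simulate_corpus, train_ensemble
from embryoscore.ensemble import (
    CANONICAL_CLASSES,
    DEFAULT_ESCORE_WEIGHTS,
    OvoEnsembleClassifier,
    PairSpec,
    build_pair_specs,
    embryonic_score,
    predict_class,
)

from conftest import log2_xy


class TestPairSpecs:
    def test_five_classes_give_twenty_directional_pairs(self):
        pairs = build_pair_specs(CANONICAL_CLASSES)
        assert len(pairs) == 20
        assert len(set(pairs)) == 20
        for p in pairs:
            assert p.positive != p.negative
        # every ordered pair exactly once
        assert {(p.positive, p.negative) for p in pairs} == {
            (a, b) for a in CANONICAL_CLASSES for b in CANONICAL_CLASSES if a != b
        }

    def test_two_classes_give_two_pairs(self):
        assert len(build_pair_specs(["ESC", "AC"])) == 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_pair_specs(["ESC"])

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PairSpec("ESC", "ESC")


class _StubNet:
    """Fixed-output network standing in for a trained member."""

    def __init__(self, value):
        self.value = value

    def forward(self, X):
        return np.full((np.asarray(X).shape[0], 1), self.value)


def mock_ensemble(outputs):
    """Fitted-looking ensemble whose (pos, neg) network returns outputs[(pos, neg)]."""
    model = OvoEnsembleClassifier()
    model.classes_ = np.asarray(CANONICAL_CLASSES, dtype=object)
    model.feature_names_in_ = np.asarray(["g0", "g1"], dtype=object)
    model.n_features_in_ = 2
    model._weights = dict(DEFAULT_ESCORE_WEIGHTS)
    model.pair_specs_ = build_pair_specs(CANONICAL_CLASSES)
    model.networks_ = {
        p: _StubNet(outputs.get((p.positive, p.negative), 0.0)) for p in model.pair_specs_
    }
    model.seed_ledger_ = {p: 0 for p in model.pair_specs_}
    return model


class TestVoteAggregation:
    def test_class_vote_sums_its_four_positive_networks(self):
        outputs = {("ESC", neg): 1.0 for neg in CANONICAL_CLASSES if neg != "ESC"}
        model = mock_ensemble(outputs)
        votes = model.ensemble_votes(np.zeros(2))
        assert votes == {"ESC": 4.0, "iPSC": 0.0, "EPC": 0.0, "ASC": 0.0, "AC": 0.0}

    def test_uniform_half_outputs_give_two_votes_each(self):
        model = mock_ensemble({(a, b): 0.5 for a in CANONICAL_CLASSES for b in CANONICAL_CLASSES})
        votes = model.ensemble_votes(np.zeros(2))
        assert votes == {c: 2.0 for c in CANONICAL_CLASSES}

    def test_votes_invariant_to_network_storage_order(self):
        rng = np.random.default_rng(0)
        outputs = {
            (a, b): float(rng.random())
            for a in CANONICAL_CLASSES
            for b in CANONICAL_CLASSES
            if a != b
        }
        model = mock_ensemble(outputs)
        votes1 = model.ensemble_votes(np.zeros(2))
        permuted = mock_ensemble(outputs)
        items = list(permuted.networks_.items())
        permuted.networks_ = dict(reversed(items))
        votes2 = permuted.ensemble_votes(np.zeros(2))
        assert votes2 == pytest.approx(votes1)

    def test_feature_mismatch_rejected(self):
        model = mock_ensemble({})
        with pytest.raises(ValueError, match="features"):
            model.decision_function(np.zeros((1, 5)))


class TestPredictClass:
    def test_forced_argmax(self):
        assert predict_class({"ESC": 4.0, "iPSC": 0, "EPC": 0, "ASC": 0, "AC": 0}) == "ESC"
        assert predict_class({"ESC": 0, "iPSC": 0, "EPC": 0, "ASC": 0, "AC": 4.0}) == "AC"

    def test_exact_tie_breaks_to_canonical_order(self, caplog):
        votes = {"ESC": 3.0, "iPSC": 3.0, "EPC": 0, "ASC": 0, "AC": 0}
        with caplog.at_level("INFO"):
            assert predict_class(votes) == "ESC"
        assert any("tie" in rec.message for rec in caplog.records)


class TestEmbryonicScore:
    def test_pure_esc_scores_one(self):
        assert embryonic_score({"ESC": 4.0, "iPSC": 0, "EPC": 0, "ASC": 0, "AC": 0}) == 1.0

    def test_pure_ac_scores_zero(self):
        assert embryonic_score({"ESC": 0, "iPSC": 0, "EPC": 0, "ASC": 0, "AC": 4.0}) == 0.0

    def test_equal_votes_hand_oracle(self):
        # (1.0 + 0.9 + 0.7 + 0.5 + 0.0) / 5
        votes = {c: 1.0 for c in CANONICAL_CLASSES}
        assert embryonic_score(votes) == pytest.approx(0.62)

    def test_esc_asc_split_hand_oracle(self):
        # (2*1.0 + 2*0.5) / 4
        votes = {"ESC": 2.0, "iPSC": 0, "EPC": 0, "ASC": 2.0, "AC": 0}
        assert embryonic_score(votes) == pytest.approx(0.75)

    def test_all_zero_votes_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            embryonic_score({c: 0.0 for c in CANONICAL_CLASSES})

    def test_negative_votes_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            embryonic_score({"ESC": -1.0, "iPSC": 1, "EPC": 0, "ASC": 0, "AC": 0})

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        st.lists(st.floats(0, 4, allow_nan=False), min_size=5, max_size=5),
        st.floats(1e-3, 1e3, allow_nan=False),
    )
    def test_scale_invariance_and_bounds(self, votes, scale):
        vec = dict(zip(CANONICAL_CLASSES, votes))
        if sum(votes) <= 0:
            return
        base = embryonic_score(vec)
        scaled = embryonic_score({c: v * scale for c, v in vec.items()})
        assert scaled == pytest.approx(base, rel=1e-9)
        weights = DEFAULT_ESCORE_WEIGHTS
        assert min(weights.values()) - 1e-12 <= base <= max(weights.values()) + 1e-12

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.lists(st.floats(0.01, 4, allow_nan=False), min_size=5, max_size=5),
           st.floats(0.001, 0.009))
    def test_moving_mass_to_higher_weight_never_decreases(self, votes, delta):
        vec = dict(zip(CANONICAL_CLASSES, votes))
        before = embryonic_score(vec)
        moved = dict(vec)
        moved["AC"] -= delta  # lowest weight
        moved["ESC"] += delta  # highest weight
        assert embryonic_score(moved) >= before - 1e-12


@pytest.fixture(scope="module")
def tiny():
    cfg = SimConfig(n_genes=120, samples_per_class=8, n_groups=5,
                    esc_ipsc_similarity=0.5, seed=3)
    sim = simulate_corpus(cfg)
    return log2_xy(sim)


class TestTrainedEnsemble:

    def test_five_class_data_yields_twenty_networks(self, tiny):
        X, y = tiny
        model = train_ensemble(X, y, spec=DnnSpec(neurons_per_layer=10, epochs=5), base_seed=1)
        assert len(model.networks_) == 20
        assert len(model.seed_ledger_) == 20

    def test_identical_base_seed_reproduces_votes(self, tiny):
        X, y = tiny
        spec = DnnSpec(neurons_per_layer=10, epochs=5)
        v1 = train_ensemble(X, y, spec=spec, base_seed=9).decision_function(X.iloc[:3])
        v2 = train_ensemble(X, y, spec=spec, base_seed=9).decision_function(X.iloc[:3])
        pd.testing.assert_frame_equal(v1, v2)

    def test_class_with_too_few_samples_named_in_error(self, tiny):
        X, y = tiny
        keep = (y != "AC") | (y.index == y.index[y == "AC"][0])
        with pytest.raises(ValueError, match="AC"):
            train_ensemble(X[keep.to_numpy()], y[keep.to_numpy()],
                           spec=DnnSpec(neurons_per_layer=10, epochs=5))

    def test_save_load_round_trip(self, tiny, tmp_path):
        X, y = tiny
        model = train_ensemble(X, y, spec=DnnSpec(neurons_per_layer=10, epochs=5), base_seed=2)
        model.save(tmp_path / "model")
        back = OvoEnsembleClassifier.load(tmp_path / "model")
        pd.testing.assert_frame_equal(
            model.decision_function(X.iloc[:4]), back.decision_function(X.iloc[:4])
        )
        np.testing.assert_array_equal(model.embryonic_score(X.iloc[:4]),
                                      back.embryonic_score(X.iloc[:4]))


def test_pairwise_networks_separate_strong_classes(separable_ensemble, separable_sim):
    """Held-out-free check: every pairwise network distinguishes its two
    classes on training data when signatures are well separated."""
    X, y = log2_xy(separable_sim)
    arr = X.to_numpy()
    yv = y.to_numpy()
    for pair, net in separable_ensemble.networks_.items():
        mask = (yv == pair.positive) | (yv == pair.negative)
        p = net.forward(arr[mask])[:, 0]
        acc = ((p > 0.5) == (yv[mask] == pair.positive)).mean()
        assert acc >= 0.95, f"{pair} accuracy {acc}"
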