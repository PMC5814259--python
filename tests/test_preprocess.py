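import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from embryoscore.matrix import ExpressionMatrix
from embryoscore.preprocess import (
    BackgroundPolicy,
    QuantileReference,
    QuantileReferenceNormalizer,
    aggregate_probes,
    apply_quantile_reference,
    fit_quantile_reference,
    mask_background,
)


def probe_matrix(values, probes, samples=None):
    samples = samples or [f"s{i}" for i in range(np.asarray(values).shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=samples), feature_space="probe"
    )


ANN = pd.Series({"p1": "G", "p2": "G", "p3": "H"})


class TestAggregateProbes:
    def test_geometric_mean_of_two_probes(self):
        m = probe_matrix([[4.0], [9.0], [8.0]], ["p1", "p2", "p3"])
        out = aggregate_probes(m, ANN)
        assert out.values.loc["G", "s0"] == pytest.approx(6.0)
        assert out.values.loc["H", "s0"] == 8.0  # single probe passes through
        assert out.feature_space == "gene"

    def test_matches_exp_mean_log_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 100, size=(3, 4))
        m = probe_matrix(vals, ["p1", "p2", "x"])
        ann = pd.Series({"p1": "G", "p2": "G", "x": "G"})
        out = aggregate_probes(m, ann)
        oracle = np.exp(np.mean(np.log(vals), axis=0))
        np.testing.assert_allclose(out.values.loc["G"].to_numpy(), oracle, atol=1e-12)

    def test_invariant_to_probe_and_sample_order(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 50, size=(3, 3))
        m = probe_matrix(vals, ["p1", "p2", "p3"])
        shuffled = ExpressionMatrix(
            m.values.iloc[[2, 0, 1], [1, 2, 0]], feature_space="probe"
        )
        a = aggregate_probes(m, ANN).values
        b = aggregate_probes(shuffled, ANN).values
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_unannotated_probes_dropped(self):
        m = probe_matrix([[4.0], [9.0], [8.0], [2.0]], ["p1", "p2", "p3", "unknown"])
        out = aggregate_probes(m, ANN)
        assert set(out.feature_ids) == {"G", "H"}

    def test_non_positive_multi_probe_value_errors(self):
        m = probe_matrix([[0.0], [9.0]], ["p1", "p2"])
        with pytest.raises(ValueError, match="geometric mean undefined"):
            aggregate_probes(m, ANN)

    def test_pseudo_floor_rescues_non_positive(self):
        m = probe_matrix([[0.0], [9.0]], ["p1", "p2"])
        out = aggregate_probes(m, ANN, pseudo_floor=1.0)
        assert out.values.loc["G", "s0"] == pytest.approx(3.0)  # sqrt(1*9)


class TestMaskBackground:
    def test_floor_raises_sub_threshold_values(self):
        m = ExpressionMatrix(pd.DataFrame([[100.0], [200.0]], index=["a", "b"], columns=["s"]))
        out = mask_background(m, BackgroundPolicy(threshold=130, mode="floor"))
        assert out.values.loc["a", "s"] == 130.0
        assert out.values.loc["b", "s"] == 200.0

    def test_boundary_value_unchanged(self):
        m = ExpressionMatrix(pd.DataFrame([[130.0]], index=["a"], columns=["s"]))
        out = mask_background(m, BackgroundPolicy(threshold=130, mode="floor"))
        assert out.values.loc["a", "s"] == 130.0  # strict "under"

    def test_drop_removes_all_background_features(self):
        m = ExpressionMatrix(
            pd.DataFrame([[100.0, 120.0], [100.0, 150.0]], index=["a", "b"], columns=["s1", "s2"])
        )
        out = mask_background(m, BackgroundPolicy(threshold=130, mode="drop"))
        assert out.feature_ids == ["b"]

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            BackgroundPolicy(threshold=-1)
        with pytest.raises(ValueError):
            BackgroundPolicy(mode="clip")


class TestQuantileReference:
    def test_fit_matches_hand_oracle(self):
        # samples (1,5) and (3,7): sorted columns averaged rank-wise -> (2,6)
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 3.0], [5.0, 7.0]], index=["g1", "g2"], columns=["s1", "s2"])
        )
        ref = fit_quantile_reference(m)
        np.testing.assert_array_equal(ref.quantiles, [2.0, 6.0])
        assert ref.gene_ids == ["g1", "g2"]

    def test_identical_columns_give_shared_sorted_column(self):
        col = np.array([7.0, 1.0, 4.0])
        m = ExpressionMatrix(
            pd.DataFrame(np.column_stack([col, col]), index=list("abc"), columns=["s1", "s2"])
        )
        ref = fit_quantile_reference(m)
        np.testing.assert_array_equal(ref.quantiles, np.sort(col))

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["s"]))
        with pytest.raises(ValueError, match=">= 2"):
            fit_quantile_reference(m)

    def test_apply_rank_maps_onto_reference(self):
        ref = QuantileReference(quantiles=[2.0, 6.0], gene_ids=["g1", "g2"])
        m = ExpressionMatrix(pd.DataFrame([[10.0], [20.0]], index=["g1", "g2"], columns=["x"]))
        out = apply_quantile_reference(m, ref)
        assert out.values["x"].tolist() == [2.0, 6.0]

    def test_reference_values_are_fixed_point(self):
        ref = QuantileReference(quantiles=[2.0, 6.0], gene_ids=["g1", "g2"])
        m = ExpressionMatrix(pd.DataFrame([[2.0], [6.0]], index=["g1", "g2"], columns=["x"]))
        out = apply_quantile_reference(m, ref)
        assert out.values["x"].tolist() == [2.0, 6.0]

    def test_ties_receive_mean_of_tied_quantiles(self):
        ref = QuantileReference(quantiles=[2.0, 6.0], gene_ids=["g1", "g2"])
        m = ExpressionMatrix(pd.DataFrame([[5.0], [5.0]], index=["g1", "g2"], columns=["x"]))
        out = apply_quantile_reference(m, ref)
        assert out.values["x"].tolist() == [4.0, 4.0]

    def test_normalized_training_columns_share_sorted_values(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 1000, size=(30, 6))
        m = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(30)],
                                          columns=[f"s{j}" for j in range(6)]))
        ref = fit_quantile_reference(m)
        out = apply_quantile_reference(m, ref)
        for col in out.sample_ids:
            np.testing.assert_allclose(np.sort(out.values[col].to_numpy()), ref.quantiles)

    def test_serialization_round_trips_bit_identically(self, tmp_path):
        rng = np.random.default_rng(3)
        ref = QuantileReference(
            quantiles=np.sort(rng.uniform(0, 1, 20)),
            gene_ids=[f"g{i}" for i in range(20)],
            provenance="platform=test\nn_samples=5",
        )
        path = tmp_path / "ref.tsv"
        ref.save(path)
        back = QuantileReference.load(path)
        np.testing.assert_array_equal(back.quantiles, ref.quantiles)
        assert back.gene_ids == ref.gene_ids
        assert "platform=test" in back.provenance

    def test_missing_genes_error_lists_them(self):
        ref = QuantileReference(quantiles=[1.0, 2.0, 3.0], gene_ids=["a", "b", "c"])
        m = ExpressionMatrix(pd.DataFrame([[5.0], [9.0]], index=["a", "b"], columns=["x"]))
        with pytest.raises(ValueError, match="'c'"):
            apply_quantile_reference(m, ref)

    def test_median_impute_fills_missing_genes(self):
        ref = QuantileReference(quantiles=[1.0, 2.0, 3.0], gene_ids=["a", "b", "c"])
        m = ExpressionMatrix(pd.DataFrame([[5.0], [9.0]], index=["a", "b"], columns=["x"]))
        out = apply_quantile_reference(m, ref, missing_policy="median_impute")
        assert out.feature_ids == ["a", "b", "c"]
        assert np.isfinite(out.values.to_numpy()).all()

    def test_empty_gene_intersection_errors(self):
        ref = QuantileReference(quantiles=[1.0], gene_ids=["zzz"])
        m = ExpressionMatrix(pd.DataFrame([[5.0]], index=["a"], columns=["x"]))
        with pytest.raises(ValueError, match="no overlap"):
            apply_quantile_reference(m, ref)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(arrays(np.float64, 12, elements=st.floats(0, 1e4, allow_nan=False, width=32)))
    def test_rank_preservation_property(self, sample):
        ref = QuantileReference(
            quantiles=np.sort(np.linspace(1, 100, 12)), gene_ids=[f"g{i}" for i in range(12)]
        )
        norm = ref.to_normalizer()
        out = norm.transform(sample[None, :]).to_numpy()[0]
        # output ordering equals input ordering; ties map to equal outputs
        for i in range(12):
            for j in range(12):
                if sample[i] < sample[j]:
                    assert out[i] < out[j]
                elif sample[i] == sample[j]:
                    assert out[i] == out[j]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotence_property(self, seed):
        rng = np.random.default_rng(seed)
        ref = QuantileReference(
            quantiles=np.sort(rng.uniform(0, 50, 15)), gene_ids=[f"g{i}" for i in range(15)]
        )
        norm = ref.to_normalizer()
        x = rng.uniform(0, 1000, size=(1, 15))
        once = norm.transform(x)
        twice = norm.transform(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy())

    def test_log2_pretransform_preserves_ranks_of_counts(self):
        ref = QuantileReference(quantiles=np.arange(1.0, 6.0), gene_ids=[f"g{i}" for i in range(5)])
        counts = np.array([[0.0, 10.0, 5.0, 1000.0, 2.0]])
        out = ref.to_normalizer(log2_transform=True).transform(counts).to_numpy()[0]
        assert list(np.argsort(out)) == list(np.argsort(counts[0]))


def test_agrees_with_limma_normalize_quantiles(tmp_path):
    """Independent oracle: limma::normalizeQuantiles on the training matrix."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(1, 500, size=(25, 4))
    m = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(25)],
                                      columns=[f"s{j}" for j in range(4)]))
    ref = fit_quantile_reference(m)
    ours = apply_quantile_reference(m, ref).values.to_numpy()

    inp = tmp_path / "m.tsv"
    out = tmp_path / "norm.tsv"
    m.values.to_csv(inp, sep="\t")
    script = tmp_path / "qn.R"
    script.write_text(
        f"""suppressMessages(library(limma))
x <- as.matrix(read.delim("{inp}", row.names=1))
write.table(normalizeQuantiles(x, ties=TRUE), "{out}", sep="\t", quote=FALSE)
"""
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    theirs = pd.read_csv(out, sep="\t").to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-8)
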