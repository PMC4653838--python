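import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibfe import (
    IBFE,
    correlation_similarity,
    direct_concatenate,
    ibfe,
    integrate,
    stack_features,
)
from oracles import brute_force_ibfe, loop_pearson, loop_spearman


def square(values, ids=None):
    ids = ids or [f"p{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=ids, columns=ids)


class TestCorrelationSimilarity:
    def test_perfect_linear_relation_gives_unit_pearson(self):
        X = np.array([[1.0, 2, 3], [2, 4, 6], [5, 1, 0]])
        S = correlation_similarity(X, "pearson")
        assert S.iloc[0, 1] == pytest.approx(1.0)

    def test_monotone_nonlinear_map_preserves_spearman_only(self):
        X = np.array([[1.0, 2, 3], [10, 100, 1000], [3, 1, 2]])
        assert correlation_similarity(X, "spearman").iloc[0, 1] == pytest.approx(1.0)
        assert correlation_similarity(X, "pearson").iloc[0, 1] < 1.0

    def test_tied_values_use_midranks(self):
        a, b = [1.0, 2, 2, 3], [1.0, 3, 2, 4]
        X = np.array([a, b, [4.0, 0, 2, 1]])
        expected = loop_spearman(a, b)
        assert correlation_similarity(X, "spearman").iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_loop_oracle_on_random_input(self, rng):
        X = rng.normal(size=(5, 7))
        P = correlation_similarity(X, "pearson").to_numpy()
        S = correlation_similarity(X, "spearman").to_numpy()
        for a in range(5):
            for b in range(5):
                assert P[a, b] == pytest.approx(loop_pearson(X[a], X[b]) if a != b else 1.0, abs=1e-12)
                assert S[a, b] == pytest.approx(loop_spearman(X[a], X[b]) if a != b else 1.0, abs=1e-12)

    def test_zero_variance_row_gets_zero_similarity_and_unit_diagonal(self):
        X = np.array([[1.0, 1, 1], [1, 2, 3], [3, 1, 2]])
        with pytest.warns(RuntimeWarning, match="constant row"):
            S = correlation_similarity(X, "pearson")
        assert S.iloc[0, 1] == 0.0
        assert S.iloc[0, 0] == 1.0

    @pytest.mark.parametrize(
        "bad, err",
        [
            (np.ones((4, 1)), "at least 2 feature"),
            (np.full((4, 3), np.nan), "non-finite"),
            (np.ones((2, 5)), "at least 3 patients"),
        ],
    )
    def test_invalid_inputs_rejected(self, bad, err):
        with pytest.raises(ValueError, match=err):
            correlation_similarity(bad, "pearson")

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="pearson"):
            correlation_similarity(rng.normal(size=(4, 4)), "kendall")


class TestStacking:
    def test_column_count_is_patients_times_blocks(self, toy_views):
        sims = [
            correlation_similarity(v, kind)
            for v in toy_views
            for kind in ("pearson", "spearman")
        ]
        Y = stack_features(sims)
        assert Y.shape == (12, 12 * 4)
        assert np.abs(Y.to_numpy()).max() <= 1.0

    def test_single_block_stack_is_identity(self, toy_views):
        P = correlation_similarity(toy_views[0], "pearson")
        Y = stack_features([P])
        np.testing.assert_array_equal(Y.to_numpy(), P.to_numpy())

    def test_blocks_placed_in_supplied_order(self, rng):
        mats = [square(np.clip(rng.normal(size=(4, 4)), -1, 1)) for _ in range(4)]
        Y = stack_features(mats)
        np.testing.assert_array_equal(Y.to_numpy()[:, 4:8], mats[1].to_numpy())
        assert list(Y.columns.names) == ["block", "patient"]

    def test_mismatched_patient_ids_raise(self, rng):
        a = square(np.eye(3), ids=["x", "y", "z"])
        b = square(np.eye(3), ids=["x", "z", "y"])
        with pytest.raises(ValueError, match="align"):
            stack_features([a, b])


class TestIntegrate:
    def test_identical_rows_fully_correlated(self):
        Y = np.array([[1.0, 2, 3, 1], [1, 2, 3, 1], [0, 5, 1, 2]])
        Z = integrate(Y)
        assert Z.iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_rows(self):
        base = np.array([1.0, -2, 3, -1])
        Z = integrate(np.vstack([base, -base, np.array([0.0, 1, 2, 5])]))
        assert Z.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_pairwise_loop_oracle(self, rng):
        Y = rng.normal(size=(4, 6))
        Z = integrate(Y).to_numpy()
        for a in range(4):
            for b in range(4):
                expected = 1.0 if a == b else loop_pearson(Y[a], Y[b])
                assert Z[a, b] == pytest.approx(expected, abs=1e-12)


class TestIbfe:
    def test_single_dataset_pearson_only_composition(self, toy_views):
        X = toy_views[0]
        Z = ibfe([X], variant="ibfe2")
        P = correlation_similarity(X, "pearson")
        np.testing.assert_allclose(Z.to_numpy(), integrate(P).to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("variant", ["ibfe1", "ibfe2", "ibfe3"])
    def test_small_instances_match_brute_force_steps(self, rng, variant):
        datasets = [rng.normal(size=(6, 5)), rng.normal(size=(6, 8))]
        Z = ibfe(datasets, variant=variant).to_numpy()
        np.testing.assert_allclose(Z, brute_force_ibfe(datasets, variant), atol=1e-10)

    def test_monotone_transforms_leave_spearman_variant_unchanged(self, toy_views):
        Z = ibfe(toy_views, variant="ibfe3").to_numpy()
        transformed = [np.exp(toy_views[0]), toy_views[1] ** 3 + 5 * toy_views[1]]
        Z2 = ibfe(transformed, variant="ibfe3").to_numpy()
        np.testing.assert_allclose(Z, Z2, atol=1e-10)

    def test_permuting_patients_permutes_similarity(self, toy_views, rng):
        perm = rng.permutation(12)
        Z = ibfe(toy_views, variant="ibfe1").to_numpy()
        Zp = ibfe([v.iloc[perm] for v in toy_views], variant="ibfe1").to_numpy()
        np.testing.assert_allclose(Zp, Z[np.ix_(perm, perm)], atol=1e-10)

    def test_replicated_datasets_collapse_to_single_view(self, toy_views):
        X = toy_views[0]
        Z1 = ibfe([X], variant="ibfe2").to_numpy()
        Z3 = ibfe([X, X, X], variant="ibfe2").to_numpy()
        np.testing.assert_allclose(Z1, Z3, atol=1e-10)

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError, match="at least one dataset"):
            ibfe([], variant="ibfe1")

    def test_unknown_variant_rejected(self, toy_views):
        with pytest.raises(ValueError, match="variant"):
            ibfe(toy_views, variant="ibfe9")

    def test_misaligned_datasets_rejected(self, toy_views):
        shuffled = toy_views[1].sample(frac=1, random_state=0)
        with pytest.raises(ValueError, match="align"):
            ibfe([toy_views[0], shuffled])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        m=st.integers(3, 8),
        n=st.integers(2, 6),
        variant=st.sampled_from(["ibfe1", "ibfe2", "ibfe3"]),
    )
    def test_similarity_invariants_on_random_inputs(self, seed, m, n, variant):
        gen = np.random.default_rng(seed)
        Z = ibfe([gen.normal(size=(m, n)), gen.normal(size=(m, n + 1))], variant=variant).to_numpy()
        assert np.allclose(Z, Z.T, atol=1e-10)
        assert np.allclose(np.diag(Z), 1.0, atol=1e-10)
        assert Z.min() >= -1.0 and Z.max() <= 1.0


class TestDirectConcatenate:
    def test_shapes_add_up(self, rng):
        a, b = rng.normal(size=(10, 7)), rng.normal(size=(10, 4))
        out = direct_concatenate([a, b])
        assert out.shape == (10, 11)

    def test_single_input_is_identity(self, toy_views):
        out = direct_concatenate([toy_views[0]])
        np.testing.assert_array_equal(out.to_numpy(), toy_views[0].to_numpy())

    def test_column_order_preserved_within_blocks(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 4))
        out = direct_concatenate([a, b]).to_numpy()
        np.testing.assert_array_equal(out[:, 3], np.asarray(b)[:, 0])

    def test_feature_ids_prefixed_by_datatype(self, toy_views):
        out = direct_concatenate(toy_views, labels=["meth", "mrna"])
        assert out.columns[0].startswith("meth:")
        assert out.columns[-1].startswith("mrna:")
        assert out.columns.is_unique


class TestEstimator:
    def test_fit_exposes_similarity_and_embedding(self, toy_views):
        est = IBFE(variant="ibfe1").fit(toy_views)
        assert est.similarity_.shape == (12, 12)
        assert est.stacked_.shape == (12, 48)
        assert est.n_views_ == 2
        np.testing.assert_array_equal(est.embedding_, est.similarity_.to_numpy())

    def test_fit_transform_matches_function_api(self, toy_views):
        emb = IBFE(variant="ibfe3").fit_transform(toy_views)
        np.testing.assert_allclose(emb, ibfe(toy_views, "ibfe3").to_numpy(), atol=1e-12)

    def test_sklearn_params_protocol(self):
        from sklearn.base import clone

        est = IBFE(variant="ibfe2")
        assert est.get_params() == {"variant": "ibfe2"}
        cloned = clone(est).set_params(variant="ibfe3")
        assert cloned.get_params()["variant"] == "ibfe3"

    def test_invalid_variant_raises_at_fit(self, toy_views):
        with pytest.raises(ValueError, match="variant"):
            IBFE(variant="nope").fit(toy_views)
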