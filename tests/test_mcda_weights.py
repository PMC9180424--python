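import numpy as np
import pandas as pd
import pytest

from hazetol.mcda_weights import (
    BUNDLED_MATRICES,
    JudgmentMatrix,
    ValidationError,
    ahp_weights,
    combine_weights,
    compose_hierarchy,
    composite_score,
    entropy_weights,
    load_bundled_matrices,
    read_judgment_matrix,
    ri_lookup,
    standardize,
)


def dense_eigen_oracle(a: np.ndarray):
    """Independent eigen-decomposition route for the principal pair."""
    vals, vecs = np.linalg.eig(a)
    i = np.argmax(vals.real)
    w = np.abs(vecs[:, i].real)
    return vals[i].real, w / w.sum()


def consistent_matrix(w):
    w = np.asarray(w, dtype=float)
    return w[:, None] / w[None, :]


class TestReadJudgmentMatrix:
    def test_bundled_primary_matrix(self):
        m = read_judgment_matrix(BUNDLED_MATRICES["primary"])
        assert m.order == 3
        assert m.labels == ("ecological environment", "social economy", "social media")
        assert m.values[0, 1] == 4.0

    def test_reciprocity_violation_reported_with_cells(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("i,a,b\na,1,2\nb,0.4,1\n")
        with pytest.raises(ValidationError, match=r"a\[0,1\]=2"):
            read_judgment_matrix(p)

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("i,a,b\na,1,2\n")
        with pytest.raises(ValidationError):
            read_judgment_matrix(p)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError, match="non-positive"):
            JudgmentMatrix(("a", "b"), np.array([[1.0, -2.0], [-0.5, 1.0]]))

    def test_one_by_one_valid_with_weight_one(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("i,a\na,1\n")
        m = read_judgment_matrix(p)
        w, rep = ahp_weights(m)
        assert w[0] == pytest.approx(1.0)
        assert rep.CR == 0.0


class TestAhpWeights:
    def test_consistent_matrix_recovers_weights_exactly(self):
        target = np.array([0.6, 0.3, 0.1])
        m = JudgmentMatrix(("a", "b", "c"), consistent_matrix(target))
        w, rep = ahp_weights(m)
        np.testing.assert_allclose(w, target, atol=1e-10)
        assert rep.CR == pytest.approx(0.0, abs=1e-9)

    def test_bundled_primary_weights_and_consistency(self):
        m = read_judgment_matrix(BUNDLED_MATRICES["primary"])
        w, rep = ahp_weights(m)
        lam_o, w_o = dense_eigen_oracle(m.values)
        np.testing.assert_allclose(w, w_o, atol=1e-8)
        assert rep.lambda_max == pytest.approx(lam_o, abs=1e-8)
        np.testing.assert_allclose(w, [0.263, 0.079, 0.659], atol=2e-3)
        assert rep.lambda_max == pytest.approx(3.03, abs=5e-3)
        assert rep.CR == pytest.approx(0.03, abs=5e-3)
        assert rep.consistent

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8, 9])
    def test_matches_dense_eigendecomposition(self, n):
        rng = np.random.default_rng(n)
        a = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a[i, j] = rng.choice([1 / 5, 1 / 3, 1, 2, 3, 5, 7])
                a[j, i] = 1.0 / a[i, j]
        m = JudgmentMatrix(tuple(f"c{k}" for k in range(n)), a)
        w, rep = ahp_weights(m)
        lam_o, w_o = dense_eigen_oracle(a)
        np.testing.assert_allclose(w, w_o, atol=1e-8)
        assert rep.lambda_max == pytest.approx(lam_o, abs=1e-7)

    def test_order_two_has_cr_zero(self):
        m = JudgmentMatrix(("a", "b"), np.array([[1.0, 5.0], [0.2, 1.0]]))
        _, rep = ahp_weights(m)
        assert rep.CR == 0.0 and rep.consistent


class TestRiLookup:
    @pytest.mark.parametrize(
        "n, ri",
        [(1, 0.0), (2, 0.0), (3, 0.58), (4, 0.90), (5, 1.12),
         (6, 1.24), (7, 1.32), (8, 1.41), (9, 1.45)],
    )
    def test_tabulated_values(self, n, ri):
        assert ri_lookup(n) == ri

    def test_unsupported_order(self):
        with pytest.raises(ValueError, match="1-9"):
            ri_lookup(10)


class TestComposeHierarchy:
    def test_single_group_identity(self):
        out = compose_hierarchy({"g": 1.0}, {"g": {"x": 0.4, "y": 0.6}})
        assert out == {"x": 0.4, "y": 0.6}

    def test_products(self):
        out = compose_hierarchy(
            {"g1": 0.5, "g2": 0.5}, {"g1": {"x": 1.0}, "g2": {"y": 0.4, "z": 0.6}}
        )
        assert out == pytest.approx({"x": 0.5, "y": 0.2, "z": 0.3})
        assert sum(out.values()) == pytest.approx(1.0)

    def test_group_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            compose_hierarchy({"g1": 1.0}, {"g2": {"x": 1.0}})

    def test_topic_index_absolute_weight_from_bundled_matrices(self):
        mats = load_bundled_matrices()
        w_first, _ = ahp_weights(mats["primary"])
        w_sm, _ = ahp_weights(mats["social media"])
        absolute = w_first[2] * w_sm[4]  # social-media layer x topic-index row
        assert absolute == pytest.approx(0.25, abs=0.01)


class TestStandardize:
    def test_benefit_with_zero_floor(self):
        panel = pd.DataFrame({"c": [1.0, 2.0, 3.0]})
        y = standardize(panel, {"c": "benefit"})
        np.testing.assert_allclose(y["c"], [0.01, 0.5, 1.0])

    def test_cost_mirrors(self):
        panel = pd.DataFrame({"c": [1.0, 2.0, 3.0]})
        y = standardize(panel, {"c": "cost"})
        np.testing.assert_allclose(y["c"], [1.0, 0.5, 0.01])

    def test_constant_column_maps_to_ones(self):
        y = standardize(pd.DataFrame({"c": [7.0, 7.0, 7.0]}), {"c": "benefit"})
        np.testing.assert_allclose(y["c"], 1.0)

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            standardize(pd.DataFrame({"c": [1.0, 2.0]}), {})

    def test_missing_cell_located(self):
        panel = pd.DataFrame({"c": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="'c'"):
            standardize(panel, {"c": "benefit"})


class TestEntropyWeights:
    def test_uniform_column_has_max_entropy_and_zero_weight(self):
        Y = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "varied": [0.01, 0.5, 1.0]})
        et = entropy_weights(Y)
        assert et.entropy["flat"] == pytest.approx(1.0, abs=1e-12)
        assert et.weights["flat"] == 0.0
        assert et.weights["varied"] == pytest.approx(1.0)

    def test_hand_arithmetic_entropy(self):
        # independent oracle: -(1/ln 3) * sum P ln P with P = Y / sum(Y)
        col = np.array([0.01, 0.5, 1.0])
        p = col / col.sum()
        expected = -(p * np.log(p)).sum() / np.log(3)
        et = entropy_weights(pd.DataFrame({"c": col, "d": [1.0, 1.0, 1.0]}))
        assert et.entropy["c"] == pytest.approx(expected, abs=1e-12)
        assert et.entropy["c"] == pytest.approx(0.612, abs=1e-3)

    def test_mirror_columns_share_weight_equally(self):
        Y = pd.DataFrame({"a": [0.01, 0.5, 1.0], "b": [1.0, 0.5, 0.01]})
        et = entropy_weights(Y)
        assert et.weights["a"] == pytest.approx(0.5)
        assert et.weights["b"] == pytest.approx(0.5)

    def test_column_shares_sum_to_one(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.uniform(0.01, 1, size=(6, 4)), columns=list("abcd"))
        et = entropy_weights(Y)
        np.testing.assert_allclose(et.P.sum(axis=0), 1.0)
        assert et.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        Y = pd.DataFrame(rng.uniform(0.01, 1, size=(5, 3)), columns=list("abc"))
        base = entropy_weights(Y).weights
        shuffled_rows = entropy_weights(Y.sample(frac=1, random_state=2)).weights
        np.testing.assert_allclose(shuffled_rows[base.index], base, atol=1e-12)
        perm_cols = entropy_weights(Y[["c", "a", "b"]]).weights
        assert perm_cols["a"] == pytest.approx(base["a"])

    def test_all_uniform_panel_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            entropy_weights(pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]}))


class TestCombineWeights:
    def test_geometric_mean_fixed_point(self):
        w = pd.Series([0.25, 0.75], index=["a", "b"])
        pd.testing.assert_series_equal(
            combine_weights(w, w), w.rename("combined_weight")
        )

    def test_hand_arithmetic(self):
        w1 = pd.Series([0.5, 0.5], index=["a", "b"])
        w2 = pd.Series([0.8, 0.2], index=["a", "b"])
        out = combine_weights(w1, w2)
        np.testing.assert_allclose(out, [2 / 3, 1 / 3])

    def test_normalization_contract(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            idx = [f"c{i}" for i in range(6)]
            out = combine_weights(pd.Series(a, index=idx), pd.Series(b, index=idx))
            assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_weights(pd.Series([1.0], index=["a"]),
                            pd.Series([0.5, 0.5], index=["a", "b"]))


class TestCompositeScore:
    def test_one_hot_weights_select_indicator(self):
        panel = pd.DataFrame({"a": [0.2, 0.9], "b": [0.5, 0.1]})
        w = pd.Series([1.0, 0.0], index=["a", "b"])
        out = composite_score(w, panel)
        np.testing.assert_allclose(out["z"], panel["a"])

    def test_all_ones_gives_one(self):
        panel = pd.DataFrame({"a": [1.0], "b": [1.0]})
        w = pd.Series([0.3, 0.7], index=["a", "b"])
        assert composite_score(w, panel)["z"].iloc[0] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        panel = pd.DataFrame({"a": [1.0], "b": [0.0], "c": [0.5]})
        w = pd.Series([0.2, 0.3, 0.5], index=["a", "b", "c"])
        assert composite_score(w, panel)["z"].iloc[0] == pytest.approx(0.45)

    def test_missing_indicator_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            composite_score(pd.Series([1.0], index=["a"]),
                            pd.DataFrame({"a": [1.0], "b": [1.0]}))
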