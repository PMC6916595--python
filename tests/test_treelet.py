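"""Treelet transform: rotations, bases, sparsity and scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import treeletomics as tm
from treeletomics.treelet import TreeletTransform, stability_bootstrap

from conftest import three_block_data

GOLDEN = np.sqrt(5.0)


class TestTwoVariableClosedForm:
    """C = [[2,1],[1,1]] has an exact 2x2 eigendecomposition."""

    @pytest.fixture
    def tree(self):
        rng = np.random.default_rng(0)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 1.0]]))
        X = rng.standard_normal((10, 2)) @ L.T
        return tm.fit_treelet(X, covariance=np.array([[2.0, 1.0], [1.0, 1.0]]))

    def test_rotation_angle(self, tree):
        assert tree.steps[0].theta == pytest.approx(0.5 * np.arctan2(2.0, 1.0))
        assert tree.steps[0].theta == pytest.approx(0.5536, abs=1e-4)

    def test_rotated_variances_are_eigenvalues(self, tree):
        s = tree.steps[0]
        assert s.sum_variance == pytest.approx((3 + GOLDEN) / 2, abs=1e-12)
        assert s.diff_variance == pytest.approx((3 - GOLDEN) / 2, abs=1e-12)
        assert s.sum_variance >= s.diff_variance

    def test_sum_loadings_equal_top_eigenvector(self, tree):
        comps = tm.select_components(tree, 1, 1)
        _, vecs = np.linalg.eigh(np.array([[2.0, 1.0], [1.0, 1.0]]))
        top = vecs[:, -1] * np.sign(vecs[np.argmax(np.abs(vecs[:, -1])), -1])
        np.testing.assert_allclose(comps.loadings[0], np.abs(top), atol=1e-12)

    def test_variance_explained_closed_form(self, tree):
        comps = tm.select_components(tree, 1, 1)
        fracs, total = tm.variance_explained(comps, tree.covariance)
        assert total == pytest.approx((3 + GOLDEN) / 2 / 3.0, abs=1e-12)

    def test_p2_treelet_equals_pca(self, rng):
        X = rng.standard_normal((50, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]])
        tree = tm.fit_treelet(X)
        basis = tm.basis_at_level(tree, 1)
        _, vecs = np.linalg.eigh(np.cov(X, rowvar=False))
        # columns agree with the PCA rotation up to sign and order
        overlap = np.abs(basis.T @ vecs)
        np.testing.assert_allclose(np.sort(overlap.max(axis=1)), [1.0, 1.0],
                                   atol=1e-10)


class TestDegenerateInputs:
    def test_identity_covariance_tie_break(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        tree = tm.fit_treelet(X, covariance=np.eye(3))
        s = tree.steps[0]
        assert (s.alpha, s.beta) == (0, 1)
        assert s.theta == 0.0
        np.testing.assert_array_equal(tree.basis_at_level(1), np.eye(3))

    def test_constant_variable_rejected(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 2] = np.arange(10) ** 2
        with pytest.raises(ValueError, match="constant"):
            tm.fit_treelet(X)

    def test_single_variable_rejected(self, rng):
        with pytest.raises(ValueError):
            tm.fit_treelet(rng.standard_normal((10, 1)))

    def test_cut_level_out_of_range(self, rng):
        tree = tm.fit_treelet(rng.standard_normal((30, 4)))
        for bad in (0, 4, -1):
            with pytest.raises(ValueError):
                tree.basis_at_level(bad)

    def test_k_too_large_for_cut(self, rng):
        tree = tm.fit_treelet(rng.standard_normal((30, 5)))
        with pytest.raises(ValueError, match="active sum"):
            tm.select_components(tree, 4, 2)

    def test_k_zero_empty(self, rng):
        tree = tm.fit_treelet(rng.standard_normal((30, 5)))
        comps = tm.select_components(tree, 2, 0)
        assert comps.n_components == 0
        fracs, total = tm.variance_explained(comps, tree.covariance)
        assert total == 0.0


@settings(max_examples=15, deadline=None, derandomize=True)
@given(n=st.integers(20, 60), p=st.integers(3, 12), seed=st.integers(0, 10**6))
def test_orthonormality_and_trace_at_every_level(n, p, seed):
    """B'B = I and tr(rotated C) = tr(C) after every merge."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, p + 2))
    X = rng.standard_normal((n, p)) @ A[:, :p]
    tree = tm.fit_treelet(X)
    assert tree.n_levels == p - 1
    C = tree.covariance
    for c in range(1, p):
        B = tree.basis_at_level(c)
        np.testing.assert_allclose(B.T @ B, np.eye(p), atol=1e-10)
        np.testing.assert_allclose(
            np.trace(B.T @ C @ B), np.trace(C), atol=1e-10 * max(1, np.trace(C)))
        # the tracked diagonal matches the explicitly rotated covariance
        np.testing.assert_allclose(
            tree.variances_at_level(c), np.diag(B.T @ C @ B), atol=1e-8)


def test_full_panel_has_p_minus_1_levels(rng):
    X = rng.standard_normal((150, 119))
    tree = tm.fit_treelet(X)
    assert tree.n_levels == 118


def test_single_rotation_touches_two_columns(rng):
    tree = tm.fit_treelet(rng.standard_normal((40, 6)))
    B = tree.basis_at_level(1)
    changed = np.flatnonzero(np.any(B != np.eye(6), axis=0))
    assert len(changed) == 2


class TestSparsity:
    def test_support_equals_subtree_leaves_exact_zeros(self, rng):
        X = three_block_data(400, rng)
        tree = tm.fit_treelet(X)
        comps = tm.select_components(tree, 21, 3)
        expected = [set(range(0, 10)), set(range(10, 18)), set(range(18, 24))]
        supports = [set(map(int, comps.support(k))) for k in range(3)]
        assert sorted(map(sorted, supports)) == sorted(map(sorted, expected))
        for k in range(3):
            outside = np.setdiff1d(np.arange(24), list(supports[k]))
            assert np.all(comps.loadings[k][outside] == 0.0)  # exact zeros

    def test_two_block_oracle_per_block_pca(self, rng):
        """With an exactly block-diagonal covariance the component of each
        block equals that block's first principal component."""
        n = 2000
        X1 = three_block_data(n, rng, sizes=(5,), within_corr=0.6)
        X2 = 2.0 * three_block_data(n, rng, sizes=(4,), within_corr=0.5)
        X = np.hstack([X1, X2])
        C = np.cov(X, rowvar=False)
        C[:5, 5:] = 0.0
        C[5:, :5] = 0.0  # exactly block diagonal
        tree = tm.fit_treelet(X, covariance=C)
        comps = tm.select_components(tree, 7, 2)
        seen_blocks = set()
        for k in range(2):
            sup = set(map(int, comps.support(k)))
            # supported entirely within one block
            assert sup <= set(range(5)) or sup <= set(range(5, 9))
            block = slice(0, 5) if min(sup) < 5 else slice(5, 9)
            seen_blocks.add(block.start)
            _, vecs = np.linalg.eigh(C[block, block])
            # close to that block's first principal component
            assert abs(comps.loadings[k][block] @ vecs[:, -1]) > 0.95
        assert seen_blocks == {0, 5}

    def test_sign_convention_largest_loading_positive(self, rng):
        X = three_block_data(300, rng)
        comps = tm.select_components(tm.fit_treelet(X), 21, 3)
        for k in range(3):
            assert comps.loadings[k][np.argmax(np.abs(comps.loadings[k]))] > 0


class TestScores:
    def test_unit_vector_loading_returns_column(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        tree = tm.fit_treelet(X)
        loadings = np.zeros((1, 4))
        loadings[0, 2] = 1.0
        comps = tm.ComponentSet(1, loadings, np.ones(1), list("abcd"))
        scores, _ = tm.compute_scores(X, comps)
        np.testing.assert_allclose(scores.iloc[:, 0], X["c"], atol=1e-15)

    def test_hand_dot_product(self):
        loadings = np.array([[0.6, 0.8]])
        comps = tm.ComponentSet(1, loadings, np.ones(1), ["a", "b"])
        scores, _ = tm.compute_scores(np.array([[1.0, 2.0], [0.0, 0.0]]), comps)
        assert scores[0, 0] == pytest.approx(2.2, abs=1e-12)
        assert scores[1, 0] == 0.0

    def test_score_variance_matches_quadratic_form(self, rng):
        X = three_block_data(500, rng)
        tree = tm.fit_treelet(X)
        comps = tm.select_components(tree, 21, 3)
        scores, _ = tm.compute_scores(X, comps)
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1),
            np.einsum("kp,pq,kq->k", comps.loadings, tree.covariance,
                      comps.loadings),
            rtol=1e-8)

    def test_scoring_does_not_alter_the_tree(self, rng):
        X_ctrl = three_block_data(200, rng)
        tt = TreeletTransform(n_components=3, cut_level=21).fit(X_ctrl)
        before = tt.components_.copy()
        tt.transform(three_block_data(50, rng))
        np.testing.assert_array_equal(tt.components_, before)

    def test_dimension_mismatch(self, rng):
        comps = tm.ComponentSet(1, np.ones((1, 3)) / np.sqrt(3), np.ones(1),
                                ["a", "b", "c"])
        with pytest.raises(ValueError, match="variables"):
            tm.compute_scores(rng.standard_normal((5, 4)), comps)


class TestVarianceExplained:
    def test_single_coordinate_identity(self):
        loadings = np.zeros((1, 5))
        loadings[0, 0] = 1.0
        comps = tm.ComponentSet(1, loadings, np.ones(1), list("abcde"))
        _, total = tm.variance_explained(comps, np.eye(5))
        assert total == pytest.approx(0.2)

    def test_complete_eigenbasis_sums_to_one(self, rng):
        X = rng.standard_normal((100, 6))
        C = np.cov(X, rowvar=False)
        _, vecs = np.linalg.eigh(C)
        comps = tm.ComponentSet(5, vecs.T, np.ones(6), [str(i) for i in range(6)])
        _, total = tm.variance_explained(comps, C)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zero_total_variance_rejected(self):
        comps = tm.ComponentSet(1, np.ones((1, 2)) / np.sqrt(2), np.ones(1),
                                ["a", "b"])
        with pytest.raises(ValueError):
            tm.variance_explained(comps, np.zeros((2, 2)))


class TestStabilityBootstrap:
    def test_identical_resamples_give_congruence_one(self, rng):
        X = three_block_data(150, rng)
        out = stability_bootstrap(X, 21, 3, B=5, seed=0, replace=False)
        np.testing.assert_allclose(out["median_congruence"], 1.0, atol=1e-12)

    def test_strong_blocks_stable_noise_unstable(self, rng):
        X = three_block_data(400, rng)
        strong = stability_bootstrap(X, 21, 3, B=20, seed=1)
        assert (strong["median_congruence"] > 0.95).all()
        noise = rng.standard_normal((400, 24))
        weak = stability_bootstrap(noise, 21, 3, B=20, seed=2)
        assert weak["median_congruence"].mean() < strong["median_congruence"].mean()

    def test_minimum_resamples(self, rng):
        with pytest.raises(ValueError):
            stability_bootstrap(rng.standard_normal((50, 4)), 2, 1, B=1)
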