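"""FDR ranking, PCA, PLS, z-scoring and feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcipredict.features import (
    assemble_features,
    fdr_rank,
    pca_fit,
    pca_transform,
    pls_fit,
    pls_transform,
    zscore_apply,
    zscore_fit,
)


def brute_force_fdr(X, y):
    """Independent per-feature evaluation of the discriminant ratio."""
    values, n = [], X.shape[0]
    for j in range(X.shape[1]):
        a = [X[i, j] for i in range(n) if y[i] == -1]
        b = [X[i, j] for i in range(n) if y[i] == +1]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        va = sum((v - ma) ** 2 for v in a) / (len(a) - 1)
        vb = sum((v - mb) ** 2 for v in b) / (len(b) - 1)
        num, den = (ma - mb) ** 2, va + vb
        values.append(
            num / den if den > 0 else (float("inf") if num > 0 else 0.0)
        )
    order = sorted(range(X.shape[1]), key=lambda j: (-values[j], j))
    return values, order


class TestFdr:
    def test_hand_example(self):
        """Classes {1,2,3} vs {4,5,6}: (2-5)^2 / (1+1) = 4.5."""
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        r = fdr_rank(X, y)
        assert r.fdr_values[0] == pytest.approx(4.5)

    def test_identical_distributions_rank_last(self, rng):
        informative = np.concatenate([rng.normal(0, 1, 10),
                                      rng.normal(3, 1, 10)])
        same = np.tile(rng.normal(size=10), 2)
        X = np.column_stack([same, informative])
        y = np.array([-1] * 10 + [1] * 10)
        r = fdr_rank(X, y)
        assert r.order[0] == 1 and r.fdr_values[-1] == 0.0

    def test_tie_break_by_original_index(self, rng):
        col = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8)])
        X = np.column_stack([col, col, col])
        y = np.array([-1] * 8 + [1] * 8)
        r = fdr_rank(X, y)
        np.testing.assert_array_equal(r.order, [0, 1, 2])

    def test_zero_variance_separated_is_infinite(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([-1, -1, 1, 1])
        r = fdr_rank(X, y)
        assert np.isinf(r.fdr_values[0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            fdr_rank(np.ones((4, 2)), np.array([1, 1, 1, 1]))

    def test_matches_brute_force_oracle(self, rng):
        y = np.array([-1] * 15 + [1] * 15)
        for _ in range(20):
            X = rng.normal(size=(30, 10))
            r = fdr_rank(X, y)
            values, order = brute_force_fdr(X, y)
            assert list(r.order) == order
            np.testing.assert_allclose(
                r.fdr_values, [values[j] for j in order], rtol=1e-10
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50, allow_nan=False),
           scale=st.floats(0.01, 50), seed=st.integers(0, 50))
    def test_shift_and_scale_invariance(self, shift, scale, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(20, 5))
        y = np.array([-1] * 10 + [1] * 10)
        base = fdr_rank(X, y)
        moved = fdr_rank(X * scale + shift, y)
        np.testing.assert_array_equal(base.order, moved.order)
        np.testing.assert_allclose(base.fdr_values, moved.fdr_values,
                                   rtol=1e-8)


class TestPca:
    def test_component_cap_is_samples_minus_one(self, rng):
        model = pca_fit(rng.normal(size=(10, 25)))
        assert model.n_components == 9

    def test_rank_one_data(self):
        x = np.linspace(-3, 3, 40)
        X = np.column_stack([x, 2 * x])
        model = pca_fit(X)
        total = model.explained_variance.sum()
        assert model.explained_variance[0] / total > 1 - 1e-10
        assert model.explained_variance[1] <= 1e-10

    def test_mean_maps_to_zero(self, rng):
        X = rng.normal(size=(12, 6))
        model = pca_fit(X)
        np.testing.assert_allclose(
            pca_transform(X.mean(axis=0), model), 0.0, atol=1e-10
        )

    def test_orthonormal_loadings_and_variance_sum(self, rng):
        X = rng.normal(size=(15, 8))
        model = pca_fit(X)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.n_components),
                                   atol=1e-8)
        total = X.var(axis=0, ddof=1).sum()
        assert model.explained_variance.sum() == pytest.approx(total,
                                                               rel=1e-8)

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(10, 4))
        model = pca_fit(X)
        coeffs = pca_transform(X, model)
        back = model.mean + coeffs @ model.loadings.T
        np.testing.assert_allclose(back, X, atol=1e-6)

    def test_scores_uncorrelated(self, rng):
        X = rng.normal(size=(25, 6))
        coeffs = pca_transform(X, pca_fit(X))
        corr = np.corrcoef(coeffs, rowvar=False)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.abs(off).max() <= 1e-6

    def test_gram_route_matches_direct_svd(self, rng):
        """Wide matrices take the dual eigen-route; it must agree with the
        plain SVD factorization computed here directly."""
        X = rng.normal(size=(15, 60))  # triggers the Gram path
        model = pca_fit(X)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = model.n_components
        np.testing.assert_allclose(
            np.abs(model.loadings), np.abs(Vt[:k].T), atol=1e-8
        )
        np.testing.assert_allclose(
            model.explained_variance, s[:k] ** 2 / (X.shape[0] - 1), rtol=1e-8
        )

    def test_training_scores_equal_transform(self, rng):
        X = rng.normal(size=(12, 40))
        model = pca_fit(X)
        np.testing.assert_allclose(
            model.training_scores, pca_transform(X, model), atol=1e-8
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.ones((1, 5)))

    def test_dimension_mismatch_rejected(self, rng):
        model = pca_fit(rng.normal(size=(8, 5)))
        with pytest.raises(ValueError, match="dimension"):
            pca_transform(rng.normal(size=(3, 7)), model)


class TestPls:
    def test_single_feature_equal_to_label(self):
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        X = y.reshape(-1, 1).copy()
        model = pls_fit(X, y, 1)
        assert abs(abs(model.weights[0, 0]) - 1.0) < 1e-12

    def test_orthogonal_to_label_gives_null_covariance(self):
        y = np.array([-1.0, -1, 1, 1])
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])  # zero covariance with y
        model = pls_fit(X, y, 1)
        scores = pls_transform(X, model)
        yc = y - y.mean()
        assert abs(scores[:, 0] @ yc) <= 1e-10

    def test_deflation_decorrelates_components(self, rng):
        X = rng.normal(size=(30, 8))
        y = np.where(rng.random(30) < 0.5, -1.0, 1.0)
        y[:2], y[2:4] = -1, 1
        model = pls_fit(X, y, 2)
        scores = pls_transform(X, model)
        r = np.corrcoef(scores.T)[0, 1]
        assert abs(r) <= 1e-6

    def test_matches_reference_implementation(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(25, 10))
        y = np.array([-1.0] * 12 + [1.0] * 13)
        ours = pls_transform(X, pls_fit(X, y, 3))
        ref = PLSRegression(n_components=3, scale=False).fit(X, y).transform(X)
        np.testing.assert_allclose(np.abs(ours), np.abs(ref), atol=1e-8)

    def test_out_of_range_components_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        y = np.array([-1, -1, -1, 1, 1, 1])
        with pytest.raises(ValueError, match="out of range"):
            pls_fit(X, y, 6)


class TestZScore:
    def test_basic_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        out = zscore_apply(X, zscore_fit(X))
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1])

    def test_constant_column_warns_and_zeros(self):
        X = np.array([[2.0, 1.0], [2.0, 2.0], [2.0, 3.0]])
        stats = zscore_fit(X)
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_apply(X, stats)
        assert np.all(out[:, 0] == 0)
        np.testing.assert_allclose(out[:, 1], [-1, 0, 1])

    def test_training_data_standardized(self, rng):
        X = rng.normal(3, 5, size=(20, 4))
        out = zscore_apply(X, zscore_fit(X))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_width_mismatch_rejected(self, rng):
        stats = zscore_fit(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="width"):
            zscore_apply(rng.normal(size=(2, 4)), stats)


class TestAssemble:
    @pytest.fixture
    def parts(self, rng):
        y = np.array([-1] * 8 + [1] * 8)
        coeffs = rng.normal(size=(16, 6))
        scores = rng.normal(size=(16, 4))
        return coeffs, scores, fdr_rank(coeffs, y), fdr_rank(scores, y)

    def test_mri_only(self, parts):
        coeffs, scores, rc, rs = parts
        X, labels = assemble_features(coeffs, scores, rc, rs, 3, 0,
                                      score_names=list("abcd"))
        assert X.shape == (16, 3)
        assert all(lab.startswith("mri:") for lab in labels)

    def test_scores_only(self, parts):
        coeffs, scores, rc, rs = parts
        X, labels = assemble_features(coeffs, scores, rc, rs, 0, 4,
                                      score_names=list("abcd"))
        assert X.shape == (16, 4)
        assert all(lab.startswith("np:") for lab in labels)

    def test_provenance_roundtrip(self, parts):
        coeffs, scores, rc, rs = parts
        names = ["w", "x", "y", "z"]
        X, labels = assemble_features(coeffs, scores, rc, rs, 2, 2,
                                      score_names=names)
        for j, lab in enumerate(labels):
            kind, ident = lab.split(":", 1)
            if kind == "mri":
                np.testing.assert_array_equal(X[:, j], coeffs[:, int(ident)])
            else:
                np.testing.assert_array_equal(
                    X[:, j], scores[:, names.index(ident)]
                )

    def test_both_zero_rejected(self, parts):
        coeffs, scores, rc, rs = parts
        with pytest.raises(ValueError):
            assemble_features(coeffs, scores, rc, rs, 0, 0)
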