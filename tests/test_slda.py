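"""Sparse discriminant model: oracles, geometry, cross-validation."""

import numpy as np
import pytest
from scipy import linalg as sla

from connstage.slda import (
    SparseDiscriminantAnalysis,
    baseline_errors,
    interclass_distance_matrix,
    ldd_clinical_correlations,
    loocv_evaluate,
    nearest_centroid_classify,
    standardize_features,
)

import pandas as pd


def make_gaussian_classes(rng, means, n_per_class, scale=1.0):
    X, labels = [], []
    for name, mu in means.items():
        X.append(rng.normal(size=(n_per_class, len(mu))) * scale + np.asarray(mu))
        labels += [name] * n_per_class
    return np.vstack(X), np.array(labels)


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(30, 6))
        fm = standardize_features(X, np.array(["a"] * 15 + ["b"] * 15))
        np.testing.assert_allclose(fm.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(fm.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_already_standardized_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        fm = standardize_features(X, np.array(["a", "b"] * 20))
        np.testing.assert_allclose(fm.values, X, atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            fm = standardize_features(X, np.array(["a", "b"] * 10))
        np.testing.assert_array_equal(fm.kept, [0, 2])
        assert fm.transform(X).shape == (20, 2)

    def test_small_class_rejected(self):
        X = np.random.default_rng(3).normal(size=(5, 3))
        with pytest.raises(ValueError, match="class"):
            standardize_features(X, np.array(["a", "a", "a", "a", "b"]))


class TestFit:
    def test_separable_feature_selected_and_loocv_zero(self):
        rng = np.random.default_rng(4)
        X, labels = make_gaussian_classes(
            rng, {"a": [0] * 10, "b": [0] * 10}, 12, scale=0.3
        )
        X[:12, 4] += 8.0  # class a separated along feature 4 only
        model = SparseDiscriminantAnalysis(X, labels, sparsity=3)
        res = model.fit()
        dominant = np.argmax(np.abs(res.beta[:, 0]))
        assert model.features.kept[dominant] == 4
        ev = loocv_evaluate(X, labels, sparsity=3)
        assert ev.loocv_error == 0.0

    def test_q_is_classes_minus_one(self):
        rng = np.random.default_rng(5)
        X, labels = make_gaussian_classes(
            rng, {"II": [0, 0], "IIIa": [2, 0], "IIIb": [0, 2], "IIIc": [2, 2]}, 6
        )
        res = SparseDiscriminantAnalysis(X, labels, sparsity=2).fit()
        assert res.beta.shape[1] == 3
        assert res.theta.shape == (4, 3)

    def test_deterministic_refit(self):
        rng = np.random.default_rng(6)
        X, labels = make_gaussian_classes(
            rng, {"a": [0, 0, 0], "b": [1, 0, 0], "c": [0, 1, 0]}, 10
        )
        r1 = SparseDiscriminantAnalysis(X, labels, sparsity=2).fit()
        r2 = SparseDiscriminantAnalysis(X, labels, sparsity=2).fit()
        np.testing.assert_array_equal(r1.beta, r2.beta)
        np.testing.assert_array_equal(r1.theta, r2.theta)

    def test_theta_orthonormal_in_class_proportion_metric(self):
        rng = np.random.default_rng(7)
        X, labels = make_gaussian_classes(
            rng, {"a": [0, 0, 0, 0], "b": [1, 1, 0, 0], "c": [0, 0, 1, 1]}, 9
        )
        res = SparseDiscriminantAnalysis(X, labels, sparsity=4).fit()
        counts = np.array([(labels == c).sum() for c in res.class_order]) / len(labels)
        G = res.theta.T @ (counts[:, None] * res.theta)
        np.testing.assert_allclose(G, np.eye(res.theta.shape[1]), atol=1e-6)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(8)
        X, labels = make_gaussian_classes(rng, {"a": [0, 0], "b": [3, 1]}, 15)
        res = SparseDiscriminantAnalysis(X, labels, sparsity=2).fit()
        col = res.beta[:, 0]
        assert col[np.argmax(np.abs(col))] > 0

    def test_sparsity_budget_respected(self):
        rng = np.random.default_rng(9)
        X, labels = make_gaussian_classes(
            rng, {"a": [0] * 20, "b": [0.5] * 20, "c": [1] * 20}, 10
        )
        res = SparseDiscriminantAnalysis(X, labels, sparsity=5).fit()
        for q in range(res.beta.shape[1]):
            assert np.count_nonzero(res.beta[:, q]) <= 5

    def test_dense_heavy_ridge_matches_classical_lda_subspace(self):
        """Full budget + ridge equals the generalized-eigenvalue LDA
        subspace (independent oracle), to tiny principal angles."""
        rng = np.random.default_rng(10)
        X, labels = make_gaussian_classes(
            rng, {"a": [0, 0, 0, 0, 0], "b": [2, 1, 0, 0, 0], "c": [0, 0, 2, 1, 0]},
            20,
        )
        ridge = 0.5
        model = SparseDiscriminantAnalysis(X, labels, ridge=ridge, sparsity=99)
        res = model.fit()
        Z = model.features.values
        n = Z.shape[0]
        Y = np.column_stack([(labels == c).astype(float) for c in model.class_order])
        Sb = Z.T @ Y @ np.linalg.inv(Y.T @ Y) @ Y.T @ Z
        M = Z.T @ Z + ridge * n * np.eye(Z.shape[1])
        eigval, eigvec = sla.eigh(Sb, M)
        oracle = eigvec[:, ::-1][:, :2]  # top Q = K - 1 = 2 directions
        qa, _ = np.linalg.qr(res.beta)
        qb, _ = np.linalg.qr(oracle)
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert angles.max() < 1e-3


class TestProjectionAndClassification:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(11)
        X, labels = make_gaussian_classes(
            rng, {"a": [0, 0, 0], "b": [2, 0, 0], "c": [0, 2, 0]}, 12
        )
        model = SparseDiscriminantAnalysis(X, labels, sparsity=3)
        return X, labels, model.fit()

    def test_training_projection_reproduces_centroids(self, fitted):
        X, labels, res = fitted
        scores = res.project(X)
        for k, c in enumerate(res.class_order):
            np.testing.assert_allclose(
                scores[labels == c].mean(axis=0), res.centroids[k], atol=1e-10
            )

    def test_zero_beta_column_gives_zero_scores(self, fitted):
        X, _, res = fitted
        res.beta[:, -1] = 0.0
        assert (res.project(X)[:, -1] == 0).all()

    def test_point_at_centroid_classified_there(self, fitted):
        _, _, res = fitted
        pred = nearest_centroid_classify(res.centroids, res.centroids, res.class_order)
        assert list(pred) == res.class_order

    def test_equidistant_tie_breaks_to_first_class(self):
        centroids = np.array([[1.0, 0.0], [-1.0, 0.0]])
        pred = nearest_centroid_classify([[0.0, 5.0]], centroids, ["II", "IIIa"])
        assert pred[0] == "II"

    def test_feature_mismatch_rejected(self, fitted):
        X, _, res = fitted
        with pytest.raises(ValueError, match="features"):
            res.project(X[:, :2])


class TestBaselines:
    def test_reference_class_sizes(self):
        labels = ["II"] * 25 + ["IIIa"] * 17 + ["IIIb"] * 17 + ["IIIc"] * 12
        chance, naive = baseline_errors(labels, 4)
        assert chance == 0.75
        assert naive == pytest.approx(46 / 71)

    def test_single_class_naive_zero(self):
        chance, naive = baseline_errors(["a"] * 10, 1)
        assert naive == 0.0

    def test_loocv_majority_matches_closed_form(self):
        """Stable unique majority: naive LOOCV equals 1 - n_major/n."""
        labels = ["x"] * 9 + ["y"] * 4 + ["z"] * 3
        _, naive = baseline_errors(labels, 3)
        assert naive == pytest.approx(1 - 9 / 16)


class TestDistances:
    def test_identical_centroids_zero(self):
        D, avg = interclass_distance_matrix(np.ones((4, 3)))
        assert (D == 0).all() and (avg == 0).all()

    def test_simplex_corners(self):
        D, avg = interclass_distance_matrix(np.eye(3))
        off = D[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, np.sqrt(2))
        np.testing.assert_allclose(avg, np.sqrt(2))

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(12)
        D, _ = interclass_distance_matrix(rng.normal(size=(4, 3)))
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)


class TestLoocv:
    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(13)
        X, labels = make_gaussian_classes(
            rng, {"a": [0, 0], "b": [1, 0], "c": [0, 1]}, 8
        )
        ev = loocv_evaluate(X, labels, sparsity=2)
        np.testing.assert_allclose(ev.confusion.sum(axis=1), 100.0, atol=0.5)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(14)
        X, labels = make_gaussian_classes(
            rng, {"a": [2, 0, 0], "b": [0, 2, 0], "c": [0, 0, 2], "d": [1, 1, 1]}, 10
        )
        perm_labels = rng.permutation(labels)
        ev = loocv_evaluate(X, perm_labels, sparsity=3)
        assert abs(ev.loocv_error - 0.75) < 0.2

    def test_separated_classes_identity_confusion(self):
        rng = np.random.default_rng(15)
        X, labels = make_gaussian_classes(
            rng, {"a": [10, 0], "b": [0, 10], "c": [-10, -10]}, 6, scale=0.2
        )
        ev = loocv_evaluate(X, labels, sparsity=2)
        assert ev.loocv_error == 0.0
        np.testing.assert_allclose(np.diag(ev.confusion), 100.0)


class TestClinicalCorrelations:
    def test_report_format_and_pairwise_missing(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=(30, 3))
        table = pd.DataFrame({
            "doi": np.r_[rng.uniform(0, 8, 28), np.nan, np.nan],
            "processing_speed": rng.normal(45, 10, 30),
        })
        out = ldd_clinical_correlations(scores, table)
        assert set(out.columns) == {"ldd", "variable", "n", "r", "p"}
        assert set(out["ldd"]) == {1, 2, 3}
        assert (out.loc[out["variable"] == "doi", "n"] == 28).all()

    def test_planted_gradient_recovered(self):
        rng = np.random.default_rng(17)
        doi = rng.uniform(0, 8, 40)
        scores = np.column_stack([-doi + rng.normal(scale=1.0, size=40),
                                  rng.normal(size=40)])
        table = pd.DataFrame({"doi": doi, "processing_speed": rng.normal(size=40)})
        out = ldd_clinical_correlations(scores, table)
        row = out[(out["ldd"] == 1) & (out["variable"] == "doi")]
        assert float(row["r"].iloc[0]) < -0.5
        assert float(row["p"].iloc[0]) < 0.05
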