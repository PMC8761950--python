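import numpy as np
import pytest

from qgtrial import (
    GenotypeMeansMatrix,
    genotype_means,
    kmeans,
    pca,
    silhouette_widths,
    simulate_rcbd,
    table1_like_config,
)

from conftest import long_table


def matrix_of(values: np.ndarray, standardized=True) -> GenotypeMeansMatrix:
    values = np.asarray(values, dtype=float)
    if standardized:
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    return GenotypeMeansMatrix(
        genotype_ids=[f"g{i}" for i in range(len(values))],
        trait_names=[f"t{j}" for j in range(values.shape[1])],
        values=values,
        standardized=standardized,
    )


class TestGenotypeMeans:
    def test_single_block_means_equal_raw_values(self, rng):
        y = rng.normal(size=(5, 3, 2))
        table = long_table(y)
        sub = table[table["block"] == "b1"]
        m = genotype_means(sub, standardize=False)
        np.testing.assert_allclose(m.values, y[:, 0, :])

    def test_standardized_columns(self, rng):
        m = genotype_means(long_table(rng.normal(size=(10, 3, 4))), standardize=True)
        np.testing.assert_allclose(m.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(m.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_full_panel_dimensions(self):
        m = genotype_means(simulate_rcbd(table1_like_config(2)))
        assert m.values.shape == (64, 15)

    def test_degenerate_column_rejected(self):
        y = np.ones((4, 2, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            genotype_means(long_table(y), standardize=True)


class TestPCA:
    def test_rank_one_limit(self, rng):
        x = rng.normal(size=(20, 1))
        res = pca(matrix_of(np.hstack([x, 3 * x])))
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-12)

    def test_two_variable_closed_form(self, rng):
        for rho in (0.2, -0.5, 0.83):
            a = rng.normal(size=(4000, 2))
            a[:, 1] = rho * a[:, 0] + np.sqrt(1 - rho**2) * a[:, 1]
            res = pca(matrix_of(a))
            sample_rho = np.corrcoef(a, rowvar=False)[0, 1]
            np.testing.assert_allclose(
                res.eigenvalues, [1 + abs(sample_rho), 1 - abs(sample_rho)], atol=1e-9
            )

    def test_eigenvalue_sum_and_cumulative_percent(self, rng):
        m = matrix_of(rng.normal(size=(30, 7)))
        res = pca(m)
        assert res.eigenvalues.sum() == pytest.approx(7.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(np.diff(res.cumulative_percent) >= -1e-12)
        assert res.cumulative_percent[-1] == pytest.approx(100.0)

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        m = matrix_of(rng.normal(size=(50, 4)))
        res = pca(m)
        cov = np.cov(res.scores, rowvar=False)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        res = pca(matrix_of(rng.normal(size=(25, 5))))
        for j in range(5):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_requires_standardized_input(self, rng):
        m = matrix_of(rng.normal(size=(10, 3)), standardized=False)
        with pytest.raises(ValueError, match="standardized"):
            pca(m)


class TestKMeans:
    def test_k_equals_n_zero_objective(self, rng):
        x = rng.normal(size=(6, 2))
        res = kmeans(x, k=6, seed=0)
        assert res.objective_j == pytest.approx(0.0, abs=1e-12)

    def test_k_one_grand_mean(self, rng):
        x = rng.normal(size=(20, 3))
        res = kmeans(x, k=1, seed=0)
        np.testing.assert_allclose(res.centroids[0], x.mean(axis=0))
        assert res.objective_j == pytest.approx(((x - x.mean(axis=0)) ** 2).sum())
        assert res.silhouette is None

    def test_separated_blobs_recovered_across_seeds(self, rng):
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(15, 2)) + 10.0  # 10-sd separation
        x = np.vstack([a, b])
        truth = np.repeat([0, 1], 15)
        for seed in range(50):
            res = kmeans(x, k=2, seed=seed)
            agree = (res.assignments == truth).mean()
            assert agree in (0.0, 1.0)  # label-permutation invariant, no errors

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(30, 4))
        r1, r2 = kmeans(x, 4, seed=9), kmeans(x, 4, seed=9)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)
        assert r1.objective_j == r2.objective_j

    def test_matches_sklearn_objective(self, rng):
        from sklearn.cluster import KMeans as SkKMeans

        x = rng.normal(size=(60, 3))
        ours = kmeans(x, 4, seed=0, n_restarts=10)
        sk = SkKMeans(n_clusters=4, n_init=10, random_state=0).fit(x)
        assert ours.objective_j == pytest.approx(sk.inertia_, rel=0.05)

    def test_invalid_k_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        for k in (0, 6):
            with pytest.raises(ValueError):
                kmeans(x, k, seed=0)


class TestSilhouette:
    def test_equidistant_point_scores_zero(self):
        x = np.array([[0.0], [2.0], [1.0]])
        s, _ = silhouette_widths(x, np.array([0, 1, 0]))
        # middle point: a = 1 (own cluster mate), b = 1 (other cluster)
        assert s[2] == pytest.approx(0.0)

    def test_perfectly_separated_coincident_clusters(self):
        x = np.array([[0.0], [0.0], [9.0], [9.0]])
        s, cluster_means = silhouette_widths(x, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(s, 1.0)
        np.testing.assert_allclose(cluster_means, 1.0)

    def test_hand_computed_four_point_example(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        s, _ = silhouette_widths(x, np.array([0, 0, 1, 1]))
        b = (10.0 + np.sqrt(101.0)) / 2
        expected = (b - 1.0) / b
        np.testing.assert_allclose(s, expected, atol=1e-12)
        assert s[0] == pytest.approx(0.9003, abs=1e-4)

    def test_bounds_and_sklearn_agreement_on_random_data(self, rng):
        from sklearn.metrics import silhouette_samples

        for _ in range(20):
            x = rng.normal(size=(rng.integers(10, 30), 3))
            res = kmeans(x, k=int(rng.integers(2, 5)), seed=1)
            assert np.all(res.silhouette >= -1) and np.all(res.silhouette <= 1)
            counts = np.bincount(res.assignments)
            if (counts[counts > 0] > 1).all():
                ref = silhouette_samples(x, res.assignments)
                np.testing.assert_allclose(res.silhouette, ref, atol=1e-9)

    def test_single_cluster_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="single cluster"):
            silhouette_widths(x, np.zeros(5, dtype=int))

    def test_singleton_cluster_convention(self):
        x = np.array([[0.0], [0.1], [5.0]])
        s, _ = silhouette_widths(x, np.array([0, 0, 1]))
        assert s[2] == 0.0
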