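"""Network estimation: elastic-net fits, BIC selection, invariants."""

import numpy as np
import pytest

from gbnea import (DataValidationError, DirectedNetwork, ExpressionDataset,
                   RegressionConfig, compute_bic, estimate_network,
                   fit_target_regression)
from conftest import make_dataset

EXACT_CONFIG = RegressionConfig(standardize=False, cd_tol=1e-12,
                                cd_max_sweeps=100_000)


def orthonormal_design(rng, n=32, p=8):
    q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    return q  # columns orthonormal: X^T X = I


class TestFitTargetRegression:
    @pytest.mark.parametrize("lam", [0.05, 0.3, 1.0])
    def test_soft_threshold_on_orthonormal_design(self, rng, lam):
        """Lasso on an orthonormal design is exact soft-thresholding."""
        X = orthonormal_design(rng)
        y = rng.standard_normal(X.shape[0])
        beta = fit_target_regression(y, X, EXACT_CONFIG, lam)
        xty = X.T @ y
        expected = np.sign(xty) * np.maximum(np.abs(xty) - lam, 0.0)
        np.testing.assert_allclose(beta, expected, atol=1e-6)

    def test_single_active_regulator_is_shrunk_by_lam(self, rng):
        X = orthonormal_design(rng)
        beta_star = np.zeros(X.shape[1])
        beta_star[3] = 5.0
        y = X @ beta_star
        beta = fit_target_regression(y, X, EXACT_CONFIG, lam=0.5)
        assert np.count_nonzero(beta) == 1
        assert beta[3] == pytest.approx(5.0 - 0.5, abs=1e-8)

    def test_zero_response_gives_zero_coefficients(self, rng):
        X = rng.standard_normal((20, 6))
        beta = fit_target_regression(np.zeros(20), X, EXACT_CONFIG, 0.1)
        assert np.all(beta == 0)

    def test_full_shrinkage_limit(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        lam = 1e6 * np.max(np.abs(X.T @ y))
        beta = fit_target_regression(y, X, EXACT_CONFIG, lam)
        assert np.all(beta == 0)

    @pytest.mark.parametrize("delta", [1.0, 0.5, 0.1])
    def test_matches_sklearn_elasticnet(self, rng, delta):
        """Independent check of the coordinate-descent solver."""
        from sklearn.linear_model import ElasticNet

        cfg = RegressionConfig(delta=delta, standardize=False,
                               cd_tol=1e-12, cd_max_sweeps=100_000)
        for _ in range(10):
            n, p = 30, int(rng.integers(4, 20))
            X = rng.standard_normal((n, p))
            y = X @ (rng.standard_normal(p) * (rng.random(p) < 0.4)) \
                + rng.standard_normal(n)
            lam = float(rng.uniform(0.1, 2.0)) * n
            beta = fit_target_regression(y, X, cfg, lam)
            ref = ElasticNet(alpha=lam / n, l1_ratio=delta,
                             fit_intercept=False, tol=1e-12,
                             max_iter=500_000).fit(X, y)
            np.testing.assert_allclose(beta, ref.coef_, atol=1e-6)

    def test_lam_zero_is_least_squares(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        beta = fit_target_regression(y, X, EXACT_CONFIG, 0.0)
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_lam_zero_requires_more_samples_than_regulators(self, rng):
        X = rng.standard_normal((5, 8))
        with pytest.raises(DataValidationError):
            fit_target_regression(rng.standard_normal(5), X, EXACT_CONFIG, 0.0)

    def test_non_finite_values_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        y[0] = np.nan
        with pytest.raises(DataValidationError):
            fit_target_regression(y, X, EXACT_CONFIG, 0.1)
        X[1, 1] = np.inf
        with pytest.raises(DataValidationError):
            fit_target_regression(np.ones(10), X, EXACT_CONFIG, 0.1)

    def test_zero_variance_regulator_gets_zero_coefficient(self, rng):
        X = rng.standard_normal((25, 4))
        X[:, 2] = 3.14
        y = X[:, 0] * 2 + 0.01 * rng.standard_normal(25)
        beta = fit_target_regression(y, X, RegressionConfig(), 0.1)
        assert beta[2] == 0.0

    def test_monotone_sparsity_along_path(self, rng):
        """Raising the penalty never adds nonzero coefficients (lasso)."""
        X = rng.standard_normal((60, 12))
        y = X @ (rng.standard_normal(12) * (rng.random(12) < 0.5)) \
            + 0.5 * rng.standard_normal(60)
        lam_max = np.max(np.abs(X.T @ y))
        nnz = [np.count_nonzero(
            fit_target_regression(y, X, EXACT_CONFIG, lam))
            for lam in lam_max * np.array([1e-3, 1e-2, 0.1, 0.5, 1.0])]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestComputeBic:
    def test_perfect_fit_leaves_penalty_term(self):
        y = np.arange(100, dtype=float)
        assert compute_bic(y, y, df=3, sigma2=1.0, n=100) == \
            pytest.approx(np.log(100) * 3 / 100)

    def test_null_model_arithmetic(self):
        y = np.zeros(50)
        y_hat = np.full(50, 1.0)  # rss = 50
        assert compute_bic(y, y_hat, df=0, sigma2=1.0, n=50) == \
            pytest.approx(1.0)

    def test_more_df_with_equal_residuals_is_worse(self, rng):
        y = rng.standard_normal(30)
        y_hat = y + 0.1
        small = compute_bic(y, y_hat, df=2, sigma2=0.5, n=30)
        large = compute_bic(y, y_hat, df=5, sigma2=0.5, n=30)
        assert large > small

    def test_zero_sigma2_points_to_fallback(self):
        with pytest.raises(DataValidationError, match="fallback"):
            compute_bic(np.ones(5), np.ones(5), df=1, sigma2=0.0, n=5)


class TestEstimateNetwork:
    def planted_dataset(self, rng, n=200, noise=0.05):
        g1 = rng.standard_normal(n)
        g2 = 2.0 * g1 + noise * rng.standard_normal(n)
        g3 = rng.standard_normal(n)
        values = np.vstack([g1, g2, g3])
        return ExpressionDataset(values, ("g1", "g2", "g3"),
                                 tuple(f"s{i}" for i in range(n)),
                                 ("C",) * n)

    def test_planted_support_recovery(self, rng):
        """g2 = 2 g1 + noise: the edge g1 -> g2 is found, g3 stays isolated."""
        data = self.planted_dataset(rng)
        net = estimate_network(data, "C")
        assert ("g1", "g2") in net.coefficients
        assert net.coefficients[("g1", "g2")] == pytest.approx(2.0, abs=0.1)
        # the independent gene may pick up at most noise-level weights
        g3_weights = [abs(w) for e, w in net.coefficients.items()
                      if "g3" in e]
        assert all(w < 0.05 for w in g3_weights)

    def test_single_sample_phenotype_rejected(self, rng):
        data = ExpressionDataset(rng.standard_normal((3, 3)),
                                 ("a", "b", "c"), ("s1", "s2", "s3"),
                                 ("C", "N", "N"))
        with pytest.raises(DataValidationError, match="at least 2"):
            estimate_network(data, "C")

    def test_absent_phenotype_rejected(self, noise_dataset):
        with pytest.raises(DataValidationError, match="absent"):
            estimate_network(noise_dataset, "missing")

    def test_huge_lambda_grid_gives_empty_network(self, noise_dataset):
        config = RegressionConfig(lambda_grid=(1e6,))
        net = estimate_network(noise_dataset, "C", config)
        assert net.n_edges == 0

    def test_deterministic(self, rng):
        data = make_dataset(rng, n_genes=10, n_per_group=12)
        net1 = estimate_network(data, "C")
        net2 = estimate_network(data, "C")
        assert net1.coefficients == net2.coefficients
        assert net1.lambda_selected == net2.lambda_selected

    def test_returned_network_satisfies_invariants(self, rng):
        data = make_dataset(rng, n_genes=12, n_per_group=15)
        net = estimate_network(data, "N")
        universe = set(net.gene_ids)
        for (reg, tgt), w in net.coefficients.items():
            assert reg != tgt
            assert reg in universe and tgt in universe
            assert w != 0 and np.isfinite(w)

    def test_zero_variance_gene_stays_isolated(self, rng):
        data = make_dataset(rng, n_genes=6, n_per_group=10)
        values = data.values.copy()
        values[2] = 7.0
        flat = ExpressionDataset(values, data.gene_ids, data.sample_ids,
                                 data.phenotype)
        net = estimate_network(flat, "C")
        assert not [e for e in net.coefficients if data.gene_ids[2] in e]

    def test_grid_with_zero_requires_small_p(self, rng):
        data = make_dataset(rng, n_genes=15, n_per_group=6)
        with pytest.raises(DataValidationError, match="lambda = 0"):
            estimate_network(data, "C",
                             RegressionConfig(lambda_grid=(0.0, 0.5)))

    def test_grid_with_zero_runs_when_p_below_n(self, rng):
        data = make_dataset(rng, n_genes=4, n_per_group=20)
        net = estimate_network(data, "C",
                               RegressionConfig(lambda_grid=(0.0, 1e6)))
        assert set(net.lambda_selected.values()) <= {0.0, 1e6}


class TestDirectedNetwork:
    def test_self_edge_rejected(self):
        with pytest.raises(DataValidationError, match="self-edge"):
            DirectedNetwork(("a", "b"), {("a", "a"): 1.0})

    def test_zero_weight_rejected(self):
        with pytest.raises(DataValidationError, match="nonzero"):
            DirectedNetwork(("a", "b"), {("a", "b"): 0.0})

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(DataValidationError, match="universe"):
            DirectedNetwork(("a", "b"), {("a", "z"): 1.0})

    def test_matrix_round_trip(self, tiny_network_pair):
        net, _ = tiny_network_pair
        back = DirectedNetwork.from_matrix(net.gene_ids, net.to_matrix(),
                                           net.phenotype_label)
        assert back.coefficients == net.coefficients
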