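"""core_model: penalty scales, weighted lasso, CV, weight updates, full fit."""

import numpy as np
import pytest

import rdriver.model as m
from rdriver.errors import ValidationError
from rdriver.model import ModelConfig

from oracles import proximal_gradient_lasso


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


def _random_instance(rng, n=50, M=5, snr=1.0):
    X = _standardize(rng.normal(size=(n, M)))
    beta_true = rng.normal(size=M) * snr
    y = X @ beta_true + rng.normal(size=n)
    return y - y.mean(), X


class TestPenaltyScale:
    def test_zero_weights_give_half(self, rng):
        F = rng.normal(size=(7, 3))
        delta = m.compute_penalty_scale(np.zeros(3), F)
        np.testing.assert_allclose(delta, 0.5)

    def test_literal_mode_matches_printed_sigmoid(self):
        delta = m.compute_penalty_scale(
            np.array([1.0]), np.array([[np.log(3)]]), mode="literal"
        )
        np.testing.assert_allclose(delta, [0.75])

    def test_oriented_mode_flips_sign(self):
        delta = m.compute_penalty_scale(
            np.array([1.0]), np.array([[np.log(3)]]), mode="oriented"
        )
        np.testing.assert_allclose(delta, [0.25])

    def test_floor_applied(self):
        delta = m.compute_penalty_scale(
            np.array([10.0]), np.array([[5.0]]), mode="oriented", delta_min=0.05
        )
        assert delta[0] == 0.05

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError, match="does not match"):
            m.compute_penalty_scale(np.zeros(2), np.zeros((3, 3)))


@pytest.mark.parametrize(
    "z,gamma,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)]
)
def test_soft_threshold(z, gamma, expected):
    assert m.soft_threshold(z, gamma) == expected


class TestWeightedLasso:
    def test_ols_limit_single_predictor(self, rng):
        x = _standardize(rng.normal(size=(40, 1)))
        y = 2.0 * x[:, 0]
        beta, ok = m.fit_weighted_lasso(y, x, np.array([0.5]), lambda1=0.0)
        assert ok
        np.testing.assert_allclose(beta, [2.0], atol=1e-8)

    def test_null_threshold_gives_exact_zero(self, rng):
        y, X = _random_instance(rng)
        delta = np.full(X.shape[1], 0.7)
        n = len(y)
        lam_max = np.max(np.abs(X.T @ y) / (n * delta))
        beta, _ = m.fit_weighted_lasso(y, X, delta, lambda1=lam_max * 1.0000001)
        assert np.all(beta == 0.0)

    def test_matches_proximal_gradient_oracle(self, rng):
        # 20 random instances, per-coefficient agreement within 1e-6
        for i in range(20):
            y, X = _random_instance(rng)
            delta = rng.uniform(0.1, 1.0, size=X.shape[1])
            lam = 0.1
            beta, ok = m.fit_weighted_lasso(y, X, delta, lam, tol=1e-9)
            ref = proximal_gradient_lasso(y, X, delta, lam, tol=1e-12)
            assert ok
            np.testing.assert_allclose(beta, ref, atol=1e-6)

    def test_delta_one_matches_sklearn_lasso(self, rng):
        # prior-free reduction against an independent plain-lasso solver
        from sklearn.linear_model import Lasso

        for i in range(20):
            y, X = _random_instance(rng, n=40, M=6)
            lam = 0.15
            beta, _ = m.fit_weighted_lasso(y, X, np.ones(6), lam, tol=1e-9)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=100000)
            ref.fit(X, y)
            np.testing.assert_allclose(beta, ref.coef_, atol=1e-6)

    def test_kkt_certificate(self, rng):
        y, X = _random_instance(rng)
        delta = rng.uniform(0.2, 1.0, size=X.shape[1])
        lam = 0.2
        beta, _ = m.fit_weighted_lasso(y, X, delta, lam, tol=1e-8)
        n = len(y)
        grad = X.T @ (y - X @ beta) / n
        for k in range(X.shape[1]):
            if beta[k] == 0:
                assert abs(grad[k]) <= lam * delta[k] + 1e-6
            else:
                assert abs(grad[k] - lam * delta[k] * np.sign(beta[k])) <= 1e-6

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            m.fit_weighted_lasso(np.array([np.nan, 1.0]), np.ones((2, 1)),
                                 np.ones(1), 0.1)

    def test_monotone_support_along_path(self, rng):
        # warm-started decreasing-lambda path never loses sparsity monotonicity
        for _ in range(10):
            y, X = _random_instance(rng, n=30, M=8)
            delta = rng.uniform(0.3, 1.0, size=8)
            lam_max = np.max(np.abs(X.T @ y) / (len(y) * delta))
            beta = np.zeros(8)
            sizes = []
            for lam in lam_max * np.logspace(0, -2, 10):
                beta, _ = m.fit_weighted_lasso(y, X, delta, lam, beta0=beta)
                sizes.append(int(np.sum(beta != 0)))
            assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_scaling_equivariance(self, rng):
        # multiplying y by c and lambda1 by c multiplies beta by c
        y, X = _random_instance(rng)
        delta = rng.uniform(0.2, 1.0, size=X.shape[1])
        b1, _ = m.fit_weighted_lasso(y, X, delta, 0.1, tol=1e-10)
        c = 3.7
        b2, _ = m.fit_weighted_lasso(c * y, X, delta, c * 0.1, tol=1e-10)
        np.testing.assert_allclose(b2, c * b1, atol=1e-6)


class TestObjective:
    def test_zero_beta_and_weights(self, rng):
        Y = rng.normal(size=(4, 3))
        X = rng.normal(size=(4, 2))
        val = m.objective(Y, X, np.zeros((2, 3)), np.ones(2), 0.5, 0.5, np.zeros(1))
        np.testing.assert_allclose(val, 0.5 / 4 * np.sum(Y**2))

    def test_exact_fit_residual_zero(self):
        y = np.array([[1.0], [-1.0]])
        X = np.array([[1.0], [-1.0]])
        val = m.objective(y, X, np.array([[1.0]]), np.ones(1), 0.0, 0.0, np.zeros(1))
        assert val == 0.0

    def test_hand_summed_tiny_instance(self):
        # n=2, one gene: y=(1,0), x=(1,-1), beta=0.5, delta=0.8,
        # lam1=0.2, lam2=0.3, w=(2,)
        y = np.array([[1.0], [0.0]])
        X = np.array([[1.0], [-1.0]])
        beta = np.array([[0.5]])
        # residual (0.5, 0.5): rss/2n = 0.25/2 + ... = (0.25+0.25)/4 = 0.125
        expected = 0.125 + 0.2 * 0.8 * 0.5 + 0.3 * 4.0
        val = m.objective(y, X, beta, np.array([0.8]), 0.2, 0.3, np.array([2.0]))
        np.testing.assert_allclose(val, expected)


class TestSelectLambdasCV:
    def test_pure_noise_selects_sparse_fit(self):
        # Under the null the min-MSE rule usually picks a large lambda and a
        # mostly-zero fit. "Usually", not always: a fixed noise vector's
        # chance correlations with X persist across folds, so CV sometimes
        # legitimately prefers a dense fit — sklearn's LassoCV makes the
        # same choice on the same draws (checked below), so the assertion
        # is majority-level, matched to that independent oracle.
        hits = 0
        zero_fracs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = _standardize((rng.random((100, 10)) < 0.2).astype(float))
            y = rng.normal(size=100)
            y -= y.mean()
            delta = np.full(10, 0.5)
            params = m.select_lambdas_cv(y, X, delta, k_folds=10, seed=seed)
            ratios = np.logspace(0, np.log10(0.01), 20)
            lam_max = np.max(np.abs(X.T @ y) / (100 * delta))
            rank = np.argmin(np.abs(ratios * lam_max - params.lambda1[0]))
            hits += rank < 5  # top quartile of the 20-point grid
            beta, _ = m.fit_weighted_lasso(y, X, delta, float(params.lambda1[0]))
            zero_fracs.append(np.mean(beta == 0))
        assert hits >= 7
        assert np.mean(zero_fracs) >= 0.75

    def test_null_selection_no_denser_than_sklearn_oracle(self):
        # dual route: our CV selection should be at least as sparse, on
        # average, as sklearn's LassoCV with the same grid and fold count
        from sklearn.linear_model import Lasso, LassoCV
        from sklearn.model_selection import KFold

        ours, oracle = [], []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = _standardize((rng.random((100, 10)) < 0.2).astype(float))
            y = rng.normal(size=100)
            y -= y.mean()
            delta = np.full(10, 0.5)
            params = m.select_lambdas_cv(y, X, delta, k_folds=10, seed=seed)
            beta, _ = m.fit_weighted_lasso(y, X, delta, float(params.lambda1[0]))
            ours.append(np.mean(beta == 0))
            lam_max = np.max(np.abs(X.T @ y) / 100) / 0.5
            alphas = np.logspace(0, -2, 20) * lam_max * 0.5
            cv = LassoCV(alphas=alphas, fit_intercept=False,
                         cv=KFold(10, shuffle=True, random_state=seed)).fit(X, y)
            b = Lasso(alpha=cv.alpha_, fit_intercept=False).fit(X, y).coef_
            oracle.append(np.mean(b == 0))
        assert np.mean(ours) >= np.mean(oracle) - 0.05

    def test_planted_signal_recovered_at_selected_lambda(self):
        rng = np.random.default_rng(5)
        X = _standardize(rng.normal(size=(100, 6)))
        y = 3.0 * X[:, 2] + rng.normal(0, 0.1, size=100)
        y -= y.mean()
        delta = np.full(6, 0.5)
        params = m.select_lambdas_cv(y, X, delta, k_folds=10, seed=1)
        beta, _ = m.fit_weighted_lasso(y, X, delta, float(params.lambda1[0]))
        assert beta[2] != 0.0

    def test_deterministic_given_seed(self, rng):
        y, X = _random_instance(rng, n=40)
        delta = np.full(X.shape[1], 0.5)
        a = m.select_lambdas_cv(y, X, delta, k_folds=5, seed=42)
        b = m.select_lambdas_cv(y, X, delta, k_folds=5, seed=42)
        np.testing.assert_array_equal(a.lambda1, b.lambda1)

    def test_too_few_samples_errors(self, rng):
        y, X = _random_instance(rng, n=5)
        with pytest.raises(ValidationError, match="k_folds"):
            m.select_lambdas_cv(y, X, np.full(5, 0.5), k_folds=10, seed=0)


class TestUpdateWeights:
    def test_zero_beta_drives_weights_to_zero(self, rng):
        F = rng.normal(size=(6, 2))
        w, ok = m.update_weights(np.zeros((6, 4)), F, np.full(4, 0.1),
                                 np.full(4, 0.1), np.array([0.5, 1.0]))
        assert ok
        np.testing.assert_allclose(w, 0.0, atol=1e-6)

    def test_informative_feature_outranks_noise(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            M = 20
            selected = np.zeros(M, dtype=bool)
            selected[:5] = True
            F = np.column_stack([
                np.where(selected, 1.5, -0.5) + rng.normal(0, 0.3, M),  # informative
                rng.normal(size=M),                                      # noise
            ])
            F = (F - F.mean(0)) / F.std(0)
            beta = np.where(selected[:, None], 1.0, 0.0) * np.ones((M, 10))
            w, _ = m.update_weights(beta, F, np.full(10, 0.5), np.full(10, 0.01),
                                    np.zeros(2))
            wins += w[0] > w[1]
        assert wins >= 8

    def test_projection_keeps_weights_nonnegative(self, rng):
        F = rng.normal(size=(8, 3))
        beta = rng.normal(size=(8, 5))
        w, _ = m.update_weights(beta, F, np.full(5, 0.3), np.full(5, 0.1),
                                rng.uniform(size=3), mode="literal")
        assert np.all(w >= 0)


class TestFitRdriver:
    def test_null_data_is_sparse(self):
        # no-association cohorts at the standard study scale: fewer than 5%
        # of (allele, gene) coefficients survive, on average over seeds
        from rdriver.simulate import SimulationConfig, simulate_null_dataset

        fractions = []
        for seed in range(3):
            ds = simulate_null_dataset(SimulationConfig(seed=400 + seed))
            fit = m.fit_rdriver(ds.Y, ds.X, ds.F,
                                ModelConfig(n_lambda1=10, k_folds=5, seed=seed))
            fractions.append(fit.support.mean())
        assert np.mean(fractions) < 0.05

    def test_descent_within_lambda_epochs(self, tiny_dataset):
        fit = m.fit_rdriver(tiny_dataset.Y, tiny_dataset.X, tiny_dataset.F,
                            ModelConfig(n_lambda1=8, k_folds=5, seed=3))
        trace = fit.objective_trace
        bounds = fit.lambda_epochs + [len(trace)]
        for s, e in zip(bounds, bounds[1:]):
            seg = trace[s:e]
            assert all(a >= b - 1e-9 * max(abs(a), 1.0)
                       for a, b in zip(seg, seg[1:]))

    def test_degenerate_columns_dropped_not_fatal(self, rng):
        X = (rng.random((50, 4)) < 0.3).astype(float)
        X[:, 1] = 0.0  # never mutated
        X[:2, [0, 2, 3]] = 1
        Y = rng.normal(size=(50, 6))
        Y[:, 2] = 4.2  # constant gene
        F = rng.normal(size=(4, 2))
        fit = m.fit_rdriver(Y, X, F, ModelConfig(n_lambda1=6, k_folds=5, seed=0))
        assert fit.dropped_alleles == ["m1"]
        assert fit.dropped_genes == ["g2"]
        assert np.all(fit.beta[1] == 0)
        assert np.isnan(fit.r2[2])

    def test_kkt_certificate_at_convergence(self, tiny_dataset):
        cfg = ModelConfig(n_lambda1=8, k_folds=5, seed=11)
        fit = m.fit_rdriver(tiny_dataset.Y, tiny_dataset.X, tiny_dataset.F, cfg)
        Xs, keep = m.standardize_columns(tiny_dataset.X.values.astype(float))
        Yc = tiny_dataset.Y.values - tiny_dataset.Y.values.mean(axis=0)
        n = Yc.shape[0]
        grad = Xs.T @ (Yc - Xs @ fit.beta) / n
        thr = np.outer(fit.delta, fit.lambdas.lambda1)
        nz = fit.beta != 0
        assert np.all(np.abs(grad[~nz]) <= thr[~nz] + 1e-6)
        assert np.all(np.abs(grad[nz] - thr[nz] * np.sign(fit.beta[nz])) <= 1e-6)


class TestVarianceExplained:
    def test_zero_beta_gives_zero(self, rng):
        Y = rng.normal(size=(10, 3))
        X = rng.normal(size=(10, 2))
        np.testing.assert_allclose(m.variance_explained(Y, X, np.zeros((2, 3))), 0.0)

    def test_noiseless_fit_approaches_one(self, rng):
        X = (rng.random((60, 3)) < 0.4).astype(float)
        Xs, _ = m.standardize_columns(X)
        beta = np.array([[1.0, 0.0], [0.0, 2.0], [0.5, 0.0]])
        Y = Xs @ beta
        r2 = m.variance_explained(Y, X, beta)
        np.testing.assert_allclose(r2, 1.0, atol=1e-6)

    def test_two_sample_hand_instance(self):
        # y = (1,-1), x = (1,-1) standardized; beta = 0.5 leaves residual
        # (0.5,-0.5): R2 = 1 - 0.5/2 = 0.75
        Y = np.array([[1.0], [-1.0]])
        X = np.array([[1.0], [0.0]])  # standardizes to (1,-1)
        r2 = m.variance_explained(Y, X, np.array([[0.5]]))
        np.testing.assert_allclose(r2, [0.75])

    def test_constant_gene_reported_missing(self, rng):
        Y = np.column_stack([np.full(8, 2.0), rng.normal(size=8)])
        X = rng.normal(size=(8, 1))
        r2 = m.variance_explained(Y, X, np.zeros((1, 2)))
        assert np.isnan(r2[0]) and r2[1] == 0.0
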