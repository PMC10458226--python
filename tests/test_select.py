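import math

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from specfuse.fuse import SpectralDataset
from specfuse.preprocess import Modality
from specfuse.select import (
    FeatureMask, anova_filter, enet_objective, enet_fit, enet_path,
    enet_select, lambda_max, default_lambda_path,
)
from specfuse._enet_solver import standardize
from conftest import make_multinomial_problem


def brute_force_anova_f(X, y):
    """Two-loop between/within mean-squares reference."""
    classes = np.unique(y)
    n, p = X.shape
    K = classes.size
    F = np.zeros(p)
    for j in range(p):
        grand = X[:, j].mean()
        ss_between = 0.0
        ss_within = 0.0
        for c in classes:
            xc = X[y == c, j]
            ss_between += len(xc) * (xc.mean() - grand) ** 2
            ss_within += np.sum((xc - xc.mean()) ** 2)
        ms_between = ss_between / (K - 1)
        ms_within = ss_within / (n - K)
        F[j] = np.inf if ms_within == 0 else ms_between / ms_within
    return F


class TestAnovaFilter:
    @pytest.mark.parametrize("n, p, K, seed", [(12, 5, 3, 0), (100, 50, 4, 1)])
    def test_matches_brute_force_mean_squares(self, n, p, K, seed):
        gen = np.random.default_rng(seed)
        X = gen.normal(size=(n, p))
        y = np.repeat(np.arange(K), n // K)[:n]
        X[:, 0] += y * 2.0  # one clearly informative channel
        ref = brute_force_anova_f(X, y)
        order_ref = np.argsort(-ref, kind="stable")
        mask = anova_filter(X, p, y=y)
        # recompute the implementation's ranking through increasing keep_n
        sizes = [len(anova_filter(X, k, y=y).indices) for k in range(1, p + 1)]
        assert sizes == list(range(1, p + 1))
        top1 = anova_filter(X, 1, y=y).indices[0]
        assert top1 == order_ref[0] == 0

    def test_f_statistics_equal_reference_to_1e10(self):
        from sklearn.feature_selection import f_classif
        gen = np.random.default_rng(3)
        X = gen.normal(size=(60, 20))
        y = np.repeat(np.arange(3), 20)
        F_impl, _ = f_classif(X, y)
        np.testing.assert_allclose(F_impl, brute_force_anova_f(X, y), rtol=1e-10)

    def test_constant_channel_is_excluded_when_others_vary(self):
        gen = np.random.default_rng(0)
        X = gen.normal(size=(30, 4))
        X[:, 2] = 5.0
        y = np.repeat([0, 1, 2], 10)
        X[:, 0] += y
        mask = anova_filter(X, 3, y=y)
        assert 2 not in mask.indices

    def test_keep_n_larger_than_channels_rejected(self):
        X, y = make_multinomial_problem(n=30, p=5)
        with pytest.raises(ValueError, match="keep_n"):
            anova_filter(X, 6, y=y)

    def test_accepts_spectral_dataset(self):
        from specfuse.axes import SpectralAxis, AxisKind
        X, y = make_multinomial_problem(n=30, p=8)
        axis = SpectralAxis(AxisKind.wavelength_nm, np.linspace(400, 500, 8))
        ds = SpectralDataset(X, y.astype(str), Modality.libs, axis)
        assert len(anova_filter(ds, 4)) == 4


class TestFeatureMask:
    def test_indices_sorted_unique_in_range(self):
        mask = FeatureMask(np.array([5, 1, 3]), "anova", 10)
        np.testing.assert_array_equal(mask.indices, [1, 3, 5])
        with pytest.raises(ValueError):
            FeatureMask(np.array([1, 1]), "anova", 10)
        with pytest.raises(ValueError):
            FeatureMask(np.array([10]), "anova", 10)


class TestEnetObjective:
    def test_null_model_on_balanced_classes_is_log_K(self):
        X, _ = make_multinomial_problem(n=12, p=4)
        y = np.repeat([0, 1, 2], 4)
        K = 3
        val = enet_objective(X, y, np.zeros((K, 4)), np.zeros(K), 0.5, 1.0)
        assert val == pytest.approx(math.log(K), rel=1e-12)

    def test_hand_computed_three_sample_instance(self):
        # 3 samples, 2 features, 2 classes; coefficients chosen by hand
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([0, 1, 1])
        B = np.array([[0.5, -0.25], [-0.5, 0.25]])
        b0 = np.array([0.1, -0.1])
        nll = 0.0
        for i in range(3):
            scores = [b0[k] + X[i] @ B[k] for k in range(2)]
            denom = sum(math.exp(s) for s in scores)
            nll -= math.log(math.exp(scores[y[i]]) / denom)
        nll /= 3
        lam, alpha = 0.7, 0.3
        pen = lam * sum(
            alpha * np.abs(B[k]).sum() + 0.5 * (1 - alpha) * (B[k] ** 2).sum()
            for k in range(2)
        )
        assert enet_objective(X, y, B, b0, alpha, lam) == pytest.approx(nll + pen, rel=1e-12)

    def test_penalty_linear_in_lambda(self):
        X, y = make_multinomial_problem(n=20, p=5)
        B = np.random.default_rng(0).normal(size=(3, 5))
        b0 = np.zeros(3)
        f0 = enet_objective(X, y, B, b0, 0.5, 0.0)
        f1 = enet_objective(X, y, B, b0, 0.5, 1.0)
        f2 = enet_objective(X, y, B, b0, 0.5, 2.0)
        assert f2 - f0 == pytest.approx(2 * (f1 - f0), rel=1e-9)

    def test_nonfinite_coefficients_rejected(self):
        X, y = make_multinomial_problem(n=10, p=3)
        B = np.full((3, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            enet_objective(X, y, B, np.zeros(3), 0.5, 0.1)


class TestEnetFit:
    def test_all_zero_at_and_above_lambda_max(self):
        X, y = make_multinomial_problem(seed=1)
        lmax = lambda_max(X, y, 1.0)
        for lam in (lmax, 1.5 * lmax):
            fit = enet_fit(X, y, 1.0, lam)
            assert np.all(fit.coefficients == 0.0)
        below = enet_fit(X, y, 1.0, 0.9 * lmax)
        assert np.any(below.coefficients != 0.0)

    def test_near_zero_lambda_matches_unpenalized_oracle(self):
        # small non-separable instance; oracle is an unpenalized fit
        gen = np.random.default_rng(4)
        X = gen.normal(size=(40, 2))
        logits = 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (logits + gen.normal(scale=1.5, size=40) > 0).astype(int)
        Xs, _, _ = standardize(X)
        oracle = LogisticRegression(penalty=None, tol=1e-10, max_iter=5000)
        oracle.fit(Xs, y)
        dev_oracle = -2 * oracle.score(Xs, y)  # placeholder, replaced below
        from scipy.special import logsumexp
        def deviance(eta):
            log_p = eta - logsumexp(eta, axis=1, keepdims=True)
            return float(-2 * log_p[np.arange(len(y)), y].mean())
        eta_oracle = oracle.decision_function(Xs)
        eta_oracle = np.column_stack([-eta_oracle / 2, eta_oracle / 2])
        dev_oracle = deviance(eta_oracle)
        fit = enet_fit(X, y, 1.0, 1e-8, tol=1e-9, obj_tol=0.0, max_iter=50000)
        eta_fit = Xs @ fit.coefficients.T + fit.intercepts
        assert deviance(eta_fit) == pytest.approx(dev_oracle, abs=1e-4)

    @pytest.mark.parametrize("seed, alpha", [(0, 1.0), (1, 0.5), (2, 0.7)])
    def test_kkt_conditions_at_convergence(self, seed, alpha):
        X, y = make_multinomial_problem(seed=seed)
        n = X.shape[0]
        lmax = lambda_max(X, y, alpha)
        lam = 0.3 * lmax
        fit = enet_fit(X, y, alpha, lam, tol=1e-9, obj_tol=0.0)
        Xs, _, _ = standardize(X)
        classes = np.unique(y)
        Y = (y[:, None] == classes).astype(float)
        eta = Xs @ fit.coefficients.T + fit.intercepts
        P = np.exp(eta - eta.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        G = -(Xs.T @ (Y - P)) / n + lam * (1 - alpha) * fit.coefficients.T
        B = fit.coefficients.T
        zero = B == 0
        assert np.all(np.abs(G[zero]) <= lam * alpha + 1e-6)
        active = ~zero
        if active.any():
            stat = G[active] + lam * alpha * np.sign(B[active])
            assert np.max(np.abs(stat)) < 1e-6

    def test_objective_monotone_in_iteration_budget(self):
        X, y = make_multinomial_problem(seed=5)
        Xs, _, _ = standardize(X)
        vals = []
        for iters in (1, 2, 3, 5, 8, 13, 21):
            fit = enet_fit(X, y, 0.5, 0.05, max_iter=iters, obj_tol=0.0)
            vals.append(enet_objective(Xs, y, fit.coefficients, fit.intercepts, 0.5, 0.05))
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_warm_start_matches_cold_start_objective(self):
        X, y = make_multinomial_problem(seed=6)
        Xs, _, _ = standardize(X)
        lmax = lambda_max(X, y, 1.0)
        lams = [lmax * 0.5, lmax * 0.2]
        warm = enet_path(X, y, 1.0, lams, tol=1e-8, obj_tol=0.0)[-1]
        cold = enet_fit(X, y, 1.0, lams[-1], tol=1e-8, obj_tol=0.0)
        ow = enet_objective(Xs, y, warm.coefficients, warm.intercepts, 1.0, lams[-1])
        oc = enet_objective(Xs, y, cold.coefficients, cold.intercepts, 1.0, lams[-1])
        assert abs(ow - oc) < 1e-6

    def test_mask_size_nonincreasing_in_lambda_on_coarse_grid(self):
        X, y = make_multinomial_problem(seed=7, n=150, p=25)
        lmax = lambda_max(X, y, 1.0)
        sizes = [
            enet_fit(X, y, 1.0, lam).active_channels.size
            for lam in np.geomspace(lmax, 1e-2 * lmax, 6)
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_ridge_fit_satisfies_sum_to_zero_symmetry(self):
        X, y = make_multinomial_problem(seed=8)
        fit = enet_fit(X, y, 0.0, 0.05, tol=1e-10, obj_tol=0.0, max_iter=50000)
        assert fit.symmetry_gap() < 1e-6

    def test_invalid_hyperparameters_rejected(self):
        X, y = make_multinomial_problem(n=20, p=3)
        with pytest.raises(ValueError):
            enet_fit(X, y, 1.5, 0.1)
        with pytest.raises(ValueError):
            enet_fit(X, y, 0.5, -0.1)


class TestEnetSelect:
    def test_planted_support_recovered(self):
        gen = np.random.default_rng(9)
        n, p, n_inf = 200, 30, 10
        y = np.repeat(np.arange(4), n // 4)
        X = gen.normal(size=(n, p))
        shifts = gen.normal(scale=3.0, size=(4, n_inf))
        X[:, :n_inf] += shifts[y]
        mask, fit = enet_select(
            X, y.astype(str), alpha_grid=(1.0,), n_lambdas=15,
            cv_folds=5, cv_repeats=1, seed=0,
        )
        assert set(range(n_inf)) <= set(mask.indices)
        false_pos = set(mask.indices) - set(range(n_inf))
        assert len(false_pos) <= 5

    def test_lambda_max_only_path_is_an_error(self):
        X, y = make_multinomial_problem(seed=10, n=60, p=10)
        lmax = lambda_max(X, y, 1.0)
        with pytest.raises(ValueError, match="no features survived"):
            enet_select(X, y, alpha_grid=(1.0,), lambda_path=[lmax * 1.01],
                        cv_folds=5, cv_repeats=1, seed=0)

    def test_deterministic_given_seed(self):
        X, y = make_multinomial_problem(seed=11, n=80, p=12)
        kwargs = dict(alpha_grid=(0.5,), n_lambdas=10, cv_folds=4,
                      cv_repeats=1, seed=3)
        m1, _ = enet_select(X, y, **kwargs)
        m2, _ = enet_select(X, y, **kwargs)
        np.testing.assert_array_equal(m1.indices, m2.indices)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        with pytest.raises(ValueError, match="2 classes"):
            enet_select(X, np.zeros(20, dtype=int), cv_folds=5, cv_repeats=1)
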