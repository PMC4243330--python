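import numpy as np
import pytest
from scipy.optimize import minimize


from snpsel.svr import (
    CVResult,
    KernelSpec,
    SVRHyper,
    default_grids,
    fit_svr,
    grid_search,
    kernel_matrix,
    repeated_cv_correlation,
    select_best_group,
)


class TestKernels:
    def test_linear_is_inner_product(self):
        X = np.array([[1.0, 2.0], [0.0, 1.0]])
        K = kernel_matrix(X, X, KernelSpec("linear"))
        np.testing.assert_allclose(K, X @ X.T)

    def test_rbf_closed_form(self):
        X = np.array([[0.0]])
        Z = np.array([[1.0]])
        K = kernel_matrix(X, Z, KernelSpec("rbf", gamma=1.0))
        assert K[0, 0] == pytest.approx(np.exp(-1.0))

    def test_puk_is_one_at_zero_distance(self):
        x = np.array([[0.3, -1.2, 4.0]])
        for omega, sigma in [(0.5, 0.25), (1.0, 1.0), (16.0, 8.0)]:
            K = kernel_matrix(x, x, KernelSpec("puk", omega=omega, sigma=sigma))
            assert K[0, 0] == pytest.approx(1.0)

    def test_puk_omega_one_closed_form(self):
        # omega=1, sigma=1, distance 0.5: K = 1/(1 + (2*0.5*1)^2) = 0.5
        K = kernel_matrix(np.array([[0.0]]), np.array([[0.5]]),
                          KernelSpec("puk", omega=1.0, sigma=1.0))
        assert K[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        for spec in [KernelSpec("rbf", gamma=0.5),
                     KernelSpec("puk", omega=2.0, sigma=1.5)]:
            K = kernel_matrix(X, X, spec)
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            assert np.all(K > 0) and np.all(K <= 1 + 1e-12)

    def test_puk_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 5, 40)[:, None]
        K = kernel_matrix(np.zeros((1, 1)), d, KernelSpec("puk", omega=2.0, sigma=1.0))
        assert np.all(np.diff(K[0]) < 0)

    @pytest.mark.parametrize("omega", [0.5, 1.0, 4.0, 16.0])
    @pytest.mark.parametrize("sigma", [0.5, 2.0])
    def test_puk_gram_matrix_is_positive_semidefinite(self, omega, sigma):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        K = kernel_matrix(X, X, KernelSpec("puk", omega=omega, sigma=sigma))
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_puk_mimics_rbf_at_matched_parameters(self):
        # large omega turns the Pearson VII shape Gaussian:
        # K -> exp(-4 ln2 d^2 / sigma^2), i.e. gamma = 4 ln2 / sigma^2
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        gamma = 1.0
        sigma = np.sqrt(4 * np.log(2) / gamma)
        K_rbf = kernel_matrix(X, X, KernelSpec("rbf", gamma=gamma))
        K_puk = kernel_matrix(X, X, KernelSpec("puk", omega=50.0, sigma=sigma))
        off = ~np.eye(30, dtype=bool)
        corr = np.corrcoef(K_rbf[off], K_puk[off])[0, 1]
        assert corr > 0.99

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf")
        with pytest.raises(ValueError):
            KernelSpec("puk", omega=1.0)
        with pytest.raises(ValueError):
            KernelSpec("sigmoid")
        with pytest.raises(ValueError):
            kernel_matrix(np.array([[np.nan]]), np.array([[1.0]]), KernelSpec("linear"))


def _qp_dual_predictions(X, y, hyper, X_new):
    """Brute-force reference: solve the epsilon-SVR dual with SLSQP."""
    n = len(y)
    K = kernel_matrix(X, X, hyper.kernel)
    C, eps = hyper.C, hyper.epsilon

    def objective(z):
        a, a_star = z[:n], z[n:]
        beta = a - a_star
        return 0.5 * beta @ K @ beta + eps * z.sum() - y @ beta

    def jac(z):
        a, a_star = z[:n], z[n:]
        beta = a - a_star
        Kb = K @ beta
        return np.concatenate([Kb + eps - y, -Kb + eps + y])

    cons = [{"type": "eq",
             "fun": lambda z: z[:n].sum() - z[n:].sum(),
             "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}]
    res = minimize(objective, np.zeros(2 * n), jac=jac, bounds=[(0, C)] * 2 * n,
                   constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success
    beta = res.x[:n] - res.x[n:]
    # intercept from a free support vector (0 < alpha < C)
    b_vals = []
    for i in range(n):
        if 1e-6 < res.x[i] < C - 1e-6:
            b_vals.append(y[i] - eps - K[i] @ beta)
        elif 1e-6 < res.x[n + i] < C - 1e-6:
            b_vals.append(y[i] + eps - K[i] @ beta)
    b = float(np.mean(b_vals))
    return kernel_matrix(X_new, X, hyper.kernel) @ beta + b


class TestFitSVR:
    def test_realizable_line_stays_inside_tube(self):
        x = np.linspace(0, 1, 25)[:, None]
        y = 2 * x.ravel() + 1
        hyper = SVRHyper(C=1e3, epsilon=0.01, kernel=KernelSpec("linear"))
        model = fit_svr(x, y, hyper)
        resid = np.abs(model.predict(x) - y)
        assert np.all(resid <= 0.01 + 1e-6)

    def test_constant_target_gives_zero_duals(self):
        x = np.linspace(0, 1, 10)[:, None]
        y = np.full(10, 3.7)
        model = fit_svr(x, y, SVRHyper(C=10.0, epsilon=0.1,
                                       kernel=KernelSpec("rbf", gamma=1.0)))
        np.testing.assert_allclose(model.predict(x), 3.7, atol=0.1 + 1e-8)
        np.testing.assert_allclose(model.dual_coef, 0.0, atol=1e-8)

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=30)
        hyper = SVRHyper(C=5.0, epsilon=0.05, kernel=KernelSpec("rbf", gamma=0.7))
        model = fit_svr(X, y, hyper, tol=1e-8)
        assert np.all(np.abs(model.dual_coef) <= hyper.C + 1e-8)
        assert model.dual_coef.sum() == pytest.approx(0.0, abs=1e-6)
        # strictly inside the tube (KKT: margin up to solver tolerance)
        inside = np.abs(model.predict(X) - y) < hyper.epsilon - 1e-5
        np.testing.assert_allclose(model.dual_coef[inside], 0.0, atol=1e-8)

    @pytest.mark.parametrize("family,kwargs", [
        ("rbf", {"gamma": 0.5}),
        ("puk", {"omega": 1.0, "sigma": 2.0}),
        ("linear", {}),
    ])
    def test_matches_generic_qp_oracle(self, family, kwargs):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] ** 2 - X[:, 1] + 0.2 * rng.normal(size=20)
        hyper = SVRHyper(C=2.0, epsilon=0.1, kernel=KernelSpec(family, **kwargs))
        X_new = rng.normal(size=(8, 2))
        expected = _qp_dual_predictions(X, y, hyper, X_new)
        got = fit_svr(X, y, hyper, tol=1e-8).predict(X_new)
        np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_svr(np.array([[1.0]]), np.array([1.0]),
                    SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("linear")))


class TestRepeatedCV:
    def test_strong_signal_reaches_high_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        hyper = SVRHyper(C=100.0, epsilon=0.01, kernel=KernelSpec("linear"))
        res = repeated_cv_correlation(X, y, hyper, k=5, r=3, seed=0)
        assert res.mean >= 0.99

    def test_independent_target_has_near_zero_correlation(self):
        # permutation-style null at n=250: the CV correlation averages ~0
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(250, 5)).astype(float)
        hyper = SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("rbf", gamma=0.1))
        means = []
        for draw in range(5):
            y = np.random.default_rng(100 + draw).normal(size=250)
            means.append(repeated_cv_correlation(X, y, hyper, k=10, r=2, seed=1).mean)
        assert abs(np.mean(means)) < 0.15
        assert max(np.abs(means)) < 0.4

    def test_fixed_seed_reproduces_result(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + rng.normal(size=40)
        hyper = SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("linear"))
        a = repeated_cv_correlation(X, y, hyper, k=4, r=3, seed=42)
        b = repeated_cv_correlation(X, y, hyper, k=4, r=3, seed=42)
        assert a.correlations == b.correlations
        assert a.mean == b.mean and a.sd == b.sd

    def test_mean_and_sd_recomputable_from_store(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + 0.5 * rng.normal(size=40)
        res = repeated_cv_correlation(
            X, y, SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("linear")),
            k=4, r=5, seed=2)
        assert res.mean == pytest.approx(np.mean(res.correlations))
        assert res.sd == pytest.approx(np.std(res.correlations, ddof=1))

    def test_per_fold_mode_runs(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        y = X[:, 0]
        res = repeated_cv_correlation(
            X, y, SVRHyper(C=10.0, epsilon=0.01, kernel=KernelSpec("linear")),
            k=4, r=2, seed=3, mode="per_fold")
        assert res.mode == "per_fold" and len(res.correlations) == 2

    def test_degenerate_predictions_flagged_as_zero(self):
        # constant target: every fold predicts the same constant
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 1))
        y = np.full(30, 2.0)
        res = repeated_cv_correlation(
            X, y, SVRHyper(C=0.1, epsilon=1.0, kernel=KernelSpec("linear")),
            k=3, r=2, seed=4)
        assert res.correlations == [0.0, 0.0]
        assert res.degenerate_repeats == [0, 1]


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 2))
        y = X[:, 0]
        hyper = SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("linear"))
        best, res, table = grid_search(X, y, [hyper], k=3, r=2, seed=0)
        assert best is hyper and len(table) == 1

    def test_known_optimum_is_found(self):
        # linear target: a sane linear configuration must beat a kernel with
        # absurdly narrow bandwidth (test points land outside every bump)
        rng = np.random.default_rng(13)
        X = rng.normal(size=(60, 2))
        y = X @ np.array([1.0, -2.0])
        good = SVRHyper(C=100.0, epsilon=0.01, kernel=KernelSpec("linear"))
        bad = SVRHyper(C=100.0, epsilon=0.01, kernel=KernelSpec("rbf", gamma=1e4))
        best, _, _ = grid_search(X, y, [bad, good], k=5, r=2, seed=0)
        assert best is good

    def test_exact_ties_break_by_grid_order(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 2))
        y = X[:, 0]
        h = SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("linear"))
        twin = SVRHyper(C=1.0, epsilon=0.1, kernel=KernelSpec("linear"))
        best, _, _ = grid_search(X, y, [h, twin], k=3, r=2, seed=0)
        assert best is h

    def test_default_grids_scale_with_dimension(self):
        g1 = default_grids("puk", y_sd=1.0, preset="coarse", n_features=1)
        g100 = default_grids("puk", y_sd=1.0, preset="coarse", n_features=100)
        assert max(h.kernel.sigma for h in g100) == pytest.approx(
            10 * max(h.kernel.sigma for h in g1))
        lin = default_grids("linear", y_sd=2.0, preset="full")
        assert all(h.kernel.family == "linear" for h in lin)
        assert {h.epsilon for h in lin} == {0.002, 0.02, 0.2, 2.0}


def _series_with_sizes(sizes):
    ids = [f"SNP{i}" for i in range(max(sizes))]
    members = [ids[:s] for s in sizes]
    thresholds = tuple(0.1 * (i + 1) for i in range(len(sizes)))
    from snpsel.ranking import GroupSeries
    return GroupSeries(thresholds, members, use_adjusted=False)


def _cv(mean, sd=0.0):
    return CVResult([mean], mean, sd, 10, 1, 0)


class TestSelectBestGroup:
    def test_smallest_among_equal_means(self):
        groups = _series_with_sizes([2, 4, 40])
        idx = select_best_group(groups, [_cv(0.5), _cv(0.7), _cv(0.7)],
                                tie_tolerance=0.0)
        assert idx == 1

    def test_single_group(self):
        groups = _series_with_sizes([3])
        assert select_best_group(groups, [_cv(0.4)]) == 0

    def test_tolerance_prefers_fewer_snps(self):
        groups = _series_with_sizes([3, 10])
        idx = select_best_group(groups, [_cv(0.695), _cv(0.700)],
                                tie_tolerance=0.01)
        assert idx == 0

    def test_all_empty_rejected(self):
        groups = _series_with_sizes([0, 0])
        with pytest.raises(ValueError):
            select_best_group(groups, [_cv(0.0), _cv(0.0)])
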