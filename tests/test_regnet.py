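"""Collinearity diagnostics and the coordinate-descent elastic net."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexpov import (compare_supports, cross_validate, enet_objective, fit_enet,
                    lambda_path, standardize, vif)
from hexpov.regnet import DesignMatrix, kkt_residual


def make_design(n=50, p=8, sparsity=3, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    sparsity = min(sparsity, p)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:sparsity] = rng.uniform(1, 2, sparsity) * rng.choice([-1, 1], sparsity)
    y = X @ beta + noise * rng.normal(size=n)
    return standardize(X, y), beta


class TestStandardize:
    def test_hand_example(self):
        D = standardize(np.array([[1.0], [2.0], [3.0]]), np.zeros(3))
        assert D.X[:, 0] == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        D1 = standardize(X, rng.normal(size=40))
        D2 = standardize(D1.X, D1.y)
        assert np.allclose(D1.X, D2.X, atol=1e-12)

    def test_constant_column_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            D = standardize(X, np.arange(10.0), ["C", "T"])
        assert D.column_names == ["T"] and D.dropped_columns == ["C"]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            standardize(np.ones((1, 2)), np.ones(1))


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        out = vif(X)
        assert out["vif"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_perfect_collinearity_unbounded(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=30)
        X = np.column_stack([x1, 2 * x1, rng.normal(size=30)])
        out = vif(X, ["X1", "X2", "X3"])
        assert np.isinf(out.loc[out["column"] == "X1", "vif"].iloc[0])

    def test_closed_form_r09(self):
        """Exact correlation 0.9 between two columns: VIF = 1/(1-0.81)."""
        rng = np.random.default_rng(5)
        n = 200
        A = rng.normal(size=(n, 3))
        A -= A.mean(axis=0)
        # QR of a centered matrix: columns stay mean-zero and orthonormal,
        # so mixing gives an exact sample correlation of 0.9
        q, _ = np.linalg.qr(A)
        x1 = q[:, 0]
        x2 = 0.9 * q[:, 0] + np.sqrt(1 - 0.81) * q[:, 1]
        X = np.column_stack([x1, x2, q[:, 2]])
        out = vif(X)
        assert out["vif"].to_numpy()[:2] == pytest.approx([1 / 0.19] * 2, rel=1e-9)
        assert out["vif"].iloc[2] == pytest.approx(1.0, rel=1e-9)
        # independent OLS oracle
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        Xc = sm.add_constant(X)
        oracle = [variance_inflation_factor(Xc, j + 1) for j in range(3)]
        assert out["vif"].to_numpy() == pytest.approx(oracle, rel=1e-8)

    def test_rank_deficient_shape_rejected(self):
        with pytest.raises(ValueError, match=r"\(3, 4\)"):
            vif(np.ones((3, 4)) + np.random.default_rng(0).normal(size=(3, 4)))

    def test_tolerance_vif_reciprocal_property(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 6))
        X[:, 3] = X[:, 0] + 0.5 * rng.normal(size=60)  # some collinearity
        out = vif(X)
        finite = out[np.isfinite(out["vif"])]
        assert (finite["tolerance"] * finite["vif"]).to_numpy() == pytest.approx(
            np.ones(len(finite)), abs=1e-10)
        assert (out["vif"] >= 1 - 1e-12).all()
        assert out["tolerance"].between(0, 1).all()


class TestObjective:
    def test_null_model_half_variance(self):
        D, _ = make_design(seed=3)
        assert enet_objective(0.0, np.zeros(D.p), D, 1.0, 0.5) == pytest.approx(
            0.5 * np.mean(D.y ** 2))

    def test_no_penalty(self):
        D, _ = make_design(seed=4)
        beta = np.full(D.p, 0.1)
        r = D.y - D.X @ beta
        assert enet_objective(0.0, beta, D, 0.0, 1.0) == pytest.approx(
            0.5 * np.mean(r ** 2))

    def test_l1_penalty_arithmetic(self):
        D, _ = make_design(n=10, p=2, seed=5)
        beta = np.array([1.0, -1.0])
        with_pen = enet_objective(0.0, beta, D, 2.0, 1.0)
        without = enet_objective(0.0, beta, D, 0.0, 1.0)
        assert with_pen - without == pytest.approx(4.0)


class TestFitEnet:
    def test_lambda_zero_equals_ols(self):
        D, _ = make_design(seed=7)
        sol = fit_enet(D, 0.0, 0.5)
        ols, *_ = np.linalg.lstsq(D.X, D.y, rcond=None)
        assert sol.beta == pytest.approx(ols, abs=1e-6)

    def test_orthonormal_lasso_soft_threshold(self):
        rng = np.random.default_rng(11)
        n, p = 64, 5
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)
        q, _ = np.linalg.qr(A)       # zero-mean orthonormal columns
        X = q * np.sqrt(n)           # unit n-denominator sd, X'X/n = I
        assert np.allclose(X.T @ X / n, np.eye(p), atol=1e-10)
        y = rng.normal(size=n)
        D = DesignMatrix(X=X, y=y - y.mean(), column_names=[f"X{j}" for j in range(p)],
                         x_mean=np.zeros(p), x_sd=np.ones(p), y_mean=float(y.mean()))
        lam = 0.05
        sol = fit_enet(D, lam, 1.0)
        rho = X.T @ D.y / n
        expect = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0)
        assert sol.beta == pytest.approx(expect, abs=1e-8)

    def test_ridge_closed_form(self):
        D, _ = make_design(seed=13)
        lam = 0.3
        sol = fit_enet(D, lam, 0.0)
        n = D.n
        closed = np.linalg.solve(D.X.T @ D.X / n + lam * np.eye(D.p),
                                 D.X.T @ D.y / n)
        assert sol.beta == pytest.approx(closed, abs=1e-8)

    def test_objective_monotone_per_sweep(self):
        D, _ = make_design(n=80, p=10, seed=17)
        sol = fit_enet(D, 0.05, 0.5, record_objective=True)
        h = sol.objective_history
        assert np.all(np.diff(h) <= 1e-12)

    def test_kkt_certificate_along_path(self):
        D, _ = make_design(n=60, p=10, seed=19)
        for alpha in (0.0, 0.5, 1.0):
            lams = lambda_path(D, alpha, n_lambda=30)
            beta = np.zeros(D.p)
            for lam in lams:
                sol = fit_enet(D, lam, alpha, warm_start=beta)
                beta = sol.beta
                assert kkt_residual(D, beta, lam, alpha) < 1e-6

    def test_invalid_args(self):
        D, _ = make_design()
        with pytest.raises(ValueError):
            fit_enet(D, -1.0, 0.5)
        with pytest.raises(ValueError):
            fit_enet(D, 1.0, 1.5)


class TestLambdaPath:
    def test_all_zero_at_lambda_max(self):
        D, _ = make_design(seed=23)
        lams = lambda_path(D, 1.0)
        sol = fit_enet(D, lams[0], 1.0)
        assert np.all(sol.beta == 0)

    def test_active_just_below_lambda_max(self):
        D, _ = make_design(seed=23)
        lams = lambda_path(D, 1.0)
        sol = fit_enet(D, lams[0] * 0.95, 1.0)
        assert np.any(sol.beta != 0)

    def test_strictly_decreasing_with_length(self):
        D, _ = make_design(seed=29)
        lams = lambda_path(D, 0.5, n_lambda=57, ratio=1e-3)
        assert lams.size == 57
        assert np.all(np.diff(lams) < 0)

    def test_zero_y_variance_error(self):
        D, _ = make_design(seed=31)
        D.y = np.zeros(D.n)
        with pytest.raises(ValueError):
            lambda_path(D, 0.5)


class TestCrossValidate:
    def test_seed_reproducibility(self):
        D, _ = make_design(n=60, p=6, seed=37)
        a = cross_validate(D, alpha=0.5, k=5, seed=9, n_lambda=30)
        b = cross_validate(D, alpha=0.5, k=5, seed=9, n_lambda=30)
        assert a.lambda_min == b.lambda_min
        assert np.array_equal(a.cv_mse_mean, b.cv_mse_mean)

    def test_pure_noise_selects_near_empty_support(self):
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 20))
            y = rng.normal(size=100)  # independent of X
            D = standardize(X, y)
            fit = cross_validate(D, alpha=0.5, k=10, seed=seed, n_lambda=50)
            if len(fit.selected_support) <= 2:
                hits += 1
        assert hits > n_rep / 2

    def test_noiseless_recovery_contains_true_support(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(200, 20))
        beta = np.zeros(20)
        beta[[2, 7, 15]] = [1.5, -2.0, 1.0]
        y = X @ beta
        names = [f"X{j+1}" for j in range(20)]
        D = standardize(X, y, names)
        fit = cross_validate(D, alpha=0.5, k=10, seed=1, n_lambda=50)
        assert {"X3", "X8", "X16"} <= set(fit.selected_support)

    def test_matches_reference_implementation_at_fixed_lambda(self):
        """Same objective parametrization as the reference solver."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        D, _ = make_design(n=80, p=10, noise=0.3, seed=43)
        for lam, alpha in [(0.05, 0.5), (0.2, 1.0), (0.1, 0.2)]:
            mine = fit_enet(D, lam, alpha, tol=1e-12)
            ref = sklearn.ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                                     tol=1e-12, max_iter=500_000)
            ref.fit(D.X, D.y)
            assert mine.beta == pytest.approx(ref.coef_, abs=1e-6)

    def test_k_larger_than_rows_rejected(self):
        D, _ = make_design(n=8, p=3)
        with pytest.raises(ValueError):
            cross_validate(D, k=9)


class TestCompareSupports:
    def test_identical_fits(self):
        D, _ = make_design(n=60, p=6, seed=47)
        fit = cross_validate(D, alpha=0.5, k=5, seed=2, n_lambda=30)
        rep = compare_supports(fit, fit)
        assert rep.symmetric_difference == []
        assert rep.jaccard == 1.0
        assert all(d == 0.0 for d in rep.coefficient_deltas.values())

    def test_set_arithmetic(self):
        D, _ = make_design(n=60, p=6, seed=53)
        a = cross_validate(D, alpha=0.5, k=5, seed=2, n_lambda=30)
        b = cross_validate(D, alpha=0.5, k=5, seed=2, n_lambda=30)
        a.coefficients = np.array([1.0, 0, 0.5, 0, 0, 0])
        b.coefficients = np.array([1.0, 0, 0, 0, 0.7, 0])
        a.column_names = b.column_names = ["X2", "X3", "X5", "X7", "X10", "X11"]
        rep = compare_supports(a, b)
        assert rep.intersection == ["X2"]
        assert sorted(rep.symmetric_difference) == ["X10", "X5"]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 500), st.floats(0.0, 1.0), st.floats(0.001, 1.0))
def test_kkt_property_random_instances(seed, alpha, lam):
    D, _ = make_design(n=40, p=6, noise=0.5, seed=seed)
    sol = fit_enet(D, lam, alpha)
    assert kkt_residual(D, sol.beta, lam, alpha) < 1e-6
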