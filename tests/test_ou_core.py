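"""Reparameterizations, design matrices, covariances, limits, generative checks."""

import numpy as np
import pytest
from scipy.integrate import dblquad, quad
from scipy.stats import multivariate_normal

from phylou import ou_core, simulate
from phylou.ou_core import (
    ModelSpec,
    OUParams,
    adaptive_lag_matrix,
    alpha_to_half_life,
    half_life_to_alpha,
    model_covariance,
    model_mean,
    ou_covariance,
    regime_weights,
    rho_correction,
    sigma2_from_stationary,
    stationary_variance,
)
from phylou.phylo import paint_regimes, parse_newick, shared_times


class TestReparameterizations:
    def test_known_values(self):
        assert abs(half_life_to_alpha(np.log(2)) - 1.0) < 1e-12
        assert abs(half_life_to_alpha(0.25) - 2.772589) < 1e-6
        assert abs(stationary_variance(2.0, 1.0) - 1.0) < 1e-12
        # the validation design: t_half = 0.1, v = 0.01
        a = half_life_to_alpha(0.1)
        assert abs(sigma2_from_stationary(0.01, a) - 0.13863) < 1e-5

    def test_round_trips(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.01, 10, 100)
        assert np.allclose(alpha_to_half_life(half_life_to_alpha(x)), x,
                           rtol=1e-14)
        a = rng.uniform(0.1, 20, 100)
        v = stationary_variance(x, a)
        assert np.allclose(sigma2_from_stationary(v, a), x, rtol=1e-14)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_positivity_enforced(self, bad):
        with pytest.raises(ValueError):
            half_life_to_alpha(bad)
        with pytest.raises(ValueError):
            stationary_variance(bad, 1.0)
        with pytest.raises(ValueError):
            OUParams(half_life=bad, stationary_var=0.01)

    def test_ouparams_consistency(self):
        p = OUParams(half_life=0.1, stationary_var=0.01)
        assert abs(p.alpha - np.log(2) / 0.1) < 1e-12
        assert abs(p.sigma2_y - 2 * p.alpha * 0.01) < 1e-12
        q = OUParams.from_alpha(p.alpha, p.sigma2_y)
        assert abs(q.half_life - 0.1) < 1e-12


class TestRho:
    def test_known_value(self):
        assert abs(rho_correction(np.log(2) / 0.25, 1.0) - 0.66187) < 1e-5

    def test_limits(self):
        assert rho_correction(1.0, 0.0) == 0.0
        assert rho_correction(1e6, 1.0) > 1 - 1e-5
        x = 1e-7
        assert abs(rho_correction(x, 1.0) - x / 2) < 1e-10  # Taylor limit

    def test_monotone_increasing(self):
        xs = np.logspace(-4, 3, 1000)
        vals = rho_correction(1.0, xs)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals >= 0) & (vals <= 1))


class TestRegimeWeights:
    def test_single_regime_column_of_ones(self, tree3):
        p = paint_regimes(tree3, {int(tree3.root): "R0"}, ("R0",))
        for alpha in (1e-3, 1.0, 50.0):
            W = regime_weights(alpha, p, shared_times(tree3).tip_depths)
            assert np.allclose(W, 1.0)

    def test_three_tip_hand_value(self, tree3):
        p = paint_regimes(tree3, {int(tree3.root): "R0", 1: "R1"}, ("R0", "R1"))
        W = regime_weights(np.log(2), p, shared_times(tree3).tip_depths)
        lab = dict(zip(tree3.tip_labels, W))
        assert np.allclose(lab["A"], [0.5, 0.5], atol=1e-12)
        assert np.allclose(lab["C"], [1.0, 0.0], atol=1e-12)

    def test_fast_adaptation_limit(self, tree3):
        # alpha = 25 / tree height: terminal regime dominates
        p = paint_regimes(tree3, {int(tree3.root): "R0", 1: "R1"}, ("R0", "R1"))
        W = regime_weights(25.0 / 2.0 * 2, p, shared_times(tree3).tip_depths)
        lab = dict(zip(tree3.tip_labels, W))
        assert lab["A"][1] > 1 - 1e-8

    @pytest.mark.parametrize("alpha", np.logspace(-3, 3, 7))
    def test_rows_sum_to_one(self, alpha):
        sim = simulate.simulate_dataset(
            simulate.SimConfig(n_tips=30, n_regimes=3, theta=(0, 0, 0), seed=2)
        )
        W = regime_weights(alpha, sim.painting, sim.tree.tip_depths)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((W >= 0) & (W <= 1 + 1e-12))


class TestOUCovariance:
    def test_no_shared_history_zero_covariance(self, tree3):
        st = shared_times(tree3)
        V = ou_covariance(1.0, 0.5, st)
        i = {lab: k for k, lab in enumerate(st.tip_labels)}
        assert abs(V[i["A"], i["C"]]) < 1e-12

    def test_diagonal_value(self):
        # unit-height ultrametric: V_ii = v (1 - e^(-2 alpha))
        t = parse_newick("(A:1,B:1);")
        st = shared_times(t)
        V = ou_covariance(half_life_to_alpha(0.1), 0.01, st)
        assert abs(V[0, 0] - 0.0099999) < 1e-6

    def test_bm_limit_elementwise(self):
        tree = simulate.simulate_tree(10, seed=4)
        st = shared_times(tree)
        alpha = 1e-6
        sigma2_y = 0.1
        v = sigma2_y / (2 * alpha)
        V = ou_covariance(alpha, v, st)
        assert np.allclose(V, sigma2_y * st.s, rtol=1e-3)

    def test_bm_limit_loglik(self):
        """OU log-likelihood at alpha -> 0 equals the BM log-likelihood."""
        tree = simulate.simulate_tree(10, seed=4)
        st = shared_times(tree)
        rng = np.random.default_rng(1)
        sigma2_y = 0.3
        y = simulate.simulate_bm(tree, sigma2_y, seed=9)
        # match the tiny factorization jitter on both sides (the default
        # 1e-10 v jitter grows without bound as alpha -> 0 since v = s2/2a)
        Vbm = sigma2_y * st.s + 1e-12 * np.eye(10)
        Vou = ou_covariance(1e-6, sigma2_y / 2e-6, st, jitter=1e-12)
        ll_bm = multivariate_normal.logpdf(y, mean=np.zeros(10), cov=Vbm)
        ll_ou = multivariate_normal.logpdf(y, mean=np.zeros(10), cov=Vou)
        assert abs(ll_bm - ll_ou) < 1e-3

    def test_symmetric_pd_random(self):
        rng = np.random.default_rng(3)
        for seed in range(8):
            tree = simulate.simulate_tree(15, seed=200 + seed)
            st = shared_times(tree)
            alpha = float(rng.uniform(0.05, 30))
            v = float(rng.uniform(1e-3, 2.0))
            V = ou_covariance(alpha, v, st)
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V)[0] > 0


class TestAdaptiveLag:
    @pytest.mark.parametrize("alpha,s", [
        (2.3, 0.4), (0.5, 0.9), (8.0, 0.1), (1.0, 1.0), (0.05, 0.5),
    ])
    def test_matches_quadrature(self, alpha, s):
        """Closed form equals direct numerical integration of the history terms."""
        T = 1.0
        I, _ = dblquad(
            lambda u, w: np.exp(-alpha * (2 * T - u - w)) * min(u, w, s),
            0, T, 0, T, epsabs=1e-13,
        )
        J, _ = quad(
            lambda u: np.exp(-alpha * (T - u)) * min(u, s),
            0, T, points=[s], epsabs=1e-14,
        )
        rho = rho_correction(alpha, T)
        M_num = alpha**2 * I - 2 * rho * alpha * J + rho**2 * s
        M = adaptive_lag_matrix(alpha, np.array(s), T)
        assert abs(M - M_num) < 1e-9 + 1e-6 * abs(M_num)

    def test_series_region_matches_quadrature(self):
        T, s, alpha = 1.0, 0.6, 0.004
        I, _ = dblquad(
            lambda u, w: np.exp(-alpha * (2 * T - u - w)) * min(u, w, s),
            0, T, 0, T, epsabs=1e-15,
        )
        J, _ = quad(lambda u: np.exp(-alpha * (T - u)) * min(u, s), 0, T,
                    points=[s], epsabs=1e-16)
        rho = rho_correction(alpha, T)
        M_num = alpha**2 * I - 2 * rho * alpha * J + rho**2 * s
        M = adaptive_lag_matrix(alpha, np.array(s), T)
        assert abs(M - M_num) / abs(M_num) < 1e-4

    def test_limits(self):
        s = np.array([0.3, 0.7, 1.0])
        assert np.all(np.abs(adaptive_lag_matrix(500.0, s, 1.0)) < 1e-2)
        assert np.all(np.abs(adaptive_lag_matrix(1e-5, s, 1.0)) < 1e-8)


def _painted_tree3():
    t = parse_newick("((A:1,B:1):1,C:2);")
    p = paint_regimes(t, {int(t.root): "R0", 1: "R1"}, ("R0", "R1"))
    return t, p, shared_times(t)


class TestModelMeanCovariance:
    def test_single_regime_constant_mean(self, tree3):
        p = paint_regimes(tree3, {int(tree3.root): "R0"}, ("R0",))
        st = shared_times(tree3)
        W = regime_weights(1.0, p, st.tip_depths)
        spec = ModelSpec(model_kind="multi_optima", n_regimes=1)
        mu = model_mean(spec, {"theta": [2.5]}, W)
        assert np.allclose(mu, 2.5)

    def test_centering_convention(self):
        t, p, st = _painted_tree3()
        W = regime_weights(1.0, p, st.tip_depths)
        spec = ModelSpec(model_kind="multi_optima_direct", n_regimes=2,
                         n_predictors=1)
        theta = np.array([1.0, 2.0])
        X0 = np.zeros((3, 1))  # at the predictor mean
        mu = model_mean(spec, {"theta": theta, "beta": np.array([0.7])}, W, X0,
                        p.tip_regimes)
        assert np.allclose(mu, W @ theta)

    def test_adaptive_fast_limit_equals_direct_effect(self):
        t, p, st = _painted_tree3()
        alpha = 1e7
        W = regime_weights(alpha, p, st.tip_depths)
        X = np.array([[0.3], [-0.2], [0.6]])
        theta = np.array([1.0, 2.0])
        beta = np.array([0.7])
        ad = ModelSpec(model_kind="multi_optima_adaptive", n_regimes=2,
                       n_predictors=1)
        de = ModelSpec(model_kind="multi_optima_direct", n_regimes=2,
                       n_predictors=1)
        mu_ad = model_mean(ad, {"theta": theta, "beta": beta, "alpha": alpha},
                           W, X, p.tip_regimes, tip_depth=2.0)
        mu_de = model_mean(de, {"theta": theta, "beta": beta}, W, X,
                           p.tip_regimes)
        assert np.allclose(mu_ad, mu_de, atol=1e-6)
        # covariance collapses to the OU part (predictor lag vanishes)
        V_ad = model_covariance(
            ad, {"alpha": alpha, "v": 0.01, "beta": beta, "sigma2_x": 1.0},
            st, p.tip_regimes,
        )
        V_de = model_covariance(de, {"alpha": alpha, "v": 0.01}, st,
                                p.tip_regimes)
        assert np.allclose(V_ad, V_de, atol=1e-4)

    def test_multi_optima_covariance_is_ou(self):
        t, p, st = _painted_tree3()
        spec = ModelSpec(model_kind="multi_optima", n_regimes=2)
        V = model_covariance(spec, {"alpha": 1.3, "v": 0.2}, st)
        assert np.array_equal(V, ou_covariance(1.3, 0.2, st, check=False))

    def test_response_se_inflates_diagonal(self):
        t, p, st = _painted_tree3()
        spec = ModelSpec(model_kind="multi_optima", n_regimes=2,
                         me_response=True)
        params = {"alpha": 1.3, "v": 0.2}
        V0 = model_covariance(spec, params, st)
        V1 = model_covariance(spec, params, st, se_y=np.full(3, 0.01))
        assert np.allclose(np.diag(V1) - np.diag(V0), 1e-4)
        assert np.allclose(V1 - np.diag(np.diag(V1)),
                           V0 - np.diag(np.diag(V0)))

    def test_adaptive_requires_ultrametric(self):
        t = parse_newick("((A:1,B:1):1,C:1.5);")
        st = shared_times(t)
        spec = ModelSpec(model_kind="adaptive", n_regimes=1, n_predictors=1)
        with pytest.raises(ValueError, match="ultrametric"):
            model_covariance(
                spec,
                {"alpha": 1.0, "v": 0.1, "beta": np.array([0.5]),
                 "sigma2_x": 1.0},
                st,
            )


class TestGenerativeConsistency:
    """Simulator moments match the assembled model mean and covariance."""

    @pytest.mark.parametrize("kind,beta", [
        ("multi_optima", None),
        ("multi_optima_direct", np.array([0.6])),
        ("multi_optima_adaptive", np.array([0.6])),
    ])
    def test_moments_4tip(self, kind, beta):
        t = parse_newick("((A:0.6,B:0.6):0.4,(C:0.8,D:0.8):0.2);")
        p = paint_regimes(t, {int(t.root): "R0", 1: "R1"}, ("R0", "R1"))
        st = shared_times(t)
        n_pred = 0 if beta is None else 1
        spec = ModelSpec(model_kind=kind, n_regimes=2, n_predictors=n_pred)
        params = {"alpha": half_life_to_alpha(0.2), "v": 0.05,
                  "theta": np.array([1.0, 2.0]), "sigma2_x": 1.0}
        X = None
        if beta is not None:
            params["beta"] = beta
            X = np.array([[0.4], [-0.1], [0.8], [-0.5]])
        n = 30000
        Y = simulate.simulate_response(t, p, spec, params, X=X, seed=11,
                                       size=n)
        W = regime_weights(params["alpha"], p, st.tip_depths)
        Xc = None if X is None else X - X.mean(axis=0)
        mu = model_mean(spec, params, W, Xc, p.tip_regimes, tip_depth=1.0)
        V = model_covariance(spec, params, st, p.tip_regimes, check=False)
        se_mean = np.sqrt(np.diag(V) / n)
        assert np.all(np.abs(Y.mean(axis=0) - mu) < 3.5 * se_mean)
        C = np.cov(Y, rowvar=False)
        se_cov = np.sqrt(
            (np.outer(np.diag(V), np.diag(V)) + V**2) / n
        )
        assert np.all(np.abs(C - V) < 3.5 * se_cov)

    def test_v_zero_returns_mean_exactly(self, tree3):
        p = paint_regimes(tree3, {int(tree3.root): "R0"}, ("R0",))
        spec = ModelSpec(model_kind="multi_optima", n_regimes=1)
        params = {"alpha": 1.0, "v": 0.0, "theta": np.array([1.5])}
        y = simulate.simulate_response(tree3, p, spec, params, seed=0)
        assert np.allclose(y, 1.5)


class TestAdaptiveSDEOracle:
    def test_covariance_matches_euler_simulation(self):
        """The adaptive-model algebra against Euler-Maruyama SDE paths.

        Simulates the OU response tracking a Brownian predictor along a
        3-tip tree and compares (i) the covariance of the predictor with the
        response and (ii) the covariance of the evolutionary-regression
        residuals with the closed forms.
        """
        alpha, v, s2x, beta, theta = 2.0, 0.05, 1.0, 0.5, 1.0
        sig_y = np.sqrt(2 * alpha * v)
        rng = np.random.default_rng(8)
        n, dt = 20000, 1e-3
        steps = int(round(1.0 / dt))
        split = int(round(0.4 / dt))

        def evolve(x, y, nsteps):
            for _ in range(nsteps):
                x = x + np.sqrt(s2x * dt) * rng.standard_normal(n)
                y = y + (-alpha * (y - theta - beta * x) * dt
                         + sig_y * np.sqrt(dt) * rng.standard_normal(n))
            return x, y

        x0 = np.zeros(n)
        y0 = np.full(n, theta)  # root starts at its optimum
        xab, yab = evolve(x0.copy(), y0.copy(), split)
        xa, ya = evolve(xab.copy(), yab.copy(), steps - split)
        xb, yb = evolve(xab.copy(), yab.copy(), steps - split)
        xc, yc = evolve(x0.copy(), y0.copy(), steps)

        T = 1.0
        rho = rho_correction(alpha, T)
        # tip-level slope: Cov(y, x)/Var(x) = beta * rho
        slope = np.cov(ya, xa)[0, 1] / np.var(xa)
        assert abs(slope - beta * rho) < 0.02
        # residual covariance between the two sister tips (s = 0.4)
        ra, rb = ya - rho * beta * xa, yb - rho * beta * xb
        M = adaptive_lag_matrix(alpha, np.array(0.4), T)
        vou = v * np.exp(-alpha * 2 * (T - 0.4)) * (1 - np.exp(-2 * alpha * 0.4))
        expected = vou + beta**2 * s2x * M
        got = np.cov(ra, rb)[0, 1]
        se = np.sqrt((np.var(ra) * np.var(rb) + got**2) / n)
        assert abs(got - expected) < 4 * se + 0.02 * abs(expected)
        # unrelated tips (s = 0): residuals uncorrelated
        rc = yc - rho * beta * xc
        assert abs(np.cov(ra, rc)[0, 1]) < 4 * np.sqrt(
            np.var(ra) * np.var(rc) / n
        )


class TestOLSLimit:
    def test_map_slope_matches_ols_at_fast_adaptation(self):
        """alpha = 50/tree height: the evolutionary slope converges on OLS."""
        from phylou import inference

        tree = simulate.simulate_tree(25, seed=77)
        p = paint_regimes(tree, {int(tree.root): "R0"}, ("R0",))
        spec = ModelSpec(model_kind="adaptive", n_regimes=1, n_predictors=1)
        params = {"alpha": 50.0, "v": 1e-4, "theta": np.array([1.0]),
                  "beta": np.array([0.5]), "sigma2_x": 1.0}
        X = simulate.simulate_bm(tree, 1.0, seed=5)
        Y = simulate.simulate_response(tree, p, spec, params, X=X, seed=6)
        Xc = X - X.mean()
        ols = float(np.sum(Xc * (Y - Y.mean())) / np.sum(Xc * Xc))
        priors = inference.default_priors(Y, X, spec)
        target = inference.build_log_posterior(spec, priors, tree, p, Y, X)
        m = inference.map_estimate(target, seed=0, n_starts=2)
        evol_slope = float(m["beta"][0]) * rho_correction(m["alpha"], 1.0)
        assert abs(evol_slope - ols) / abs(ols) < 0.02
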