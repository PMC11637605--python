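"""PSIS-LOO, WAIC, bridge sampling, and predictive checks."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from phylou import evaluate, inference, ou_core, simulate
from phylou.evaluate import (
    PointwiseLogLik,
    band_coverage,
    bayes_factor,
    bridge_log_marginal,
    compare_elpd,
    gpd_fit,
    pointwise_loglik,
    posterior_predictive,
    prior_predictive,
    psis_loo,
    waic,
)
from phylou.phylo import paint_regimes, parse_newick


# -- conjugate normal-normal toy: y_i ~ N(mu, s2), mu ~ N(m0, t02) ----------


def _conjugate(seed, n=10, s2=1.0, m0=0.0, t02=4.0, mu_true=1.0, S=4000):
    rng = np.random.default_rng(seed)
    y = rng.normal(mu_true, np.sqrt(s2), size=n)
    post_var = 1 / (n / s2 + 1 / t02)
    post_mean = post_var * (y.sum() / s2 + m0 / t02)
    mus = rng.normal(post_mean, np.sqrt(post_var), size=S)
    pll = norm.logpdf(y[None, :], mus[:, None], np.sqrt(s2))
    return y, mus, pll, (post_mean, post_var)


class _ConjTarget:
    def __init__(self, y, s2=1.0, m0=0.0, t02=4.0):
        self.y, self.s2, self.m0, self.t02 = y, s2, m0, t02
        self.dim = 1

    def logp(self, z):
        mu = z[0]
        return float(
            norm.logpdf(mu, self.m0, np.sqrt(self.t02))
            + norm.logpdf(self.y, mu, np.sqrt(self.s2)).sum()
        )


class TestPointwiseLogLik:
    def test_diagonal_modes_agree(self):
        """On a star tree V is diagonal: conditional == marginal."""
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        p = paint_regimes(tree, {int(tree.root): "R0"}, ("R0",))
        Y = np.array([0.1, 0.5, -0.3, 0.9])
        spec = ou_core.ModelSpec(model_kind="multi_optima", n_regimes=1)
        pri = inference.default_priors(Y)
        t = inference.build_log_posterior(spec, pri, tree, p, Y)
        z = t.unconstrain(dict(t_half=0.3, v=0.2, theta=np.array([0.2])))
        cond = t.pointwise_loglik(z, mode="conditional")
        marg = t.pointwise_loglik(z, mode="marginal")
        assert np.allclose(cond, marg, atol=1e-10)

    def test_conditional_matches_schur_oracle(self, tree3):
        p = paint_regimes(tree3, {int(tree3.root): "R0"}, ("R0",))
        Y = np.array([1.2, 0.7, 2.0])
        spec = ou_core.ModelSpec(model_kind="multi_optima", n_regimes=1)
        pri = inference.default_priors(Y)
        t = inference.build_log_posterior(spec, pri, tree3, p, Y)
        z = t.unconstrain(dict(t_half=0.5, v=0.4, theta=np.array([1.0])))
        c = t.constrain(z)
        asm = t._assemble(c)
        mu, V = asm["mu"], asm["V"]
        got = t.pointwise_loglik(z, mode="conditional")
        for i in range(3):
            o = [j for j in range(3) if j != i]
            Voo = V[np.ix_(o, o)]
            cov = V[i, o] @ np.linalg.solve(Voo, Y[o] - mu[o])
            cvar = V[i, i] - V[i, o] @ np.linalg.solve(Voo, V[o, i])
            want = norm.logpdf(Y[i], mu[i] + cov, np.sqrt(cvar))
            assert abs(got[i] - want) < 1e-9

    def test_marginal_sum_differs_from_joint_when_correlated(self, tree3):
        p = paint_regimes(tree3, {int(tree3.root): "R0"}, ("R0",))
        Y = np.array([1.2, 0.7, 2.0])
        spec = ou_core.ModelSpec(model_kind="multi_optima", n_regimes=1)
        pri = inference.default_priors(Y)
        t = inference.build_log_posterior(spec, pri, tree3, p, Y)
        z = t.unconstrain(dict(t_half=0.5, v=0.4, theta=np.array([1.0])))
        c = t.constrain(z)
        joint = t._assemble(c)["loglik"]
        marg_sum = t.pointwise_loglik(z, mode="marginal").sum()
        assert abs(joint - marg_sum) > 1e-3

    def test_stored_matrix_finite(self, small_fit):
        draws, target, _ = small_fit
        pll = pointwise_loglik(draws)
        assert pll.values.shape[1] == 20
        assert np.all(np.isfinite(pll.values))


class TestPsisLoo:
    def test_constant_loglik_degenerate_tail(self):
        mat = np.tile(np.linspace(-1, -2, 8), (300, 1))
        loo = psis_loo(mat)
        assert loo.elpd_loo == pytest.approx(mat[0].sum())
        assert np.all(loo.pareto_k <= 0)

    def test_matches_exact_refit_loo(self):
        """PSIS-LOO within 2 SE of exact leave-one-out refits (conjugate)."""
        y, mus, pll, _ = _conjugate(seed=0)
        n, s2, m0, t02 = len(y), 1.0, 0.0, 4.0
        exact = 0.0
        for i in range(n):
            yi = np.delete(y, i)
            pv = 1 / ((n - 1) / s2 + 1 / t02)
            pm = pv * (yi.sum() / s2 + m0 / t02)
            exact += norm.logpdf(y[i], pm, np.sqrt(pv + s2))
        loo = psis_loo(pll)
        assert abs(loo.elpd_loo - exact) < 2 * loo.se_elpd
        assert np.all(loo.pareto_k < 0.7)
        assert loo.p_loo > 0

    def test_gpd_shape_recovery(self):
        rng = np.random.default_rng(1)
        k_true = 0.5
        u = rng.uniform(size=4000)
        x = ((1 - u) ** (-k_true) - 1) / k_true
        k_hat, _ = gpd_fit(x)
        assert abs(k_hat - k_true) < 0.15

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100 draws"):
            psis_loo(np.zeros((50, 5)))

    def test_contaminated_observation_flagged(self):
        """An outlier at 10 residual SDs gets the largest Pareto k."""
        hits = 0
        for seed in range(20):
            y, mus, pll, _ = _conjugate(seed=100 + seed, n=12, S=2000)
            y2 = y.copy()
            y2[0] = y2[0] + 10.0  # 10 residual SDs (s2 = 1)
            pll2 = norm.logpdf(y2[None, :], mus[:, None], 1.0)
            loo = psis_loo(pll2)
            if loo.pareto_k[0] >= loo.pareto_k.max() - 1e-12:
                hits += 1
        assert hits >= 18

    def test_cross_check_against_arviz(self):
        """Independent PSIS implementation (arviz) agrees on the weights."""
        import arviz as az

        _, _, pll, _ = _conjugate(seed=5)
        loo = psis_loo(pll)
        lw, k_az = az.psislw(-pll.T)
        elpd_az = float(
            np.sum(
                np.log(np.sum(np.exp(lw.T + pll - pll.max(0)), axis=0))
                + pll.max(0)
            )
        )
        assert abs(loo.elpd_loo - elpd_az) < 0.05
        assert np.allclose(loo.pareto_k, np.asarray(k_az), atol=0.1)


class TestWaic:
    def test_zero_variance_pll(self):
        mat = np.tile(np.linspace(-1, -2, 6), (200, 1))
        e, p, se = waic(mat)
        assert p == pytest.approx(0.0)
        assert e == pytest.approx(mat[0].sum())

    def test_agrees_with_psis_loo(self):
        _, _, pll, _ = _conjugate(seed=2)
        loo = psis_loo(pll)
        e, p, se = waic(pll)
        assert abs(e - loo.elpd_loo) < 2 * max(se, loo.se_elpd)

    def test_noise_parameter_increases_p_waic(self):
        """Adding a pure-noise parameter inflates the effective count."""
        wins = 0
        for seed in range(5):
            y, mus, pll, _ = _conjugate(seed=10 + seed)
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 0.3, size=(mus.size, 1))
            pll_noisy = norm.logpdf(y[None, :], mus[:, None] + noise, 1.0)
            _, p0, _ = waic(pll)
            _, p1, _ = waic(pll_noisy)
            wins += p1 > p0
        assert wins == 5


class TestCompare:
    def test_self_comparison_zero(self):
        _, _, pll, _ = _conjugate(seed=3)
        loo = psis_loo(pll)
        comp = compare_elpd({"a": loo, "b": loo})
        assert comp.diff[("a", "b")] == 0.0
        assert comp.diff_se[("a", "b")] == 0.0
        assert not comp.substantial("a", "b")

    def test_permutation_equivariance(self):
        _, _, pll1, _ = _conjugate(seed=4)
        _, mus, _, _ = _conjugate(seed=5)
        y, _, pll2, _ = _conjugate(seed=4, mu_true=0.0)
        l1, l2 = psis_loo(pll1), psis_loo(pll2)
        c_ab = compare_elpd({"a": l1, "b": l2})
        c_ba = compare_elpd({"b": l2, "a": l1})
        assert c_ab.diff[("a", "b")] == -c_ba.diff[("b", "a")]
        assert c_ab.diff_se[("a", "b")] == c_ba.diff_se[("b", "a")]

    def test_true_model_wins_mostly(self):
        """The generating model attains >= its rival's elpd in >=90% of reps."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(400 + seed)
            n, s2 = 15, 1.0
            y = rng.normal(0.0, 1.0, size=n)
            # model A: correct prior centered at 0; model B: badly offset
            def posterior_pll(m0, t02):
                pv = 1 / (n / s2 + 1 / t02)
                pm = pv * (y.sum() / s2 + m0 / t02)
                mus = rng.normal(pm, np.sqrt(pv), size=2000)
                return norm.logpdf(y[None, :], mus[:, None], 1.0)

            la = psis_loo(posterior_pll(0.0, 1.0))
            lb = psis_loo(posterior_pll(8.0, 0.05))
            if la.elpd_loo >= lb.elpd_loo:
                wins += 1
        assert wins >= 18

    def test_mismatched_observations_rejected(self):
        _, _, pll, _ = _conjugate(seed=6)
        _, _, pll2, _ = _conjugate(seed=6, n=12)
        with pytest.raises(ValueError, match="different data|observation"):
            compare_elpd({"a": psis_loo(pll), "b": psis_loo(pll2)})


class TestBridgeSampling:
    def test_matches_conjugate_closed_form(self):
        y, mus, _, _ = _conjugate(seed=0)
        n, s2, m0, t02 = len(y), 1.0, 0.0, 4.0
        closed = multivariate_normal.logpdf(
            y, mean=np.full(n, m0), cov=s2 * np.eye(n) + t02 * np.ones((n, n))
        )
        lm, se = bridge_log_marginal(mus[:, None], _ConjTarget(y), seed=1)
        assert abs(lm - closed) < 0.02

    def test_doubling_draws_invariance(self):
        y, mus, _, post = _conjugate(seed=7, S=8000)
        lm1, se1 = bridge_log_marginal(mus[:4000, None], _ConjTarget(y), seed=2)
        lm2, se2 = bridge_log_marginal(mus[:, None], _ConjTarget(y), seed=2)
        assert abs(lm1 - lm2) < 3 * (se1 + se2) + 1e-3

    def test_self_bayes_factor_near_one(self):
        y, _, _, (pm, pv) = _conjugate(seed=8)
        rng1 = np.random.default_rng(21)
        rng2 = np.random.default_rng(22)
        t = _ConjTarget(y)
        lma, _ = bridge_log_marginal(
            rng1.normal(pm, np.sqrt(pv), size=(4000, 1)), t, seed=3
        )
        lmb, _ = bridge_log_marginal(
            rng2.normal(pm, np.sqrt(pv), size=(4000, 1)), t, seed=4
        )
        bf = bayes_factor(lma, lmb)
        assert 0.9 < bf < 1.1
        assert bayes_factor(lma, lmb) * bayes_factor(lmb, lma) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_too_few_draws(self):
        y, mus, _, _ = _conjugate(seed=9, S=500)
        with pytest.raises(ValueError, match="1000 draws"):
            bridge_log_marginal(mus[:, None], _ConjTarget(y))


class TestPredictiveChecks:
    def test_point_mass_priors_fix_parameters(self, small_dataset):
        sim = small_dataset
        spec = ou_core.ModelSpec(
            model_kind="multi_optima_direct", n_regimes=2, n_predictors=1
        )
        pri = inference.PriorSet(
            t_half=inference.LogNormalPrior(np.log(0.2), 1e-10),
            v=inference.UniformPrior(0.0499999, 0.05),
            theta=inference.NormalPrior(1.0, 1e-12),
            beta=inference.NormalPrior(0.4, 1e-12),
        )
        res = prior_predictive(
            spec, pri, sim.tree, sim.painting, X=sim.X_obs, n_draws=20, seed=0
        )
        th = np.array([p["theta"] for p in res["params"]])
        assert np.ptp(th) < 1e-6
        assert res["replicates"].shape == (20, 20)

    def test_prior_predictive_band_covers_data(self, small_dataset):
        """Default priors generate bands spanning most of the observed data."""
        sim = small_dataset
        spec = ou_core.ModelSpec(
            model_kind="multi_optima_direct", n_regimes=2, n_predictors=1
        )
        pri = inference.default_priors(sim.Y_obs, sim.X_obs, spec)
        res = prior_predictive(
            spec, pri, sim.tree, sim.painting, X=sim.X_obs, n_draws=300, seed=1
        )
        assert band_coverage(sim.Y_obs, res["replicates"], level=0.99) >= 0.8

    def test_posterior_predictive_covers_observed_mean(self, small_fit):
        draws, target, sim = small_fit
        res = posterior_predictive(draws, n_draws=300, seed=2)
        means = res["summaries"]["mean"]
        lo, hi = np.percentile(means, [2.5, 97.5])
        assert lo <= sim.Y_obs.mean() <= hi

    def test_overlay_plot_written(self, small_fit, tmp_path):
        draws, target, sim = small_fit
        res = posterior_predictive(draws, n_draws=50, seed=3)
        out = evaluate.plot_predictive_overlay(
            sim.Y_obs, res["replicates"], tmp_path / "ppc.png"
        )
        assert (tmp_path / "ppc.png").exists()
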