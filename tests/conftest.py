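import warnings

import numpy as np
import pytest

from phylou import inference, ou_core, simulate

warnings.filterwarnings("ignore", category=FutureWarning)


class FunnelTarget:
    """Neal's funnel: v ~ N(0, 3), x_i ~ N(0, e^(v/2)).

    The centered form defeats a single HMC step size; the non-centered
    reparameterization (x = e^(v/2) z) is a product of standard normals.
    """

    def __init__(self, centered, n=5):
        self.centered = centered
        self.dim = n + 1

    def logp(self, z):
        v, x = z[0], z[1:]
        lp = -0.5 * (v / 3.0) ** 2 - np.log(3.0)
        if self.centered:
            s = np.exp(v / 2.0)
            lp += float(np.sum(-0.5 * (x / s) ** 2 - np.log(s)))
        else:
            lp += float(np.sum(-0.5 * x**2))
        return lp

    def value_and_grad(self, z):
        v, x = z[0], z[1:]
        g = np.zeros_like(z)
        g[0] = -v / 9.0
        if self.centered:
            s2 = np.exp(v)
            g[1:] = -x / s2
            g[0] += float(np.sum(0.5 * x**2 / s2 - 0.5))
        else:
            g[1:] = -x
        return self.logp(z), g


@pytest.fixture(scope="session")
def tree3():
    from phylou.phylo import parse_newick

    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-tip, 2-regime direct-effect dataset with known truth."""
    cfg = simulate.SimConfig(
        n_tips=20,
        n_regimes=2,
        model_kind="multi_optima_direct",
        theta=(0.5, 1.5),
        beta=(0.4,),
        half_life=0.15,
        stationary_var=0.02,
        me_response_sd=0.01,
        seed=42,
    )
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A converged NUTS fit of the matching model on ``small_dataset``."""
    sim = small_dataset
    spec = ou_core.ModelSpec(
        model_kind="multi_optima_direct", n_regimes=2, n_predictors=1,
        me_response=True,
    )
    priors = inference.default_priors(sim.Y_obs, sim.X_obs, spec)
    target = inference.build_log_posterior(
        spec, priors, sim.tree, sim.painting, sim.Y_obs, sim.X_obs,
        se_y=sim.Y_se,
    )
    draws = inference.sample_posterior(
        target, chains=2, iterations=700, warmup=400, seed=7
    )
    return draws, target, sim
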