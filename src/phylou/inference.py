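"""Priors, log-posterior construction, NUTS sampling, and diagnostics.

Priors are built from five guidelines, each in the parameter's biologically
meaningful units on the unit-height tree:

* half-life: log-normal whose lower 10% tail sits below 10% of tree height
  and whose upper 10% tail starts at tree height — spanning nearly
  instantaneous adaptation through Brownian-motion-like inertia;
* stationary variance: exponential with mean equal to the sample variance of
  the response (uniform[0, 4 var] and half-Cauchy available);
* optima: normal centered at the mean response;
* optimal / direct-effect slopes: normal centered on the OLS slope;
* hierarchical scales: exponential; intercept/slope correlation: LKJ(4).

The posterior is sampled with a self-contained No-U-Turn sampler (dual
averaging step-size adaptation, diagonal mass-matrix estimation during
warmup, divergence reporting).  Gradients of the log posterior are analytic
for every parameter except the two covariance-shape parameters (log
half-life, log stationary variance), which use central finite differences;
the accept/reject step always uses the exact log posterior, so sampling is
exact regardless.

Positive parameters are sampled on the log scale and the intercept/slope
correlation through atanh, with Jacobians included.  Centered and
non-centered parameterizations of the regime hierarchy are both available;
the non-centered form usually mixes better when regimes are few.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import ndtri

from . import ou_core
from .ou_core import ModelSpec
from .phylo import Phylogeny, RegimePainting, SharedTimes, shared_times

__all__ = [
    "LogNormalPrior",
    "NormalPrior",
    "ExponentialPrior",
    "HalfCauchyPrior",
    "UniformPrior",
    "LKJPrior",
    "PriorSet",
    "default_priors",
    "build_log_posterior",
    "LogPosterior",
    "sample_posterior",
    "PosteriorDraws",
    "Diagnostics",
    "diagnostics",
    "summary_table",
    "map_estimate",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# prior distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalPrior:
    log_median: float
    log_sd: float

    def __post_init__(self):
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    def logpdf(self, x):
        x = np.maximum(x, 1e-300)
        z = (np.log(x) - self.log_median) / self.log_sd
        return -np.log(x) - np.log(self.log_sd) - 0.5 * (_LOG2PI + z * z)

    def sample(self, rng, size=None):
        return np.exp(rng.normal(self.log_median, self.log_sd, size=size))


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def logpdf(self, x):
        z = (np.asarray(x) - self.mean) / self.sd
        return -np.log(self.sd) - 0.5 * (_LOG2PI + z * z)

    def dlogpdf(self, x):
        return -(np.asarray(x) - self.mean) / self.sd**2

    def sample(self, rng, size=None):
        return rng.normal(self.mean, self.sd, size=size)


@dataclass(frozen=True)
class ExponentialPrior:
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def logpdf(self, x):
        x = np.asarray(x)
        return np.where(x > 0, np.log(self.rate) - self.rate * x, -np.inf)

    def dlogpdf(self, x):
        return -self.rate * np.ones_like(np.asarray(x, dtype=float))

    def sample(self, rng, size=None):
        return rng.exponential(1.0 / self.rate, size=size)


@dataclass(frozen=True)
class HalfCauchyPrior:
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def logpdf(self, x):
        x = np.asarray(x)
        return np.where(
            x > 0,
            np.log(2.0 / (np.pi * self.scale)) - np.log1p((x / self.scale) ** 2),
            -np.inf,
        )

    def dlogpdf(self, x):
        x = np.asarray(x)
        return -2.0 * x / (self.scale**2 + x * x)

    def sample(self, rng, size=None):
        return np.abs(self.scale * rng.standard_cauchy(size=size))


@dataclass(frozen=True)
class UniformPrior:
    lo: float
    hi: float

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("hi must exceed lo")

    def logpdf(self, x):
        x = np.asarray(x)
        return np.where(
            (x >= self.lo) & (x <= self.hi), -np.log(self.hi - self.lo), -np.inf
        )

    def dlogpdf(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def sample(self, rng, size=None):
        return rng.uniform(self.lo, self.hi, size=size)


@dataclass(frozen=True)
class LKJPrior:
    """LKJ correlation prior; for a 2x2 matrix the density is (1-r^2)^(eta-1)."""

    eta: float = 4.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")

    def logpdf_r(self, r):
        return (self.eta - 1.0) * np.log1p(-np.asarray(r) ** 2)

    def sample_r(self, rng, size=None):
        # for 2x2, r ~ 2*Beta(eta, eta) - 1
        return 2.0 * rng.beta(self.eta, self.eta, size=size) - 1.0


@dataclass(frozen=True)
class PriorSet:
    """Prior settings for every block a model may use (unused blocks ignored)."""

    t_half: LogNormalPrior
    v: ExponentialPrior | HalfCauchyPrior | UniformPrior
    theta: NormalPrior
    beta: NormalPrior | None = None
    theta_bar: NormalPrior | None = None
    beta_bar: NormalPrior | None = None
    sigma_theta: ExponentialPrior = ExponentialPrior(1.0)
    sigma_beta: ExponentialPrior = ExponentialPrior(1.0)
    rho: LKJPrior = LKJPrior(4.0)
    sigma2_x: HalfCauchyPrior = HalfCauchyPrior(1.0)
    x0: NormalPrior = NormalPrior(0.0, 2.0)
    latent_x_sd_factor: float = 10.0  # latent-X prior sd = factor * reported SE

    def sample_params(self, spec: ModelSpec, rng: np.random.Generator) -> dict:
        """One parameter draw from the priors (for prior-predictive checks)."""
        t_half = float(self.t_half.sample(rng))
        out = {
            "t_half": t_half,
            "alpha": float(ou_core.half_life_to_alpha(t_half)),
            "v": float(self.v.sample(rng)),
        }
        K = spec.n_regimes
        n_slopes = K if spec.varying_slopes else spec.n_predictors
        if spec.multilevel == "none":
            out["theta"] = np.atleast_1d(self.theta.sample(rng, size=K))
            if spec.has_slopes:
                b = np.atleast_1d(self.beta.sample(rng, size=n_slopes))
                out["beta"] = b[:, None] if spec.varying_slopes else b
        elif spec.multilevel == "varying_intercepts":
            tb = float(self.theta_bar.sample(rng))
            st = float(self.sigma_theta.sample(rng))
            out["theta"] = rng.normal(tb, st, size=K)
            if spec.has_slopes:
                b = np.atleast_1d(self.beta.sample(rng, size=n_slopes))
                out["beta"] = b[:, None] if spec.varying_slopes else b
        else:  # varying_effects
            tb = float(self.theta_bar.sample(rng))
            bb = float(self.beta_bar.sample(rng))
            st = float(self.sigma_theta.sample(rng))
            sb = float(self.sigma_beta.sample(rng))
            r = float(self.rho.sample_r(rng))
            L = np.array([[1.0, 0.0], [r, np.sqrt(1.0 - r * r)]])
            z = rng.standard_normal((K, 2))
            tbk = np.array([tb, bb]) + (z @ L.T) * np.array([st, sb])
            out["theta"] = tbk[:, 0]
            out["beta"] = tbk[:, 1][:, None]
        if spec.is_adaptive:
            out["sigma2_x"] = float(self.sigma2_x.sample(rng))
        return out


def default_priors(
    response_values: np.ndarray,
    predictor_values: np.ndarray | None = None,
    spec: ModelSpec | None = None,
    t_half_q10: float = 0.1,
    t_half_q90: float = 1.0,
    v_prior: str = "exponential",
) -> PriorSet:
    """Construct the default prior set from the data, following the guidelines.

    The half-life log-normal solves the two-quantile problem
    ``P(t_half < t_half_q10) = P(t_half > t_half_q90) = 0.10`` on the
    unit-height tree; the stationary-variance exponential has mean equal to
    the sample variance of Y; optima are centered at the mean of Y; slope
    priors are centered on the pooled OLS slope of Y on (mean-centered) X.
    """
    y = np.asarray(response_values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 species to build default priors")
    z90 = float(ndtri(0.9))
    log_median = 0.5 * (np.log(t_half_q10) + np.log(t_half_q90))
    log_sd = (np.log(t_half_q90) - np.log(t_half_q10)) / (2.0 * z90)
    t_half = LogNormalPrior(log_median, log_sd)

    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise ValueError("response variance is zero; cannot set a variance prior")
    if v_prior == "exponential":
        v = ExponentialPrior(1.0 / var_y)
    elif v_prior == "half_cauchy":
        v = HalfCauchyPrior(var_y)
    elif v_prior == "uniform":
        v = UniformPrior(0.0, 4.0 * var_y)
    else:
        raise ValueError("v_prior must be exponential, half_cauchy or uniform")

    theta = NormalPrior(float(np.mean(y)), 1.0)
    theta_bar = NormalPrior(float(np.mean(y)), 1.0)

    beta = beta_bar = None
    if predictor_values is not None:
        X = np.atleast_2d(np.asarray(predictor_values, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        Xc = X - X.mean(axis=0)
        if np.any(Xc.std(axis=0) == 0):
            raise ValueError(
                "a predictor is constant across species; the OLS-centered "
                "slope prior is undefined — drop it or supply priors manually"
            )
        ols, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(y.size), Xc]), y, rcond=None
        )
        slopes = ols[1:]
        sd = max(1.0, 2.0 * float(np.max(np.abs(slopes))))
        beta = NormalPrior(float(slopes[0]) if slopes.size == 1 else float(
            np.mean(slopes)), sd)
        beta_bar = NormalPrior(beta.mean, 0.25 * sd)

    return PriorSet(
        t_half=t_half, v=v, theta=theta, beta=beta,
        theta_bar=theta_bar, beta_bar=beta_bar,
    )


# ---------------------------------------------------------------------------
# parameter layout and log posterior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Block:
    name: str
    size: int
    offset: int


class LogPosterior:
    """Differentiable unnormalized log posterior over unconstrained parameters.

    Wraps the model likelihood (multivariate normal with mean from
    ``model_mean`` and covariance from ``model_covariance``), the priors, and
    all transform Jacobians.  ``value_and_grad`` supplies analytic gradients
    except for log half-life / log stationary variance (central differences);
    ``logp`` is exact everywhere.
    """

    FD_BLOCKS = ("log_t_half", "log_v")
    _FD_H = 1e-6

    def __init__(
        self,
        spec: ModelSpec,
        priors: PriorSet,
        tree: Phylogeny | None,
        painting: RegimePainting | None,
        Y: np.ndarray | None,
        X: np.ndarray | None = None,
        se_y: np.ndarray | None = None,
        se_x: np.ndarray | None = None,
        estimate_sigma2_x: bool = True,
        sigma2_x_plugin: float | None = None,
    ):
        self.spec = spec
        self.priors = priors
        self.tree = tree
        self.painting = painting
        self.prior_only = Y is None
        self.scale_factor = float(tree.scale_factor) if tree is not None else 1.0

        if spec.has_slopes and priors.beta is None and not self.prior_only:
            raise ValueError("priors.beta is required for models with slopes")

        if not self.prior_only:
            self.Y = np.asarray(Y, dtype=float)
            self.n_obs = self.Y.size
            self.shared = shared_times(tree)
            if spec.is_adaptive and not tree.is_ultrametric():
                raise ValueError("the adaptive model requires an ultrametric tree")
            if spec.is_adaptive and spec.n_predictors != 1:
                raise ValueError(
                    "adaptive-model fitting supports exactly one predictor"
                )
            self.segs = ou_core.segment_arrays(painting)
            self.tip_depths = self.shared.tip_depths
            self.T = float(self.tip_depths.max())
            self.tip_regimes = painting.tip_regimes
            self.se_y = None if se_y is None else np.asarray(se_y, dtype=float)
            if X is not None:
                X = np.atleast_2d(np.asarray(X, dtype=float))
                if X.shape[0] != self.n_obs:
                    X = X.T
                self.x_center = X.mean(axis=0)
                self.Xc = X - self.x_center
                self.X_raw = X
            else:
                self.Xc = self.X_raw = None
                self.x_center = None
            self.se_x = None if se_x is None else np.asarray(se_x, dtype=float)
            self.latent_x = spec.me_predictors and self.se_x is not None
            # X-process likelihood pieces (BM covariance factorizes as sigma2_x * s)
            self.estimate_sigma2_x = bool(
                spec.is_adaptive and estimate_sigma2_x and sigma2_x_plugin is None
            )
            self.sigma2_x_plugin = sigma2_x_plugin
            if spec.is_adaptive:
                S = self.shared.s.copy()
                S[np.diag_indices_from(S)] += 1e-10 * self.T
                self._cho_s = cho_factor(S, lower=True)
                self._logdet_s = 2.0 * np.sum(np.log(np.diag(self._cho_s[0])))
                if sigma2_x_plugin is None and not estimate_sigma2_x:
                    # plug-in defaults to the BM GLS estimate from observed X
                    xr = self.X_raw[:, 0]
                    one = np.ones_like(xr)
                    siv = cho_solve(self._cho_s, np.column_stack([xr, one]))
                    x0 = (one @ siv[:, 0]) / (one @ siv[:, 1])
                    q = (xr - x0) @ cho_solve(self._cho_s, xr - x0)
                    self.sigma2_x_plugin = float(q / max(self.n_obs - 1, 1))
        else:
            self.n_obs = 0
            self.latent_x = False
            self.estimate_sigma2_x = spec.is_adaptive and estimate_sigma2_x
            self.sigma2_x_plugin = sigma2_x_plugin

        self.blocks: list[_Block] = []
        off = 0

        def add(name, size):
            nonlocal off
            self.blocks.append(_Block(name, size, off))
            off += size

        K, p = spec.n_regimes, spec.n_predictors
        add("log_t_half", 1)
        add("log_v", 1)
        ml = spec.multilevel
        nc = spec.parameterization == "non_centered"
        n_slopes = K if spec.varying_slopes else p
        if ml == "none":
            add("theta", K)
            if spec.has_slopes:
                add("beta", n_slopes)
        elif ml == "varying_intercepts":
            add("theta_bar", 1)
            add("log_sigma_theta", 1)
            add("z_theta" if nc else "theta", K)
            if spec.has_slopes:
                add("beta", n_slopes)
        else:  # varying_effects (p == 1)
            add("theta_bar", 1)
            add("beta_bar", 1)
            add("log_sigma_theta", 1)
            add("log_sigma_beta", 1)
            add("atanh_rho", 1)
            if nc:
                add("z_theta", K)
                add("z_beta", K)
            else:
                add("theta", K)
                add("beta", K)
        if self.estimate_sigma2_x:
            add("x0", 1)
            add("log_sigma2_x", 1)
        if not self.prior_only and self.latent_x:
            add("x_true", self.n_obs)  # latent true predictor values (column 0)
        self.dim = off
        self._index = {b.name: b for b in self.blocks}

    # -- layout helpers ----------------------------------------------------

    def has_block(self, name: str) -> bool:
        return name in self._index

    def get(self, z: np.ndarray, name: str) -> np.ndarray:
        b = self._index[name]
        return z[b.offset : b.offset + b.size]

    def param_names(self) -> list:
        """Flat constrained-parameter names, one per reported series."""
        K, p = self.spec.n_regimes, self.spec.n_predictors
        names = ["t_half", "v"]
        names += [f"theta[{k}]" for k in range(K)]
        if self.spec.has_slopes:
            if self.spec.varying_slopes:
                names += [f"beta[{k}]" for k in range(K)]
            else:
                names += [f"beta[{j}]" for j in range(p)]
        if self.spec.multilevel != "none":
            names += ["theta_bar", "sigma_theta"]
        if self.spec.multilevel == "varying_effects":
            names += ["beta_bar", "sigma_beta", "rho"]
        if self.estimate_sigma2_x:
            names += ["x0", "sigma2_x"]
        return names

    # -- transforms --------------------------------------------------------

    def constrain(self, z: np.ndarray) -> dict:
        """Constrained parameter dict (plus derived alpha/sigma2_y) from z."""
        spec = self.spec
        K, p = spec.n_regimes, spec.n_predictors
        c: dict = {}
        c["t_half"] = float(np.exp(min(self.get(z, "log_t_half")[0], 700.0)))
        c["v"] = float(np.exp(min(self.get(z, "log_v")[0], 700.0)))
        c["alpha"] = float(np.log(2.0) / c["t_half"])
        c["sigma2_y"] = 2.0 * c["alpha"] * c["v"]
        ml = spec.multilevel
        if ml != "none":
            c["theta_bar"] = float(self.get(z, "theta_bar")[0])
            c["sigma_theta"] = float(np.exp(self.get(z, "log_sigma_theta")[0]))
        if ml == "varying_effects":
            c["beta_bar"] = float(self.get(z, "beta_bar")[0])
            c["sigma_beta"] = float(np.exp(self.get(z, "log_sigma_beta")[0]))
            c["rho"] = float(np.tanh(self.get(z, "atanh_rho")[0]))
        if self.has_block("theta"):
            c["theta"] = self.get(z, "theta").copy()
        elif ml == "varying_intercepts":
            c["theta"] = c["theta_bar"] + c["sigma_theta"] * self.get(z, "z_theta")
        else:  # VE non-centered
            zt = self.get(z, "z_theta")
            zb = self.get(z, "z_beta")
            r = c["rho"]
            c["theta"] = c["theta_bar"] + c["sigma_theta"] * zt
            c["beta"] = (
                c["beta_bar"]
                + c["sigma_beta"] * (r * zt + np.sqrt(1.0 - r * r) * zb)
            )[:, None]
        if spec.has_slopes and "beta" not in c:
            b = self.get(z, "beta").copy()
            c["beta"] = b[:, None] if spec.varying_slopes else b
        if spec.varying_slopes and c["beta"].ndim == 1:
            c["beta"] = c["beta"][:, None]
        if self.estimate_sigma2_x:
            c["x0"] = float(self.get(z, "x0")[0])
            c["sigma2_x"] = float(np.exp(self.get(z, "log_sigma2_x")[0]))
        elif spec.is_adaptive:
            c["sigma2_x"] = float(self.sigma2_x_plugin)
        if self.has_block("x_true"):
            c["x_true"] = self.get(z, "x_true").copy()
        return c

    def unconstrain(self, params: dict) -> np.ndarray:
        """Inverse of :meth:`constrain` (centered blocks read directly)."""
        z = np.zeros(self.dim)
        z[self._index["log_t_half"].offset] = np.log(params["t_half"])
        z[self._index["log_v"].offset] = np.log(params["v"])
        spec = self.spec

        def put(name, val):
            b = self._index[name]
            z[b.offset : b.offset + b.size] = val

        ml = spec.multilevel
        theta = np.atleast_1d(np.asarray(params.get("theta", []), dtype=float))
        beta = np.asarray(params.get("beta", []), dtype=float)
        if beta.ndim == 2:
            beta = beta[:, 0]
        if ml != "none":
            put("theta_bar", params.get("theta_bar", theta.mean() if theta.size else 0.0))
            put("log_sigma_theta", np.log(params.get("sigma_theta", 0.5)))
        if ml == "varying_effects":
            put("beta_bar", params.get("beta_bar", beta.mean() if beta.size else 0.0))
            put("log_sigma_beta", np.log(params.get("sigma_beta", 0.5)))
            put("atanh_rho", np.arctanh(np.clip(params.get("rho", 0.0), -0.999, 0.999)))
        if self.has_block("theta"):
            put("theta", theta)
        else:
            tb = params.get("theta_bar", theta.mean())
            st = params.get("sigma_theta", 0.5)
            put("z_theta", (theta - tb) / st)
            if ml == "varying_effects":
                bb = params.get("beta_bar", beta.mean())
                sb = params.get("sigma_beta", 0.5)
                r = params.get("rho", 0.0)
                zt = (theta - tb) / st
                put("z_beta", ((beta - bb) / sb - r * zt) / np.sqrt(1 - r * r))
        if self.has_block("beta"):
            put("beta", beta)
        if self.estimate_sigma2_x:
            put("x0", params.get("x0", 0.0))
            put("log_sigma2_x", np.log(params.get("sigma2_x", 1.0)))
        if self.has_block("x_true"):
            put("x_true", params.get("x_true", self.X_raw[:, 0]))
        return z

    # -- likelihood assembly ------------------------------------------------

    def _effective_X(self, c: dict):
        if self.Xc is None:
            return None
        if self.latent_x and "x_true" in c:
            X = self.Xc.copy()
            X[:, 0] = c["x_true"] - self.x_center[0]
            return X
        return self.Xc

    def _assemble(self, c: dict):
        """mu, V cholesky and residual solve for the current parameters.

        Lean inlined equivalent of model_mean/model_covariance (this is the
        sampler's hot path; the public functions carry validation overhead).
        """
        spec = self.spec
        alpha, v = c["alpha"], c["v"]
        n = self.n_obs
        W = ou_core._regime_weights_from_segments(alpha, self.segs, self.tip_depths)
        mu = W @ c["theta"]
        Xeff = None
        B = None
        if spec.has_slopes:
            Xeff = self._effective_X(c)
            beta = c["beta"]
            if beta.ndim == 2:
                B = beta[self.tip_regimes]
            else:
                B = np.broadcast_to(beta, (n, beta.shape[0]))
            term = np.einsum("ij,ij->i", Xeff, B)
            if spec.is_adaptive:
                term = term * ou_core.rho_correction(alpha, self.T)
            mu = mu + term
        V = v * np.exp(-alpha * self.shared.d) * (
            -np.expm1(-2.0 * alpha * self.shared.s)
        )
        if spec.is_adaptive:
            M = ou_core.adaptive_lag_matrix(alpha, self.shared.s, self.T)
            b0 = B[:, 0]
            V += c["sigma2_x"] * np.outer(b0, b0) * M
        diag = V.reshape(-1)[:: n + 1]
        diag += 1e-10 * v
        if self.se_y is not None:
            diag += self.se_y**2
        try:
            cho = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        r = self.Y - mu
        a = cho_solve(cho, r, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        loglik = -0.5 * (n * _LOG2PI + logdet + r @ a)
        return dict(W=W, Xeff=Xeff, mu=mu, V=V, cho=cho, r=r, a=a, loglik=loglik)

    def _x_process_loglik(self, c: dict):
        """BM likelihood of the (latent or observed) predictor values."""
        if not self.estimate_sigma2_x:
            return 0.0, None
        x = c["x_true"] if self.latent_x and "x_true" in c else self.X_raw[:, 0]
        rx = x - c["x0"]
        siv = cho_solve(self._cho_s, rx)
        q = rx @ siv
        s2 = c["sigma2_x"]
        ll = -0.5 * (
            self.n_obs * _LOG2PI + self.n_obs * np.log(s2) + self._logdet_s + q / s2
        )
        return float(ll), dict(siv=siv, q=q, rx=rx)

    def _me_loglik(self, c: dict):
        """Observed predictors given latent true values."""
        if not (self.latent_x and "x_true" in c):
            return 0.0
        se = np.maximum(self.se_x if self.se_x.ndim == 1 else self.se_x[:, 0], 1e-12)
        zx = (self.X_raw[:, 0] - c["x_true"]) / se
        return float(-np.sum(np.log(se)) - 0.5 * np.sum(_LOG2PI + zx * zx))

    def _log_prior_and_jacobian(self, z: np.ndarray, c: dict):
        spec, pr = self.spec, self.priors
        lp = 0.0
        # Jacobians of log transforms: log|dx/dz| = z
        lp += float(self.get(z, "log_t_half")[0]) + float(self.get(z, "log_v")[0])
        lp += float(pr.t_half.logpdf(c["t_half"]))
        lp += float(pr.v.logpdf(c["v"]))
        ml = spec.multilevel
        if ml == "none":
            lp += float(np.sum(pr.theta.logpdf(c["theta"])))
            if spec.has_slopes:
                lp += float(np.sum(pr.beta.logpdf(np.ravel(c["beta"]))))
        elif ml == "varying_intercepts":
            lp += float(pr.theta_bar.logpdf(c["theta_bar"]))
            lp += float(self.get(z, "log_sigma_theta")[0])
            lp += float(pr.sigma_theta.logpdf(c["sigma_theta"]))
            if self.has_block("theta"):
                zk = (c["theta"] - c["theta_bar"]) / c["sigma_theta"]
                lp += float(
                    np.sum(-np.log(c["sigma_theta"]) - 0.5 * (_LOG2PI + zk * zk))
                )
            else:
                zt = self.get(z, "z_theta")
                lp += float(np.sum(-0.5 * (_LOG2PI + zt * zt)))
            if spec.has_slopes:
                lp += float(np.sum(pr.beta.logpdf(np.ravel(c["beta"]))))
        else:  # varying_effects
            lp += float(pr.theta_bar.logpdf(c["theta_bar"]))
            lp += float(pr.beta_bar.logpdf(c["beta_bar"]))
            lp += float(self.get(z, "log_sigma_theta")[0])
            lp += float(self.get(z, "log_sigma_beta")[0])
            lp += float(pr.sigma_theta.logpdf(c["sigma_theta"]))
            lp += float(pr.sigma_beta.logpdf(c["sigma_beta"]))
            r = c["rho"]
            lp += float(pr.rho.logpdf_r(r))
            lp += float(np.log1p(-r * r))  # d tanh jacobian
            if self.has_block("theta"):  # centered bivariate normal per regime
                st, sb = c["sigma_theta"], c["sigma_beta"]
                dt = (c["theta"] - c["theta_bar"]) / st
                db = (np.ravel(c["beta"]) - c["beta_bar"]) / sb
                det = 1.0 - r * r
                quad = (dt * dt - 2.0 * r * dt * db + db * db) / det
                lp += float(
                    np.sum(
                        -np.log(st) - np.log(sb) - 0.5 * np.log(det)
                        - _LOG2PI - 0.5 * quad
                    )
                )
            else:
                zt = self.get(z, "z_theta")
                zb = self.get(z, "z_beta")
                lp += float(np.sum(-0.5 * (_LOG2PI + zt * zt)))
                lp += float(np.sum(-0.5 * (_LOG2PI + zb * zb)))
        if self.estimate_sigma2_x:
            lp += float(pr.x0.logpdf(c["x0"]))
            lp += float(self.get(z, "log_sigma2_x")[0])
            lp += float(pr.sigma2_x.logpdf(c["sigma2_x"]))
        if self.has_block("x_true"):
            se = np.maximum(
                self.se_x if self.se_x.ndim == 1 else self.se_x[:, 0], 1e-12
            ) * self.priors.latent_x_sd_factor
            zx = (c["x_true"] - self.X_raw[:, 0]) / se
            lp += float(np.sum(-np.log(se) - 0.5 * (_LOG2PI + zx * zx)))
        return lp

    def logp(self, z: np.ndarray) -> float:
        c = self.constrain(z)
        lp = self._log_prior_and_jacobian(z, c)
        if not np.isfinite(lp):
            return -np.inf
        if self.prior_only:
            return lp
        asm = self._assemble(c)
        if asm is None:
            return -np.inf
        llx, _ = self._x_process_loglik(c)
        return float(lp + asm["loglik"] + llx + self._me_loglik(c))

    # -- gradient ----------------------------------------------------------

    def value_and_grad(self, z: np.ndarray):
        c = self.constrain(z)
        lp = self._log_prior_and_jacobian(z, c)
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.dim)
        g = np.zeros(self.dim)
        spec = self.spec
        f0 = lp

        if not self.prior_only:
            asm = self._assemble(c)
            if asm is None:
                return -np.inf, np.zeros(self.dim)
            llx, _ = self._x_process_loglik(c)
            f0 = lp + asm["loglik"] + llx + self._me_loglik(c)
            a = asm["a"]
            W, Xeff = asm["W"], asm["Xeff"]
            rho_T = (
                ou_core.rho_correction(c["alpha"], self.T) if spec.is_adaptive else 1.0
            )
            # dloglik/dtheta_k = W^T a ; dloglik/dbeta via mean (and V if adaptive)
            g_theta = W.T @ a
            g_beta = None
            if spec.has_slopes:
                B = ou_core._tip_slopes(spec, c["beta"], self.tip_regimes)
                scale = rho_T if spec.is_adaptive else 1.0
                if spec.varying_slopes:
                    g_beta = np.zeros(spec.n_regimes)
                    for k in range(spec.n_regimes):
                        m = self.tip_regimes == k
                        g_beta[k] = scale * (Xeff[m, 0] @ a[m])
                else:
                    g_beta = scale * (Xeff.T @ a)
                if spec.is_adaptive:
                    # covariance path: V += s2x * (B B^T) o M
                    Vinv = cho_solve(asm["cho"], np.eye(self.n_obs))
                    G = 0.5 * (np.outer(a, a) - Vinv)
                    M = ou_core.adaptive_lag_matrix(c["alpha"], self.shared.s, self.T)
                    GMB = (G * M) @ B[:, 0]
                    s2x = c["sigma2_x"]
                    if spec.varying_slopes:
                        for k in range(spec.n_regimes):
                            m = self.tip_regimes == k
                            g_beta[k] += 2.0 * s2x * float(GMB[m].sum())
                    else:
                        g_beta = np.atleast_1d(g_beta)
                        g_beta[0] += 2.0 * s2x * float(GMB.sum())
                    if self.estimate_sigma2_x:
                        Vad = s2x * np.outer(B[:, 0], B[:, 0]) * M
                        g_ls2x_V = float(np.sum(G * Vad))  # d/d log sigma2_x
            # scatter mean-parameter gradients into z-space
            self._scatter_linear_grads(z, c, g, g_theta, g_beta)
            # latent x gradient
            if self.has_block("x_true"):
                b = self._index["x_true"]
                B = (
                    ou_core._tip_slopes(spec, c["beta"], self.tip_regimes)
                    if spec.has_slopes
                    else None
                )
                gx = a * (B[:, 0] * (rho_T if spec.is_adaptive else 1.0))
                if self.estimate_sigma2_x:
                    _, xinfo = self._x_process_loglik(c)
                    gx = gx - xinfo["siv"] / c["sigma2_x"]
                se = np.maximum(
                    self.se_x if self.se_x.ndim == 1 else self.se_x[:, 0], 1e-12
                )
                gx = gx + (self.X_raw[:, 0] - c["x_true"]) / se**2
                sep = se * self.priors.latent_x_sd_factor
                gx = gx - (c["x_true"] - self.X_raw[:, 0]) / sep**2
                g[b.offset : b.offset + b.size] += gx
            if self.estimate_sigma2_x:
                llx, xinfo = self._x_process_loglik(c)
                bx0 = self._index["x0"]
                g[bx0.offset] += float(np.sum(xinfo["siv"])) / c["sigma2_x"]
                g[bx0.offset] += float(self.priors.x0.dlogpdf(c["x0"]))
                bls = self._index["log_sigma2_x"]
                gl = -0.5 * self.n_obs + 0.5 * xinfo["q"] / c["sigma2_x"]
                if spec.is_adaptive and spec.has_slopes:
                    gl += g_ls2x_V
                gl += 1.0 + float(
                    self.priors.sigma2_x.dlogpdf(c["sigma2_x"])
                ) * c["sigma2_x"]
                g[bls.offset] += gl

        # prior (and hierarchy) gradients for the linear blocks
        self._prior_grads(z, c, g)

        # covariance-shape parameters: analytic for non-adaptive models,
        # central finite differences where the adaptive lag terms enter
        if not self.prior_only and not spec.is_adaptive:
            self._alpha_v_grads(z, c, asm, g)
        else:
            for name in self.FD_BLOCKS:
                if not self.has_block(name):
                    continue
                b = self._index[name]
                for i in range(b.size):
                    zp = z.copy()
                    zp[b.offset + i] += self._FD_H
                    zm = z.copy()
                    zm[b.offset + i] -= self._FD_H
                    g[b.offset + i] = (
                        self.logp(zp) - self.logp(zm)
                    ) / (2 * self._FD_H)
        return f0, g

    def _alpha_v_grads(self, z, c, asm, g):
        """Analytic d logp / d(log t_half, log v) via dV/dalpha and dW/dalpha."""
        alpha, v = c["alpha"], c["v"]
        a = asm["a"]
        cho = asm["cho"]
        Vinv = cho_solve(cho, np.eye(self.n_obs), check_finite=False)
        G = 0.5 * (np.outer(a, a) - Vinv)
        d, s = self.shared.d, self.shared.s
        E_d = np.exp(-alpha * d)
        E_2s = np.exp(-2.0 * alpha * s)
        Vou = v * E_d * (1.0 - E_2s)
        Vou_jit = Vou + 1e-10 * v * np.eye(self.n_obs)
        # d loglik / d log v  (V_OU and jitter both scale with v)
        gl_v = float(np.sum(G * Vou_jit))
        # d V / d alpha
        dV = v * E_d * (-d * (1.0 - E_2s) + 2.0 * s * E_2s)
        # d mu / d alpha through the design matrix
        segs = self.segs
        T = self.tip_depths[segs.tip]
        dwseg = -(T - segs.t_end) * np.exp(-alpha * (T - segs.t_end)) + (
            T - segs.t_start
        ) * np.exp(-alpha * (T - segs.t_start))
        dW = np.zeros((segs.n_tips, segs.n_regimes))
        np.add.at(dW, (segs.tip, segs.regime), dwseg)
        dW[:, segs.root_regime] += -self.tip_depths * np.exp(
            -alpha * self.tip_depths
        )
        dmu = dW @ c["theta"]
        gl_a = float(np.sum(G * dV)) + float(a @ dmu)
        gl_t = -alpha * gl_a  # d alpha / d log t_half = -alpha
        # prior + Jacobian contributions
        pr = self.priors
        lt = np.log(c["t_half"])
        gl_t += 1.0 - 1.0 - (lt - pr.t_half.log_median) / pr.t_half.log_sd**2
        gl_v += 1.0 + float(pr.v.dlogpdf(c["v"])) * c["v"]
        g[self._index["log_t_half"].offset] += gl_t
        g[self._index["log_v"].offset] += gl_v

    def _scatter_linear_grads(self, z, c, g, g_theta, g_beta):
        """Chain likelihood gradients w.r.t. theta/beta into z coordinates."""
        spec = self.spec
        ml = spec.multilevel
        nc = not self.has_block("theta")
        if not nc:
            b = self._index["theta"]
            g[b.offset : b.offset + b.size] += g_theta
        else:
            st = c["sigma_theta"]
            bzt = self._index["z_theta"]
            g[bzt.offset : bzt.offset + bzt.size] += st * g_theta
            btb = self._index["theta_bar"]
            g[btb.offset] += float(np.sum(g_theta))
            bst = self._index["log_sigma_theta"]
            zt = self.get(z, "z_theta")
            g[bst.offset] += float(np.sum(g_theta * zt * st))
        if g_beta is None:
            return
        if self.has_block("beta"):
            b = self._index["beta"]
            g[b.offset : b.offset + b.size] += np.atleast_1d(g_beta)
        else:  # VE non-centered: beta = beta_bar + sigma_beta (r z_t + sqrt(1-r^2) z_b)
            r = c["rho"]
            sb = c["sigma_beta"]
            zt = self.get(z, "z_theta")
            zb = self.get(z, "z_beta")
            sq = np.sqrt(1.0 - r * r)
            g[self._index["beta_bar"].offset] += float(np.sum(g_beta))
            b = self._index["z_beta"]
            g[b.offset : b.offset + b.size] += sb * sq * np.atleast_1d(g_beta)
            bzt = self._index["z_theta"]
            g[bzt.offset : bzt.offset + bzt.size] += sb * r * np.atleast_1d(g_beta)
            bsb = self._index["log_sigma_beta"]
            g[bsb.offset] += float(np.sum(g_beta * (r * zt + sq * zb) * sb))
            bar = self._index["atanh_rho"]
            # d beta / d atanh_rho = sigma_beta (z_t - r/sq z_b) (1 - r^2)
            dr = (1.0 - r * r)
            g[bar.offset] += float(
                np.sum(g_beta * sb * (zt - (r / sq) * zb) * dr)
            )

    def _prior_grads(self, z, c, g):
        """Analytic gradients of the prior + Jacobian for linear blocks."""
        spec, pr = self.spec, self.priors
        ml = spec.multilevel
        if ml == "none":
            b = self._index["theta"]
            g[b.offset : b.offset + b.size] += pr.theta.dlogpdf(c["theta"])
            if spec.has_slopes:
                b = self._index["beta"]
                g[b.offset : b.offset + b.size] += pr.beta.dlogpdf(
                    np.ravel(c["beta"])
                )
            return
        if ml == "varying_intercepts":
            tb, st = c["theta_bar"], c["sigma_theta"]
            if self.has_block("theta"):
                zk = (c["theta"] - tb) / st
                b = self._index["theta"]
                g[b.offset : b.offset + b.size] += -zk / st
                g[self._index["theta_bar"].offset] += float(np.sum(zk / st))
                g[self._index["log_sigma_theta"].offset] += float(
                    np.sum(zk * zk - 1.0)
                )
            else:
                zt = self.get(z, "z_theta")
                b = self._index["z_theta"]
                g[b.offset : b.offset + b.size] += -zt
            g[self._index["theta_bar"].offset] += float(pr.theta_bar.dlogpdf(tb))
            g[self._index["log_sigma_theta"].offset] += 1.0 + float(
                pr.sigma_theta.dlogpdf(st)
            ) * st
            if spec.has_slopes:
                b = self._index["beta"]
                g[b.offset : b.offset + b.size] += pr.beta.dlogpdf(np.ravel(c["beta"]))
            return
        # varying_effects
        tb, bb = c["theta_bar"], c["beta_bar"]
        st, sb, r = c["sigma_theta"], c["sigma_beta"], c["rho"]
        g[self._index["theta_bar"].offset] += float(pr.theta_bar.dlogpdf(tb))
        g[self._index["beta_bar"].offset] += float(pr.beta_bar.dlogpdf(bb))
        g[self._index["log_sigma_theta"].offset] += 1.0 + float(
            pr.sigma_theta.dlogpdf(st)
        ) * st
        g[self._index["log_sigma_beta"].offset] += 1.0 + float(
            pr.sigma_beta.dlogpdf(sb)
        ) * sb
        det = 1.0 - r * r
        # LKJ kernel + tanh jacobian, both functions of atanh_rho
        g[self._index["atanh_rho"].offset] += (
            -2.0 * r * (pr.rho.eta - 1.0) * det / det - 2.0 * r
        )
        if self.has_block("theta"):  # centered
            dt = (c["theta"] - tb) / st
            db = (np.ravel(c["beta"]) - bb) / sb
            K = spec.n_regimes
            # quad = (dt^2 - 2 r dt db + db^2)/det
            ddt = -(2 * dt - 2 * r * db) / det / 2.0  # d(-0.5 quad)/d dt
            ddb = -(2 * db - 2 * r * dt) / det / 2.0
            b = self._index["theta"]
            g[b.offset : b.offset + b.size] += ddt / st
            b = self._index["beta"]
            g[b.offset : b.offset + b.size] += ddb / sb
            g[self._index["theta_bar"].offset] += float(np.sum(-ddt / st))
            g[self._index["beta_bar"].offset] += float(np.sum(-ddb / sb))
            g[self._index["log_sigma_theta"].offset] += float(np.sum(-ddt * dt)) - K
            g[self._index["log_sigma_beta"].offset] += float(np.sum(-ddb * db)) - K
            quad_r = np.sum(
                (-2 * dt * db * det + (dt * dt - 2 * r * dt * db + db * db) * 2 * r)
                / det**2
            )
            # d/dr of sum(-0.5 log det - 0.5 quad) is K r/det - 0.5 dquad/dr;
            # chain through r = tanh(z) multiplies by det
            g[self._index["atanh_rho"].offset] += float(
                (K * r / det - 0.5 * quad_r) * det
            )
        else:
            zt = self.get(z, "z_theta")
            zb = self.get(z, "z_beta")
            b = self._index["z_theta"]
            g[b.offset : b.offset + b.size] += -zt
            b = self._index["z_beta"]
            g[b.offset : b.offset + b.size] += -zb
        if self.estimate_sigma2_x and self.prior_only:
            g[self._index["x0"].offset] += float(pr.x0.dlogpdf(c["x0"]))
            g[self._index["log_sigma2_x"].offset] += 1.0 + float(
                pr.sigma2_x.dlogpdf(c["sigma2_x"])
            ) * c["sigma2_x"]

    # -- pointwise log-likelihood -------------------------------------------

    def pointwise_loglik(self, z: np.ndarray, mode: str = "conditional") -> np.ndarray:
        """Per-species log predictive density at one draw.

        ``conditional``: log density of y_i given all other observed y under
        the draw's multivariate normal (leave-one-out conditional normal);
        ``marginal``: univariate normal from (mu_i, V_ii).  Residuals are
        phylogenetically correlated, so the conditional mode is the default.
        """
        c = self.constrain(z)
        asm = self._assemble(c)
        if asm is None:
            return np.full(self.n_obs, -np.inf)
        if mode == "marginal":
            sd = np.sqrt(np.diag(asm["V"]))
            zz = asm["r"] / sd
            return -np.log(sd) - 0.5 * (_LOG2PI + zz * zz)
        if mode != "conditional":
            raise ValueError("mode must be conditional or marginal")
        Vinv = cho_solve(asm["cho"], np.eye(self.n_obs))
        lam = np.diag(Vinv)
        if np.any(lam <= 0):
            raise np.linalg.LinAlgError("singular conditional variance")
        cond_var = 1.0 / lam
        cond_mean = self.Y - (Vinv @ asm["r"]) / lam
        zz = (self.Y - cond_mean) / np.sqrt(cond_var)
        return -0.5 * (np.log(cond_var) + _LOG2PI + zz * zz)

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Starting values: prior draw shrunk toward the prior medians."""
        for _ in range(50):
            p = self.priors.sample_params(self.spec, rng)
            p["t_half"] = float(np.clip(p["t_half"], 0.02, 2.0))
            p["v"] = float(np.clip(p["v"], 1e-4, None))
            if "sigma2_x" in p:
                p["sigma2_x"] = float(np.clip(p["sigma2_x"], 1e-3, 100.0))
            p.setdefault("theta_bar", float(np.mean(p["theta"])))
            p.setdefault("sigma_theta", 0.5)
            if self.spec.multilevel == "varying_effects":
                p.setdefault("beta_bar", float(np.mean(p["beta"])))
                p.setdefault("sigma_beta", 0.5)
                p.setdefault("rho", 0.0)
            if self.has_block("x_true"):
                p["x_true"] = self.X_raw[:, 0].copy()
            if self.estimate_sigma2_x:
                p.setdefault("x0", 0.0)
                p.setdefault("sigma2_x", 1.0)
            z = self.unconstrain(p)
            z = z + 0.01 * rng.standard_normal(self.dim)
            if np.isfinite(self.logp(z)):
                return z
        raise RuntimeError(
            "could not find a finite starting point; check priors and data "
            "(log posterior non-finite at the prior median)"
        )


def build_log_posterior(
    spec: ModelSpec,
    priors: PriorSet,
    tree: Phylogeny | None,
    painting: RegimePainting | None = None,
    Y: np.ndarray | None = None,
    X: np.ndarray | None = None,
    se_y: np.ndarray | None = None,
    se_x: np.ndarray | None = None,
    estimate_sigma2_x: bool = True,
    sigma2_x_plugin: float | None = None,
) -> LogPosterior:
    """Assemble the differentiable posterior target for one model.

    Pass ``Y=None`` for a prior-only target (the posterior of a zero-data
    model is its prior).  Predictors are mean-centered internally; centering
    constants are stored on the returned object for back-transforming
    intercepts.
    """
    return LogPosterior(
        spec, priors, tree, painting, Y, X, se_y, se_x,
        estimate_sigma2_x=estimate_sigma2_x, sigma2_x_plugin=sigma2_x_plugin,
    )


# ---------------------------------------------------------------------------
# No-U-Turn sampler
# ---------------------------------------------------------------------------

_DIVERGENCE = 1000.0


def _leapfrog(vg, z, p, g, eps, minv):
    p = p + 0.5 * eps * g
    z = z + eps * minv * p
    f1, g1 = vg(z)
    p = p + 0.5 * eps * g1
    return z, p, f1, g1


class _Tree:
    __slots__ = ("zm", "pm", "gm", "zp", "pp", "gp", "zprop", "n", "s", "alpha", "na")


def _nuts_chain(
    vg: Callable,
    z0: np.ndarray,
    n_samples: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
):
    """One NUTS chain (Hoffman-Gelman slice variant, diagonal metric)."""
    import contextlib

    ctx = np.errstate(over="ignore", invalid="ignore")
    with contextlib.ExitStack() as stack:
        stack.enter_context(ctx)
        return _nuts_chain_impl(
            vg, z0, n_samples, warmup, rng, target_accept, max_treedepth
        )


def _nuts_chain_impl(vg, z0, n_samples, warmup, rng, target_accept,
                     max_treedepth):
    d = len(z0)
    minv = np.ones(d)
    z = z0.copy()
    f, g = vg(z)
    if not np.isfinite(f):
        raise ValueError("non-finite log posterior at the initial point")

    # dual averaging state
    def init_da(eps0):
        return dict(mu=np.log(10 * eps0), eps=eps0, eps_bar=1.0, h_bar=0.0,
                    gamma=0.05, t0=10.0, kappa=0.75, m=0)

    def find_eps(z, f, g):
        eps = 1.0
        p = rng.standard_normal(d) / np.sqrt(minv)
        joint0 = f - 0.5 * np.sum(minv * p * p)
        z1, p1, f1, _ = _leapfrog(vg, z, p, g, eps, minv)
        joint1 = f1 - 0.5 * np.sum(minv * p1 * p1)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0**direction
            z1, p1, f1, _ = _leapfrog(vg, z, p, g, eps, minv)
            joint1 = f1 - 0.5 * np.sum(minv * p1 * p1)
            if not np.isfinite(joint1):
                joint1 = -np.inf
            if direction * (joint1 - joint0) < direction * np.log(0.5):
                break
        return max(eps, 1e-10)

    da = init_da(find_eps(z, f, g))

    def build_tree(zq, pq, gq, logu, vdir, depth, joint0, eps):
        t = _Tree()
        if depth == 0:
            z1, p1, f1, g1 = _leapfrog(vg, zq, pq, gq, vdir * eps, minv)
            joint = f1 - 0.5 * np.sum(minv * p1 * p1)
            if not np.isfinite(joint):
                joint = -np.inf
            t.zm = t.zp = z1
            t.pm = t.pp = p1
            t.gm = t.gp = g1
            t.zprop = z1
            t.n = int(logu <= joint)
            t.s = int(joint - logu > -_DIVERGENCE)
            t.alpha = min(1.0, np.exp(joint - joint0)) if np.isfinite(joint) else 0.0
            t.na = 1
            return t, joint - logu <= -_DIVERGENCE
        t1, div = build_tree(zq, pq, gq, logu, vdir, depth - 1, joint0, eps)
        if t1.s == 0 or div:
            return t1, div
        if vdir == -1:
            t2, div = build_tree(t1.zm, t1.pm, t1.gm, logu, vdir, depth - 1,
                                 joint0, eps)
            t1.zm, t1.pm, t1.gm = t2.zm, t2.pm, t2.gm
        else:
            t2, div = build_tree(t1.zp, t1.pp, t1.gp, logu, vdir, depth - 1,
                                 joint0, eps)
            t1.zp, t1.pp, t1.gp = t2.zp, t2.pp, t2.gp
        if t2.n > 0 and rng.random() < t2.n / max(t1.n + t2.n, 1):
            t1.zprop = t2.zprop
        dz = t1.zp - t1.zm
        nostop = (dz @ (minv * t1.pm) >= 0) and (dz @ (minv * t1.pp) >= 0)
        t1.s = int(t1.s and t2.s and nostop)
        t1.n += t2.n
        t1.alpha += t2.alpha
        t1.na += t2.na
        return t1, div

    total = warmup + n_samples
    draws = np.empty((n_samples, d))
    divergences = 0
    accept_sum = 0.0
    depth_sum = 0
    # warmup windows for mass-matrix estimation
    w1 = max(int(0.15 * warmup), 10)
    w2 = max(int(0.75 * warmup), w1 + 10)
    acc = []
    for it in range(total):
        p = rng.standard_normal(d) / np.sqrt(minv)
        f, g = vg(z)
        joint0 = f - 0.5 * np.sum(minv * p * p)
        logu = joint0 + np.log(rng.random())
        t = _Tree()
        t.zm = t.zp = z
        t.pm = t.pp = p
        t.gm = t.gp = g
        t.zprop = z
        t.n, t.s = 1, 1
        t.alpha, t.na = 0.0, 0
        depth = 0
        diverged = False
        while t.s == 1 and depth < max_treedepth:
            vdir = -1 if rng.random() < 0.5 else 1
            if vdir == -1:
                sub, div = build_tree(t.zm, t.pm, t.gm, logu, vdir, depth,
                                      joint0, da["eps"])
                t.zm, t.pm, t.gm = sub.zm, sub.pm, sub.gm
            else:
                sub, div = build_tree(t.zp, t.pp, t.gp, logu, vdir, depth,
                                      joint0, da["eps"])
                t.zp, t.pp, t.gp = sub.zp, sub.pp, sub.gp
            diverged = diverged or div
            if sub.s == 1 and rng.random() < min(1.0, sub.n / max(t.n, 1)):
                z = sub.zprop.copy()
            t.n += sub.n
            t.alpha += sub.alpha
            t.na += sub.na
            dz = t.zp - t.zm
            t.s = int(
                sub.s and (dz @ (minv * t.pm) >= 0) and (dz @ (minv * t.pp) >= 0)
            )
            depth += 1
        astat = t.alpha / max(t.na, 1)
        if it < warmup:
            da["m"] += 1
            frac = 1.0 / (da["m"] + da["t0"])
            da["h_bar"] = (1 - frac) * da["h_bar"] + frac * (target_accept - astat)
            log_eps = da["mu"] - np.sqrt(da["m"]) / da["gamma"] * da["h_bar"]
            eta = da["m"] ** (-da["kappa"])
            da["eps_bar"] = np.exp(
                eta * log_eps + (1 - eta) * np.log(da["eps_bar"])
            )
            da["eps"] = float(np.exp(log_eps))
            if w1 <= it < w2:
                acc.append(z.copy())
            if it == w2 - 1 and len(acc) > 5:
                var = np.var(np.asarray(acc), axis=0)
                n_acc = len(acc)
                minv = (n_acc * var + 5e-3) / (n_acc + 5.0)  # regularized
                f, g = vg(z)
                da = init_da(find_eps(z, f, g))
        else:
            if it == warmup:
                da["eps"] = float(da["eps_bar"])
            if diverged:
                divergences += 1
            draws[it - warmup] = z
            accept_sum += astat
            depth_sum += depth
    return dict(
        draws=draws,
        divergences=divergences,
        step_size=float(da["eps"]),
        mass_inv=minv,
        mean_accept=accept_sum / max(n_samples, 1),
        mean_treedepth=depth_sum / max(n_samples, 1),
    )


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Named posterior draws by chain x iteration, plus sampler metadata."""

    params: dict  # name -> (chains, draws) array of constrained values
    unconstrained: np.ndarray  # (chains, draws, dim)
    pointwise: np.ndarray | None  # (chains, draws, n_obs) log-likelihood
    pointwise_mode: str
    meta: dict
    target: LogPosterior | None = None

    @property
    def n_chains(self) -> int:
        return self.unconstrained.shape[0]

    @property
    def n_draws(self) -> int:
        return self.unconstrained.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return np.ravel(self.params[name])

    def to_arviz(self):
        import arviz as az

        data = {k: v for k, v in self.params.items()}
        kwargs = {}
        if self.pointwise is not None:
            kwargs["log_likelihood"] = {"Y": self.pointwise}
        return az.from_dict(posterior=data, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        rows = []
        for name, arr in self.params.items():
            for ch in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ch,
                            "iteration": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[ch],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def sample_posterior(
    target,
    chains: int = 2,
    iterations: int = 4000,
    warmup: int | None = None,
    seed: int = 0,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    pointwise: bool = True,
    pointwise_mode: str = "conditional",
    initial: np.ndarray | None = None,
) -> PosteriorDraws:
    """NUTS sampling of a log-posterior target.

    ``iterations`` counts post-warmup draws per chain; ``warmup`` defaults to
    ``iterations // 2`` additional adaptation iterations (discarded).  Fixed
    seeds give bit-identical draws on the same platform.  A chain with more
    than 10% divergent transitions triggers a warning suggesting the
    non-centered parameterization.
    """
    if warmup is None:
        warmup = max(iterations // 2, 50)
    vg = target.value_and_grad
    is_model = isinstance(target, LogPosterior)
    ss = np.random.SeedSequence(int(seed))
    chain_seeds = ss.spawn(chains + 1)
    results = []
    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        if initial is not None:
            z0 = np.asarray(initial, dtype=float).copy()
        elif is_model:
            z0 = target.initial_point(rng)
        else:
            z0 = 0.1 * rng.standard_normal(target.dim)
        res = _nuts_chain(
            vg, z0, iterations, warmup, rng,
            target_accept=target_accept, max_treedepth=max_treedepth,
        )
        results.append(res)

    zdraws = np.stack([r["draws"] for r in results])  # (chains, draws, dim)
    divergences = [int(r["divergences"]) for r in results]
    frac_div = sum(divergences) / max(chains * iterations, 1)
    if frac_div > 0.10:
        warnings.warn(
            f"{100 * frac_div:.1f}% divergent transitions; consider switching "
            "to a non-centered parameterization or increasing target_accept"
        )

    params: dict = {}
    pll = None
    if is_model:
        names = target.param_names()
        series = {n: np.empty((chains, iterations)) for n in names}
        if pointwise and not target.prior_only:
            pll = np.empty((chains, iterations, target.n_obs))
        K = target.spec.n_regimes
        for ch in range(chains):
            for i in range(iterations):
                c = target.constrain(zdraws[ch, i])
                series["t_half"][ch, i] = c["t_half"]
                series["v"][ch, i] = c["v"]
                for k in range(K):
                    series[f"theta[{k}]"][ch, i] = c["theta"][k]
                if target.spec.has_slopes:
                    b = np.ravel(c["beta"])
                    for j in range(b.size):
                        series[f"beta[{j}]"][ch, i] = b[j]
                if target.spec.multilevel != "none":
                    series["theta_bar"][ch, i] = c["theta_bar"]
                    series["sigma_theta"][ch, i] = c["sigma_theta"]
                if target.spec.multilevel == "varying_effects":
                    series["beta_bar"][ch, i] = c["beta_bar"]
                    series["sigma_beta"][ch, i] = c["sigma_beta"]
                    series["rho"][ch, i] = c["rho"]
                if target.estimate_sigma2_x:
                    series["x0"][ch, i] = c["x0"]
                    series["sigma2_x"][ch, i] = c["sigma2_x"]
                if pll is not None:
                    pll[ch, i] = target.pointwise_loglik(
                        zdraws[ch, i], mode=pointwise_mode
                    )
        params = series
        # derived quantities
        params["alpha"] = np.log(2.0) / params["t_half"]
        params["sigma2_y"] = 2.0 * params["alpha"] * params["v"]
        params["t_half_original"] = params["t_half"] * target.scale_factor
        if target.spec.is_adaptive and not target.prior_only:
            rho_T = ou_core.rho_correction(params["alpha"], target.T)
            for j in range(
                K if target.spec.varying_slopes else target.spec.n_predictors
            ):
                params[f"evolutionary_beta[{j}]"] = params[f"beta[{j}]"] * rho_T
    else:
        for j in range(zdraws.shape[2]):
            params[f"x[{j}]"] = zdraws[:, :, j]

    meta = dict(
        seed=int(seed),
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        divergences=divergences,
        step_sizes=[float(r["step_size"]) for r in results],
        mean_accept=[float(r["mean_accept"]) for r in results],
        mean_treedepth=[float(r["mean_treedepth"]) for r in results],
    )
    return PosteriorDraws(
        params=params,
        unconstrained=zdraws,
        pointwise=pll,
        pointwise_mode=pointwise_mode,
        meta=meta,
        target=target if is_model else None,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostics:
    """Split-chain R-hat and effective sample size per parameter."""

    rhat: dict
    ess: dict
    flagged: tuple
    rhat_threshold: float = 1.1
    ess_threshold: float = 100.0

    @property
    def converged(self) -> bool:
        return len(self.flagged) == 0


def diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.1,
    ess_threshold: float = 100.0,
) -> Diagnostics:
    """Rank-based split R-hat and ESS; flags parameters failing the cutoffs.

    R-hat below 1.1 and effective sample size of at least 100 are the
    conventional convergence criteria for these models.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError(
            "at least 2 chains are required for a reliable split R-hat"
        )
    if draws.n_draws < 4:
        raise ValueError("need at least 4 draws per chain")
    rhat: dict = {}
    ess: dict = {}
    flagged = []
    for name, arr in draws.params.items():
        if np.allclose(arr.std(), 0):
            rhat[name] = 1.0
            ess[name] = float(arr.size)
            continue
        da = az.convert_to_dataset(arr[..., None])
        r = float(az.rhat(da)["x"].values[0])
        e = float(az.ess(da)["x"].values[0])
        rhat[name] = r
        ess[name] = e
        if not np.isfinite(r) or r >= rhat_threshold or e < ess_threshold:
            flagged.append(name)
    return Diagnostics(
        rhat=rhat,
        ess=ess,
        flagged=tuple(flagged),
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
    )


def summary_table(draws: PosteriorDraws, ci: float = 0.95) -> pd.DataFrame:
    """Posterior summary: mean, CI bounds, sd, n_eff, R-hat per parameter."""
    diag = diagnostics(draws)
    lo_q, hi_q = 50 * (1 - ci), 50 * (1 + ci)
    rows = []
    for name, arr in draws.params.items():
        flat = np.ravel(arr)
        rows.append(
            dict(
                parameter=name,
                mean=float(np.mean(flat)),
                ci_low=float(np.percentile(flat, lo_q)),
                ci_high=float(np.percentile(flat, hi_q)),
                sd=float(np.std(flat, ddof=1)),
                n_eff=diag.ess.get(name, np.nan),
                rhat=diag.rhat.get(name, np.nan),
            )
        )
    return pd.DataFrame(rows)


def map_estimate(target: LogPosterior, seed: int = 0, n_starts: int = 3) -> dict:
    """Posterior mode via quasi-Newton optimization from seeded starts."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        z0 = target.initial_point(rng)
        res = minimize(
            lambda zz: -target.logp(zz),
            z0,
            jac=lambda zz: -target.value_and_grad(zz)[1],
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    out = target.constrain(best.x)
    out["logp"] = -float(best.fun)
    return out
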