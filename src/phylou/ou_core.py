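"""Deterministic core of the linear Ornstein-Uhlenbeck model family.

The response trait y evolves toward a primary optimum theta(t) under

    dy = -alpha (y - theta) dt + sigma_y dB,

where ``alpha`` is the rate of adaptation.  Two reparameterizations make the
process interpretable on a unit-height tree: the phylogenetic half-life
``t_half = ln 2 / alpha`` (time to close half the gap to a new optimum) and
the stationary variance ``v = sigma_y^2 / (2 alpha)`` (equilibrium
among-species variance around a long-held optimum).

This module assembles, for every implemented model kind, the mean vector and
among-species covariance matrix of the tip values:

* multi-optima: mean ``W theta`` with ``W`` the Hansen regime-weight design
  matrix (exponentially discounted time spent in each regime);
* direct effect: predictors enter the mean directly (``X beta``), residuals
  are OU;
* adaptive: the optimum tracks Brownian predictors; the tip-level
  (evolutionary) slope is the optimal slope discounted by the phylogenetic
  correction factor ``rho(alpha T)``, and the predictor history inflates the
  residual covariance.

Everything here is deterministic and fully vectorized; sampling lives in
:mod:`phylou.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor

from .phylo import RegimePainting, SharedTimes

__all__ = [
    "OUParams",
    "ModelSpec",
    "half_life_to_alpha",
    "alpha_to_half_life",
    "stationary_variance",
    "sigma2_from_stationary",
    "rho_correction",
    "regime_weights",
    "segment_arrays",
    "ou_covariance",
    "adaptive_lag_matrix",
    "model_mean",
    "model_covariance",
    "cholesky_pd",
]

MODEL_KINDS = (
    "multi_optima",
    "direct_effect",
    "adaptive",
    "multi_optima_direct",
    "multi_optima_adaptive",
)
MULTILEVEL = ("none", "varying_intercepts", "varying_effects")


def _check_positive(name: str, x) -> None:
    if not np.all(np.asarray(x) > 0):
        raise ValueError(f"{name} must be strictly positive, got {x}")


def half_life_to_alpha(t_half):
    """alpha = ln(2) / t_half."""
    _check_positive("t_half", t_half)
    return np.log(2.0) / np.asarray(t_half, dtype=float)


def alpha_to_half_life(alpha):
    """t_half = ln(2) / alpha (exact inverse of :func:`half_life_to_alpha`)."""
    _check_positive("alpha", alpha)
    return np.log(2.0) / np.asarray(alpha, dtype=float)


def stationary_variance(sigma2_y, alpha):
    """v = sigma_y^2 / (2 alpha)."""
    _check_positive("sigma2_y", sigma2_y)
    _check_positive("alpha", alpha)
    return np.asarray(sigma2_y, dtype=float) / (2.0 * np.asarray(alpha, dtype=float))


def sigma2_from_stationary(v, alpha):
    """sigma_y^2 = 2 alpha v (inverse of :func:`stationary_variance`)."""
    _check_positive("v", v)
    _check_positive("alpha", alpha)
    return 2.0 * np.asarray(alpha, dtype=float) * np.asarray(v, dtype=float)


@dataclass(frozen=True)
class OUParams:
    """OU process parameters with both parameterizations kept in sync."""

    half_life: float
    stationary_var: float

    def __post_init__(self):
        _check_positive("half_life", self.half_life)
        _check_positive("stationary_var", self.stationary_var)

    @property
    def alpha(self) -> float:
        return float(np.log(2.0) / self.half_life)

    @property
    def sigma2_y(self) -> float:
        return float(2.0 * self.alpha * self.stationary_var)

    @classmethod
    def from_alpha(cls, alpha: float, sigma2_y: float) -> "OUParams":
        _check_positive("alpha", alpha)
        _check_positive("sigma2_y", sigma2_y)
        return cls(
            half_life=float(np.log(2.0) / alpha),
            stationary_var=float(sigma2_y / (2.0 * alpha)),
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which model to build: kind, multilevel structure, measurement error.

    ``model_kind`` is one of multi_optima | direct_effect | adaptive |
    multi_optima_direct | multi_optima_adaptive.  ``multilevel`` controls
    partial pooling across regimes (none, varying_intercepts, varying_effects)
    and ``parameterization`` picks the centered or non-centered form of the
    hierarchy.  Measurement-error handling: the response is marginalized
    analytically (reported SEs inflate the covariance diagonal, equivalent to
    the latent-variable formulation for a Gaussian model); predictors use
    explicit latent true values when ``me_predictors`` is set.
    """

    model_kind: str = "multi_optima"
    multilevel: str = "none"
    parameterization: str = "centered"
    n_regimes: int = 1
    n_predictors: int = 0
    slope_structure: str = "shared"  # shared | by_regime
    me_response: bool = False
    me_predictors: bool = False

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.multilevel not in MULTILEVEL:
            raise ValueError(f"multilevel must be one of {MULTILEVEL}")
        if self.slope_structure not in ("shared", "by_regime"):
            raise ValueError("slope_structure must be shared or by_regime")
        if self.multilevel == "varying_effects" and self.slope_structure == "shared":
            object.__setattr__(self, "slope_structure", "by_regime")
        if self.slope_structure == "by_regime" and self.n_predictors != 1:
            raise ValueError("by_regime slopes require exactly 1 predictor")
        if self.parameterization not in ("centered", "non_centered"):
            raise ValueError("parameterization must be centered or non_centered")
        if self.has_slopes and self.n_predictors < 1:
            raise ValueError(f"{self.model_kind} requires at least one predictor")
        if self.model_kind == "multi_optima" and self.n_predictors != 0:
            raise ValueError("multi_optima takes no continuous predictors")
        if self.multilevel == "varying_effects":
            if self.n_predictors != 1:
                raise ValueError(
                    "varying_effects requires exactly 1 continuous predictor "
                    "(the intercept/slope correlation matrix is 2x2)"
                )
            if self.n_regimes < 2:
                raise ValueError("varying_effects requires >= 2 regimes")
        if self.n_regimes < 1:
            raise ValueError("n_regimes must be >= 1")

    @property
    def has_slopes(self) -> bool:
        return self.model_kind != "multi_optima"

    @property
    def is_adaptive(self) -> bool:
        return self.model_kind in ("adaptive", "multi_optima_adaptive")

    @property
    def varying_slopes(self) -> bool:
        """Regime-specific slopes (hierarchical or with fixed priors)."""
        return self.has_slopes and self.slope_structure == "by_regime"


def rho_correction(alpha, t):
    """Phylogenetic correction factor rho(alpha t) = 1 - (1 - e^-at)/(at).

    The evolutionary (realized) regression slope is the optimal slope times
    rho.  rho -> 0 as alpha t -> 0 (pure phylogenetic inertia, Brownian
    residuals) and rho -> 1 as alpha t -> infinity (instantaneous adaptation);
    rho(0) is defined by continuity as 0.
    """
    _check_positive("alpha", alpha)
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    x = np.asarray(alpha * np.asarray(t, dtype=float))
    out = np.where(
        x < 1e-4,
        x / 2.0 - x**2 / 6.0,
        1.0 + np.expm1(-np.maximum(x, 1e-300)) / np.maximum(x, 1e-300),
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SegmentArrays:
    """Flattened lineage segments for fast design-matrix rebuilds."""

    tip: np.ndarray  # segment -> tip row index
    regime: np.ndarray  # segment -> regime index
    t_start: np.ndarray
    t_end: np.ndarray
    root_regime: int
    n_tips: int
    n_regimes: int


def segment_arrays(painting: RegimePainting) -> SegmentArrays:
    tip, reg, ta, tb = [], [], [], []
    for i, segs in enumerate(painting.tip_lineages):
        for (k, a, b) in segs:
            tip.append(i)
            reg.append(k)
            ta.append(a)
            tb.append(b)
    return SegmentArrays(
        tip=np.asarray(tip, dtype=int),
        regime=np.asarray(reg, dtype=int),
        t_start=np.asarray(ta, dtype=float),
        t_end=np.asarray(tb, dtype=float),
        root_regime=painting.root_regime,
        n_tips=len(painting.tip_lineages),
        n_regimes=painting.n_regimes,
    )


def _regime_weights_from_segments(
    alpha: float, segs: SegmentArrays, tip_depths: np.ndarray
) -> np.ndarray:
    T = tip_depths[segs.tip]
    wseg = np.exp(-alpha * (T - segs.t_end)) - np.exp(-alpha * (T - segs.t_start))
    W = np.zeros((segs.n_tips, segs.n_regimes))
    np.add.at(W, (segs.tip, segs.regime), wseg)
    # residual mass of the root's regime (no separate ancestral-state parameter)
    W[:, segs.root_regime] += np.exp(-alpha * tip_depths)
    return W


def regime_weights(
    alpha: float, painting: RegimePainting, tip_depths: np.ndarray
) -> np.ndarray:
    """Hansen regime-weight design matrix W (n_tips x n_regimes).

    The weight of regime k for tip i sums ``e^{-a(T_i - t_end)} -
    e^{-a(T_i - t_start)}`` over the lineage segments painted k; the residual
    root mass ``e^{-a T_i}`` goes to the root's regime, so rows sum to 1.
    """
    _check_positive("alpha", alpha)
    return _regime_weights_from_segments(float(alpha), segment_arrays(painting),
                                         np.asarray(tip_depths, dtype=float))


def ou_covariance(
    alpha: float,
    v: float,
    shared: SharedTimes,
    jitter: float | None = None,
    check: bool = True,
) -> np.ndarray:
    """OU residual covariance V[i,j] = v e^{-a d_ij} (1 - e^{-2 a s_ij}).

    ``jitter`` (default ``1e-10 v``) is added to the diagonal before any
    factorization; with ``check`` the matrix is verified positive definite and
    a failure reports the smallest eigenvalue.  As alpha -> 0 with sigma_y^2
    = 2 alpha v held fixed, V converges on the Brownian-motion covariance
    ``sigma_y^2 s``.
    """
    _check_positive("alpha", alpha)
    _check_positive("v", v)
    V = v * np.exp(-alpha * shared.d) * (-np.expm1(-2.0 * alpha * shared.s))
    if jitter is None:
        jitter = 1e-10 * v
    V[np.diag_indices_from(V)] += jitter
    if check:
        cholesky_pd(V, jitter=0.0)
    return V


def _adaptive_I(alpha: float, s: np.ndarray, T: float) -> np.ndarray:
    return (
        2.0 * alpha * s
        + 4.0 * np.exp(-alpha * T)
        + np.exp(-2.0 * alpha * (T - s))
        - 4.0 * np.exp(-alpha * (T - s))
        - np.exp(-2.0 * alpha * T)
    ) / (2.0 * alpha**3)


def _adaptive_J(alpha: float, s: np.ndarray, T: float) -> np.ndarray:
    return (alpha * s - np.exp(-alpha * (T - s)) + np.exp(-alpha * T)) / alpha**2


def adaptive_lag_matrix(alpha: float, s: np.ndarray, T: float) -> np.ndarray:
    """Per-unit-sigma2_x residual inflation from tracking a Brownian predictor.

    For tips i, j at common depth T with MRCA time s, the residual of the
    evolutionary regression (deterministic slope beta * rho(alpha T)) has
    covariance ``V_OU + beta_i beta_j sigma2_x M(s)`` where

        M(s) = a^2 I(s) - 2 rho a J(s) + rho^2 s,

    with I and J elementary integrals of the exponentially discounted
    predictor history (J = int_0^T e^{-a(T-u)} min(u,s) du and I its double
    analogue).  M -> 0 as alpha -> infinity (direct-effect limit) and
    M = O(alpha^2) -> 0 as alpha -> 0 (Brownian-motion limit).  Below
    ``alpha T < 1e-2`` a series expansion in alpha avoids catastrophic
    cancellation of the closed form.
    """
    _check_positive("alpha", alpha)
    s = np.asarray(s, dtype=float)
    x = alpha * T
    if x < 1e-2:
        # exact expansion to O(alpha^4); relative truncation error O((aT)^3)
        c2 = s * (90 * T**2 - 180 * T * s + 120 * s**2) / 360.0
        c3 = s * (-120 * T**3 + 300 * T**2 * s - 300 * T * s**2 + 90 * s**3) / 360.0
        c4 = s * (
            85 * T**4 - 255 * T**3 * s + 340 * T**2 * s**2
            - 195 * T * s**3 + 42 * s**4
        ) / 360.0
        return alpha**2 * c2 + alpha**3 * c3 + alpha**4 * c4
    rho = rho_correction(alpha, T)
    return (
        alpha**2 * _adaptive_I(alpha, s, T)
        - 2.0 * rho * alpha * _adaptive_J(alpha, s, T)
        + rho**2 * s
    )


def _tip_slopes(spec: ModelSpec, beta: np.ndarray, tip_regimes) -> np.ndarray:
    """Per-tip slope matrix (n_tips x n_predictors)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.ndim == 1:
        if beta.shape[0] != spec.n_predictors:
            raise ValueError(
                f"beta has {beta.shape[0]} entries, expected {spec.n_predictors}"
            )
        return np.broadcast_to(beta, (len(tip_regimes), spec.n_predictors))
    if beta.shape != (spec.n_regimes, spec.n_predictors):
        raise ValueError(
            f"varying-slope beta must be (K, p) = "
            f"({spec.n_regimes}, {spec.n_predictors}), got {beta.shape}"
        )
    return beta[np.asarray(tip_regimes, dtype=int)]


def model_mean(
    spec: ModelSpec,
    params: dict,
    W: np.ndarray,
    X: np.ndarray | None = None,
    tip_regimes=None,
    tip_depth: float | None = None,
) -> np.ndarray:
    """Mean tip values mu for the given model.

    multi-optima: ``mu = W theta``; direct-effect terms add ``X beta`` (slope
    per tip regime under varying effects); adaptive terms add ``rho(alpha T) X
    beta`` so the implied tip-level regression slope is the optimal slope
    discounted by rho.  ``X`` must be mean-centered so intercepts are optima
    at the average interspecific predictor value.
    """
    theta = np.atleast_1d(np.asarray(params["theta"], dtype=float))
    if W.shape[1] != theta.shape[0]:
        raise ValueError(f"W has {W.shape[1]} columns but theta has {len(theta)}")
    mu = W @ theta
    if spec.has_slopes:
        if X is None:
            raise ValueError(f"{spec.model_kind} requires predictors X")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != W.shape[0]:
            X = X.T
        if tip_regimes is None:
            tip_regimes = np.zeros(W.shape[0], dtype=int)
        B = _tip_slopes(spec, params["beta"], tip_regimes)
        term = (X * B).sum(axis=1)
        if spec.is_adaptive:
            if tip_depth is None:
                raise ValueError("adaptive model needs the common tip depth")
            term = term * rho_correction(params["alpha"], tip_depth)
        mu = mu + term
    return mu


def model_covariance(
    spec: ModelSpec,
    params: dict,
    shared: SharedTimes,
    tip_regimes=None,
    se_y: np.ndarray | None = None,
    check: bool = True,
) -> np.ndarray:
    """Total residual covariance for the given model.

    Multi-optima and direct-effect models use the OU covariance unchanged.
    The adaptive model adds the predictor-history inflation
    ``beta_i beta_j sigma2_x M(s_ij)`` (see :func:`adaptive_lag_matrix`) and
    requires an ultrametric tree.  Response measurement-error SEs, when given,
    add ``se_y^2`` to the diagonal (the analytically marginalized
    latent-variable formulation).
    """
    alpha, v = float(params["alpha"]), float(params["v"])
    V = ou_covariance(alpha, v, shared, check=False)
    if spec.is_adaptive:
        depths = shared.tip_depths
        T = float(depths.max())
        if np.ptp(depths) > 1e-8 * max(T, 1.0):
            raise ValueError("the adaptive model requires an ultrametric tree")
        if tip_regimes is None:
            tip_regimes = np.zeros(V.shape[0], dtype=int)
        B = _tip_slopes(spec, params["beta"], tip_regimes)
        sigma2_x = np.atleast_1d(np.asarray(params["sigma2_x"], dtype=float))
        M = adaptive_lag_matrix(alpha, shared.s, T)
        for j in range(spec.n_predictors):
            V = V + sigma2_x[j] * np.outer(B[:, j], B[:, j]) * M
    if se_y is not None:
        V = V.copy()
        V[np.diag_indices_from(V)] += np.asarray(se_y, dtype=float) ** 2
    if check:
        cholesky_pd(V, jitter=0.0)
    return V


def cholesky_pd(V: np.ndarray, jitter: float | None = None):
    """Cholesky factor of V, failing loudly (smallest eigenvalue reported)."""
    if jitter:
        V = V.copy()
        V[np.diag_indices_from(V)] += jitter
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    lam = float(np.linalg.eigvalsh(V)[0])
    raise np.linalg.LinAlgError(
        f"covariance matrix is not positive definite after jitter "
        f"(smallest eigenvalue {lam:.3e})"
    )
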