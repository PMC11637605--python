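"""Generative engine: trees, Brownian predictors, OU responses, fixtures.

Every operation is a pure function of its inputs and a seed.  Child seeds are
derived from the master seed with a fixed counter scheme
(``SeedSequence([seed, counter])`` with one documented counter per stream), so
adding a new random step never perturbs earlier streams.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import dendropy
from dendropy.simulate import treesim

from . import ou_core
from .phylo import (
    Phylogeny,
    RegimePainting,
    paint_regimes,
    parse_newick,
    scale_to_unit_height,
    shared_times,
)

__all__ = [
    "child_rng",
    "simulate_tree",
    "simulate_bm",
    "simulate_response",
    "add_measurement_error",
    "random_regime_painting",
    "SimConfig",
    "SimResult",
    "simulate_dataset",
    "validation_fixture",
]

# fixed stream counters for child-seed derivation
STREAMS = {
    "tree": 0,
    "painting": 1,
    "bm": 2,
    "response": 3,
    "me_response": 4,
    "me_predictor": 5,
}


def child_rng(seed: int, stream: str | int) -> np.random.Generator:
    """Generator for a named child stream of the master seed."""
    counter = STREAMS[stream] if isinstance(stream, str) else int(stream)
    return np.random.default_rng(np.random.SeedSequence([int(seed), counter]))


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_retries: int = 100,
) -> Phylogeny:
    """Seeded birth-death tree with ``n_tips`` extant tips, unit height.

    Default is a pure-birth (Yule) process.  Lineage extinction before
    reaching ``n_tips`` triggers an internal retry up to ``max_retries``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate < 0 or death_rate < 0:
        raise ValueError("rates must be non-negative")
    base = random.Random(int(seed))
    last = None
    for _ in range(max_retries):
        try:
            # gsa_ntax samples a time slice while exactly n_tips are extant,
            # avoiding the zero-length terminal cherry of stopping at a birth
            t = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_tips,
                gsa_ntax=n_tips + 1,
                rng=random.Random(base.randrange(2**31)),
            )
            newick = t.as_string(schema="newick", suppress_rooting=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tree = parse_newick(newick)
            if tree.n_tips != n_tips or tree.height <= 0:
                raise ValueError("degenerate simulated tree")
            return scale_to_unit_height(tree)
        except Exception as exc:  # extinction or degenerate tree; retry
            last = exc
    raise RuntimeError(
        f"could not simulate a {n_tips}-tip tree in {max_retries} tries: {last}"
    )


def simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    seed: int = 0,
    x0: float = 0.0,
    size: int | None = None,
) -> np.ndarray:
    """Brownian motion along the tree from root value ``x0``; tip values.

    Increments on a branch of length t are Normal(0, sigma2 * t).  With
    ``size`` given, returns ``size`` independent replicates, shape
    (size, n_tips).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = 1 if size is None else int(size)
    vals = np.zeros((tree.n_nodes, width))
    order = tree._preorder()
    vals[order[0]] = x0
    bl = tree.branch_lengths
    for u in order[1:]:
        vals[u] = vals[tree.parents[u]] + rng.normal(
            0.0, np.sqrt(sigma2 * bl[u]), size=width
        )
    out = vals[tree.tip_ids].T
    return out[0] if size is None else out


def simulate_response(
    tree: Phylogeny,
    painting: RegimePainting,
    spec: ou_core.ModelSpec,
    params: dict,
    X: np.ndarray | None = None,
    seed: int = 0,
    shared=None,
    size: int | None = None,
) -> np.ndarray:
    """Draw tip responses Y from the model's multivariate normal.

    The mean and covariance are exactly those the fitted model uses
    (:func:`phylou.ou_core.model_mean` / ``model_covariance``); for adaptive
    models the draw is conditional on the supplied predictor values X.
    Predictors are mean-centered before entering the mean, matching the
    estimation convention (intercepts are optima at the average interspecific
    predictor value), so simulated optima are directly comparable to fitted
    ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if shared is None:
        shared = shared_times(tree)
    depths = shared.tip_depths
    alpha = float(params["alpha"])
    v = float(params["v"])
    W = ou_core.regime_weights(alpha, painting, depths)
    Xc = None
    if spec.has_slopes:
        Xc = np.atleast_2d(np.asarray(X, dtype=float))
        if Xc.shape[0] != len(depths):
            Xc = Xc.T
        Xc = Xc - Xc.mean(axis=0)
    mu = ou_core.model_mean(
        spec, params, W, Xc, painting.tip_regimes, tip_depth=float(depths.max())
    )
    n = len(mu)
    V = np.zeros((n, n))
    if v > 0:
        V += ou_core.ou_covariance(alpha, v, shared, check=False)
    if spec.is_adaptive:
        B = ou_core._tip_slopes(spec, params["beta"], painting.tip_regimes)
        sigma2_x = np.atleast_1d(np.asarray(params["sigma2_x"], dtype=float))
        M = ou_core.adaptive_lag_matrix(alpha, shared.s, float(depths.max()))
        for j in range(spec.n_predictors):
            V += sigma2_x[j] * np.outer(B[:, j], B[:, j]) * M
    if not V.any():
        return mu.copy() if size is None else np.tile(mu, (int(size), 1))
    scale = np.trace(V) / n
    V[np.diag_indices_from(V)] += 1e-12 * scale
    L = np.linalg.cholesky(V)
    if size is None:
        return mu + L @ rng.standard_normal(n)
    return mu + (L @ rng.standard_normal((n, int(size)))).T


def add_measurement_error(values: np.ndarray, sd, seed: int = 0):
    """Add iid Normal(0, sd) noise; return (observed, reported_se)."""
    values = np.asarray(values, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), values.shape).copy()
    if np.any(sd < 0):
        raise ValueError("measurement-error sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    return obs, sd


def random_regime_painting(
    tree: Phylogeny,
    n_regimes: int = 4,
    seed: int = 0,
    min_clade: int = 5,
    max_clade: int = 40,
    min_tips_per_regime: int = 5,
    max_retries: int = 500,
) -> RegimePainting:
    """Paint ``n_regimes`` clade-structured regimes at random.

    ``n_regimes - 1`` internal nodes are chosen uniformly among those
    subtending ``min_clade``..``max_clade`` tips; the root carries the
    remaining regime.  Paintings leaving any regime with fewer than
    ``min_tips_per_regime`` tips are regenerated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kids = tree.children()
    n_below = np.zeros(tree.n_nodes, dtype=int)
    for u in tree._preorder()[::-1]:
        n_below[u] = 1 if not kids[u] else sum(n_below[c] for c in kids[u])
    candidates = [
        u
        for u in range(tree.n_nodes)
        if kids[u] and u != tree.root and min_clade <= n_below[u] <= max_clade
    ]
    if len(candidates) < n_regimes - 1:
        raise ValueError(
            f"tree has only {len(candidates)} internal nodes subtending "
            f"{min_clade}-{max_clade} tips; cannot paint {n_regimes} regimes"
        )
    names = tuple(f"R{k}" for k in range(n_regimes))
    for _ in range(max_retries):
        chosen = rng.choice(candidates, size=n_regimes - 1, replace=False)
        assignments = {int(tree.root): names[0]}
        for k, node in enumerate(chosen, start=1):
            assignments[int(node)] = names[k]
        painting = paint_regimes(tree, assignments, regime_names=names)
        counts = np.bincount(painting.tip_regimes, minlength=n_regimes)
        if counts.min() >= min_tips_per_regime:
            return painting
    raise RuntimeError(
        f"could not find a painting with >= {min_tips_per_regime} tips per "
        f"regime in {max_retries} tries"
    )


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulated dataset."""

    n_tips: int = 100
    birth_rate: float = 1.0
    death_rate: float = 0.0
    newick: str | None = None  # fixed tree instead of birth-death
    n_regimes: int = 1
    model_kind: str = "multi_optima"
    multilevel: str = "none"
    half_life: float = 0.25
    stationary_var: float = 0.01
    theta: tuple = (0.0,)
    beta: tuple = ()  # flat (p,) or nested (K rows) for varying slopes
    sigma2_x: float = 1.0
    me_response_sd: float = 0.0
    me_predictor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.half_life <= 0 or self.stationary_var < 0:
            raise ValueError("half_life must be > 0 and stationary_var >= 0")
        if self.me_response_sd < 0 or self.me_predictor_sd < 0:
            raise ValueError("measurement-error sds must be >= 0")
        if self.sigma2_x < 0:
            raise ValueError("sigma2_x must be >= 0")
        if len(self.theta) != self.n_regimes:
            raise ValueError("theta must have one entry per regime")
        b = np.asarray(self.beta, dtype=float)
        if b.size and b.ndim == 2 and b.shape[0] != self.n_regimes:
            raise ValueError("nested beta must have one row per regime")

    def model_spec(self) -> ou_core.ModelSpec:
        b = np.asarray(self.beta, dtype=float)
        n_pred = 0 if b.size == 0 else (b.shape[-1] if b.ndim == 2 else b.shape[0])
        return ou_core.ModelSpec(
            model_kind=self.model_kind,
            multilevel=self.multilevel,
            n_regimes=self.n_regimes,
            n_predictors=n_pred,
            slope_structure="by_regime" if b.ndim == 2 else "shared",
            me_response=self.me_response_sd > 0,
            me_predictors=self.me_predictor_sd > 0,
        )


@dataclass(frozen=True)
class SimResult:
    """A simulated dataset plus the full truth record needed to re-run it."""

    config: SimConfig
    tree: Phylogeny
    painting: RegimePainting
    X_true: np.ndarray | None
    X_obs: np.ndarray | None
    X_se: np.ndarray | None
    Y_true: np.ndarray
    Y_obs: np.ndarray
    Y_se: np.ndarray
    truth: dict

    @property
    def species(self) -> tuple:
        return self.tree.tip_labels

    def write(self, out_dir) -> dict:
        """Write tree (Newick), regimes (CSV), trait table (CSV), truth (JSON).

        These four files are exactly what the fit command consumes.
        """
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        node_labels = {
            u: f"n{u}"
            for u in range(self.tree.n_nodes)
            if int(u) not in set(int(t) for t in self.tree.tip_ids)
        }
        (out / "tree.nwk").write_text(self.tree.to_newick(node_labels=node_labels))
        regs = pd.DataFrame(
            {
                "node_label": [
                    node_labels.get(u, self.tree.labels[u])
                    for u in range(self.tree.n_nodes)
                ],
                "regime": [
                    self.painting.regime_names[k] for k in self.painting.node_regime
                ],
            }
        )
        regs.to_csv(out / "regimes.csv", index=False)
        cols = {"species": list(self.species)}
        cols["Y"] = self.Y_obs
        if self.config.me_response_sd > 0:
            cols["Y_se"] = self.Y_se
        if self.X_obs is not None:
            X = np.atleast_2d(self.X_obs.T).T
            for j in range(X.shape[1]):
                name = "X" if X.shape[1] == 1 else f"X{j+1}"
                cols[name] = X[:, j]
                if self.config.me_predictor_sd > 0:
                    cols[f"{name}_se"] = np.atleast_2d(self.X_se.T).T[:, j]
        cols["regime"] = [
            self.painting.regime_names[k] for k in self.painting.tip_regimes
        ]
        pd.DataFrame(cols).to_csv(out / "traits.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))
        return {
            "tree": str(out / "tree.nwk"),
            "regimes": str(out / "regimes.csv"),
            "traits": str(out / "traits.csv"),
            "truth": str(out / "truth.json"),
        }


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate one dataset under ``config`` (tree, painting, X, Y, noise)."""
    seed = config.seed
    if config.newick:
        tree = scale_to_unit_height(parse_newick(config.newick))
    else:
        tree = simulate_tree(
            config.n_tips, config.birth_rate, config.death_rate,
            seed=int(child_rng(seed, "tree").integers(2**31)),
        )
    if config.n_regimes > 1:
        painting = random_regime_painting(
            tree, config.n_regimes, seed=child_rng(seed, "painting")
        )
    else:
        painting = paint_regimes(tree, {int(tree.root): "R0"}, regime_names=("R0",))

    spec = config.model_spec()
    params = {
        "alpha": ou_core.half_life_to_alpha(config.half_life),
        "v": config.stationary_var,
        "theta": np.asarray(config.theta, dtype=float),
        "sigma2_x": config.sigma2_x,
    }
    X_true = X_obs = X_se = None
    if spec.has_slopes:
        params["beta"] = np.asarray(config.beta, dtype=float)
        X_true = simulate_bm(tree, config.sigma2_x, seed=child_rng(seed, "bm"))
        X_obs, X_se = add_measurement_error(
            X_true, config.me_predictor_sd, seed=child_rng(seed, "me_predictor")
        )
    Y_true = simulate_response(
        tree, painting, spec, params, X=X_true, seed=child_rng(seed, "response")
    )
    Y_obs, Y_se = add_measurement_error(
        Y_true, config.me_response_sd, seed=child_rng(seed, "me_response")
    )
    truth = {
        "half_life": config.half_life,
        "stationary_var": config.stationary_var,
        "theta": list(np.asarray(config.theta, dtype=float)),
        "beta": np.asarray(config.beta, dtype=float).tolist(),
        "sigma2_x": config.sigma2_x,
        "me_response_sd": config.me_response_sd,
        "me_predictor_sd": config.me_predictor_sd,
        "model_kind": config.model_kind,
        "multilevel": config.multilevel,
        "n_regimes": config.n_regimes,
        "n_tips": int(tree.n_tips),
        "seed": int(seed),
        "regime_names": list(painting.regime_names),
        "tip_counts_per_regime": np.bincount(
            painting.tip_regimes, minlength=config.n_regimes
        ).tolist(),
    }
    return SimResult(
        config=config,
        tree=tree,
        painting=painting,
        X_true=X_true,
        X_obs=X_obs,
        X_se=X_se,
        Y_true=Y_true,
        Y_obs=Y_obs,
        Y_se=Y_se,
        truth=truth,
    )


def validation_fixture(seed: int = 0, n_tips: int = 100) -> SimResult:
    """The package's standard validation dataset.

    A ~100-tip unit-height Yule tree with 4 clade-structured regimes (each
    covering at least 5 tips), a Brownian predictor with sigma2 = 1, and a
    multi-optima adaptive varying-effects response with half-life 0.1 (fast
    adaptation), stationary variance 0.01, optima theta = (1, 2, 3, 4),
    optimal slopes beta = (0.75, 0.5, 0.35, 0.25), and Normal(0, 0.01)
    measurement error added to both variables (with 0.01 reported as the SE).
    """
    config = SimConfig(
        n_tips=n_tips,
        n_regimes=4,
        model_kind="multi_optima_adaptive",
        multilevel="varying_effects",
        half_life=0.1,
        stationary_var=0.01,
        theta=(1.0, 2.0, 3.0, 4.0),
        beta=((0.75,), (0.5,), (0.35,), (0.25,)),
        sigma2_x=1.0,
        me_response_sd=0.01,
        me_predictor_sd=0.01,
        seed=seed,
    )
    return simulate_dataset(config)
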