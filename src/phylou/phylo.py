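"""Phylogeny handling: parsing, scaling, shared times, regime painting, Mk reconstruction.

Trees are rooted time trees.  Node times are measured forward from the root
(root at time 0, tips at their depth), which matches the "evolve half the
distance from the ancestral state" framing of the half-life parameter.  All
matrices produced from a tree follow the tree's stored tip order (order of
first appearance in the Newick string); every exported table carries tip
labels so the order is explicit.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import dendropy
from scipy.linalg import expm
from scipy.optimize import minimize

__all__ = [
    "Phylogeny",
    "SharedTimes",
    "RegimePainting",
    "MkResult",
    "parse_newick",
    "scale_to_unit_height",
    "shared_times",
    "paint_regimes",
    "mk_ancestral_states",
    "painting_from_mk",
]


@dataclass(frozen=True)
class Phylogeny:
    """Array-backed rooted time tree.

    ``parents[i]`` is the parent node id of node ``i`` (-1 for the root);
    ``branch_lengths[i]`` the length of the edge above node ``i`` (nan for the
    root); ``labels[i]`` the node label (taxon label for tips, may be ``None``
    for internal nodes).  ``scale_factor`` carries the original tree height
    after unit-height rescaling so estimates can be back-transformed.
    """

    parents: np.ndarray
    branch_lengths: np.ndarray
    labels: tuple
    tip_ids: np.ndarray
    scale_factor: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return int(np.where(self.parents < 0)[0][0])

    @property
    def node_times(self) -> np.ndarray:
        """Time of each node measured from the root (root = 0)."""
        t = np.zeros(self.n_nodes)
        for i in self._preorder()[1:]:
            t[i] = t[self.parents[i]] + self.branch_lengths[i]
        return t

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[i] for i in self.tip_ids)

    @property
    def tip_depths(self) -> np.ndarray:
        return self.node_times[self.tip_ids]

    @property
    def height(self) -> float:
        return float(self.tip_depths.max())

    def children(self) -> list:
        out = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                out[p].append(i)
        return out

    def _preorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        kids = self.children()
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(reversed(kids[u]))
        return np.asarray(order)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = self.tip_depths
        return bool(np.ptp(d) <= tol * max(self.height, 1.0))

    def path_to_root(self, node: int) -> list:
        path = [node]
        while self.parents[path[-1]] >= 0:
            path.append(int(self.parents[path[-1]]))
        return path

    def label_to_node(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels) if lab}

    def to_newick(self, node_labels: Mapping[int, str] | None = None) -> str:
        """Newick string with branch lengths; optional internal-node labels."""
        kids = self.children()

        def rec(u: int) -> str:
            lab = None
            if node_labels is not None and u in node_labels:
                lab = node_labels[u]
            elif self.labels[u]:
                lab = self.labels[u]
            lab = lab or ""
            if kids[u]:
                inner = ",".join(rec(c) for c in kids[u])
                s = f"({inner}){lab}"
            else:
                s = lab
            if self.parents[u] >= 0:
                s += f":{self.branch_lengths[u]:.17g}"
            return s

        return rec(self.root) + ";"


@dataclass(frozen=True)
class SharedTimes:
    """Pairwise tree times in the tree's tip order.

    ``s[i, j]`` is the time of the most recent common ancestor of tips i and j
    measured from the root (``s[i, i]`` is tip i's depth); ``d[i, j]`` the
    patristic time distance ``depth_i + depth_j - 2 s[i, j]``.
    """

    s: np.ndarray
    d: np.ndarray
    tip_depths: np.ndarray
    tip_labels: tuple


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of every branch segment (and the root) to one of K regimes.

    A branch carries the regime of its *parent* node; painting a node starts a
    new regime on the branches below it.  ``tip_lineages[i]`` decomposes tip
    i's root-to-tip path into contiguous ``(regime_index, t_start, t_end)``
    segments tiling ``[0, depth_i]``.
    """

    regime_names: tuple
    node_regime: np.ndarray
    tip_lineages: tuple
    tip_ids: np.ndarray
    root: int

    @property
    def n_regimes(self) -> int:
        return len(self.regime_names)

    @property
    def root_regime(self) -> int:
        return int(self.node_regime[self.root])

    @property
    def tip_regimes(self) -> np.ndarray:
        """Regime index of each tip node, in tip order."""
        return self.node_regime[self.tip_ids]


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on all non-root edges.  Polytomies are kept;
    zero-length *internal* branches are collapsed into polytomies with a
    warning; zero-length terminal branches are accepted.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer/reader errors
        raise ValueError(f"malformed Newick string: {exc}") from None

    # collapse zero-length internal branches into polytomies
    collapsed = 0
    for nd in list(tree.postorder_node_iter()):
        if nd.parent_node is not None and not nd.is_leaf() and nd.edge.length == 0:
            parent = nd.parent_node
            for ch in list(nd.child_nodes()):
                nd.remove_child(ch)
                parent.add_child(ch)
            parent.remove_child(nd)
            collapsed += 1
    if collapsed:
        warnings.warn(
            f"collapsed {collapsed} zero-length internal branch(es) into polytomies"
        )

    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parents = np.full(len(nodes), -1, dtype=int)
    blen = np.full(len(nodes), np.nan)
    labels: list = [None] * len(nodes)
    tip_ids = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parents[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError(
                    f"missing branch length on the edge above node "
                    f"{nd.taxon.label if nd.taxon else nd.label or i!r}"
                )
            blen[i] = float(nd.edge.length)
            if blen[i] < 0:
                raise ValueError("negative branch length")
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon else nd.label
            if not lab or not str(lab).strip():
                raise ValueError("empty tip label")
            labels[i] = str(lab).strip()
            tip_ids.append(i)
        else:
            labels[i] = str(nd.label).strip() if nd.label else None

    tips = [labels[i] for i in tip_ids]
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")

    return Phylogeny(
        parents=parents,
        branch_lengths=blen,
        labels=tuple(labels),
        tip_ids=np.asarray(tip_ids, dtype=int),
    )


def scale_to_unit_height(tree: Phylogeny) -> Phylogeny:
    """Rescale so the maximum root-to-tip time is 1; store the original height.

    Idempotent: applying twice equals applying once.  ``scale_factor`` is the
    original tree height, used to back-transform half-lives into time units.
    """
    h = tree.height
    if not np.isfinite(h) or h <= 0:
        raise ValueError(f"tree height must be positive, got {h}")
    bl = tree.branch_lengths / h
    return replace(
        tree, branch_lengths=bl, scale_factor=float(tree.scale_factor * h)
    )


def shared_times(tree: Phylogeny) -> SharedTimes:
    """MRCA-time and patristic-distance matrices over tips, in tip order."""
    n = tree.n_tips
    tip_pos = {int(t): i for i, t in enumerate(tree.tip_ids)}
    times = tree.node_times
    kids = tree.children()
    s = np.zeros((n, n))
    # post-order accumulation of tip sets; cross-child pairs coalesce here
    below: dict = {}
    for u in tree._preorder()[::-1]:
        if not kids[u]:
            below[u] = [tip_pos[u]]
            continue
        groups = [below.pop(c) for c in kids[u]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        s[i, j] = s[j, i] = times[u]
        below[u] = [i for g in groups for i in g]
    depths = tree.tip_depths
    np.fill_diagonal(s, depths)
    d = depths[:, None] + depths[None, :] - 2.0 * s
    return SharedTimes(s=s, d=d, tip_depths=depths, tip_labels=tree.tip_labels)


def paint_regimes(
    tree: Phylogeny,
    assignments: Mapping,
    regime_names: Sequence[str] | None = None,
) -> RegimePainting:
    """Build a regime painting from node→regime assignments.

    ``assignments`` keys are node labels (tips or labeled internal nodes) or
    integer node ids; values are regime names.  Unpainted nodes inherit the
    regime of their nearest painted ancestor; the root must be painted.
    """
    lab2node = tree.label_to_node()
    painted: dict = {}
    for key, reg in assignments.items():
        if isinstance(key, (int, np.integer)):
            node = int(key)
            if not 0 <= node < tree.n_nodes:
                raise ValueError(f"node id {node} out of range")
        else:
            if str(key) not in lab2node:
                raise ValueError(f"unknown node label {key!r} in regime assignments")
            node = lab2node[str(key)]
        painted[node] = str(reg)

    if regime_names is None:
        regime_names = sorted(set(painted.values()))
    regime_names = tuple(regime_names)
    reg_idx = {r: k for k, r in enumerate(regime_names)}
    for node, reg in painted.items():
        if reg not in reg_idx:
            raise ValueError(
                f"regime {reg!r} (node {node}) not in regime_names {regime_names}"
            )

    root = tree.root
    if root not in painted:
        raise ValueError("the root must be assigned a regime")

    node_regime = np.full(tree.n_nodes, -1, dtype=int)
    for u in tree._preorder():
        if u in painted:
            node_regime[u] = reg_idx[painted[u]]
        else:
            node_regime[u] = node_regime[tree.parents[u]]

    times = tree.node_times
    lineages = []
    for tip in tree.tip_ids:
        path = tree.path_to_root(int(tip))[::-1]  # root ... tip
        segs = []
        for parent, child in zip(path[:-1], path[1:]):
            reg = int(node_regime[parent])  # a branch carries its parent's regime
            t0, t1 = float(times[parent]), float(times[child])
            if segs and segs[-1][0] == reg:
                segs[-1] = (reg, segs[-1][1], t1)
            else:
                segs.append((reg, t0, t1))
        lineages.append(tuple(segs))

    return RegimePainting(
        regime_names=regime_names,
        node_regime=node_regime,
        tip_lineages=tuple(lineages),
        tip_ids=tree.tip_ids,
        root=root,
    )


# ---------------------------------------------------------------------------
# Mk ancestral state reconstruction
# ---------------------------------------------------------------------------

RATE_MODELS = ("ER", "SYM", "ARD")


@dataclass(frozen=True)
class MkResult:
    """Fitted Mk model and marginal ancestral state reconstruction.

    ``node_marginals[u]`` holds the scaled likelihoods (summing to 1) of each
    state at node u under the maximum-likelihood rates with a uniform root
    state distribution; ``ml_states[u]`` is the argmax state index.
    """

    rate_model: str
    states: tuple
    rates: np.ndarray  # free off-diagonal rate parameters
    Q: np.ndarray  # full generator matrix
    log_likelihood: float
    aic: float
    node_marginals: np.ndarray  # (n_nodes, K)
    ml_states: np.ndarray  # (n_nodes,) state indices

    @property
    def n_params(self) -> int:
        return len(self.rates)


def _mk_generator(rates: np.ndarray, k: int, rate_model: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if rate_model == "ER":
        Q[:] = rates[0]
    elif rate_model == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    else:  # ARD, row-major off-diagonal order
        off = ~np.eye(k, dtype=bool)
        Q[off] = rates
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _mk_n_rates(k: int, rate_model: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[rate_model]


def _mk_passes(tree: Phylogeny, tip_state_idx: dict, Q: np.ndarray):
    """Pruning down-pass and marginal up-pass.  Returns (loglik, marginals)."""
    k = Q.shape[0]
    kids = tree.children()
    order = tree._preorder()
    P = {}  # transition matrix for the branch above each non-root node
    for u in order[1:]:
        P[u] = expm(Q * tree.branch_lengths[u])

    L = np.zeros((tree.n_nodes, k))  # scaled partial likelihoods below
    logscale = np.zeros(tree.n_nodes)
    for u in order[::-1]:
        if not kids[u]:
            L[u, tip_state_idx[u]] = 1.0
            continue
        part = np.ones(k)
        sc = 0.0
        for c in kids[u]:
            part = part * (P[c] @ L[c])
            sc += logscale[c]
        m = part.max()
        if m <= 0 or not np.isfinite(m):
            raise ValueError("non-finite or zero Mk likelihood (rates too extreme)")
        L[u] = part / m
        logscale[u] = sc + np.log(m)

    root = tree.root
    prior = np.full(k, 1.0 / k)  # uniform root state distribution
    loglik = float(np.log(prior @ L[root]) + logscale[root])

    # up-pass: likelihood of everything outside each node's subtree
    A = np.zeros((tree.n_nodes, k))
    A[root] = prior
    for u in order:
        if not kids[u]:
            continue
        down = {c: P[c] @ L[c] for c in kids[u]}
        for c in kids[u]:
            sib = np.ones(k)
            for w in kids[u]:
                if w != c:
                    sib = sib * down[w]
            Ac = (A[u] * sib) @ P[c]
            tot = Ac.sum()
            A[c] = Ac / tot if tot > 0 else Ac

    marg = A * L
    marg /= marg.sum(axis=1, keepdims=True)
    return loglik, marg


def mk_ancestral_states(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    rate_model: str = "ER",
    n_starts: int = 3,
    seed: int = 0,
    fixed_rates: np.ndarray | None = None,
) -> MkResult:
    """Fit an Mk model by maximum likelihood and reconstruct marginal states.

    The transition-rate matrix follows one of three structures — equal rates
    (ER), symmetric (SYM), or all rates different (ARD) — and rates are
    maximized numerically from multiple seeded starts (the ARD pruning
    likelihood can be multi-modal).  The root state distribution is uniform.
    Rates are box-constrained to [1e-8, 100] per unit tree height.
    ``fixed_rates`` skips the optimization and reconstructs at the given
    rates.
    """
    if rate_model not in RATE_MODELS:
        raise ValueError(f"rate_model must be one of {RATE_MODELS}")
    missing = [lab for lab in tree.tip_labels if lab not in tip_states]
    if missing:
        raise ValueError(f"tips without a state: {missing}")

    states = tuple(sorted({str(tip_states[lab]) for lab in tree.tip_labels}))
    k = len(states)
    if k < 2:
        raise ValueError(
            "only one state observed at the tips; ancestral reconstruction is "
            "trivial — paint a single regime instead"
        )
    sidx = {s: i for i, s in enumerate(states)}
    tip_state_idx = {
        int(t): sidx[str(tip_states[tree.labels[t]])] for t in tree.tip_ids
    }

    n_rates = _mk_n_rates(k, rate_model)
    lo, hi = 1e-8, 100.0

    def negloglik(log_rates):
        Q = _mk_generator(np.exp(log_rates), k, rate_model)
        try:
            ll, _ = _mk_passes(tree, tip_state_idx, Q)
        except ValueError:
            return 1e10
        return -ll

    if fixed_rates is not None:
        rates = np.broadcast_to(np.asarray(fixed_rates, dtype=float),
                                (n_rates,)).copy()
        Q = _mk_generator(rates, k, rate_model)
        loglik, marg = _mk_passes(tree, tip_state_idx, Q)
        return _mk_result(rate_model, states, rates, Q, loglik, marg, n_rates)

    rng = np.random.default_rng(seed)
    # crude empirical scale: one change per tree height
    best = None
    for s in range(n_starts):
        x0 = np.log(np.clip(rng.lognormal(0.0, 1.0, size=n_rates) / tree.height,
                            lo, hi))
        res = minimize(
            negloglik, x0, method="L-BFGS-B",
            bounds=[(np.log(lo), np.log(hi))] * n_rates,
        )
        if best is None or res.fun < best.fun:
            best = res

    rates = np.exp(best.x)
    Q = _mk_generator(rates, k, rate_model)
    loglik, marg = _mk_passes(tree, tip_state_idx, Q)
    if not np.isfinite(loglik):
        raise ValueError("non-finite Mk likelihood at the optimum")
    return _mk_result(rate_model, states, rates, Q, loglik, marg, n_rates)


def _mk_result(rate_model, states, rates, Q, loglik, marg, n_rates) -> MkResult:
    ml = np.argmax(marg, axis=1)
    near = np.isclose(marg, marg.max(axis=1, keepdims=True), rtol=0, atol=1e-9)
    tied = near.sum(axis=1) > 1
    if tied.any():
        warnings.warn(
            f"{int(tied.sum())} node(s) had tied marginal states; "
            "ties broken by lowest state index"
        )
        for u in np.where(tied)[0]:
            ml[u] = int(np.argmax(near[u]))

    aic = 2.0 * n_rates - 2.0 * loglik
    return MkResult(
        rate_model=rate_model,
        states=states,
        rates=rates,
        Q=Q,
        log_likelihood=loglik,
        aic=aic,
        node_marginals=marg,
        ml_states=ml,
    )


def painting_from_mk(
    tree: Phylogeny,
    mk_result: MkResult,
    tip_states: Mapping[str, str],
) -> RegimePainting:
    """Regime painting from an Mk reconstruction.

    Internal nodes take their maximum-likelihood reconstructed state; tips take
    their observed state.  Regime names are the Mk state set.
    """
    if mk_result.node_marginals.shape[0] != tree.n_nodes:
        raise ValueError("MkResult does not match this tree")
    assignments: dict = {}
    tipset = set(int(t) for t in tree.tip_ids)
    for u in range(tree.n_nodes):
        if u in tipset:
            assignments[u] = str(tip_states[tree.labels[u]])
        else:
            assignments[u] = mk_result.states[int(mk_result.ml_states[u])]
    return paint_regimes(tree, assignments, regime_names=mk_result.states)
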