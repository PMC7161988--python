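"""Phylogenetic model of duplicate-gene loss with hidden subgenome tracking.

Six states describe a pillar's copy status at any point on the species
tree: U (undifferentiated duplicate), F (fixed duplicate, permanently
retained), C1/C2 (converging states committed to keeping the subgenome-1
or subgenome-2 copy) and S1/S2 (single copy, the subgenome-1 or
subgenome-2 gene surviving).  Subgenome 1 is by construction the less
fractionated parent: the biased-fractionation parameter ``eps1 <= 1``
scales the rate of losing the subgenome-1 copy relative to the
subgenome-2 copy.

The generator (states ordered U, F, C1, C2, S1, S2) is::

    U -> F  : gamma            (duplicate fixation)
    U -> C1 : delta            (conversion, keeping subgenome 1)
    U -> C2 : delta * eps2     (conversion, keeping subgenome 2)
    U -> S1 : 1                (loss of the subgenome-2 copy; base rate)
    U -> S2 : eps1             (loss of the subgenome-1 copy)
    Ck -> Sk: eta * (1 + eps1) (convergent loss completes)

with F, S1 and S2 absorbing.  The base loss rate U -> S1 is fixed at 1,
so branch lengths are expected relative loss intensities ("alpha * t").
With ``eta = 1`` the total loss rate out of a converging state equals the
total loss rate out of U.

Observations are per-genome copy states of pillars (duplicated / single
with the survivor on track 1 or 2).  Which physical track corresponds to
which subgenome is hidden and follows a Markov chain along the pillar
order over the 2^n tracking configurations (n genomes), with a single
flip probability ``theta`` per genome per adjacent pillar pair.  The
likelihood sums the Felsenstein-pruning emission of every pillar over all
configuration paths with an exact forward recursion; the root (the
duplication event itself) is in state U with probability 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from ._hmm import backward_scaled, forward_scaled
from .dcs_pipeline import AncestralOrder, Pillar
from .io_formats import PhyloTree, ValidationError

logger = logging.getLogger("wgdloss.model")

__all__ = [
    "STATES",
    "WGDModelSpec",
    "FitResult",
    "OptimizerConfig",
    "build_rate_matrix",
    "transition_matrix",
    "pillar_emission",
    "forward_loglik",
    "fit",
    "lrt",
    "orthology_posteriors",
    "expected_losses_per_branch",
    "classify_fates",
    "compare_topologies",
    "observation_matrix",
]

STATES = ("U", "F", "C1", "C2", "S1", "S2")
U, F, C1, C2, S1, S2 = range(6)
_DUPLICATED = (U, F, C1, C2)


class OptimizationError(RuntimeError):
    """Raised when an optimisation result is internally inconsistent."""


# ---------------------------------------------------------------------------
# model catalogue
# ---------------------------------------------------------------------------

#: free parameters, whether eps2 is tied to eps1, and fixed values per model
_MODEL_TABLE: dict[str, tuple[tuple[str, ...], bool, dict[str, float]]] = {
    "wgd-n": ((), False, {"gamma": 0.0, "delta": 0.0, "eps1": 1.0, "eps2": 1.0, "eta": 1.0}),
    "wgd-b": (("eps1",), True, {"gamma": 0.0, "delta": 0.0, "eta": 1.0}),
    "wgd-f": (("gamma",), False, {"delta": 0.0, "eps1": 1.0, "eps2": 1.0, "eta": 1.0}),
    "wgd-c": (("delta", "eta"), False, {"gamma": 0.0, "eps1": 1.0, "eps2": 1.0}),
    "wgd-bf": (("gamma", "eps1"), True, {"delta": 0.0, "eta": 1.0}),
    "wgd-cf": (("gamma", "delta", "eta"), False, {"eps1": 1.0, "eps2": 1.0}),
    "wgd-bc": (("delta", "eta", "eps1"), True, {"gamma": 0.0}),
    "wgd-bcf": (("gamma", "delta", "eta", "eps1"), True, {}),
    "wgd-bcnf": (("gamma", "delta", "eta", "eps1"), False, {"eps2": 1.0}),
    "wgd-b2cf": (("gamma", "delta", "eta", "eps1", "eps2"), False, {}),
    "wgd-bcnbnf": (("gamma", "delta", "eps1"), False, {"eps2": 1.0, "eta": 1.0}),
}

_PARAM_BOUNDS = {
    "gamma": (0.0, 50.0),
    "delta": (0.0, 50.0),
    "eps1": (1e-3, 1.0),
    "eps2": (1e-3, 1.0),
    "eta": (1e-3, 50.0),
}

_DEFAULT_START = {"gamma": 0.1, "delta": 0.1, "eps1": 0.9, "eps2": 0.9, "eta": 1.0}


def _canonical_name(name: str) -> str:
    return name.lower().replace("^", "").replace("_", "").replace(" ", "")


@dataclass
class WGDModelSpec:
    """A named loss model with its parameter values and free/fixed flags.

    ``eps1`` and ``eps2`` are constrained to (0, 1] so that subgenome 1 is
    the less fractionated parent by construction (this breaks the
    label-swap symmetry of the likelihood).  ``tie_eps`` keeps
    ``eps2 == eps1`` during fitting (the single-epsilon bias models).
    """

    name: str
    gamma: float = 0.0
    delta: float = 0.0
    eps1: float = 1.0
    eps2: float = 1.0
    eta: float = 1.0
    free: tuple[str, ...] = ()
    tie_eps: bool = False

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.delta < 0:
            raise ValidationError("gamma and delta must be >= 0")
        for nm in ("eps1", "eps2"):
            v = getattr(self, nm)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{nm} must lie in (0, 1], got {v}")
        if self.eta <= 0:
            raise ValidationError("eta must be > 0")
        if self.tie_eps:
            object.__setattr__(self, "eps2", self.eps1)

    @classmethod
    def from_name(cls, name: str, **overrides: float) -> "WGDModelSpec":
        key = _canonical_name(name)
        if key not in _MODEL_TABLE:
            raise ValidationError(
                f"unknown model {name!r}; known: {sorted(_MODEL_TABLE)}"
            )
        free, tie_eps, fixed = _MODEL_TABLE[key]
        values = dict(_DEFAULT_START)
        values.update(fixed)
        values.update(overrides)
        if tie_eps:
            values["eps2"] = values["eps1"]
        return cls(name=name, free=free, tie_eps=tie_eps, **values)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def with_values(self, **values: float) -> "WGDModelSpec":
        if self.tie_eps and "eps1" in values:
            values.setdefault("eps2", values["eps1"])
        return replace(self, **values)

    def params(self) -> dict[str, float]:
        return {
            "gamma": self.gamma,
            "delta": self.delta,
            "eps1": self.eps1,
            "eps2": self.eps2,
            "eta": self.eta,
        }


def build_rate_matrix(spec: WGDModelSpec | Mapping[str, float]) -> np.ndarray:
    """6x6 generator for the loss model; rows sum to zero."""
    if isinstance(spec, WGDModelSpec):
        p = spec.params()
    else:
        p = dict(spec)
    gamma, delta = p["gamma"], p["delta"]
    eps1, eps2, eta = p["eps1"], p["eps2"], p["eta"]
    if gamma < 0 or delta < 0 or not (0 < eps1 <= 1) or not (0 < eps2 <= 1) or eta <= 0:
        raise ValidationError("rate-matrix parameters out of range")
    Q = np.zeros((6, 6))
    Q[U, F] = gamma
    Q[U, C1] = delta
    Q[U, C2] = delta * eps2
    Q[U, S1] = 1.0
    Q[U, S2] = eps1
    Q[C1, S1] = eta * (1.0 + eps1)
    Q[C2, S2] = eta * (1.0 + eps1)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(generator: np.ndarray, b: float) -> np.ndarray:
    """exp(Q * b): the state-transition probabilities over a branch."""
    if b < 0:
        raise ValidationError(f"branch length must be >= 0, got {b}")
    P = expm(np.asarray(generator, float) * b)
    # expm of a generator can stray slightly negative; clip and renormalise
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# observations and emissions
# ---------------------------------------------------------------------------

# observation codes per genome per pillar
OBS_DUP, OBS_SINGLE_T1, OBS_SINGLE_T2 = 0, 1, 2

# leaf likelihood vectors indexed [obs, tracking bit, state]; bit 0 means
# the genome's track 1 currently carries the subgenome-1 gene
_LEAF_VECTORS = np.zeros((3, 2, 6))
_LEAF_VECTORS[OBS_DUP, :, [U, F, C1, C2]] = 1.0
_LEAF_VECTORS[OBS_SINGLE_T1, 0, S1] = 1.0
_LEAF_VECTORS[OBS_SINGLE_T1, 1, S2] = 1.0
_LEAF_VECTORS[OBS_SINGLE_T2, 0, S2] = 1.0
_LEAF_VECTORS[OBS_SINGLE_T2, 1, S1] = 1.0


def genome_order_of(tree: PhyloTree) -> list[str]:
    """Canonical genome ordering used for tracking-configuration bits."""
    return sorted(tree.leaf_names.values())


def observation_matrix(
    pillars: Sequence[Pillar],
    tree: PhyloTree,
    order: AncestralOrder | Sequence[int] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Code pillars as an (n_pillars, n_genomes) int8 matrix.

    Pillars are taken in ``order`` (identity if omitted).  Raises if a
    pillar lacks a genome present in the tree.
    """
    genomes = genome_order_of(tree)
    if order is None:
        perm = np.arange(len(pillars))
    elif isinstance(order, AncestralOrder):
        perm = order.permutation
    else:
        perm = np.asarray(order, dtype=np.int64)
    obs = np.zeros((len(perm), len(genomes)), dtype=np.int8)
    for row, idx in enumerate(perm):
        pillar = pillars[idx]
        for g, gid in enumerate(genomes):
            state = pillar.copy_state(gid)
            if state == "absent":
                raise ValidationError(
                    f"pillar {pillar.anchor} has no gene in genome {gid} "
                    "present in the tree"
                )
            if state == "duplicated":
                obs[row, g] = OBS_DUP
            else:
                obs[row, g] = (
                    OBS_SINGLE_T1 if pillar.filled_slot(gid) == 0 else OBS_SINGLE_T2
                )
    return obs, genomes


def _config_bits(n_genomes: int) -> np.ndarray:
    """(2^n, n) matrix of tracking bits; configuration index c has bit
    (c >> g) & 1 for genome g."""
    C = 1 << n_genomes
    c = np.arange(C)
    return ((c[:, None] >> np.arange(n_genomes)[None, :]) & 1).astype(np.int8)


def _flip_indices(n_genomes: int) -> np.ndarray:
    C = 1 << n_genomes
    c = np.arange(C)
    return np.stack([c ^ (1 << g) for g in range(n_genomes)]).astype(np.int64)


def _branch_transitions(
    tree: PhyloTree, Q: np.ndarray, branch_lengths: np.ndarray
) -> np.ndarray:
    trans = np.empty((tree.n_nodes, 6, 6))
    for i in range(tree.n_nodes):
        trans[i] = transition_matrix(Q, branch_lengths[i]) if i != tree.root else np.eye(6)
    return trans


def _leaf_nodes_by_genome(tree: PhyloTree, genomes: Sequence[str]) -> list[int]:
    name_to_node = {v: k for k, v in tree.leaf_names.items()}
    missing = [g for g in genomes if g not in name_to_node]
    if missing:
        raise ValidationError(f"genomes {missing} absent from tree")
    return [name_to_node[g] for g in genomes]


def _emissions(
    obs: np.ndarray,
    bits: np.ndarray,
    tree: PhyloTree,
    trans: np.ndarray,
    genomes: Sequence[str],
    return_partials: bool = False,
):
    """Pruning likelihood of every pillar under every configuration.

    obs: (P, G) observation codes; bits: (C, G) tracking bits.
    Returns E (P, C), and optionally the per-node upward partials.
    """
    leaf_node = _leaf_nodes_by_genome(tree, genomes)
    node_of_genome = {n: g for g, n in enumerate(leaf_node)}
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        node = int(node)
        if not tree.children[node]:
            g = node_of_genome[node]
            partials[node] = _LEAF_VECTORS[obs[:, g]][:, bits[:, g], :]
        else:
            part = None
            for child in tree.children[node]:
                msg = np.einsum(
                    "pcb,ab->pca", partials[child], trans[child], optimize=True
                )
                part = msg if part is None else part * msg
                if not return_partials:
                    del partials[child]
            partials[node] = part
    E = partials[tree.root][:, :, U].copy()
    if return_partials:
        return E, partials
    return E


def pillar_emission(
    pillar: Pillar,
    config: Mapping[str, int] | Sequence[int],
    tree: PhyloTree,
    spec: WGDModelSpec,
    branch_lengths: np.ndarray | None = None,
) -> float:
    """Felsenstein-pruning likelihood of one pillar under one tracking
    configuration (bit per genome: 0 = track 1 holds the subgenome-1 gene).
    """
    genomes = genome_order_of(tree)
    if isinstance(config, Mapping):
        bits = np.array([[config[g] for g in genomes]], dtype=np.int8)
    else:
        bits = np.asarray(config, dtype=np.int8).reshape(1, -1)
    obs, _ = observation_matrix([pillar], tree)
    Q = build_rate_matrix(spec)
    blen = tree.branch_length if branch_lengths is None else branch_lengths
    trans = _branch_transitions(tree, Q, blen)
    E = _emissions(obs, bits, tree, trans, genomes)
    return float(E[0, 0])


def forward_loglik(
    pillars: Sequence[Pillar],
    tree: PhyloTree,
    spec: WGDModelSpec,
    theta: float,
    order: AncestralOrder | Sequence[int] | None = None,
    branch_lengths: np.ndarray | None = None,
) -> float:
    """Exact ln-likelihood of the ordered pillars.

    Sums the per-pillar pruning emissions over all tracking-configuration
    sequences with the forward algorithm; the initial configuration
    distribution is uniform over the 2^n configurations.
    """
    if not (0.0 <= theta <= 0.5):
        raise ValidationError(f"theta must lie in [0, 0.5], got {theta}")
    obs, genomes = observation_matrix(pillars, tree, order)
    bits = _config_bits(len(genomes))
    Q = build_rate_matrix(spec)
    blen = tree.branch_length if branch_lengths is None else branch_lengths
    trans = _branch_transitions(tree, Q, blen)
    E = _emissions(obs, bits, tree, trans, genomes)
    flips = _flip_indices(len(genomes))
    ll, _, _ = forward_scaled(E, flips, float(theta))
    return float(ll)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    """Bounded quasi-Newton settings for maximum-likelihood fitting.

    ``n_starts`` seeded starting points are tried (the first is the
    model's own values); branch lengths are optimised in log space.
    ``theta`` fixes the flip probability when given; otherwise theta is a
    free parameter started at ``theta_start``.
    """

    n_starts: int = 3
    maxiter: int = 500
    ftol: float = 1e-9
    fit_branch_lengths: bool = True
    theta: float | None = None
    theta_start: float = 0.02
    blen_bounds: tuple[float, float] = (1e-4, 10.0)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a loss model to ordered pillars."""

    spec: WGDModelSpec
    theta: float
    branch_lengths: np.ndarray
    loglik: float
    converged: bool
    message: str
    n_pillars: int
    tree: PhyloTree = field(repr=False)
    obs: np.ndarray = field(repr=False)
    genomes: list[str] = field(repr=False, default_factory=list)

    @property
    def params(self) -> dict[str, float]:
        out = self.spec.params()
        out["theta"] = self.theta
        return out

    def branch_table(self) -> pd.DataFrame:
        labels = self.tree.branch_labels()
        rows = [
            {"node": i, "clade": labels[i], "branch_length": self.branch_lengths[i]}
            for i in range(self.tree.n_nodes)
            if i != self.tree.root
        ]
        return pd.DataFrame(rows)


def _pack(
    spec: WGDModelSpec, cfg: OptimizerConfig, tree: PhyloTree
) -> tuple[np.ndarray, list[tuple[float, float]], list[str]]:
    x0: list[float] = []
    bounds: list[tuple[float, float]] = []
    names: list[str] = []
    for nm in spec.free:
        x0.append(getattr(spec, nm))
        bounds.append(_PARAM_BOUNDS[nm])
        names.append(nm)
    if cfg.theta is None:
        x0.append(cfg.theta_start)
        bounds.append((1e-6, 0.5))
        names.append("theta")
    if cfg.fit_branch_lengths:
        lo, hi = cfg.blen_bounds
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            b = max(tree.branch_length[i], lo)
            x0.append(math.log(b))
            bounds.append((math.log(lo), math.log(hi)))
            names.append(f"log_b{i}")
    return np.asarray(x0), bounds, names


def _unpack(
    x: np.ndarray, spec: WGDModelSpec, cfg: OptimizerConfig, tree: PhyloTree
) -> tuple[WGDModelSpec, float, np.ndarray]:
    i = 0
    values: dict[str, float] = {}
    for nm in spec.free:
        values[nm] = float(x[i])
        i += 1
    new_spec = spec.with_values(**values) if values else spec
    theta = cfg.theta if cfg.theta is not None else float(x[i])
    if cfg.theta is None:
        i += 1
    blen = tree.branch_length.copy()
    if cfg.fit_branch_lengths:
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            blen[node] = math.exp(float(x[i]))
            i += 1
    return new_spec, theta, blen


def fit(
    pillars: Sequence[Pillar],
    order: AncestralOrder | Sequence[int] | None,
    tree: PhyloTree,
    spec: WGDModelSpec | str,
    optimizer_cfg: OptimizerConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of ``spec`` to the ordered pillars.

    Free parameters are the model's free rates, optionally theta, and
    (log-parameterised) branch lengths.  ``n_starts`` seeded restarts are
    run and the best local optimum returned; the result is deterministic
    given ``seed``.  Non-convergence is flagged on the result, never
    silent.
    """
    if isinstance(spec, str):
        spec = WGDModelSpec.from_name(spec)
    cfg = optimizer_cfg or OptimizerConfig()
    obs, genomes = observation_matrix(pillars, tree, order)
    bits = _config_bits(len(genomes))
    flips = _flip_indices(len(genomes))

    def neg_loglik(x: np.ndarray) -> float:
        cur, theta, blen = _unpack(x, spec, cfg, tree)
        Q = build_rate_matrix(cur)
        trans = _branch_transitions(tree, Q, blen)
        E = _emissions(obs, bits, tree, trans, genomes)
        ll, _, _ = forward_scaled(E, flips, theta)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0, bounds, names = _pack(spec, cfg, tree)
    if len(x0) == 0:
        # fully constrained model: nothing to optimise, just evaluate
        ll = -neg_loglik(x0)
        return FitResult(
            spec=spec,
            theta=float(cfg.theta),
            branch_lengths=tree.branch_length.copy(),
            loglik=ll,
            converged=True,
            message="no free parameters",
            n_pillars=obs.shape[0],
            tree=tree,
            obs=obs,
            genomes=list(genomes),
        )
    rng = np.random.default_rng(seed)
    best = None
    for start in range(cfg.n_starts):
        if start == 0:
            x_init = x0.copy()
        else:
            x_init = np.array(
                [
                    np.clip(v + rng.normal(0, 0.3 * max(abs(v), 0.1)), lo, hi)
                    for v, (lo, hi) in zip(x0, bounds)
                ]
            )
        res = minimize(
            neg_loglik,
            x_init,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.maxiter, "ftol": cfg.ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
    fitted_spec, theta, blen = _unpack(best.x, spec, cfg, tree)
    result = FitResult(
        spec=fitted_spec,
        theta=theta,
        branch_lengths=blen,
        loglik=-float(best.fun),
        converged=bool(best.success),
        message=str(best.message),
        n_pillars=obs.shape[0],
        tree=tree,
        obs=obs,
        genomes=list(genomes),
    )
    if not result.converged:
        logger.warning("fit(%s) did not converge: %s", fitted_spec.name, result.message)
    return result


def lrt(fit_null: FitResult, fit_alt: FitResult, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits; statistic clamped at zero."""
    delta = 2.0 * (fit_alt.loglik - fit_null.loglik)
    tol = 1e-4 * max(1.0, abs(fit_null.loglik))
    if delta < -tol:
        raise OptimizationError(
            f"alternative lnL {fit_alt.loglik:.6f} below null "
            f"{fit_null.loglik:.6f}: optimisation failure"
        )
    stat = max(0.0, delta)
    return stat, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# posteriors and loss accounting
# ---------------------------------------------------------------------------


def _fit_machinery(fit_result: FitResult):
    tree = fit_result.tree
    genomes = fit_result.genomes
    bits = _config_bits(len(genomes))
    flips = _flip_indices(len(genomes))
    Q = build_rate_matrix(fit_result.spec)
    trans = _branch_transitions(tree, Q, fit_result.branch_lengths)
    E = _emissions(fit_result.obs, bits, tree, trans, genomes)
    ll, alpha, scale = forward_scaled(E, flips, fit_result.theta)
    beta = backward_scaled(E, flips, fit_result.theta, scale)
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return bits, trans, E, post


def orthology_posteriors(fit_result: FitResult):
    """Posterior over tracking configurations per pillar.

    Returns ``(posteriors, map_config, confidence)``: the (P, 2^n)
    forward-backward posterior matrix, the index of the
    maximum-a-posteriori configuration per pillar, and its posterior mass
    (the confidence relative to the 2^n - 1 alternatives).
    """
    _, _, _, post = _fit_machinery(fit_result)
    map_config = post.argmax(axis=1)
    confidence = post[np.arange(len(post)), map_config]
    return post, map_config, confidence


def _updown_for_config(
    obs: np.ndarray,
    bit_row: np.ndarray,
    tree: PhyloTree,
    trans: np.ndarray,
    genomes: Sequence[str],
):
    """Upward partials, downward (outside) partials and per-pillar
    likelihood under one fixed tracking configuration."""
    leaf_node = _leaf_nodes_by_genome(tree, genomes)
    node_of_genome = {n: g for g, n in enumerate(leaf_node)}
    up: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        node = int(node)
        if not tree.children[node]:
            g = node_of_genome[node]
            up[node] = _LEAF_VECTORS[obs[:, g], bit_row[g]]
        else:
            part = None
            for child in tree.children[node]:
                msg = up[child] @ trans[child].T
                part = msg if part is None else part * msg
            up[node] = part
    P = obs.shape[0]
    root_prior = np.zeros((P, 6))
    root_prior[:, U] = 1.0
    # down_pre[v]: outside partial expressed at the *parent* state of v's
    # edge; down_at[v]: the same carried through the edge to v's state
    down_pre: dict[int, np.ndarray] = {}
    down_at: dict[int, np.ndarray] = {tree.root: root_prior}
    for node in reversed(tree.postorder):
        node = int(node)
        for child in tree.children[node]:
            pre = down_at[node].copy()
            for sib in tree.children[node]:
                if sib != child:
                    pre *= up[sib] @ trans[sib].T
            down_pre[child] = pre
            down_at[child] = pre @ trans[child]
    lik = (down_at[tree.root] * up[tree.root]).sum(axis=1)
    return up, down_pre, down_at, lik


def expected_losses_per_branch(fit_result: FitResult) -> pd.DataFrame:
    """Expected number of pillars entering each single-copy state per branch.

    For every branch the posterior probability that the parent node is
    still duplicated (U/F/C1/C2) while the child node is S1 or S2 is
    summed over pillars, marginalised over tracking configurations
    weighted by their posteriors.  Entering S2 means the subgenome-1 (less
    fractionated) copy was lost; entering S1 means the subgenome-2 copy
    was lost.
    """
    bits, trans, E, post = _fit_machinery(fit_result)
    tree, obs, genomes = fit_result.tree, fit_result.obs, fit_result.genomes
    n_nodes = tree.n_nodes
    entries = np.zeros((n_nodes, 2))  # columns: into S1, into S2
    for c in range(bits.shape[0]):
        w = post[:, c]
        if w.max() < 1e-12:
            continue
        up, down_pre, down_at, lik = _updown_for_config(
            obs, bits[c], tree, trans, genomes
        )
        ok = lik > 0
        for node in range(n_nodes):
            if node == tree.root:
                continue
            pre, Pb = down_pre[node], trans[node]
            for k, sk in enumerate((S1, S2)):
                # joint P(parent in dup, child = Sk | data, config)
                num = (pre[:, _DUPLICATED] * Pb[_DUPLICATED, sk]).sum(axis=1) * up[
                    node
                ][:, sk]
                contrib = np.zeros_like(num)
                contrib[ok] = num[ok] / lik[ok]
                entries[node, k] += float((w * contrib).sum())
    labels = tree.branch_labels()
    rows = []
    for node in range(n_nodes):
        if node == tree.root:
            continue
        rows.append(
            {
                "node": node,
                "clade": labels[node],
                "entries_S1": entries[node, 0],
                "entries_S2": entries[node, 1],
                "losses_subgenome1": entries[node, 1],
                "losses_subgenome2": entries[node, 0],
            }
        )
    return pd.DataFrame(rows)


def _node_state_posterior(
    fit_result: FitResult, nodes: Sequence[int]
) -> dict[int, np.ndarray]:
    """Posterior state distribution (P, 6) at each requested node."""
    bits, trans, E, post = _fit_machinery(fit_result)
    tree, obs, genomes = fit_result.tree, fit_result.obs, fit_result.genomes
    out = {node: np.zeros((obs.shape[0], 6)) for node in nodes}
    for c in range(bits.shape[0]):
        w = post[:, c]
        if w.max() < 1e-12:
            continue
        up, down_pre, down_at, lik = _updown_for_config(
            obs, bits[c], tree, trans, genomes
        )
        ok = lik > 0
        for node in nodes:
            joint = down_at[node] * up[node]
            cond = np.zeros_like(joint)
            cond[ok] = joint[ok] / lik[ok, None]
            out[node] += w[:, None] * cond
    return out


def classify_fates(
    fit_result: FitResult,
    pillars: Sequence[Pillar],
    focal_genome: str,
    threshold: float = 0.85,
    order: AncestralOrder | Sequence[int] | None = None,
):
    """Partition pillars into ohnolog / singleton / loss-timing gene sets.

    ``RootLosses`` are single-copy pillars whose state at the end of the
    shared root branch (the tree's first speciation node) is single-copy
    with posterior >= ``threshold``; ``TipLosses`` are single-copy pillars
    whose state at the focal leaf's parent is still duplicated with the
    same confidence.  Requires a unifurcating root (an explicit root
    branch).
    """
    from .downstream_stats import GeneSet

    if not (0.5 < threshold <= 1.0):
        raise ValidationError("threshold must lie in (0.5, 1]")
    tree = fit_result.tree
    if focal_genome not in tree.leaf_names.values():
        raise ValidationError(f"{focal_genome!r} is not a leaf of the tree")
    if len(tree.children[tree.root]) != 1:
        raise ValidationError(
            "loss-timing classification needs an explicit root branch "
            "(unifurcating root)"
        )
    first_speciation = tree.children[tree.root][0]
    focal_leaf = next(
        i for i, nm in tree.leaf_names.items() if nm == focal_genome
    )
    focal_parent = int(tree.parent[focal_leaf])
    node_post = _node_state_posterior(fit_result, [first_speciation, focal_parent])

    if order is None:
        perm = np.arange(len(pillars))
    elif isinstance(order, AncestralOrder):
        perm = order.permutation
    else:
        perm = np.asarray(order, dtype=np.int64)

    genomes = fit_result.genomes
    sets: dict[str, GeneSet] = {
        name: GeneSet(name=name)
        for name in (
            "Ohno_POInT",
            "Sing_POInT",
            "RootLosses",
            "TipLosses",
            "AllOhnologs",
            "AllSingle",
        )
    }
    root_single = node_post[first_speciation][:, [S1, S2]].sum(axis=1)
    parent_dup = node_post[focal_parent][:, list(_DUPLICATED)].sum(axis=1)
    for row, idx in enumerate(perm):
        pillar = pillars[idx]
        state = pillar.copy_state(focal_genome)
        genes = pillar.genes(focal_genome)
        if state == "duplicated":
            a, b = genes
            sets["Ohno_POInT"].add_pair(a, b)
            if all(pillar.copy_state(g) == "duplicated" for g in genomes):
                sets["AllOhnologs"].add_pair(a, b)
        elif state == "single":
            g = genes[0]
            sets["Sing_POInT"].add(g)
            if all(pillar.copy_state(x) == "single" for x in genomes):
                sets["AllSingle"].add(g)
            if root_single[row] >= threshold:
                sets["RootLosses"].add(g)
            elif parent_dup[row] >= threshold:
                sets["TipLosses"].add(g)
    return sets


def compare_topologies(
    trees: Sequence[PhyloTree],
    pillars: Sequence[Pillar],
    order: AncestralOrder | Sequence[int] | None,
    spec: WGDModelSpec | str,
    optimizer_cfg: OptimizerConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the model independently on each candidate topology.

    All trees must share one leaf set.  Returns a table sorted by
    ln-likelihood, best first.
    """
    leaf_sets = {frozenset(t.leaf_names.values()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValidationError("all candidate trees must share the same leaves")
    rows = []
    for i, tree in enumerate(trees):
        res = fit(pillars, order, tree, spec, optimizer_cfg=optimizer_cfg, seed=seed)
        rows.append(
            {
                "tree_index": i,
                "newick": tree.to_newick(),
                "loglik": res.loglik,
                "converged": res.converged,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("loglik", ascending=False)
        .reset_index(drop=True)
    )
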