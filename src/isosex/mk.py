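"""Mk (k-state continuous-time Markov) models of heterogamety evolution.

The Mk model treats the heterogametic type as a discrete character evolving
along a dated phylogeny under a time-homogeneous Markov chain with rate
matrix Q (rates per million years). Two parameterizations are supported:

* ER — a single shared rate for every transition;
* SYM — one rate per unordered state pair (q_ij = q_ji).

Both give a symmetric Q, whose stationary distribution is uniform; the root
prior therefore defaults to equal probabilities, which also matches how
species of unknown system are handled (all-ones partial likelihoods).

Provided operations: pruning-algorithm log-likelihood, maximum-likelihood
rate estimation, marginal ancestral state probabilities, and stochastic
character mapping by endpoint-conditioned uniformization sampling, used to
estimate expected transition counts and their directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
from scipy import optimize

from .states import CharacterStates
from .transitions import TransitionSummary

__all__ = [
    "MkModel",
    "MkFit",
    "StochasticMapResult",
    "mk_loglik",
    "fit_mk",
    "ancestral_marginals",
    "stochastic_maps",
]

_LOG_RATE_LO, _LOG_RATE_HI = math.log(1e-8), math.log(1e3)


@dataclass(frozen=True)
class MkModel:
    """State space, rate parameterization and root prior of an Mk model."""

    states: tuple[str, ...]
    parameterization: str = "ER"  # "ER" or "SYM"
    rates: np.ndarray = None  # 1 rate (ER) or k(k-1)/2 rates (SYM), per My
    root_prior: np.ndarray = None

    def __post_init__(self):
        k = len(self.states)
        if k < 2:
            raise ValueError("Mk needs at least two states")
        if self.parameterization not in ("ER", "SYM"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        n_expected = 1 if self.parameterization == "ER" else k * (k - 1) // 2
        rates = (
            np.full(n_expected, 0.01)
            if self.rates is None
            else np.atleast_1d(np.asarray(self.rates, dtype=float))
        )
        if rates.shape != (n_expected,):
            raise ValueError(
                f"{self.parameterization} with k={k} needs {n_expected} rate(s), "
                f"got shape {rates.shape}"
            )
        if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
            raise ValueError("rates must be finite and > 0")
        prior = (
            np.full(k, 1.0 / k)
            if self.root_prior is None
            else np.asarray(self.root_prior, dtype=float)
        )
        if prior.shape != (k,) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
            raise ValueError("root_prior must be a length-k probability vector")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "root_prior", prior)

    @property
    def k(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        """Symmetric rate matrix Q with rows summing to zero."""
        k = self.k
        Q = np.zeros((k, k))
        if self.parameterization == "ER":
            Q[:] = self.rates[0]
        else:
            for r, (i, j) in zip(self.rates, combinations(range(k), 2)):
                Q[i, j] = Q[j, i] = r
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def as_dict(self) -> dict:
        return {
            "states": list(self.states),
            "parameterization": self.parameterization,
            "rates": self.rates.tolist(),
            "root_prior": self.root_prior.tolist(),
        }


class _Propagator:
    """Eigendecomposition-backed matrix exponentials for a symmetric Q."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.w, self.V = np.linalg.eigh(Q)

    def __call__(self, t: float) -> np.ndarray:
        P = (self.V * np.exp(self.w * t)) @ self.V.T
        return np.clip(P, 0.0, None)


def _tip_partial(state: str, space: tuple[str, ...]) -> np.ndarray:
    if state == "UNKNOWN":
        return np.ones(len(space))
    v = np.zeros(len(space))
    v[space.index(state)] = 1.0
    return v


def _check_branch_lengths(tree: dendropy.Tree):
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError(
                "Mk likelihood requires strictly positive branch lengths on "
                "all branches"
            )


def _postorder_partials(tree, tip_states, model, prop):
    """Scaled pruning partials per node plus the summed log scaling factor."""
    partials: dict = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[node] = _tip_partial(tip_states[node.taxon.label], model.states)
        else:
            v = np.ones(model.k)
            for child in node.child_nodes():
                v = v * (prop(child.edge.length) @ partials[child])
            m = v.max()
            if m <= 0:
                return partials, -math.inf
            partials[node] = v / m
            log_scale += math.log(m)
    return partials, log_scale


def _setup(tree, states, model):
    _check_branch_lengths(tree)
    tip_states = states.for_tips([l.taxon.label for l in tree.leaf_node_iter()])
    if tuple(states.state_space) != tuple(model.states):
        raise ValueError(
            f"model states {model.states} do not match the coding scheme's "
            f"space {states.state_space}"
        )
    return tip_states, _Propagator(model.rate_matrix())


def mk_loglik(
    tree: dendropy.Tree, states: CharacterStates, model: MkModel
) -> float:
    """Log-likelihood of tip states under the Mk model (pruning algorithm).

    UNKNOWN tips get all-ones partial likelihoods (equal probability across
    systems); the root is weighted by the model's root prior.
    """
    tip_states, prop = _setup(tree, states, model)
    partials, log_scale = _postorder_partials(tree, tip_states, model, prop)
    if log_scale == -math.inf:
        return -math.inf
    site = float(model.root_prior @ partials[tree.seed_node])
    if site <= 0:
        return -math.inf
    return math.log(site) + log_scale


@dataclass
class MkFit:
    """Result of maximum-likelihood rate estimation."""

    model: MkModel
    loglik: float
    converged: bool
    at_bound: bool = False
    message: str = ""


def fit_mk(
    tree: dendropy.Tree,
    states: CharacterStates,
    parameterization: str = "ER",
) -> MkFit:
    """Maximize the Mk likelihood over positive rates (log-parameterized).

    ER uses a bounded golden-section search over log rate; SYM uses
    L-BFGS-B from a deterministic ladder of starting points. A maximum
    at the lower rate bound (e.g. all tips in one state, monotone
    likelihood) is flagged via ``at_bound``.
    """
    space = states.state_space
    observed = {s for s in states.for_tips(
        [l.taxon.label for l in tree.leaf_node_iter()]).values() if s != "UNKNOWN"}
    if not observed:
        raise ValueError("no observed tip states to fit")
    k = len(space)
    n_rates = 1 if parameterization == "ER" or k == 2 else k * (k - 1) // 2

    def negloglik(log_rates: np.ndarray) -> float:
        model = MkModel(space, parameterization, np.exp(log_rates))
        return -mk_loglik(tree, states, model)

    if n_rates == 1:
        res = optimize.minimize_scalar(
            lambda x: negloglik(np.array([x])),
            bounds=(_LOG_RATE_LO, _LOG_RATE_HI),
            method="bounded",
            options={"xatol": 1e-9},
        )
        best_x = np.array([res.x])
        best_fun = res.fun
        success = bool(res.success)
        message = getattr(res, "message", "")
    else:
        # Deterministic multistart: spread log-rate levels across the window.
        starts = [np.full(n_rates, v) for v in (-6.0, -4.0, -2.0, 0.0)]
        best = None
        success, message = False, ""
        for x0 in starts:
            res = optimize.minimize(
                negloglik,
                x0,
                method="L-BFGS-B",
                bounds=[(_LOG_RATE_LO, _LOG_RATE_HI)] * n_rates,
            )
            if best is None or res.fun < best.fun:
                best = res
        best_x, best_fun = best.x, best.fun
        success, message = bool(best.success), str(best.message)

    at_bound = bool(np.any(np.abs(best_x - _LOG_RATE_LO) < 1e-3)) or bool(
        np.any(np.abs(best_x - _LOG_RATE_HI) < 1e-3)
    )
    if at_bound and len(observed) < 2:
        message = "monotone likelihood (all observed tips share one state)"
    model = MkModel(space, "ER" if n_rates == 1 else "SYM", np.exp(best_x))
    return MkFit(
        model=model,
        loglik=-float(best_fun),
        converged=success,
        at_bound=at_bound,
        message=message,
    )


def ancestral_marginals(
    tree: dendropy.Tree, states: CharacterStates, model: MkModel
) -> dict:
    """Marginal posterior state probabilities for every node (up-down pass).

    Returns ``{node: probability_vector}`` over ``model.states``; each
    vector sums to 1. Tips with observed states get point masses.
    """
    tip_states, prop = _setup(tree, states, model)
    partials, log_scale = _postorder_partials(tree, tip_states, model, prop)
    if log_scale == -math.inf:
        raise ValueError("data have zero likelihood under this model")

    # "Outside" partials G: G[root] = prior; child v of u combines u's outside
    # partial with the below-partials of v's siblings, propagated across v's
    # branch.
    G: dict = {tree.seed_node: model.root_prior.copy()}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        down = {c: prop(c.edge.length) @ partials[c] for c in children}
        for child in children:
            g = G[node].copy()
            for sib in children:
                if sib is not child:
                    g = g * down[sib]
            gv = prop(child.edge.length).T @ g
            m = gv.max()
            G[child] = gv / m if m > 0 else gv

    out: dict = {}
    for node in tree.preorder_node_iter():
        v = G[node] * partials[node]
        total = v.sum()
        if total <= 0:
            raise ValueError("zero marginal normalization; inconsistent data")
        out[node] = v / total
    return out


@dataclass
class StochasticMapResult:
    """Mean transition counts plus the individual sampled histories."""

    mean: TransitionSummary
    per_map: list[TransitionSummary]
    histories: list[list[tuple]]  # (edge_id, rel_time, from_state, to_state)


class _Uniformizer:
    """Endpoint-conditioned path sampling by uniformization.

    The chain is embedded in a Poisson process of rate mu >= max_i(-Q_ii)
    with one-step matrix R = I + Q/mu; self-transitions of R are "virtual"
    and do not count as character changes.
    """

    def __init__(self, Q: np.ndarray, prop: _Propagator):
        self.Q = Q
        self.prop = prop
        self.mu = 1.05 * float(np.max(-np.diag(Q)))
        k = Q.shape[0]
        self.R = np.eye(k) + Q / self.mu if self.mu > 0 else np.eye(k)
        self._powers = [np.eye(k), self.R]

    def _rpow(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def sample_path(self, a: int, b: int, t: float, rng) -> list[tuple[float, int, int]]:
        """Jump times and states of one endpoint-conditioned path a->b over t.

        Returns [(time, from, to), ...] for *real* changes only.
        """
        if self.mu == 0.0:
            return []
        p_ab = float(self.prop(t)[a, b])
        if p_ab <= 0:
            raise ValueError("endpoint pair has zero transition probability")
        # Sample the number of uniformized jumps N | endpoints.
        u = rng.random() * p_ab
        mt = self.mu * t
        pois = math.exp(-mt)
        acc = 0.0
        n = 0
        while True:
            acc += pois * float(self._rpow(n)[a, b])
            if acc >= u or n > 10_000:
                break
            n += 1
            pois *= mt / n
        # Sample the uniformized chain states bridging a -> b in n steps.
        seq = [a]
        for step in range(1, n):
            prev = seq[-1]
            rem = n - step
            weights = self.R[prev, :] * self._rpow(rem)[:, b]
            total = weights.sum()
            probs = weights / total
            seq.append(int(rng.choice(len(probs), p=probs)))
        if n >= 1:
            seq.append(b)
        times = np.sort(rng.random(n)) * t
        return [
            (float(times[i]), seq[i], seq[i + 1])
            for i in range(n)
            if seq[i] != seq[i + 1]
        ]


def stochastic_maps(
    tree: dendropy.Tree,
    states: CharacterStates,
    model: MkModel,
    n_maps: int = 1000,
    seed: int = 0,
) -> StochasticMapResult:
    """Sample full character histories conditional on tips and the model.

    For each map, internal node states are drawn from their joint conditional
    distribution (root from prior x partials, then each child given its
    parent), and each branch's substitution history is sampled conditional on
    its endpoint states by uniformization. Transition counts per direction
    are averaged over ``n_maps`` maps; reproducible given ``seed``.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    tip_states, prop = _setup(tree, states, model)
    partials, log_scale = _postorder_partials(tree, tip_states, model, prop)
    if log_scale == -math.inf:
        raise ValueError("data have zero likelihood under this model")
    Q = model.rate_matrix()
    sampler = _Uniformizer(Q, prop)
    rng = np.random.default_rng(seed)
    space = model.states

    # Stable edge identifiers: head-node label for tips, postorder index else.
    edge_ids: dict = {}
    for i, node in enumerate(tree.postorder_node_iter()):
        edge_ids[node] = node.taxon.label if node.is_leaf() else f"node{i}"

    nodes_pre = list(tree.preorder_node_iter())
    per_map: list[TransitionSummary] = []
    histories: list[list[tuple]] = []
    agg: dict[tuple[str, str], float] = {}

    for _ in range(n_maps):
        node_state: dict = {}
        root = tree.seed_node
        w = model.root_prior * partials[root]
        node_state[root] = int(rng.choice(model.k, p=w / w.sum()))
        for node in nodes_pre:
            for child in node.child_nodes():
                P = prop(child.edge.length)
                w = P[node_state[node], :] * partials[child]
                node_state[child] = int(rng.choice(model.k, p=w / w.sum()))
        events: list[tuple] = []
        counts: dict[tuple[str, str], float] = {}
        for node in nodes_pre:
            for child in node.child_nodes():
                path = sampler.sample_path(
                    node_state[node], node_state[child], child.edge.length, rng
                )
                for t_rel, i, j in path:
                    pair = (space[i], space[j])
                    counts[pair] = counts.get(pair, 0.0) + 1.0
                    events.append((edge_ids[child], t_rel, space[i], space[j]))
        per_map.append(
            TransitionSummary(
                total=float(sum(counts.values())), by_direction=counts, n_maps=1
            )
        )
        histories.append(events)
        for pair, c in counts.items():
            agg[pair] = agg.get(pair, 0.0) + c

    mean_dir = {pair: c / n_maps for pair, c in agg.items()}
    mean = TransitionSummary(
        total=float(sum(mean_dir.values())), by_direction=mean_dir, n_maps=n_maps
    )
    return StochasticMapResult(mean=mean, per_map=per_map, histories=histories)
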