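"""Unordered (Fitch/Sankoff) parsimony for heterogametic-type transitions.

The minimum number of state changes needed to explain the tip distribution
is computed by the Sankoff dynamic program with unit costs between distinct
observed states; UNKNOWN tips cost zero in every state, so missing data
never adds changes. Branch lengths are ignored.

Because most-parsimonious reconstructions are generally not unique, the
per-direction breakdown (e.g. "one XY->ZW and two ZW->XY") is obtained by
exact enumeration of *all* internal labelings achieving the minimum, which
is feasible at the scale of the isopod tree (24 tips).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .states import CharacterStates
from .transitions import TransitionSummary

__all__ = [
    "UninformativeCharacterError",
    "EnumerationCapExceeded",
    "MPReconstructions",
    "parsimony_min_transitions",
    "parsimony_direction_counts",
    "brute_force_min_transitions",
]

_INF = math.inf


class UninformativeCharacterError(ValueError):
    """Raised when every tip is UNKNOWN."""


class EnumerationCapExceeded(RuntimeError):
    """Raised internally when the MP-labeling enumeration exceeds its cap."""


@dataclass
class MPReconstructions:
    """All most-parsimonious reconstructions of a character on a tree."""

    minimum: int
    summaries: list[TransitionSummary]
    direction_ranges: dict[tuple[str, str], tuple[float, float]]
    capped: bool = False

    @property
    def n_reconstructions(self) -> int:
        return len(self.summaries)


def _sankoff_costs(
    tree: dendropy.Tree, tip_states: dict[str, str], space: tuple[str, ...]
) -> dict:
    """Postorder Sankoff cost vectors; cost[node][i] = min changes in the
    subtree of `node` given `node` is in state space[i]."""
    k = len(space)
    index = {s: i for i, s in enumerate(space)}
    costs: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            if s == "UNKNOWN":
                costs[node] = np.zeros(k)
            else:
                v = np.full(k, _INF)
                v[index[s]] = 0.0
                costs[node] = v
        else:
            v = np.zeros(k)
            for child in node.child_nodes():
                c = costs[child]
                # unit cost between distinct states
                v += np.array([min(c[j] + (0 if i == j else 1) for j in range(k))
                               for i in range(k)])
            costs[node] = v
    return costs


def _prepare(tree: dendropy.Tree, states: CharacterStates):
    tip_states = states.for_tips([l.taxon.label for l in tree.leaf_node_iter()])
    if all(s == "UNKNOWN" for s in tip_states.values()):
        raise UninformativeCharacterError("all tips are UNKNOWN")
    return tip_states, states.state_space


def parsimony_min_transitions(
    tree: dendropy.Tree, states: CharacterStates
) -> TransitionSummary:
    """Global minimum number of state changes (Sankoff, unit costs).

    The returned summary's ``by_direction`` comes from the first
    most-parsimonious labeling in deterministic (state-order) enumeration;
    other MP labelings may distribute the same total differently — use
    :func:`parsimony_direction_counts` for the full set.
    """
    tip_states, space = _prepare(tree, states)
    costs = _sankoff_costs(tree, tip_states, space)
    minimum = int(min(costs[tree.seed_node]))
    first = next(_iter_mp_labelings(tree, tip_states, space, costs, minimum))
    return TransitionSummary(
        total=float(minimum),
        by_direction=_count_directions(tree, first),
        n_maps=0,
    )


def _iter_mp_labelings(tree, tip_states, space, costs, minimum):
    """Yield node->state dicts for every labeling achieving `minimum`.

    Children's optimal choices are independent given the parent state, so the
    labelings are generated by a preorder DFS over per-node argmin sets.
    """
    k = len(space)
    index = {s: i for i, s in enumerate(space)}

    def choices(node, parent_idx):
        c = costs[node]
        vals = [c[j] + (0 if j == parent_idx else 1) for j in range(k)]
        best = min(vals)
        return [j for j in range(k) if vals[j] == best]

    root = tree.seed_node
    root_best = min(costs[root])
    root_choices = [i for i in range(k) if costs[root][i] == root_best]

    nodes = list(tree.preorder_node_iter())

    def assign(i, labeling):
        if i == len(nodes):
            yield dict(labeling)
            return
        node = nodes[i]
        if node is root:
            opts = root_choices
        else:
            opts = choices(node, labeling[node.parent_node])
        if node.is_leaf() and tip_states[node.taxon.label] != "UNKNOWN":
            opts = [j for j in opts if j == index[tip_states[node.taxon.label]]]
        for j in opts:
            labeling[node] = j
            yield from assign(i + 1, labeling)
        labeling.pop(node, None)

    for lab in assign(0, {}):
        yield {n: space[j] for n, j in lab.items()}


def _count_directions(tree, labeling) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            a, b = labeling[node], labeling[child]
            if a != b:
                out[(a, b)] = out.get((a, b), 0.0) + 1.0
    return out


def parsimony_direction_counts(
    tree: dendropy.Tree,
    states: CharacterStates,
    cap: int = 1_000_000,
) -> MPReconstructions:
    """Enumerate every most-parsimonious reconstruction and its directions.

    Returns one :class:`TransitionSummary` per MP labeling plus the
    (min, max) range of counts per direction over all of them. If more than
    ``cap`` labelings exist the enumeration stops and the result carries the
    labelings found so far with ``capped=True``.
    """
    tip_states, space = _prepare(tree, states)
    costs = _sankoff_costs(tree, tip_states, space)
    minimum = int(min(costs[tree.seed_node]))

    summaries: list[TransitionSummary] = []
    capped = False
    for labeling in _iter_mp_labelings(tree, tip_states, space, costs, minimum):
        by_dir = _count_directions(tree, labeling)
        summaries.append(
            TransitionSummary(total=float(minimum), by_direction=by_dir, n_maps=0)
        )
        if len(summaries) >= cap:
            capped = True
            break

    directions = sorted({d for s in summaries for d in s.by_direction})
    ranges = {
        d: (
            min(s.count(*d) for s in summaries),
            max(s.count(*d) for s in summaries),
        )
        for d in directions
    }
    return MPReconstructions(
        minimum=minimum, summaries=summaries, direction_ranges=ranges, capped=capped
    )


def brute_force_min_transitions(
    tree: dendropy.Tree, states: CharacterStates
) -> int:
    """Exhaustive minimum over all labelings of internal nodes and UNKNOWN tips.

    Independent oracle for :func:`parsimony_min_transitions`; exponential in
    the number of free nodes, usable only on small trees.
    """
    tip_states, space = _prepare(tree, states)
    free = [
        n
        for n in tree.preorder_node_iter()
        if not n.is_leaf() or tip_states[n.taxon.label] == "UNKNOWN"
    ]
    fixed = {
        n: tip_states[n.taxon.label]
        for n in tree.leaf_node_iter()
        if tip_states[n.taxon.label] != "UNKNOWN"
    }
    best = math.inf
    for combo in itertools.product(space, repeat=len(free)):
        labeling = dict(fixed)
        labeling.update(zip(free, combo))
        changes = sum(
            1
            for node in tree.preorder_node_iter()
            for child in node.child_nodes()
            if labeling[node] != labeling[child]
        )
        best = min(best, changes)
    return int(best)
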