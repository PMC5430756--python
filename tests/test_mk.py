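"""Mk likelihood, fitting and ancestral marginals against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from isosex.mk import MkModel, ancestral_marginals, fit_mk, mk_loglik
from isosex.states import CharacterStates
from isosex.trees import parse_newick, random_bifurcating_tree, tip_labels

SPACE2 = ("XY", "ZW")


def enumeration_loglik(tree, states, model):
    """Oracle: sum over all internal-node labelings of path products."""
    Q = model.rate_matrix()
    space = model.states
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    tip_state = {n: states.states.get(n.taxon.label, "UNKNOWN")
                 for n in tree.leaf_node_iter()}
    total = 0.0
    for combo in itertools.product(range(len(space)), repeat=len(internals)):
        lab = dict(zip(internals, combo))
        prob = model.root_prior[lab[tree.seed_node]]
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                P = expm(Q * child.edge.length)
                if child.is_leaf():
                    s = tip_state[child]
                    prob *= 1.0 if s == "UNKNOWN" else P[lab[node], space.index(s)]
                else:
                    prob *= P[lab[node], lab[child]]
        total += prob
    return math.log(total)


def test_single_branch_closed_form():
    """Two tips in the same state: P_stay(t) = 1/2 + 1/2 e^{-2qt} per branch."""
    tree = parse_newick("(A:0.6,B:0.4);")  # path length 1.0 through the root
    states = CharacterStates("two_state", {"A": "XY", "B": "XY"})
    q = 0.5
    model = MkModel(SPACE2, "ER", [q])
    ll = mk_loglik(tree, states, model)

    def p_stay(t):
        return 0.5 + 0.5 * math.exp(-2 * q * t)

    def p_move(t):
        return 0.5 - 0.5 * math.exp(-2 * q * t)

    exact = 0.5 * (p_stay(0.6) * p_stay(0.4) + p_move(0.6) * p_move(0.4))
    assert ll == pytest.approx(math.log(exact), abs=1e-12)
    # and the branch-level stay probability itself at q=0.5, t=1
    assert p_stay(1.0) == pytest.approx(0.6839, abs=1e-4)


def test_vanishing_rate_with_conflicting_tips():
    tree = parse_newick("(A:1,B:1);")
    states = CharacterStates("two_state", {"A": "XY", "B": "ZW"})
    lls = [
        mk_loglik(tree, states, MkModel(SPACE2, "ER", [q]))
        for q in (1e-2, 1e-4, 1e-6)
    ]
    assert lls[0] > lls[1] > lls[2]  # likelihood vanishes as q -> 0


@pytest.mark.parametrize("trial", range(10))
def test_pruning_matches_enumeration_on_random_5tip_trees(trial):
    rng = np.random.default_rng(500 + trial)
    tree = random_bifurcating_tree(5, rng, mean_branch=15.0)
    choices = ["XY", "ZW", "UNKNOWN"]
    states = CharacterStates(
        "two_state", {t: choices[rng.integers(0, 3)] for t in tip_labels(tree)}
    )
    if all(v == "UNKNOWN" for v in states.states.values()):
        return
    model = MkModel(SPACE2, "ER", [float(rng.uniform(0.005, 0.08))])
    assert mk_loglik(tree, states, model) == pytest.approx(
        enumeration_loglik(tree, states, model), abs=1e-9
    )


def test_three_state_sym_pruning_matches_enumeration():
    rng = np.random.default_rng(77)
    tree = random_bifurcating_tree(5, rng, mean_branch=10.0)
    labels = tip_labels(tree)
    states = CharacterStates(
        "three_state",
        dict(zip(labels, ["XY", "ZW", "OTHER", "UNKNOWN", "ZW"])),
    )
    model = MkModel(("XY", "ZW", "OTHER"), "SYM", [0.02, 0.05, 0.01])
    assert mk_loglik(tree, states, model) == pytest.approx(
        enumeration_loglik(tree, states, model), abs=1e-9
    )


def test_invariant_to_child_order_and_rerooting():
    """Reversible model + uniform stationary root: the root placement is moot."""
    states = CharacterStates(
        "two_state", {"A": "XY", "B": "ZW", "C": "ZW", "D": "XY"}
    )
    model = MkModel(SPACE2, "ER", [0.3])
    t1 = parse_newick("((A:1,B:2):0.5,(C:1.5,D:0.7):0.5);")
    t2 = parse_newick("((B:2,A:1):0.5,(D:0.7,C:1.5):0.5);")  # children swapped
    t3 = parse_newick("(A:0.4,(B:2,(C:1.5,D:0.7):1.0):0.6);")  # rerooted on A's edge
    ll = mk_loglik(t1, states, model)
    assert mk_loglik(t2, states, model) == pytest.approx(ll, abs=1e-12)
    assert mk_loglik(t3, states, model) == pytest.approx(ll, abs=1e-10)


def test_zero_branch_length_rejected():
    tree = parse_newick("(A:0.0,B:1);")
    states = CharacterStates("two_state", {"A": "XY", "B": "ZW"})
    with pytest.raises(ValueError):
        mk_loglik(tree, states, MkModel(SPACE2, "ER", [0.1]))


class TestFit:
    def test_sym_equals_er_for_two_states(self):
        rng = np.random.default_rng(21)
        tree = random_bifurcating_tree(12, rng, mean_branch=25.0)
        states = CharacterStates(
            "two_state",
            {t: ("XY" if rng.random() < 0.5 else "ZW") for t in tip_labels(tree)},
        )
        fit_er = fit_mk(tree, states, "ER")
        fit_sym = fit_mk(tree, states, "SYM")
        assert fit_sym.loglik == pytest.approx(fit_er.loglik, abs=1e-6)

    def test_monomorphic_tips_hit_lower_bound(self):
        rng = np.random.default_rng(22)
        tree = random_bifurcating_tree(6, rng)
        states = CharacterStates(
            "two_state", {t: "ZW" for t in tip_labels(tree)}
        )
        fit = fit_mk(tree, states, "ER")
        assert fit.at_bound
        assert fit.model.rates[0] < 1e-6


class TestMarginals:
    def test_symmetric_two_tip_root_is_uniform(self):
        tree = parse_newick("(A:1,B:1);")
        states = CharacterStates("two_state", {"A": "XY", "B": "ZW"})
        marg = ancestral_marginals(tree, states, MkModel(SPACE2, "ER", [0.4]))
        assert marg[tree.seed_node] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_saturated_rate_returns_stationary_root_prior(self):
        """As q -> inf every node's marginal approaches the (uniform)
        stationary root prior: the data stop informing any node."""
        tree = parse_newick("((A:1,B:1):1,C:1);")
        states = CharacterStates("two_state", {"A": "XY", "B": "ZW", "C": "XY"})
        model = MkModel(SPACE2, "ER", [500.0])  # uniform prior = stationary
        marg = ancestral_marginals(tree, states, model)
        for node in tree.preorder_internal_node_iter():
            assert marg[node] == pytest.approx([0.5, 0.5], abs=1e-3)

    def test_matches_enumeration_on_4tip_tree(self):
        """Node marginals equal exhaustive posterior sums to 1e-9."""
        tree = parse_newick("((A:0.8,B:1.2):0.9,(C:0.4,D:1.1):0.7);")
        states = CharacterStates(
            "two_state", {"A": "XY", "B": "ZW", "C": "ZW", "D": "UNKNOWN"}
        )
        model = MkModel(SPACE2, "ER", [0.35])
        Q = model.rate_matrix()
        space = model.states
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        tip_state = {
            n: states.states[n.taxon.label] for n in tree.leaf_node_iter()
        }
        joint = {}
        for combo in itertools.product(range(2), repeat=len(internals)):
            lab = dict(zip(internals, combo))
            prob = model.root_prior[lab[tree.seed_node]]
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    P = expm(Q * child.edge.length)
                    if child.is_leaf():
                        s = tip_state[child]
                        prob *= (
                            1.0 if s == "UNKNOWN" else P[lab[node], space.index(s)]
                        )
                    else:
                        prob *= P[lab[node], lab[child]]
            joint[combo] = prob

        total = sum(joint.values())
        marg = ancestral_marginals(tree, states, model)
        for i, node in enumerate(internals):
            for s in range(2):
                exact = sum(p for c, p in joint.items() if c[i] == s) / total
                assert marg[node][s] == pytest.approx(exact, abs=1e-9)
        for node in tree.preorder_node_iter():
            assert float(np.sum(marg[node])) == pytest.approx(1.0, abs=1e-9)
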