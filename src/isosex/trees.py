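"""Rooted-tree I/O and manipulation (thin layer over dendropy).

Trees are rooted chronograms with branch lengths in millions of years (My).
Tip labels are unique species names with underscores preserved verbatim.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = [
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "load_newick",
    "prune_taxa",
    "tip_labels",
    "tree_length",
    "random_bifurcating_tree",
]


class NewickParseError(ValueError):
    """Raised on malformed Newick input (message carries dendropy's position)."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy Tree.

    Underscores in labels are preserved. Duplicate tip labels and malformed
    input raise :class:`NewickParseError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate tip labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, preserving labels and branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()


def load_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (root edge excluded)."""
    return float(
        sum(
            e.length or 0.0
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        )
    )


def prune_taxa(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Return a copy of the tree with the given tips removed.

    Unifurcations created by the pruning are suppressed and their branch
    lengths merged, so pruning the outgroups of a rooted tree re-roots it at
    the ingroup crown.
    """
    pruned = tree.clone(depth=1)
    pruned.prune_taxa_with_labels(labels)
    pruned.seed_node.edge.length = None  # drop the dangling root edge
    return pruned


def random_bifurcating_tree(
    n_tips: int, rng: np.random.Generator, mean_branch: float = 20.0
) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths (testing aid).

    Topology by uniform random sequential joins; branch lengths i.i.d.
    exponential with mean ``mean_branch`` (in My). Tips are labeled
    t1..t{n}.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    parts = [f"t{i + 1}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b1, b2 = rng.exponential(mean_branch, size=2)
        merged = f"({parts[i]}:{b1:.6f},{parts[j]}:{b2:.6f})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parse_newick(parts[0] + ";")
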