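"""Strict and 50% majority-rule consensus over sets of equally good trees.

A parsimony search usually returns several most-parsimonious trees; the
strict consensus keeps only clades found in every one of them, the
majority-rule consensus those found in more than half (strictly greater,
which is what guarantees the retained clades are mutually compatible).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .treecore import Tree, TreeError, clusters, tree_from_clusters

__all__ = ["ConsensusTree", "strict_consensus", "majority_consensus"]


@dataclass
class ConsensusTree:
    """Consensus topology plus the MPT frequency of each of its clusters."""

    tree: Tree
    frequencies: dict[frozenset[str], Fraction]
    kind: str  # "strict" | "majority"

    def newick_with_frequencies(self) -> str:
        """Newick with integer percent cluster frequencies as internal labels."""
        from .treecore import Node
        import io

        freqs = self.frequencies

        def write(node: Node, leaf_below: dict[int, frozenset[str]], out: io.StringIO):
            if node.is_leaf:
                out.write(node.label)
                return
            out.write("(")
            for i, c in enumerate(node.children):
                if i:
                    out.write(",")
                write(c, leaf_below, out)
            out.write(")")
            cl = leaf_below[id(node)]
            if cl in freqs:
                out.write(str(int(round(100 * float(freqs[cl])))))

        below: dict[int, frozenset[str]] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        out = io.StringIO()
        write(self.tree.root, below, out)
        out.write(";")
        return out.getvalue()


def _frequencies(trees: Sequence[Tree]) -> dict[frozenset[str], Fraction]:
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for cl in clusters(t):
            counts[cl] = counts.get(cl, 0) + 1
    n = len(trees)
    return {cl: Fraction(c, n) for cl, c in counts.items()}


def _check_leaf_sets(trees: Sequence[Tree]) -> frozenset[str]:
    if not trees:
        raise ValueError("consensus of an empty tree set")
    leaf_set = trees[0].leaf_set
    for t in trees[1:]:
        if t.leaf_set != leaf_set:
            raise TreeError("consensus requires identical leaf sets")
    return leaf_set


def strict_consensus(trees: Iterable[Tree]) -> ConsensusTree:
    """Tree of the clusters present in every input tree."""
    trees = list(trees)
    leaf_set = _check_leaf_sets(trees)
    freqs = _frequencies(trees)
    keep = {cl: f for cl, f in freqs.items() if f == 1}
    return ConsensusTree(
        tree=tree_from_clusters(leaf_set, keep),
        frequencies=keep,
        kind="strict",
    )


def majority_consensus(
    trees: Iterable[Tree], threshold: Fraction = Fraction(1, 2)
) -> ConsensusTree:
    """Tree of the clusters with frequency strictly above ``threshold``.

    Thresholds below 1/2 are rejected: only above half are the selected
    clusters guaranteed pairwise compatible.
    """
    if threshold < Fraction(1, 2):
        raise ValueError("majority threshold below 1/2 does not guarantee compatibility")
    trees = list(trees)
    leaf_set = _check_leaf_sets(trees)
    freqs = _frequencies(trees)
    keep = {cl: f for cl, f in freqs.items() if f > threshold}
    return ConsensusTree(
        tree=tree_from_clusters(leaf_set, keep),
        frequencies=keep,
        kind="majority",
    )
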