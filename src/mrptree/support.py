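"""V and V+ supertree support: how well the input trees back each clade.

For one supertree clade, each input tree is classified against it:

* **supports** — the tree, restricted to the taxa relevant to the clade,
  contains the clade;
* **conflicts** — the restricted tree has a cluster properly overlapping the
  clade (monophyly is contradicted);
* **permits** — the tree is relevant but does neither (e.g. the region is a
  polytomy);
* **irrelevant** — fewer than two clade taxa, or no outside taxon, occur in
  the tree.

With s/q/p counts of supporting/conflicting/permitting trees,
``V = (s - q)/(s + q)`` and ``V+ = (s + p - q)/(s + p + q)``, both on a
-1..+1 scale.  A clade with V = V+ = -1 occurs in no input tree at all — a
novel, spurious relationship — and the recommended treatment, applied by
:func:`collapse_novel`, is to collapse it into a polytomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional

from .curation import InputTree
from .treecore import Tree, clusters, prune_to, tree_from_clusters

__all__ = [
    "CladeSupport",
    "classify",
    "v_index",
    "score_supertree",
    "collapse_novel",
    "support_table",
]


@dataclass
class CladeSupport:
    """Per-clade classification counts and the derived V / V+ indices."""

    clade: frozenset[str]
    s: int
    q: int
    p: int
    r_irrelevant: int

    @property
    def V(self) -> Optional[Fraction]:
        if self.s + self.q == 0:
            return None
        return Fraction(self.s - self.q, self.s + self.q)

    @property
    def V_plus(self) -> Optional[Fraction]:
        if self.s + self.p + self.q == 0:
            return None
        return Fraction(self.s + self.p - self.q, self.s + self.p + self.q)

    @property
    def novel(self) -> bool:
        return self.V == -1 and self.V_plus == -1


def classify(input_tree: InputTree, clade: frozenset[str], supertree_leaves: frozenset[str]) -> str:
    """Classify one input tree against one supertree clade.

    Only the taxa the input tree shares with the supertree matter; taxa
    outside ``In ∪ Out`` never change the outcome.
    """
    leaves = input_tree.taxa
    inside = clade & leaves
    outside = (supertree_leaves - clade) & leaves
    if len(inside) < 2 or len(outside) < 1:
        return "irrelevant"
    pruned = prune_to(input_tree.tree, inside | outside)
    assert pruned is not None  # >= 3 leaves by the checks above
    cl = clusters(pruned)
    if inside in cl:
        return "supports"
    for x in cl:
        if x & inside and x - inside and inside - x:
            return "conflicts"
    return "permits"


def v_index(
    clade: frozenset[str],
    trees: Iterable[InputTree],
    supertree_leaves: frozenset[str],
) -> CladeSupport:
    """Count supporting/conflicting/permitting trees and derive V, V+.

    Each retained input tree counts once regardless of its curation weight —
    support asks how many independent sources back a clade, not how heavily
    the matrix weighted them.
    """
    s = q = p = r = 0
    for t in trees:
        kind = classify(t, clade, supertree_leaves)
        if kind == "supports":
            s += 1
        elif kind == "conflicts":
            q += 1
        elif kind == "permits":
            p += 1
        else:
            r += 1
    return CladeSupport(clade=frozenset(clade), s=s, q=q, p=p, r_irrelevant=r)


def score_supertree(
    supertree: Tree,
    trees: Iterable[InputTree],
    skip: Iterable[frozenset[str]] = (),
) -> list[CladeSupport]:
    """One CladeSupport per internal non-root cluster of the supertree.

    ``skip`` lists clades that get no score (e.g. clades constrained as
    monophyletic to partition the analysis, which the input trees were never
    asked about).  Results are sorted largest clade first.
    """
    trees = list(trees)
    skip = set(skip)
    out = []
    for clade in clusters(supertree):
        if clade in skip:
            continue
        out.append(v_index(clade, trees, supertree.leaf_set))
    out.sort(key=lambda cs: (-len(cs.clade), sorted(cs.clade)))
    return out


def collapse_novel(supertree: Tree, scores: Iterable[CladeSupport]) -> Tree:
    """Collapse every novel (V = V+ = -1) clade into a polytomy.

    Other clusters are untouched; the result is a valid tree on the same
    leaf set.
    """
    novel = {cs.clade for cs in scores if cs.novel}
    if not novel:
        return supertree
    keep = clusters(supertree) - novel
    return tree_from_clusters(supertree.leaf_set, keep)


def support_table(scores: Iterable[CladeSupport]) -> "pandas.DataFrame":
    """Support scores as a table (clade taxa, s, q, p, irrelevant, V, V+, novel)."""
    import pandas as pd

    rows = []
    for cs in scores:
        rows.append(
            {
                "clade": " ".join(sorted(cs.clade)),
                "clade_size": len(cs.clade),
                "s": cs.s,
                "q": cs.q,
                "p": cs.p,
                "irrelevant": cs.r_irrelevant,
                "V": float(cs.V) if cs.V is not None else None,
                "V_plus": float(cs.V_plus) if cs.V_plus is not None else None,
                "novel": cs.novel,
            }
        )
    return pd.DataFrame(rows)
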