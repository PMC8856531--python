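"""Input-tree curation: pseudoreplication control, weighting, taxon filters.

Published phylogenies are not independent evidence: studies reuse the same
markers and matrices, and single studies publish alternative trees.  The
protocol here reduces that pseudoreplication and weights what remains:

* two trees built from the same data type may both stay only if each keeps
  at least half of its taxa private (both overlap fractions <= 50%);
* otherwise the more comprehensive (larger) tree is preferred;
* genuinely indistinguishable alternatives are all retained, each at weight
  1/n, so together they count as one tree's worth of evidence.

Afterwards taxa seen in only one retained tree (singletons) are removed —
one tree cannot place a taxon in a supertree — and the overlap graph is
checked for connectivity (two shared taxa being the minimum for two trees to
interact in an MRP analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional

import networkx as nx

from .treecore import Tree, prune_to

__all__ = [
    "InputTree",
    "CurationReport",
    "overlap_fractions",
    "resolve_pseudoreplication",
    "remove_singletons",
    "connectivity_check",
    "representation_filter",
]


@dataclass(frozen=True)
class InputTree:
    """A published phylogeny plus the metadata curation needs."""

    tree: Tree
    tree_id: str
    study_id: str
    year: int
    data_types: frozenset[str]
    weight: Fraction = Fraction(1)

    def __post_init__(self):
        if self.weight <= 0 or self.weight > 1:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")

    @property
    def taxa(self) -> frozenset[str]:
        return self.tree.leaf_set


@dataclass
class CurationReport:
    """Exhaustive account of what curation did and why.

    Every input tree ends up either in ``retained`` or in ``discarded``;
    every removed taxon is listed with its reason code.
    """

    retained: dict[str, Fraction] = field(default_factory=dict)  # tree_id -> weight
    discarded: dict[str, str] = field(default_factory=dict)  # tree_id -> reason
    removed_taxa: dict[str, str] = field(default_factory=dict)  # taxon -> reason
    n_components: int = 1
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "CurationReport") -> "CurationReport":
        out = CurationReport(
            retained=dict(other.retained) or dict(self.retained),
            discarded={**self.discarded, **other.discarded},
            removed_taxa={**self.removed_taxa, **other.removed_taxa},
            n_components=other.n_components or self.n_components,
            warnings=self.warnings + other.warnings,
        )
        for tid in out.discarded:
            out.retained.pop(tid, None)
        return out


def overlap_fractions(t1: InputTree, t2: InputTree) -> tuple[Fraction, Fraction]:
    """Shared-taxon fraction of each tree: |shared|/|taxa_i|, both in [0,1]."""
    shared = len(t1.taxa & t2.taxa)
    return (
        Fraction(shared, len(t1.taxa)),
        Fraction(shared, len(t2.taxa)),
    )


def _share_data_type(t1: InputTree, t2: InputTree) -> bool:
    return bool(t1.data_types & t2.data_types)


def resolve_pseudoreplication(
    trees: Iterable[InputTree], overlap_max: Fraction = Fraction(1, 2)
) -> tuple[list[InputTree], CurationReport]:
    """Apply the pseudoreplication rule and assign weights.

    Conflict sets are connected components of the graph whose edges join
    trees that share a data-type tag and whose taxon overlap exceeds
    ``overlap_max`` in either direction; transitive closure makes the rule
    order-independent.  Within each set the most comprehensive tree wins;
    tied alternatives (or same-study alternatives) are all kept at weight
    1/n.  Trees outside any conflict set keep weight 1.
    """
    trees = list(trees)
    seen: set[tuple[str, str]] = set()
    for t in trees:
        if not t.data_types:
            raise ValueError(f"tree {t.tree_id!r} has no data-type tag")
        key = (t.study_id, t.tree_id)
        if key in seen:
            raise ValueError(f"duplicate (study_id, tree_id): {key}")
        seen.add(key)

    g = nx.Graph()
    g.add_nodes_from(range(len(trees)))
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            if not _share_data_type(trees[i], trees[j]):
                continue
            f1, f2 = overlap_fractions(trees[i], trees[j])
            if f1 > overlap_max or f2 > overlap_max:
                g.add_edge(i, j)

    retained: list[InputTree] = []
    report = CurationReport()
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda i: trees[i].tree_id)
        if len(members) == 1:
            t = trees[members[0]]
            retained.append(replace(t, weight=Fraction(1)))
            report.retained[t.tree_id] = Fraction(1)
            continue
        group = [trees[i] for i in members]
        same_study = len({t.study_id for t in group}) == 1
        if same_study:
            winners = group  # alternatives from one study: cannot choose
        else:
            best = max(len(t.taxa) for t in group)
            winners = [t for t in group if len(t.taxa) == best]
        w = Fraction(1, len(winners))
        winner_ids = {t.tree_id for t in winners}
        for t in group:
            if t.tree_id in winner_ids:
                retained.append(replace(t, weight=w))
                report.retained[t.tree_id] = w
            else:
                report.discarded[t.tree_id] = "pseudoreplicate_dropped"
    retained.sort(key=lambda t: t.tree_id)
    return retained, report


def remove_singletons(
    trees: Iterable[InputTree],
) -> tuple[list[InputTree], CurationReport]:
    """Prune taxa occurring in exactly one tree, to a fixed point.

    Pruning can leave a tree too small to carry any MRP character (< 3
    leaves); such trees are dropped, the occurrence census recomputed, and
    the sweep repeated until nothing changes.
    """
    current = list(trees)
    report = CurationReport()
    changed = True
    while changed:
        changed = False
        census: dict[str, int] = {}
        for t in current:
            for taxon in t.taxa:
                census[taxon] = census.get(taxon, 0) + 1
        singletons = {taxon for taxon, n in census.items() if n == 1}
        if not singletons:
            break
        nxt: list[InputTree] = []
        for t in current:
            keep = t.taxa - singletons
            hit = t.taxa & singletons
            for taxon in hit:
                report.removed_taxa[taxon] = "singleton"
            if keep == t.taxa:
                nxt.append(t)
                continue
            changed = True
            pruned = prune_to(t.tree, keep) if len(keep) >= 2 else None
            if pruned is None or len(pruned) < 3:
                report.discarded[t.tree_id] = "too_few_leaves"
            else:
                nxt.append(replace(t, tree=pruned))
        current = nxt
    for t in current:
        report.retained[t.tree_id] = t.weight
    return current, report


def connectivity_check(trees: Iterable[InputTree]) -> list[set[str]]:
    """Connected components of the >= 2-shared-taxa overlap graph.

    More than one component means the supertree cannot be resolved across
    components; callers log the warning and proceed.
    """
    trees = list(trees)
    g = nx.Graph()
    g.add_nodes_from(t.tree_id for t in trees)
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            if len(trees[i].taxa & trees[j].taxa) >= 2:
                g.add_edge(trees[i].tree_id, trees[j].tree_id)
    return [set(c) for c in nx.connected_components(g)]


def representation_filter(
    taxon_tree_counts: dict[str, int],
    taxon_cell_counts: dict[str, int],
    min_trees: int = 2,
    min_cells: int = 2,
) -> list[str]:
    """Taxa too thinly represented in the matrix for the analysis to run.

    A taxon must appear in at least ``min_trees`` retained trees and carry at
    least ``min_cells`` non-missing (0/1) cells; the thresholds are exposed in
    configuration.  Returns the taxa to remove, sorted.
    """
    removed = {
        taxon
        for taxon, n in taxon_tree_counts.items()
        if n < min_trees or taxon_cell_counts.get(taxon, 0) < min_cells
    }
    return sorted(removed)
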