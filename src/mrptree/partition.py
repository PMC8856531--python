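"""Nested data partitions: divide, solve, constrain, and graft back.

When an MRP matrix carries too much missing data for a single search, the
analysis is split along uncontroversially monophyletic clades: the innermost
clade is analysed on its own; in every enclosing partition that clade is
replaced by a single placeholder taxon; finally each sub-supertree is
grafted back onto the placeholder leaf of its parent partition.  Placeholder
clades are constrained, not inferred, so they are reported without a V
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional

from .consensus import ConsensusTree, majority_consensus, strict_consensus
from .curation import InputTree
from .mrp import encode_matrix
from .search import SearchConfig, SearchResult, heuristic_search
from .support import CladeSupport, score_supertree
from .treecore import Node, Tree, clusters, prune_to, tree_from_clusters

__all__ = ["PartitionSpec", "PartitionResult", "reduce_tree", "run_partitioned", "graft"]

log = logging.getLogger(__name__)


@dataclass
class PartitionSpec:
    """Ordered (name, taxon set) pairs, innermost first.

    Sets must be pairwise nested or disjoint and have >= 3 members; names
    double as placeholder taxon labels, so they must not collide with real
    taxa.
    """

    partitions: list[tuple[str, frozenset[str]]]

    def validate(self, taxa: Optional[set[str]] = None) -> None:
        names = [name for name, _ in self.partitions]
        if len(set(names)) != len(names):
            raise ValueError("partition names must be unique")
        for name, members in self.partitions:
            if len(members) < 3:
                raise ValueError(f"partition {name!r} needs >= 3 members")
            if taxa is not None and name in taxa:
                raise ValueError(f"partition name {name!r} collides with a taxon")
        for i, (ni, mi) in enumerate(self.partitions):
            for nj, mj in self.partitions[i + 1 :]:
                if mi & mj and not (mi <= mj or mj <= mi):
                    raise ValueError(f"partitions {ni!r} and {nj!r} overlap without nesting")
        # innermost-first ordering: a set may only be contained in later sets
        for i, (ni, mi) in enumerate(self.partitions):
            for nj, mj in self.partitions[:i]:
                if mi < mj:
                    raise ValueError(
                        f"partition {ni!r} nested inside earlier {nj!r}: order innermost first"
                    )


@dataclass
class PartitionResult:
    """Everything one partition's independent analysis produced."""

    name: str
    effective_taxa: frozenset[str]
    search: SearchResult
    strict: ConsensusTree
    majority: ConsensusTree
    supports: list[CladeSupport]
    reduced_placeholders: list[str] = field(default_factory=list)


def _mrca(tree: Tree, taxa: frozenset[str]) -> Node:
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    best: Node = tree.root
    best_size = len(tree.leaf_set)
    for node in tree.postorder():
        cl = below[id(node)]
        if taxa <= cl and len(cl) < best_size:
            best, best_size = node, len(cl)
    return best


def reduce_tree(
    tree: InputTree, name: str, members: Iterable[str], strict: bool = False
) -> Optional[InputTree]:
    """Replace the members of a named clade by one placeholder leaf.

    Monophyletic members are replaced in place (the placeholder sits on the
    clade's own edge).  Non-monophyletic members are pruned and the
    placeholder attached at the parent of their most recent common ancestor,
    with a warning (``strict=True`` raises instead).  Returns None when the
    reduction leaves fewer than 2 leaves.
    """
    members = frozenset(members)
    present = members & tree.taxa
    if not present:
        return tree
    rest = tree.taxa - present
    if len(rest) < 1:
        return None  # tree was entirely inside the clade

    mono = False
    if len(present) == 1:
        mono = True
        mrca_cl = present
    else:
        mrca = _mrca(tree.tree, present)
        mrca_cl = frozenset(
            n.label for n in Tree(mrca, validate=False).leaves()
        ) if not mrca.is_leaf else frozenset([mrca.label])
        mono = mrca_cl == present

    if mono:
        # replace the clade's subtree by the placeholder leaf
        new_clusters = {
            (cl - present) | frozenset([name]) if present <= cl else cl
            for cl in clusters(tree.tree)
            if cl != present and (present <= cl or not (cl & present))
        }
        new_leaves = rest | frozenset([name])
        new_clusters = {cl for cl in new_clusters if 1 < len(cl) < len(new_leaves)}
        if len(new_leaves) < 2:
            return None
        reduced = tree_from_clusters(new_leaves, new_clusters)
        return replace(tree, tree=reduced)

    if strict:
        raise ValueError(
            f"members of {name!r} are not monophyletic in tree {tree.tree_id!r}: "
            f"{sorted(present)}"
        )
    log.warning(
        "members of %r not monophyletic in tree %r; placeholder attached at the "
        "parent of their MRCA",
        name,
        tree.tree_id,
    )
    # prune members, then attach the placeholder as sister to what remains of
    # the MRCA region (at the parent of the members' MRCA)
    mrca_rest = mrca_cl - present
    pruned = prune_to(tree.tree, rest)
    if pruned is None:
        return None
    cl_set = clusters(pruned)
    host = None  # smallest cluster containing the MRCA leftovers
    for cl in sorted(cl_set, key=len):
        if mrca_rest <= cl:
            host = cl
            break
    new_leaves = pruned.leaf_set | frozenset([name])
    new_clusters = set(cl_set)
    if host is not None and host != pruned.leaf_set:
        parent_candidates = [c for c in cl_set if host < c]
        target = min(parent_candidates, key=len) if parent_candidates else None
        # placeholder joins at the parent's level: sister to the host cluster
        if target is not None:
            new_clusters = {
                (cl | frozenset([name])) if target <= cl else cl for cl in cl_set
            }
    new_clusters = {cl for cl in new_clusters if 1 < len(cl) < len(new_leaves)}
    reduced = tree_from_clusters(new_leaves, new_clusters)
    return replace(tree, tree=reduced)


def graft(backbone: Tree, name: str, subtree: Tree) -> Tree:
    """Replace placeholder leaf ``name`` by ``subtree``.

    The subtree's root becomes the clade's node, so the grafted taxa form a
    cluster of the result.  Leaf counts obey |result| = |backbone| - 1 +
    |subtree|.
    """
    if name not in backbone.leaf_set:
        raise ValueError(f"backbone has no placeholder leaf {name!r}")
    if backbone.leaf_set & subtree.leaf_set:
        raise ValueError("subtree leaves must be disjoint from the backbone")

    def rec(node: Node) -> Node:
        if node.is_leaf:
            if node.label == name:
                return subtree.copy().root
            return Node(node.label)
        return Node(children=[rec(c) for c in node.children])

    return Tree(rec(backbone.root))


def run_partitioned(
    trees: Iterable[InputTree],
    spec: PartitionSpec,
    config: Optional[SearchConfig] = None,
    consensus_for_graft: str = "majority",
    strict_reduction: bool = False,
) -> tuple[Tree, dict[str, PartitionResult]]:
    """Solve each partition independently and graft the results together.

    Input trees must already be curated.  For each partition, innermost
    first: reduce every directly nested inner partition to its placeholder,
    prune the trees to the partition's effective taxa, and run the full
    encode → search → consensus → support chain.  The outermost partition is
    the backbone; if the spec does not cover all taxa, an implicit backbone
    partition over everything left is appended.  Returns the grafted
    supertree and the per-partition results.
    """
    trees = list(trees)
    config = config or SearchConfig()
    all_taxa = frozenset().union(*(t.taxa for t in trees))
    spec.validate(set(all_taxa))

    parts = list(spec.partitions)
    covered = frozenset().union(*(m for _, m in parts)) if parts else frozenset()
    if all_taxa - covered or not parts:
        parts.append(("__backbone__", all_taxa))

    results: dict[str, PartitionResult] = {}
    consensus_trees: dict[str, Tree] = {}

    for idx, (name, members) in enumerate(parts):
        # inner partitions directly nested in this one (not via an intermediate)
        inner = []
        for j in range(idx):
            nj, mj = parts[j]
            if mj < members and not any(
                mj < mk < members for k, (nk, mk) in enumerate(parts[:idx]) if k != j
            ):
                inner.append((nj, mj))

        effective = (members - frozenset().union(frozenset(), *(m for _, m in inner))) | frozenset(
            n for n, _ in inner
        )
        if len(effective) < 4:
            raise ValueError(
                f"partition {name!r} has {len(effective)} effective taxa; "
                "need >= 4 for an informative search"
            )

        part_trees: list[InputTree] = []
        for t in trees:
            rt: Optional[InputTree] = t
            for n_in, m_in in inner:
                rt = reduce_tree(rt, n_in, m_in, strict=strict_reduction)
                if rt is None:
                    break
            if rt is None:
                continue
            pruned = prune_to(rt.tree, effective)
            if pruned is None or len(pruned) < 3:
                continue
            part_trees.append(replace(rt, tree=pruned))
        if not part_trees:
            raise ValueError(f"no input tree overlaps partition {name!r}")

        matrix = encode_matrix(part_trees, sorted(effective))
        part_config = replace_config(config, seed_offset=idx)
        search = heuristic_search(matrix, part_config)
        strict_c = strict_consensus(search.mpts)
        majority_c = majority_consensus(search.mpts)
        chosen = majority_c if consensus_for_graft == "majority" else strict_c
        placeholder_cl = [
            frozenset([n]) for n, _ in inner
        ]  # single leaves: never scored anyway
        supports = score_supertree(chosen.tree, part_trees)
        results[name] = PartitionResult(
            name=name,
            effective_taxa=frozenset(effective),
            search=search,
            strict=strict_c,
            majority=majority_c,
            supports=supports,
            reduced_placeholders=[n for n, _ in inner],
        )
        consensus_trees[name] = chosen.tree

    # graft from the backbone inwards
    final = consensus_trees[parts[-1][0]]
    for name, _members in reversed(parts[:-1]):
        # find which tree currently holds the placeholder
        if name in final.leaf_set:
            final = graft(final, name, consensus_trees[name])
        else:  # placeholder sits inside a not-yet-grafted partition; graft later
            for host, tree_ in consensus_trees.items():
                if name in tree_.leaf_set:
                    consensus_trees[host] = graft(tree_, name, consensus_trees[name])
                    break
            else:
                raise ValueError(f"placeholder {name!r} not found in any partition result")
    return final, results


def replace_config(config: SearchConfig, seed_offset: int) -> SearchConfig:
    """Per-partition search config: independent but reproducible seeds."""
    seed = None if config.seed is None else (config.seed + seed_offset) % (2**31)
    return SearchConfig(
        n_reps=config.n_reps,
        swap=config.swap,
        seed=seed,
        max_trees=config.max_trees,
        constraints=dict(config.constraints),
    )
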