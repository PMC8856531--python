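"""Rooted leaf-labeled trees, Newick I/O and cluster-set algebra.

Every stage of the supertree pipeline trades in one currency: the rooted,
possibly multifurcating tree, viewed as its set of *clusters* (the leaf sets
descending from internal nodes).  Branch lengths and internal node labels are
deliberately dropped on input — the analysis is purely topological.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "NewickParseError",
    "normalize_label",
    "parse_newick",
    "write_newick",
    "clusters",
    "prune_to",
    "rf_distance",
    "tree_from_clusters",
]


class TreeError(ValueError):
    """Invalid tree structure or labels."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


def normalize_label(label: str) -> str:
    """Canonical taxon label: stripped, internal whitespace unified to '_'.

    Cross-study matching of taxon names is by exact comparison after this
    normalization; synonymy beyond spelling is handled by an explicit rename
    table at ingestion, never by fuzzy matching.
    """
    return "_".join(label.strip().split())


class Node:
    """Tree node; a leaf iff it has no children, in which case it is labeled."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None, children: Optional[list["Node"]] = None):
        self.label = label
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node({len(self.children)} children)"


class Tree:
    """Rooted multifurcating tree over uniquely labeled leaves.

    Invariants (checked on construction): >= 2 leaves, unique leaf labels,
    every internal node has >= 2 children.
    """

    __slots__ = ("root", "_leaf_set")

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()
        self._leaf_set = frozenset(n.label for n in self.leaves())

    def _validate(self) -> None:
        labels = []
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf without a label")
                labels.append(node.label)
            elif len(node.children) < 2:
                raise TreeError("internal node with fewer than 2 children")
        if len(labels) < 2:
            raise TreeError(f"tree needs >= 2 leaves, got {len(labels)}")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(dups)}")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.postorder() if n.is_leaf)

    @property
    def leaf_set(self) -> frozenset[str]:
        return self._leaf_set

    def __len__(self) -> int:
        return len(self._leaf_set)

    # -- structural equality on topology ----------------------------------
    def topology_key(self) -> frozenset:
        """Hashable identity: leaf set plus cluster set."""
        return frozenset([self._leaf_set, frozenset(clusters(self))])

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            if node.is_leaf:
                return Node(node.label)
            return Node(children=[rec(c) for c in node.children])

        return Tree(rec(self.root), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({write_newick(self)})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; labels normalized here)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None:
            raise NewickParseError("unlabeled leaf in Newick input")
        return Node(normalize_label(str(label)))
    kids = [_from_dendropy(c) for c in dnode.child_nodes()]
    if len(kids) == 1:  # suppress unary nodes arising from e.g. "((A,B));"
        return kids[0]
    return Node(children=kids)


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree; branch lengths and internal labels discarded.

    Raises :class:`NewickParseError` on malformed syntax (the message carries
    dendropy's row/column diagnostics) and :class:`TreeError` on duplicate
    leaf labels.
    """
    if ";" not in text:
        raise NewickParseError("missing terminating ';' in Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None
    root = _from_dendropy(dtree.seed_node)
    if root.is_leaf:
        raise TreeError("tree needs >= 2 leaves, got 1")
    return Tree(root)


def parse_newick_list(text: str) -> list[Tree]:
    """Parse a multi-tree Newick document (one tree per ';')."""
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    return trees


def _write_node(node: Node, out: io.StringIO) -> None:
    if node.is_leaf:
        out.write(node.label)
    else:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_node(child, out)
        out.write(")")


def write_newick(tree: Tree) -> str:
    """Serialize topology only; round-trips to an identical cluster set."""
    out = io.StringIO()
    _write_node(tree.root, out)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Cluster algebra
# ---------------------------------------------------------------------------

def clusters(tree: Tree) -> set[frozenset[str]]:
    """Leaf sets of internal non-root nodes (the informative clades).

    Size-1 sets (leaves) and the full leaf set (root) are excluded; a star
    tree therefore has an empty cluster set.
    """
    result: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            cl = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = cl
            if node is not tree.root:
                result.add(cl)
    return result


def prune_to(tree: Tree, taxa: Iterable[str]) -> Optional[Tree]:
    """Restrict a tree to ``taxa``; returns None if < 2 leaves would remain.

    Unary internal nodes produced by the pruning are suppressed so the result
    honors the Tree invariants.
    """
    keep = frozenset(taxa) & tree.leaf_set
    if len(keep) < 2:
        return None

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return Node(node.label) if node.label in keep else None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return Node(children=kids)

    root = rec(tree.root)
    assert root is not None
    return Tree(root, validate=False)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Rooted Robinson–Foulds distance: |clusters(t1) XOR clusters(t2)|.

    Both trees must share one leaf set; this is a metric on that space.
    """
    if t1.leaf_set != t2.leaf_set:
        only1 = sorted(t1.leaf_set - t2.leaf_set)
        only2 = sorted(t2.leaf_set - t1.leaf_set)
        raise TreeError(f"leaf sets differ (only in t1: {only1}; only in t2: {only2})")
    return len(clusters(t1) ^ clusters(t2))


def tree_from_clusters(leaf_set: Iterable[str], cluster_set: Iterable[frozenset[str]]) -> Tree:
    """Build the unique tree displaying exactly a laminar family of clusters.

    ``cluster_set`` must be pairwise compatible (nested or disjoint) proper
    subsets of ``leaf_set`` of size >= 2; the root spans ``leaf_set``.
    """
    leaf_set = frozenset(leaf_set)
    fam = sorted({frozenset(c) for c in cluster_set}, key=len, reverse=True)
    for c in fam:
        if not (1 < len(c) < len(leaf_set)) or not c <= leaf_set:
            raise TreeError(f"cluster {sorted(c)} not a proper subset of the leaf set")
    root = Node()
    cover: list[tuple[frozenset[str], Node]] = [(leaf_set, root)]

    for c in fam:  # largest first: the parent is already placed
        parent = root
        parent_cl = leaf_set
        for cl, node in cover:
            if c <= cl and len(cl) < len(parent_cl):
                parent, parent_cl = node, cl
            elif c & cl and not (c <= cl or cl <= c):
                raise TreeError("incompatible clusters passed to tree_from_clusters")
        node = Node()
        parent.children.append(node)
        cover.append((c, node))

    # attach each leaf under the smallest cluster containing it
    for leaf in sorted(leaf_set):
        parent, parent_cl = root, leaf_set
        for cl, node in cover:
            if leaf in cl and len(cl) < len(parent_cl):
                parent, parent_cl = node, cl
        parent.children.append(Node(leaf))

    # canonical child order: by smallest leaf label, for reproducible output
    def sort_rec(node: Node) -> str:
        if node.is_leaf:
            return node.label
        keys = [sort_rec(c) for c in node.children]
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        node.children = [node.children[i] for i in order]
        return min(keys)

    sort_rec(root)
    return Tree(root)
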