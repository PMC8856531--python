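"""Synthetic input-tree collections with the structure a supertree study assumes.

A supertree analysis starts from published phylogenies that (i) sample
partially overlapping subsets of the taxa of interest, (ii) disagree with one
another to some degree, (iii) are sometimes unresolved, and (iv) come in
groups built from the same underlying data (pseudoreplicates).  This module
emulates exactly those four features on top of a known model tree, so every
downstream stage — curation, MRP coding, parsimony search, consensus,
support — can be exercised against ground truth.

The generator is fully deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

from .curation import InputTree
from .treecore import Node, Tree, clusters, parse_newick, prune_to, write_newick

__all__ = [
    "DATA_TYPE_VOCAB",
    "SimConfig",
    "generate_model_tree",
    "nni_move",
    "collapse_random_edges",
    "sample_input_trees",
    "write_bundle",
    "read_bundle",
]

# Data-type vocabulary mirroring the categories of published moth phylogenies:
# single-marker barcode studies, multilocus studies, mitogenomes, morphology.
DATA_TYPE_VOCAB = ("COI", "multilocus", "mitogenome", "morphology")


@dataclass
class SimConfig:
    """Study conditions for one synthetic input-tree collection.

    Defaults are sized after the structure of a typical genus-level
    supertree input set: a few dozen taxa in the model, input trees an
    order of magnitude smaller than the taxon universe (low pairwise
    overlap), light topological noise, occasional polytomies, and a couple
    of pseudoreplicate groups.
    """

    n_taxa: int = 32
    n_trees: int = 12
    taxa_per_tree: tuple[int, int] = (10, 14)
    perturb_moves: int = 0
    collapse_prob: float = 0.0
    pseudoreplicate_groups: int = 0
    pseudoreplicate_size: int = 2
    seed: Optional[int] = None
    year_range: tuple[int, int] = (1995, 2021)

    def validate(self) -> None:
        lo, hi = self.taxa_per_tree
        if not (3 <= lo <= hi <= self.n_taxa):
            raise ValueError(
                f"taxa_per_tree {self.taxa_per_tree} infeasible for n_taxa={self.n_taxa}"
            )
        if not 0.0 <= self.collapse_prob <= 1.0:
            raise ValueError("collapse_prob must be in [0, 1]")
        if self.pseudoreplicate_groups and self.pseudoreplicate_size < 2:
            raise ValueError("pseudoreplicate groups need size >= 2")
        if self.pseudoreplicate_groups * self.pseudoreplicate_size > self.n_trees:
            raise ValueError("pseudoreplicate groups exceed n_trees")


def generate_model_tree(n_taxa: int, seed: int) -> Tree:
    """Random rooted binary model tree on taxa T001..Tnnn (Yule process).

    Starts from a cherry and attaches each further taxon to a uniformly
    chosen branch (uniform random split), the discrete equivalent of a
    Yule pure-birth topology.
    """
    if n_taxa < 3:
        raise ValueError(f"need n_taxa >= 3, got {n_taxa}")
    rng = random.Random(seed)
    labels = [f"T{i + 1:03d}" for i in range(n_taxa)]
    root = Node(children=[Node(labels[0]), Node(labels[1])])
    tree = Tree(root, validate=False)
    for label in labels[2:]:
        # edges: (parent, child index); also the root edge (None)
        edges: list[Optional[tuple[Node, int]]] = [None]
        for node in tree.preorder():
            for i, _ in enumerate(node.children):
                edges.append((node, i))
        choice = rng.choice(edges)
        if choice is None:
            tree = Tree(Node(children=[tree.root, Node(label)]), validate=False)
        else:
            parent, i = choice
            parent.children[i] = Node(children=[parent.children[i], Node(label)])
            tree = Tree(tree.root, validate=False)
    return Tree(tree.root)


# ---------------------------------------------------------------------------
# Topological noise operators
# ---------------------------------------------------------------------------

def _parents(tree: Tree) -> dict[int, Node]:
    par: dict[int, Node] = {}
    for node in tree.preorder():
        for c in node.children:
            par[id(c)] = node
    return par


def nni_move(tree: Tree, rng: random.Random) -> Tree:
    """One random nearest-neighbor interchange on an internal edge.

    On a binary tree each effective NNI changes the cluster set by exactly
    one cluster swap (rooted RF distance 2 from the original).  Trees with
    no internal edge are returned unchanged.
    """
    t = tree.copy()
    par = _parents(t)
    internal_edges = [
        n for n in t.preorder() if n is not t.root and not n.is_leaf
    ]
    if not internal_edges:
        return t
    v = rng.choice(internal_edges)
    p = par[id(v)]
    siblings = [c for c in p.children if c is not v]
    s = rng.choice(siblings)
    c = rng.choice(v.children)
    # swap subtree c (child of v) with sibling s (child of p)
    v.children[v.children.index(c)] = s
    p.children[p.children.index(s)] = c
    return Tree(t.root, validate=False)


def collapse_random_edges(tree: Tree, prob: float, rng: random.Random) -> Tree:
    """Collapse each internal (non-root) edge to a polytomy with prob ``prob``."""
    keep = {
        cl for cl in clusters(tree) if rng.random() >= prob
    }
    from .treecore import tree_from_clusters

    return tree_from_clusters(tree.leaf_set, keep)


# ---------------------------------------------------------------------------
# Input-tree sampling
# ---------------------------------------------------------------------------

def _jitter_taxa(
    base: list[str], universe: list[str], rng: random.Random
) -> list[str]:
    """Swap ~10% of a taxon set for outside taxa (pseudoreplicate jitter)."""
    out = list(base)
    n_swap = max(1, len(base) // 10)
    outside = [t for t in universe if t not in base]
    for _ in range(n_swap):
        if not outside:
            break
        i = rng.randrange(len(out))
        j = rng.randrange(len(outside))
        out[i], outside[j] = outside[j], out[i]
    return out


def sample_input_trees(model: Tree, config: SimConfig) -> list[InputTree]:
    """Draw a synthetic collection of input trees from the model.

    Each tree is the model pruned to a random taxon subset, perturbed by
    ``perturb_moves`` random NNIs, then partially collapsed to polytomies.
    Pseudoreplicate groups clone one sampled taxon set with small jitter and
    share a study id and data-type tag, emulating alternative trees built
    from the same underlying data.
    """
    config.validate()
    seed = config.seed if config.seed is not None else random.randrange(2**31)
    rng = random.Random(seed)
    universe = sorted(model.leaf_set)
    lo, hi = config.taxa_per_tree

    def make_tree(taxa: list[str]) -> Tree:
        t = prune_to(model, taxa)
        assert t is not None
        for _ in range(config.perturb_moves):
            t = nni_move(t, rng)
        if config.collapse_prob > 0:
            t = collapse_random_edges(t, config.collapse_prob, rng)
        return t

    out: list[InputTree] = []
    idx = 0
    study = 0

    for g in range(config.pseudoreplicate_groups):
        study += 1
        tag = DATA_TYPE_VOCAB[rng.randrange(len(DATA_TYPE_VOCAB))]
        year = rng.randint(*config.year_range)
        base = rng.sample(universe, rng.randint(lo, hi))
        for m in range(config.pseudoreplicate_size):
            taxa = base if m == 0 else _jitter_taxa(base, universe, rng)
            idx += 1
            out.append(
                InputTree(
                    tree=make_tree(taxa),
                    tree_id=f"tree{idx:03d}",
                    study_id=f"study{study:03d}",
                    year=year,
                    data_types=frozenset([tag]),
                    weight=Fraction(1),
                )
            )

    while idx < config.n_trees:
        study += 1
        idx += 1
        taxa = rng.sample(universe, rng.randint(lo, hi))
        out.append(
            InputTree(
                tree=make_tree(taxa),
                tree_id=f"tree{idx:03d}",
                study_id=f"study{study:03d}",
                year=rng.randint(*config.year_range),
                data_types=frozenset([DATA_TYPE_VOCAB[rng.randrange(len(DATA_TYPE_VOCAB))]]),
                weight=Fraction(1),
            )
        )
    return out


def sample_covering_subsets(
    model: Tree, n_trees: int, taxa_per_tree: tuple[int, int], seed: int
) -> list[list[str]]:
    """Taxon subsets that jointly witness every edge of the model tree.

    Random subsampling routinely leaves some model edges unwitnessed (two
    cherry taxa never co-sampled, say), in which case no supertree method
    can recover them.  Recovery experiments need the opposite premise — the
    inputs jointly determine the model — so this design assigns each model
    edge a witnessing subset holding a leaf from two different children of
    the clade, one from its sibling region, and one from outside its parent,
    then pads every subset to the requested size with seeded random taxa.
    Deterministic given ``seed``.
    """
    rng = random.Random(seed)
    lo, hi = taxa_per_tree
    universe = sorted(model.leaf_set)
    below: dict[int, frozenset[str]] = {}
    parent_of: dict[int, Node] = {}
    for node in model.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            for c in node.children:
                parent_of[id(c)] = node

    subsets: list[set[str]] = [set() for _ in range(n_trees)]
    internal = [
        n for n in model.preorder() if not n.is_leaf and n is not model.root
    ]
    k = 0
    for node in internal:
        kids = node.children
        parent = parent_of[id(node)]
        regions = [below[id(kids[0])], below[id(kids[1])], below[id(parent)] - below[id(node)]]
        outside = model.leaf_set - below[id(parent)]
        if outside:
            regions.append(outside)
        # round-robin over subsets, reusing leaves a subset already holds and
        # adding one leaf per still-unrepresented witness region
        placed = False
        for _ in range(n_trees):
            s = subsets[k % n_trees]
            k += 1
            additions = [
                rng.choice(sorted(reg)) for reg in regions if not (s & reg)
            ]
            if len(s) + len(additions) <= hi:
                s.update(additions)
                placed = True
                break
        if not placed:
            raise ValueError(
                "covering design infeasible: too few/small subsets for this model"
            )
    for s in subsets:
        target = max(len(s), rng.randint(lo, hi))
        pool = [t for t in universe if t not in s]
        rng.shuffle(pool)
        while len(s) < target and pool:
            s.add(pool.pop())
    # a taxon sampled only once would be singleton-pruned downstream, taking
    # its witness role with it: place every taxon in >= 2 subsets
    for taxon in universe:
        holders = [s for s in subsets if taxon in s]
        if len(holders) == 1:
            others = [s for s in subsets if taxon not in s and len(s) < hi]
            if others:
                rng.choice(others).add(taxon)
    return [sorted(s) for s in subsets]


def input_trees_from_subsets(
    model: Tree,
    subsets: list[list[str]],
    year: int = 2015,
    data_type: Optional[str] = None,
) -> list[InputTree]:
    """Noise-free input trees: the model pruned to each subset.

    Unless a shared ``data_type`` is forced, each tree gets its own tag —
    these fixtures emulate independent evidence, so the pseudoreplication
    rule must not collapse them.
    """
    out = []
    for i, taxa in enumerate(subsets):
        t = prune_to(model, taxa)
        assert t is not None
        out.append(
            InputTree(
                tree=t,
                tree_id=f"tree{i + 1:03d}",
                study_id=f"study{i + 1:03d}",
                year=year,
                data_types=frozenset([data_type or f"data{i + 1:02d}"]),
                weight=Fraction(1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fixture bundle I/O: trees/*.nwk + metadata.csv + model.nwk
# ---------------------------------------------------------------------------

def write_bundle(path: Path | str, trees: list[InputTree], model: Optional[Tree] = None) -> None:
    path = Path(path)
    (path / "trees").mkdir(parents=True, exist_ok=True)
    with open(path / "metadata.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tree_id", "study_id", "year", "data_type", "n_taxa"])
        for t in sorted(trees, key=lambda t: t.tree_id):
            w.writerow(
                [t.tree_id, t.study_id, t.year, ";".join(sorted(t.data_types)), len(t.tree)]
            )
            with open(path / "trees" / f"{t.tree_id}.nwk", "w") as tf:
                tf.write(write_newick(t.tree) + "\n")
    if model is not None:
        with open(path / "model.nwk", "w") as fh:
            fh.write(write_newick(model) + "\n")


def read_bundle(path: Path | str) -> tuple[list[InputTree], Optional[Tree]]:
    path = Path(path)
    trees: list[InputTree] = []
    with open(path / "metadata.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            with open(path / "trees" / f"{row['tree_id']}.nwk") as tf:
                tree = parse_newick(tf.read())
            trees.append(
                InputTree(
                    tree=tree,
                    tree_id=row["tree_id"],
                    study_id=row["study_id"],
                    year=int(row["year"]),
                    data_types=frozenset(x for x in row["data_type"].split(";") if x),
                    weight=Fraction(1),
                )
            )
    model = None
    if (path / "model.nwk").exists():
        with open(path / "model.nwk") as fh:
            model = parse_newick(fh.read())
    return trees, model
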