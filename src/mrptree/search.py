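"""Weighted parsimony scoring and most-parsimonious-tree search on MRP matrices.

Scoring is exact: per-character minimum state changes (Fitch on binary
nodes, Hartigan's max-count generalization on polytomies, '?' as the full
ambiguity set {0,1}), weighted by exact rational character weights.  The
search explores rooted ingroup topologies — the synthetic all-zero outgroup
is held at the root, so the rooted search space is exactly the unrooted
space over ingroup + outgroup.

Two search routes are provided: an exhaustive enumeration for desk-scale
instances (the oracle every heuristic claim is tested against) and a
heuristic with random-addition-sequence replicates plus NNI/SPR/TBR branch
swapping that keeps equal-score trees to harvest the full MPT set.

Internally search trees are immutable nested tuples (leaf label or
``(left, right)``); characters of equal weight are packed into integer bit
blocks so one tree is scored with a handful of big-int operations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional, Union

from .mrp import OUTGROUP, MRPMatrix
from .treecore import Node, Tree

__all__ = [
    "SearchConfig",
    "SearchResult",
    "fitch_score",
    "exhaustive_search",
    "heuristic_search",
    "enforce_constraints",
]

Tup = Union[str, tuple]

EXHAUSTIVE_MAX_INGROUP = 8  # 135135 rooted topologies; beyond this use the heuristic


@dataclass
class SearchConfig:
    """Heuristic search settings (addition replicates + branch swapping)."""

    n_reps: int = 1000
    swap: str = "TBR"
    seed: Optional[int] = None
    max_trees: int = 10000
    constraints: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.swap not in ("TBR", "SPR", "NNI"):
            raise ValueError(f"unknown swap kind {self.swap!r}")


@dataclass
class SearchResult:
    """MPT set (outgroup removed) and its exact weighted score."""

    mpts: list[Tree]
    best_score: Fraction
    reps_completed: int = 0
    hit_max_trees: bool = False


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


class _Blocks:
    """Characters packed per weight class into bit-parallel blocks.

    For each class, each taxon maps to a pair of ints: bit i of the first is
    set when character i allows state 0 for that taxon, of the second when it
    allows state 1 ('?' allows both).  The implicit outgroup contributes one
    extra step for every character whose root state set excludes 0.
    """

    def __init__(self, m: MRPMatrix):
        by_weight: dict[Fraction, list[int]] = {}
        for i, ch in enumerate(m.characters):
            by_weight.setdefault(ch.weight, []).append(i)
        self.classes: list[tuple[Fraction, dict[str, tuple[int, int, int]], int, dict]] = []
        for w in sorted(by_weight):
            idxs = by_weight[w]
            allmask = (1 << len(idxs)) - 1
            leafbits: dict[str, tuple[int, int, int]] = {}
            for taxon in m.ingroup:
                b0 = b1 = 0
                for k, i in enumerate(idxs):
                    s = m.characters[i].state(taxon)
                    if s in ("0", "?"):
                        b0 |= 1 << k
                    if s in ("1", "?"):
                        b1 |= 1 << k
                leafbits[taxon] = (b0, b1, 0)
            # subtree state sets are pure functions of subtree content, so
            # they are memoized across the whole search (structure sharing
            # between neighboring topologies makes the hit rate high)
            self.classes.append((w, leafbits, allmask, {}))

    def _score_class(self, t: Tup, leafbits, allmask, cache) -> tuple[int, int, int]:
        if isinstance(t, str):
            return leafbits[t]
        v = cache.get(t)
        if v is None:
            a0, a1, ca = self._score_class(t[0], leafbits, allmask, cache)
            b0, b1, cb = self._score_class(t[1], leafbits, allmask, cache)
            i0 = a0 & b0
            i1 = a1 & b1
            empty = allmask & ~(i0 | i1)
            v = (
                i0 | ((a0 | b0) & empty),
                i1 | ((a1 | b1) & empty),
                ca + cb + empty.bit_count(),
            )
            cache[t] = v
        return v

    def score(self, t: Tup) -> Fraction:
        """Weighted step count of the ingroup tree rooted by the outgroup."""
        total = Fraction(0)
        for w, leafbits, allmask, cache in self.classes:
            if len(cache) > 2_000_000:  # bound memory on long searches
                cache.clear()
            r0, _r1, cost = self._score_class(t, leafbits, allmask, cache)
            cost += (allmask & ~r0).bit_count()  # joining the all-zero outgroup
            total += w * cost
        return total


def _hartigan_steps(tree: Tree, state_of: dict[str, int]) -> int:
    """Unit-cost minimum changes for one binary character on a rooted tree.

    ``state_of`` maps each leaf label to a 2-bit state set (1 = {0},
    2 = {1}, 3 = {0,1}).  Polytomies are handled by Hartigan's rule: keep
    the states held by the maximum number of children and pay one step per
    child short of that maximum.
    """
    cost = 0
    sets: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = state_of[node.label]
        else:
            n0 = n1 = 0
            for c in node.children:
                s = sets[id(c)]
                n0 += s & 1
                n1 += (s >> 1) & 1
            m = max(n0, n1)
            sets[id(node)] = (1 if n0 == m else 0) | (2 if n1 == m else 0)
            cost += len(node.children) - m
    return cost


def fitch_score(tree: Tree, m: MRPMatrix) -> Fraction:
    """Exact weighted parsimony score of ``tree`` on the matrix.

    The tree may be multifurcating and must carry exactly the matrix taxa
    (including the outgroup row).
    """
    if tree.leaf_set != frozenset(m.taxa):
        missing = sorted(frozenset(m.taxa) - tree.leaf_set)
        extra = sorted(tree.leaf_set - frozenset(m.taxa))
        raise ValueError(
            f"tree/matrix taxa mismatch (missing from tree: {missing}; not in matrix: {extra})"
        )
    total = Fraction(0)
    code = {"0": 1, "1": 2, "?": 3}
    for ch in m.characters:
        state_of = {t: code[ch.state(t)] for t in m.taxa}
        total += ch.weight * _hartigan_steps(tree, state_of)
    return total


# ---------------------------------------------------------------------------
# Tuple-tree utilities
# ---------------------------------------------------------------------------


def _tup_leaves(t: Tup) -> Iterator[str]:
    if isinstance(t, str):
        yield t
    else:
        yield from _tup_leaves(t[0])
        yield from _tup_leaves(t[1])


def _canon(t: Tup) -> Tup:
    """Canonical form: children ordered by their smallest leaf label."""
    if isinstance(t, str):
        return t
    a = _canon(t[0])
    b = _canon(t[1])
    ka = a if isinstance(a, str) else min(_tup_leaves(a))
    kb = b if isinstance(b, str) else min(_tup_leaves(b))
    return (a, b) if ka <= kb else (b, a)


def _tup_to_tree(t: Tup) -> Tree:
    def rec(x: Tup) -> Node:
        if isinstance(x, str):
            return Node(x)
        return Node(children=[rec(x[0]), rec(x[1])])

    return Tree(rec(t), validate=False)


def _tree_to_tup(tree: Tree) -> Tup:
    def rec(node: Node) -> Tup:
        if node.is_leaf:
            return node.label
        if len(node.children) != 2:
            raise ValueError("tuple representation requires a binary tree")
        return (rec(node.children[0]), rec(node.children[1]))

    return rec(tree.root)


def _tup_clusters(t: Tup, acc: set) -> frozenset[str]:
    if isinstance(t, str):
        return frozenset([t])
    left = _tup_clusters(t[0], acc)
    right = _tup_clusters(t[1], acc)
    cl = left | right
    acc.add(cl)
    return cl


def _constraints_ok(t: Tup, constraints: Iterable[frozenset[str]]) -> bool:
    constraints = list(constraints)
    if not constraints:
        return True
    acc: set[frozenset[str]] = set()
    all_leaves = _tup_clusters(t, acc)
    acc.add(all_leaves)
    for c in constraints:
        c_here = c & all_leaves
        if len(c_here) >= 2 and c_here not in acc:
            return False
    return True


def enforce_constraints(tree: Tree, constraints: Iterable[Iterable[str]]) -> bool:
    """True iff every constrained taxon set, restricted to the tree's
    leaves, is monophyletic (a cluster, a single leaf, or absent)."""
    from .treecore import clusters

    cl = clusters(tree)
    cl.add(tree.leaf_set)
    for c in constraints:
        c_here = frozenset(c) & tree.leaf_set
        if len(c_here) >= 2 and c_here not in cl:
            return False
    return True


# ---------------------------------------------------------------------------
# Neighborhoods (on tuple trees)
# ---------------------------------------------------------------------------


def _insertions(t: Tup, s: Tup) -> Iterator[Tup]:
    """All trees obtained by attaching subtree ``s`` on an edge of ``t``
    (including above the root, i.e. sister to everything)."""
    yield (t, s)
    if not isinstance(t, str):
        for a2 in _insertions(t[0], s):
            yield (a2, t[1])
        for b2 in _insertions(t[1], s):
            yield (t[0], b2)


def _bisections(t: Tup) -> Iterator[tuple[Tup, Tup]]:
    """(pruned subtree, remainder) for every non-root subtree position."""
    if isinstance(t, str):
        return
    a, b = t
    yield a, b
    yield b, a
    for s, r in _bisections(a):
        yield s, (r, b)
    for s, r in _bisections(b):
        yield s, (a, r)


def _rerootings(t: Tup) -> Iterator[Tup]:
    """Every rooted binary tree displaying the same unrooted topology."""
    yield t
    if isinstance(t, str):
        return
    # move the root into the left or right subtree, one edge at a time
    def descend(into: Tup, rest: Tup) -> Iterator[Tup]:
        if isinstance(into, str):
            return
        a, b = into
        yield (a, (b, rest))
        yield (b, (a, rest))
        yield from descend(a, (b, rest))
        yield from descend(b, (a, rest))

    yield from descend(t[0], t[1])
    yield from descend(t[1], t[0])


def _nni_neighbors(t: Tup) -> Iterator[Tup]:
    """Nearest-neighbor interchanges across each internal edge."""
    if isinstance(t, str):
        return

    def rec(x: Tup) -> Iterator[Tup]:
        if isinstance(x, str):
            return
        a, b = x
        if not isinstance(a, str):
            a1, a2 = a
            yield ((a1, b), a2)
            yield ((a2, b), a1)
        if not isinstance(b, str):
            b1, b2 = b
            yield (b1, (b2, a))
            yield (b2, (b1, a))
        for a2 in rec(a):
            yield (a2, b)
        for b2 in rec(b):
            yield (a, b2)

    yield from rec(t)


def _spr_neighbors(t: Tup) -> Iterator[Tup]:
    for s, r in _bisections(t):
        for nb in _insertions(r, s):
            yield nb


def _tbr_neighbors(t: Tup) -> Iterator[Tup]:
    for s, r in _bisections(t):
        for s2 in _rerootings(s):
            for nb in _insertions(r, s2):
                yield nb


_NEIGHBORS = {"NNI": _nni_neighbors, "SPR": _spr_neighbors, "TBR": _tbr_neighbors}


# ---------------------------------------------------------------------------
# Exhaustive search (oracle)
# ---------------------------------------------------------------------------


def _all_rooted_trees(taxa: list[str]) -> Iterator[Tup]:
    if len(taxa) == 1:
        yield taxa[0]
        return
    for sub in _all_rooted_trees(taxa[:-1]):
        yield from _insertions(sub, taxa[-1])


def exhaustive_search(
    m: MRPMatrix, constraints: Optional[dict[str, frozenset[str]]] = None
) -> SearchResult:
    """Exact optimum over all rooted binary ingroup topologies.

    Only feasible at desk scale (<= 8 ingroup taxa, 135135 topologies);
    larger instances are directed to :func:`heuristic_search`.  Every
    optimal topology satisfying the constraints is returned.
    """
    taxa = sorted(m.ingroup)
    if len(taxa) > EXHAUSTIVE_MAX_INGROUP:
        raise ValueError(
            f"{len(taxa)} ingroup taxa: exhaustive enumeration is limited to "
            f"{EXHAUSTIVE_MAX_INGROUP}; use heuristic_search"
        )
    cons = [frozenset(c) for c in (constraints or {}).values()]
    blocks = _Blocks(m)
    best: Optional[Fraction] = None
    argmin: list[Tup] = []
    for t in _all_rooted_trees(taxa):
        if cons and not _constraints_ok(t, cons):
            continue
        sc = blocks.score(t)
        if best is None or sc < best:
            best, argmin = sc, [t]
        elif sc == best:
            argmin.append(t)
    if best is None:
        raise ValueError("constraints unsatisfiable: no topology passed")
    return SearchResult(
        mpts=[_tup_to_tree(_canon(t)) for t in argmin],
        best_score=best,
        reps_completed=1,
    )


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------


def _stepwise_addition(
    order: list[str],
    blocks: _Blocks,
    cons: list[frozenset[str]],
    rng: random.Random,
) -> Tup:
    """Random-addition-sequence starting tree: insert each taxon at the
    scored-best position, ties broken by the replicate's seeded rng."""
    t: Tup = (order[0], order[1])
    for x in order[2:]:
        candidates = []
        best_sc: Optional[Fraction] = None
        for cand in _insertions(t, x):
            if cons and not _constraints_ok(cand, cons):
                continue
            sc = blocks.score(cand)
            if best_sc is None or sc < best_sc:
                best_sc, candidates = sc, [cand]
            elif sc == best_sc:
                candidates.append(cand)
        if not candidates:
            raise ValueError(f"constraints unsatisfiable while placing {x!r}")
        t = rng.choice(candidates)
    return t


def _hill_climb(
    start: Tup,
    start_score: Fraction,
    blocks: _Blocks,
    cons: list[frozenset[str]],
    neighbors,
    bound: Optional[Fraction] = None,
) -> tuple[Tup, Fraction]:
    """First-improvement descent to a local optimum of the full neighborhood.

    Cheap NNI rearrangements (a subset of SPR and TBR) are scanned first;
    only at an NNI-local optimum is the full configured neighborhood tried,
    so most moves cost a 2n-neighbor scan rather than an n^3 one.  Stops
    early at ``bound`` (the weighted character count), which no tree can
    beat.
    """
    t, sc = start, start_score

    def first_better(cur: Tup, cur_sc: Fraction, gen) -> Optional[tuple[Tup, Fraction]]:
        for nb in gen(cur):
            if cons and not _constraints_ok(nb, cons):
                continue
            nsc = blocks.score(nb)
            if nsc < cur_sc:
                return nb, nsc
        return None

    while True:
        if bound is not None and sc <= bound:
            return t, sc
        step = None
        if neighbors is not _nni_neighbors:
            step = first_better(t, sc, _nni_neighbors)
        if step is None:
            step = first_better(t, sc, neighbors)
        if step is None:
            return t, sc
        t, sc = step


class _PlateauPool:
    """Global store of equal-best trees, swept to closure exactly once.

    Swapping a pool member may reveal a strictly better tree (the pool is
    then reset) or new equal-score topologies (added until max_trees).
    """

    def __init__(self, blocks: _Blocks, cons, neighbors, max_trees: int,
                 bound: Optional[Fraction] = None):
        self.blocks = blocks
        self.cons = cons
        self.neighbors = neighbors
        self.max_trees = max_trees
        self.bound = bound
        self.best: Optional[Fraction] = None
        self.pool: dict[Tup, Tup] = {}
        self.swapped: set[Tup] = set()
        self.hit_max = False

    def offer(self, t: Tup, sc: Fraction) -> None:
        if self.best is None or sc < self.best:
            self.best = sc
            self.pool = {_canon(t): t}
            self.swapped = set()
            self.hit_max = False
        elif sc == self.best:
            ck = _canon(t)
            if ck not in self.pool:
                if len(self.pool) < self.max_trees:
                    self.pool[ck] = t
                else:
                    self.hit_max = True

    def sweep(self) -> None:
        """Swap every unswapped pool member; descend and reset on improvement."""
        while True:
            todo = [k for k in self.pool if k not in self.swapped]
            if not todo:
                return
            key = todo[0]
            self.swapped.add(key)
            for nb in self.neighbors(self.pool[key]):
                if self.cons and not _constraints_ok(nb, self.cons):
                    continue
                sc = self.blocks.score(nb)
                if sc < self.best:
                    t, sc = _hill_climb(
                        nb, sc, self.blocks, self.cons, self.neighbors, self.bound
                    )
                    self.offer(t, sc)
                    break
                if sc == self.best:
                    self.offer(nb, sc)


def heuristic_search(m: MRPMatrix, config: Optional[SearchConfig] = None) -> SearchResult:
    """Random-addition + branch-swapping search for most-parsimonious trees.

    Each replicate builds a starting tree by stepwise addition in a random
    taxon order and swaps it (``config.swap``) to a local optimum, keeping
    all equal-score topologies; the MPT set is the union of plateau trees at
    the best score seen across replicates, capped at ``max_trees``.
    Deterministic given ``config.seed``.  Monophyly constraints are enforced
    by rejecting violating topologies throughout.
    """
    config = config or SearchConfig()
    config.validate()
    seed = config.seed if config.seed is not None else random.randrange(2**31)
    rng = random.Random(seed)
    taxa = sorted(m.ingroup)
    cons = [frozenset(c) for c in config.constraints.values()]
    blocks = _Blocks(m)
    neighbors = _NEIGHBORS[config.swap]

    if len(taxa) == 2:
        t: Tup = (taxa[0], taxa[1])
        return SearchResult([_tup_to_tree(t)], blocks.score(t), reps_completed=1)

    # no topology beats one step per informative character
    bound = m.total_weight()
    pool = _PlateauPool(blocks, cons, neighbors, config.max_trees, bound)
    reps = 0
    for _ in range(config.n_reps):
        order = taxa[:]
        rng.shuffle(order)
        start = _stepwise_addition(order, blocks, cons, rng)
        t, sc = _hill_climb(start, blocks.score(start), blocks, cons, neighbors, bound)
        pool.offer(t, sc)
        reps += 1
    pool.sweep()
    assert pool.best is not None
    mpts = [_tup_to_tree(ck) for ck in sorted(pool.pool, key=repr)]
    return SearchResult(
        mpts=mpts,
        best_score=pool.best,
        reps_completed=reps,
        hit_max_trees=pool.hit_max,
    )
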