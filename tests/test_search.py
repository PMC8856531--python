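"""Parsimony scoring and search, checked against independent brute force.

The scoring oracle enumerates all internal-node state assignments and all
resolutions of missing leaves; the search oracle enumerates all rooted
topologies.  Both are kept entirely separate from the implementation paths
they check.
"""

import itertools
import random
from fractions import Fraction

import pytest

from mrptree.mrp import OUTGROUP, encode_matrix
from mrptree.search import (
    SearchConfig,
    enforce_constraints,
    exhaustive_search,
    fitch_score,
    heuristic_search,
)
from mrptree.treecore import Tree, clusters, parse_newick

from .conftest import make_input, random_tree


# ---------------------------------------------------------------------------
# Brute-force oracle: minimum changes by enumerating internal states
# ---------------------------------------------------------------------------


def brute_force_steps(tree: Tree, leaf_state: dict) -> int:
    """Minimum changes for one binary character, by full enumeration.

    ``leaf_state`` maps leaf -> '0' / '1' / '?'.  Enumerates every 0/1
    assignment to internal nodes and to '?' leaves and counts differing
    parent-child edges.
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    free_leaves = [n for n in nodes if n.is_leaf and leaf_state[n.label] == "?"]
    parent = {}
    for n in nodes:
        for c in n.children:
            parent[id(c)] = n
    best = None
    for states in itertools.product("01", repeat=len(internal) + len(free_leaves)):
        assign = {}
        for n, s in zip(internal, states):
            assign[id(n)] = s
        for n, s in zip(free_leaves, states[len(internal):]):
            assign[id(n)] = s
        for n in nodes:
            if n.is_leaf and leaf_state[n.label] != "?":
                assign[id(n)] = leaf_state[n.label]
        cost = sum(
            1
            for n in nodes
            if id(n) in parent and assign[id(n)] != assign[id(parent[id(n)])]
        )
        best = cost if best is None else min(best, cost)
    return best


def random_binary_newick(taxa, rng) -> str:
    """Random rooted binary topology over ``taxa`` by random pairwise joins."""
    items = list(taxa)
    rng.shuffle(items)
    while len(items) > 1:
        a = items.pop(rng.randrange(len(items)))
        b = items.pop(rng.randrange(len(items)))
        items.append(f"({a},{b})")
    return items[0] + ";"


def random_matrix(rng, n_taxa, n_chars, missing_prob=0.3, weights=(1,)):
    """Random informative MRP-style matrix as a list of InputTree stand-ins."""
    from mrptree.mrp import Character, MRPMatrix

    taxa = [f"T{i}" for i in range(n_taxa)]
    chars = []
    k = 0
    while len(chars) < n_chars:
        k += 1
        present = [t for t in taxa if rng.random() > missing_prob]
        if len(present) < 3:
            continue
        size = rng.randint(2, len(present) - 1)
        cluster = frozenset(rng.sample(present, size))
        chars.append(
            Character(
                tree_id=f"src{k}",
                cluster=cluster,
                in_tree=frozenset(present),
                weight=Fraction(rng.choice(weights)),
            )
        )
    return MRPMatrix(taxa, chars)


class TestFitchScore:
    def test_single_origin_costs_one(self):
        m = encode_matrix([make_input("((A,B),(C,D));", "t1")])
        t = parse_newick(f"(((A,B),(C,D)),{OUTGROUP});")
        assert fitch_score(t, m) == 2  # two characters, one step each

    def test_incongruent_tree_costs_more(self):
        m = encode_matrix([make_input("((A,B),(C,D));", "t1")])
        t = parse_newick(f"(((A,C),(B,D)),{OUTGROUP});")
        assert fitch_score(t, m) == 4

    def test_missing_state_is_free_choice(self):
        """A '?' leaf takes whichever state minimizes the count."""
        t1 = make_input("((A,B),C);", "t1")  # char over {A,B,C}: B inside
        t2 = make_input("((A,B),D);", "t2", study="s2")
        m = encode_matrix([t1, t2], ["A", "B", "C", "D"])
        t = parse_newick(f"(((A,B),(C,D)),{OUTGROUP});")
        assert fitch_score(t, m) == 2

    def test_taxon_mismatch_raises(self):
        m = encode_matrix([make_input("((A,B),C);", "t1")])
        with pytest.raises(ValueError, match="mismatch"):
            fitch_score(parse_newick("((A,B),C);"), m)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_binary_trees(self, seed):
        rng = random.Random(seed)
        m = random_matrix(rng, n_taxa=6, n_chars=4, weights=(1, 1, 2))
        ingroup_newick = random_binary_newick(m.ingroup, rng)
        full = parse_newick(f"({ingroup_newick[:-1]},{OUTGROUP});")
        expected = Fraction(0)
        for ch in m.characters:
            states = {taxon: ch.state(taxon) for taxon in m.taxa}
            expected += ch.weight * brute_force_steps(full, states)
        assert fitch_score(full, m) == expected

    @pytest.mark.parametrize("newick", [
        "((A,B,C),(D,E),{og});",
        "(A,B,C,D,E,{og});",
        "(((A,B),(C,D,E)),{og});",
    ])
    def test_matches_brute_force_on_polytomies(self, newick):
        rng = random.Random(99)
        m = random_matrix(rng, n_taxa=5, n_chars=5, weights=(1,))
        mapping = dict(zip("ABCDE", [f"T{i}" for i in range(5)]))
        for old, new in mapping.items():
            newick = newick.replace(old, new)
        t = parse_newick(newick.format(og=OUTGROUP))
        expected = sum(
            ch.weight * brute_force_steps(t, {x: ch.state(x) for x in m.taxa})
            for ch in m.characters
        )
        assert fitch_score(t, m) == expected


class TestExhaustiveSearch:
    def test_single_source_tree_recovered_uniquely(self):
        src = make_input("(((A,B),C),(D,E));", "t1")
        m = encode_matrix([src])
        res = exhaustive_search(m)
        assert res.best_score == m.n_characters  # one step per clade character
        assert len(res.mpts) == 1
        assert clusters(res.mpts[0]) == clusters(src.tree)

    def test_two_incompatible_resolutions_tie(self):
        a = make_input("((A,B),(C,D));", "t1")
        b = make_input("((A,C),(B,D));", "t2", study="s2")
        m = encode_matrix([a, b])
        res = exhaustive_search(m)
        mpt_clusters = [clusters(t) for t in res.mpts]
        assert clusters(a.tree) in mpt_clusters
        assert clusters(b.tree) in mpt_clusters

    def test_nonbinding_constraint_keeps_score(self):
        src = make_input("(((A,B),C),D);", "t1")
        m = encode_matrix([src])
        free = exhaustive_search(m)
        constrained = exhaustive_search(m, {"c": frozenset({"A", "B"})})
        assert free.best_score == constrained.best_score

    def test_too_many_taxa_rejected(self):
        rng = random.Random(0)
        m = random_matrix(rng, n_taxa=9, n_chars=3)
        with pytest.raises(ValueError, match="heuristic"):
            exhaustive_search(m)


class TestHeuristicSearch:
    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_small_instances(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 6)
        m = random_matrix(rng, n_taxa=n, n_chars=rng.randint(3, 6), weights=(1, 2))
        exact = exhaustive_search(m)
        heur = heuristic_search(m, SearchConfig(n_reps=8, swap="TBR", seed=seed))
        assert heur.best_score == exact.best_score

    def test_mpt_set_closed_at_small_size(self):
        """All optima found: heuristic MPT set == exhaustive MPT set (<=6 taxa)."""
        rng = random.Random(7)
        m = random_matrix(rng, n_taxa=6, n_chars=5)
        exact = exhaustive_search(m)
        heur = heuristic_search(m, SearchConfig(n_reps=20, swap="TBR", seed=7))
        assert {t.topology_key() for t in heur.mpts} == {
            t.topology_key() for t in exact.mpts
        }

    def test_single_tree_20_taxa_recovered(self):
        from mrptree.treecore import write_newick

        model = random_tree(20, 42)
        src = make_input(write_newick(model), "t1")
        m = encode_matrix([src])
        res = heuristic_search(m, SearchConfig(n_reps=5, swap="TBR", seed=1))
        assert res.best_score == m.n_characters
        assert len(res.mpts) == 1
        assert clusters(res.mpts[0]) == clusters(model)

    def test_weight_doubling_scales_score(self):
        from dataclasses import replace as dc_replace

        rng = random.Random(3)
        m = random_matrix(rng, n_taxa=6, n_chars=5)
        doubled = type(m)(
            m.ingroup, [dc_replace(ch, weight=ch.weight * 2) for ch in m.characters]
        )
        a = heuristic_search(m, SearchConfig(n_reps=10, seed=3))
        b = heuristic_search(doubled, SearchConfig(n_reps=10, seed=3))
        assert b.best_score == 2 * a.best_score
        assert {t.topology_key() for t in a.mpts} == {t.topology_key() for t in b.mpts}

    def test_determinism(self):
        rng = random.Random(11)
        m = random_matrix(rng, n_taxa=7, n_chars=6)
        from mrptree.treecore import write_newick

        a = heuristic_search(m, SearchConfig(n_reps=6, seed=5))
        b = heuristic_search(m, SearchConfig(n_reps=6, seed=5))
        assert [write_newick(t) for t in a.mpts] == [write_newick(t) for t in b.mpts]

    def test_constraints_respected(self):
        a = make_input("((A,B),(C,D));", "t1")
        b = make_input("((A,C),(B,D));", "t2", study="s2")
        m = encode_matrix([a, b])
        res = heuristic_search(
            m, SearchConfig(n_reps=10, seed=2, constraints={"k": frozenset("AC")})
        )
        for t in res.mpts:
            assert enforce_constraints(t, [{"A", "C"}])


class TestEnforceConstraints:
    def test_satisfied(self):
        t = parse_newick("((A,B),(C,D));")
        assert enforce_constraints(t, [{"A", "B"}])

    def test_violated(self):
        t = parse_newick("((A,B),(C,D));")
        assert not enforce_constraints(t, [{"A", "C"}])

    def test_single_present_taxon_vacuous(self):
        t = parse_newick("((A,B),(C,D));")
        assert enforce_constraints(t, [{"A", "X"}])
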