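import pytest

from mrptree.partition import PartitionSpec, graft, reduce_tree, run_partitioned
from mrptree.search import SearchConfig
from mrptree.synthgen import (
    generate_model_tree,
    input_trees_from_subsets,
    sample_covering_subsets,
)
from mrptree.treecore import clusters, parse_newick, prune_to, rf_distance, write_newick

from .conftest import make_input


class TestReduceTree:
    def test_monophyletic_members_replaced_in_place(self):
        t = make_input("((a1,a2),(B,C));", "t1")
        r = reduce_tree(t, "N", {"a1", "a2"})
        assert r.tree.leaf_set == {"N", "B", "C"}
        assert clusters(r.tree) == {frozenset({"B", "C"})}

    def test_non_monophyletic_members_attach_at_mrca_parent(self):
        t = make_input("((a1,B),(a2,C));", "t1")
        r = reduce_tree(t, "N", {"a1", "a2"})
        assert r.tree.leaf_set == {"N", "B", "C"}
        assert clusters(r.tree) == set()  # star: N at the root

    def test_strict_mode_raises_on_non_monophyly(self):
        t = make_input("((a1,B),(a2,C));", "t1")
        with pytest.raises(ValueError, match="monophyletic"):
            reduce_tree(t, "N", {"a1", "a2"}, strict=True)

    def test_tree_without_members_unchanged(self):
        t = make_input("((A,B),C);", "t1")
        assert reduce_tree(t, "N", {"X", "Y"}) is t

    def test_tree_entirely_inside_clade_dropped(self):
        t = make_input("((a1,a2),a3);", "t1")
        assert reduce_tree(t, "N", {"a1", "a2", "a3"}) is None

    def test_never_increases_leaf_count(self):
        t = make_input("(((a1,a2),B),(C,(a3,D)));", "t1")
        r = reduce_tree(t, "N", {"a1", "a2", "a3"})
        assert len(r.tree) <= len(t.tree)


class TestGraft:
    def test_basic_graft(self):
        backbone = parse_newick("(N,(B,C));")
        sub = parse_newick("((x,y),z);")
        out = graft(backbone, "N", sub)
        assert write_newick(out) == "(((x,y),z),(B,C));"
        assert frozenset("xyz") in clusters(out)

    def test_leaf_count_conservation(self):
        backbone = parse_newick("((N,A),(B,C));")
        sub = parse_newick("((x,y),(z,w));")
        out = graft(backbone, "N", sub)
        assert len(out) == len(backbone) - 1 + len(sub)

    def test_graft_then_reduce_recovers_backbone(self):
        backbone = parse_newick("((N,A),(B,C));")
        sub = parse_newick("((x,y),z);")
        grafted = graft(backbone, "N", sub)
        back = reduce_tree(make_input(write_newick(grafted), "g"), "N", {"x", "y", "z"})
        assert clusters(back.tree) == clusters(backbone)

    def test_missing_placeholder_rejected(self):
        with pytest.raises(ValueError, match="placeholder"):
            graft(parse_newick("((A,B),C);"), "N", parse_newick("(x,y);"))

    def test_overlapping_leaves_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            graft(parse_newick("((N,A),B);"), "N", parse_newick("(A,y);"))


class TestPartitionSpec:
    def test_nested_spec_valid(self):
        spec = PartitionSpec(
            [("inner", frozenset("ABC")), ("outer", frozenset("ABCDE"))]
        )
        spec.validate()

    def test_overlap_without_nesting_rejected(self):
        spec = PartitionSpec(
            [("p1", frozenset("ABC")), ("p2", frozenset("BCD"))]
        )
        with pytest.raises(ValueError, match="overlap"):
            spec.validate()

    def test_outer_before_inner_rejected(self):
        spec = PartitionSpec(
            [("outer", frozenset("ABCDE")), ("inner", frozenset("ABC"))]
        )
        with pytest.raises(ValueError, match="innermost"):
            spec.validate()

    def test_small_partition_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            PartitionSpec([("p", frozenset("AB"))]).validate()


class TestRunPartitioned:
    @staticmethod
    def fixture(seed=0, n_taxa=16, n_trees=8, sizes=(7, 9)):
        model = generate_model_tree(n_taxa, seed)
        subsets = sample_covering_subsets(model, n_trees, sizes, seed)
        return model, input_trees_from_subsets(model, subsets)

    def test_single_partition_equals_unpartitioned(self):
        from mrptree.consensus import majority_consensus
        from mrptree.mrp import encode_matrix
        from mrptree.search import heuristic_search

        model, trees = self.fixture(seed=3)
        all_taxa = frozenset().union(*(t.taxa for t in trees))
        spec = PartitionSpec([("all", all_taxa)])
        cfg = SearchConfig(n_reps=10, seed=1)
        final, results = run_partitioned(trees, spec, cfg)

        matrix = encode_matrix(trees)
        res = heuristic_search(matrix, SearchConfig(n_reps=10, seed=1))
        direct = majority_consensus(res.mpts)
        assert rf_distance(final, direct.tree) == 0

    def test_true_clade_partition_agrees_with_unpartitioned(self):
        """Conflict-free fixture, partition = true model clade: the grafted
        result matches both the unpartitioned run and the model."""
        from mrptree.consensus import majority_consensus
        from mrptree.mrp import encode_matrix
        from mrptree.search import heuristic_search

        model, trees = self.fixture(seed=1)
        # use a true model cluster of workable size as the inner partition
        clade = next(c for c in sorted(clusters(model), key=len, reverse=True)
                     if 4 <= len(c) <= 8)
        spec = PartitionSpec([("inner", clade)])
        cfg = SearchConfig(n_reps=10, seed=2)
        final, results = run_partitioned(trees, spec, cfg)

        res = heuristic_search(encode_matrix(trees), SearchConfig(n_reps=10, seed=2))
        direct = majority_consensus(res.mpts)
        assert rf_distance(final, direct.tree) == 0
        assert rf_distance(final, prune_to(model, final.leaf_set)) == 0

    def test_three_level_nesting_structure(self):
        model, trees = self.fixture(seed=2, n_taxa=18, n_trees=9, sizes=(8, 10))
        big = next(c for c in sorted(clusters(model), key=len, reverse=True)
                   if 7 <= len(c) <= 10)
        small = next((c for c in sorted(clusters(model), key=len, reverse=True)
                      if c < big and 3 <= len(c) <= len(big) - 2), None)
        if small is None:
            pytest.skip("model tree lacks a usable nested clade pair")
        spec = PartitionSpec([("small", small), ("big", big)])
        final, results = run_partitioned(trees, spec, SearchConfig(n_reps=8, seed=3))
        assert set(results) == {"small", "big", "__backbone__"}
        assert results["big"].reduced_placeholders == ["small"]
        assert small in clusters(final)
        assert big in clusters(final)
        assert final.leaf_set == frozenset().union(*(t.taxa for t in trees))
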