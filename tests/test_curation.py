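from fractions import Fraction

import pytest

from mrptree.curation import (
    connectivity_check,
    overlap_fractions,
    remove_singletons,
    representation_filter,
    resolve_pseudoreplication,
)

from .conftest import make_input


class TestOverlapFractions:
    def test_identical_leaf_sets(self):
        a = make_input("((A,B),C);", "t1")
        b = make_input("(A,(B,C));", "t2", study="s2")
        assert overlap_fractions(a, b) == (1, 1)

    def test_disjoint(self):
        a = make_input("((A,B),C);", "t1")
        b = make_input("((X,Y),Z);", "t2", study="s2")
        assert overlap_fractions(a, b) == (0, 0)

    def test_asymmetric(self):
        a = make_input("((A,B),(C,D));", "t1")
        b = make_input("(((C,D),E),(F,(G,H)));", "t2", study="s2")
        assert overlap_fractions(a, b) == (Fraction(1, 2), Fraction(1, 3))


class TestResolvePseudoreplication:
    def test_four_same_study_alternatives_weighted_quarter(self):
        """Four alternative trees from one study are all kept at 25% weight."""
        trees = [
            make_input("((A,B),(C,D));", "t1"),
            make_input("((A,C),(B,D));", "t2"),
            make_input("((A,D),(B,C));", "t3"),
            make_input("(((A,B),C),D);", "t4"),
        ]
        retained, report = resolve_pseudoreplication(trees)
        assert len(retained) == 4
        assert all(t.weight == Fraction(1, 4) for t in retained)
        assert sum(t.weight for t in retained) == 1

    def test_two_alternatives_weighted_half(self):
        trees = [
            make_input("((A,B),(C,D));", "t1"),
            make_input("((A,C),(B,D));", "t2"),
        ]
        retained, _ = resolve_pseudoreplication(trees)
        assert [t.weight for t in retained] == [Fraction(1, 2), Fraction(1, 2)]

    def test_comprehensive_tree_preferred(self):
        big = make_input("(((A,B),(C,D)),(E,F));", "big", study="s1")
        small = make_input("((A,B),(C,D),E);", "small", study="s2")
        retained, report = resolve_pseudoreplication([big, small])
        assert [t.tree_id for t in retained] == ["big"]
        assert retained[0].weight == 1
        assert report.discarded == {"small": "pseudoreplicate_dropped"}

    def test_different_data_types_not_in_conflict(self):
        a = make_input("((A,B),(C,D));", "t1", tags=("COI",))
        b = make_input("((A,C),(B,D));", "t2", study="s2", tags=("morphology",))
        retained, _ = resolve_pseudoreplication([a, b])
        assert len(retained) == 2
        assert all(t.weight == 1 for t in retained)

    def test_low_overlap_pair_both_kept(self):
        a = make_input("((A,B),(C,D));", "t1")
        b = make_input("((C,D),(E,F));", "t2", study="s2")
        retained, _ = resolve_pseudoreplication([a, b])
        assert len(retained) == 2
        assert all(t.weight == 1 for t in retained)

    def test_missing_data_type_raises(self):
        bad = make_input("((A,B),C);", "t1", tags=())
        with pytest.raises(ValueError, match="t1"):
            resolve_pseudoreplication([bad])

    def test_never_keeps_high_overlap_same_type_pair_unless_tied(self):
        big = make_input("(((A,B),(C,D)),E);", "big", study="s1")
        small = make_input("((A,B),(C,D));", "small", study="s2")
        retained, _ = resolve_pseudoreplication([big, small])
        ids = {t.tree_id for t in retained}
        assert ids == {"big"}

    def test_report_is_exhaustive(self):
        trees = [
            make_input("((A,B),(C,D));", "t1"),
            make_input("((A,C),(B,D));", "t2"),
            make_input("((X,Y),Z);", "t3", study="s3"),
        ]
        retained, report = resolve_pseudoreplication(trees)
        assert len(report.retained) + len(report.discarded) == 3


class TestRemoveSingletons:
    def test_singleton_pruned(self):
        trees = [
            make_input("((A,B),(C,X));", "t1"),
            make_input("((A,B),C);", "t2", study="s2"),
        ]
        out, report = remove_singletons(trees)
        assert report.removed_taxa == {"X": "singleton"}
        union = set().union(*(t.taxa for t in out))
        assert "X" not in union

    def test_taxon_in_two_trees_kept(self):
        trees = [
            make_input("((A,B),C);", "t1"),
            make_input("((A,B),D);", "t2", study="s2"),
        ]
        out, report = remove_singletons(trees)
        assert "C" in report.removed_taxa and "D" in report.removed_taxa
        assert {"A", "B"} <= set().union(*(t.taxa for t in out)) if out else True

    def test_cascade_to_fixed_point(self):
        """Dropping a shrunken tree can orphan another taxon; sweeps repeat."""
        trees = [
            make_input("((A,X),Y);", "t1"),          # X,Y only here with A
            make_input("((A,B),(C,D));", "t2", study="s2"),
            make_input("((B,C),(D,A));", "t3", study="s3"),
        ]
        out, report = remove_singletons(trees)
        # X and Y are singletons; pruning leaves t1 with 1 leaf -> dropped
        assert report.discarded.get("t1") == "too_few_leaves"
        assert {"X", "Y"} <= set(report.removed_taxa)
        # fixed point: a second application changes nothing
        out2, _ = remove_singletons(out)
        assert [t.tree_id for t in out2] == [t.tree_id for t in out]
        assert all(a.taxa == b.taxa for a, b in zip(out, out2))


class TestConnectivity:
    def test_two_shared_taxa_connect(self):
        a = make_input("((A,B),C);", "t1")
        b = make_input("((A,B),D);", "t2", study="s2")
        assert len(connectivity_check([a, b])) == 1

    def test_disjoint_trees_split(self):
        a = make_input("((A,B),C);", "t1")
        b = make_input("((X,Y),Z);", "t2", study="s2")
        assert len(connectivity_check([a, b])) == 2

    def test_chain_is_one_component(self):
        a = make_input("((A,B),C);", "t1")
        b = make_input("((B,C),(D,E));", "t2", study="s2")
        c = make_input("((D,E),F);", "t3", study="s3")
        assert len(connectivity_check([a, b, c])) == 1

    def test_one_shared_taxon_insufficient(self):
        a = make_input("((A,B),C);", "t1")
        b = make_input("((C,X),Y);", "t2", study="s2")
        assert len(connectivity_check([a, b])) == 2


class TestRepresentationFilter:
    def test_zero_cells_removed(self):
        assert representation_filter({"A": 3}, {"A": 0}) == ["A"]

    def test_well_represented_kept(self):
        assert representation_filter({"A": 3}, {"A": 10}) == []

    def test_monotone_in_min_cells(self):
        tree_counts = {f"T{i}": 2 + i % 3 for i in range(10)}
        cell_counts = {f"T{i}": i for i in range(10)}
        prev: set = set()
        for min_cells in range(0, 8):
            removed = set(
                representation_filter(tree_counts, cell_counts, min_cells=min_cells)
            )
            assert prev <= removed
            prev = removed
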