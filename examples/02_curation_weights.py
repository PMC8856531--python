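"""Pseudoreplication control: the 50% overlap rule and fractional weights.

Four alternative trees from one study (same underlying data) cannot be
chosen between, so all four are retained at weight 1/4 — together they count
as one tree's worth of evidence.  A more comprehensive tree beats a smaller
tree built from the same data type.
"""

from fractions import Fraction

from mrptree.curation import InputTree, overlap_fractions, resolve_pseudoreplication
from mrptree.treecore import parse_newick


def tree(newick, tree_id, study, tags=("multilocus",)):
    return InputTree(
        tree=parse_newick(newick), tree_id=tree_id, study_id=study,
        year=2015, data_types=frozenset(tags), weight=Fraction(1),
    )


four_alternatives = [
    tree("((A,B),(C,D));", "alt1", "study1"),
    tree("((A,C),(B,D));", "alt2", "study1"),
    tree("((A,D),(B,C));", "alt3", "study1"),
    tree("(((A,B),C),D);", "alt4", "study1"),
]
retained, _ = resolve_pseudoreplication(four_alternatives)
for t in retained:
    print(f"{t.tree_id}: weight {t.weight} ({float(t.weight):.0%})")

big = tree("(((A,B),(C,D)),(E,F));", "comprehensive", "study2")
small = tree("((A,B),(C,D));", "subset", "study3")
print("overlap fractions:", overlap_fractions(big, small))
retained, report = resolve_pseudoreplication([big, small])
print("kept:", [t.tree_id for t in retained], "| dropped:", dict(report.discarded))

# Each alternative gets 25% weight (they sum to one tree of evidence); the
# 6-taxon tree is preferred over the fully nested 4-taxon tree, which is
# dropped as a pseudoreplicate.
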