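"""Baum-Ragan coding: input-tree clades become binary characters.

Each internal node of each input tree is one column: 1 inside the clade,
0 elsewhere in that tree, ? for taxa the tree does not sample.  A synthetic
all-zero outgroup row roots the parsimony analysis.
"""

from fractions import Fraction

from mrptree.curation import InputTree
from mrptree.mrp import encode_matrix, matrix_fill_stats, write_nexus
from mrptree.treecore import parse_newick


def tree(newick, tree_id, weight=Fraction(1)):
    return InputTree(
        tree=parse_newick(newick), tree_id=tree_id, study_id=tree_id,
        year=2015, data_types=frozenset(["COI"]), weight=weight,
    )


trees = [
    tree("(((A,B),C),D);", "t1", weight=Fraction(1, 2)),
    tree("((B,C),(D,E));", "t2"),
]
m = encode_matrix(trees)
for taxon in m.taxa:
    print(f"{taxon:>14}  {m.row(taxon)}")
stats = matrix_fill_stats(m)
print(f"missing cells: {float(stats['missing_fraction']):.0%}")
print()
print(write_nexus(m))

# Four characters: two from each tree's internal nodes. E has ? in t1's
# columns and A in t2's. The NEXUS ASSUMPTIONS block carries the exact
# relative weights (1/2 vs 1) scaled to integers 1 and 2.
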