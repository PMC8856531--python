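"""V and V+ clade support, and collapsing novel relationships.

V = (s - q)/(s + q) over supporting and conflicting input trees;
V+ = (s + p - q)/(s + p + q) additionally counts permitting (non-conflicting)
trees as support.  A clade with V = V+ = -1 occurs in no input tree — a
novel relationship that should be collapsed into a polytomy.
"""

from fractions import Fraction

from mrptree.curation import InputTree
from mrptree.support import collapse_novel, score_supertree, support_table
from mrptree.treecore import parse_newick, write_newick


def tree(newick, tree_id, study):
    return InputTree(
        tree=parse_newick(newick), tree_id=tree_id, study_id=study,
        year=2015, data_types=frozenset([tree_id]), weight=Fraction(1),
    )


inputs = [
    tree("(((A,B),C),(D,E));", "t1", "s1"),   # supports {A,B}
    tree("(((A,C),B),(D,E));", "t2", "s2"),   # conflicts with {A,B}
    tree("((A,B,C),(D,E));", "t3", "s3"),     # polytomy: permits {A,B}
]
supertree = parse_newick("(((A,B),C),(D,E));")
scores = score_supertree(supertree, inputs)
print(support_table(scores).to_string(index=False))

collapsed = collapse_novel(supertree, scores)
print("after collapsing novel clades:", write_newick(collapsed))

# {A,B}: s=1, q=1, p=1 -> V = 0 (even conflict), V+ = 1/3 (the polytomy
# counts as weak support). {D,E} and {A,B,C} are supported by all relevant
# trees (V = +1). No clade here is novel, so the collapse is the identity.
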