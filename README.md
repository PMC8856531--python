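# mrptree

Matrix-representation-with-parsimony (MRP) supertree construction for
collections of published phylogenies — the situation faced by anyone trying
to assemble, say, a genus-level tree for a regional fauna from dozens of
papers that each sampled a different, partially overlapping handful of taxa.

The package implements the full analysis pipeline as a tested library:

1. **Curation** of input trees under a pseudoreplication protocol: two trees
   built from the same data type may both stay only if each keeps at least
   half of its taxa private; otherwise the more comprehensive tree is
   preferred; indistinguishable alternatives are all retained at weight
   1/*n* (two trees get 50% weighting, four get 25%). Taxa occurring in only
   one input tree are removed — a single tree cannot place a taxon in a
   supertree — and the tree-overlap graph is checked for connectivity.
2. **Baum–Ragan coding**: every internal node of every input tree becomes a
   binary character (1 inside the clade, 0 elsewhere in that tree, `?` for
   taxa the tree does not sample), weighted by the source tree's curation
   weight, with a synthetic all-zero outgroup row to root the analysis.
3. **Weighted parsimony search**: exact Fitch/Hartigan scoring (missing
   entries as the full ambiguity set, exact rational weights), heuristic
   search with random-addition-sequence replicates and NNI/SPR/TBR branch
   swapping that harvests the complete set of equally best trees, plus an
   exhaustive oracle for desk-scale instances. Monophyly constraints are
   enforced by rejection.
4. **Consensus**: strict and 50% majority rule (strictly-greater-than-half).
5. **Clade support**: for each supertree clade, each input tree either
   supports (s), conflicts with (q), permits (p), or is irrelevant to it;
   then `V = (s − q)/(s + q)` and `V⁺ = (s + p − q)/(s + p + q)`, both on a
   −1…+1 scale. Clades with `V = V⁺ = −1` occur in no input tree — novel,
   spurious relationships — and are collapsed into polytomies.
6. **Nested partitions**: a named clade can be analysed separately, appear
   as a single placeholder taxon in the enclosing analysis, and be grafted
   back afterwards — the standard remedy when the combined matrix carries
   too much missing data for a single search.
7. A **synthetic-data generator** (known model tree, partial taxon sampling,
   NNI noise, polytomies, pseudoreplicate groups) so that every stage is
   testable against ground truth.

## Worked example

```python
from fractions import Fraction
from mrptree import InputTree, parse_newick, encode_matrix, heuristic_search
from mrptree import SearchConfig, strict_consensus, score_supertree

def tree(nwk, tid, study, tag):
    return InputTree(tree=parse_newick(nwk), tree_id=tid, study_id=study,
                     year=2015, data_types=frozenset([tag]), weight=Fraction(1))

trees = [tree("((A,B),(C,D));", "t1", "s1", "COI"),
         tree("((A,C),(B,D));", "t2", "s2", "morphology")]
m = encode_matrix(trees)
res = heuristic_search(m, SearchConfig(n_reps=10, swap="TBR", seed=0))
print(res.best_score, len(res.mpts))
```

prints `6 2`: the four characters (two clades per input tree) cannot all fit
in one step each — whichever resolution of the contested taxa wins, the
losing tree's two characters cost one extra step apiece — and both source
topologies are equally best. Their strict consensus is the star `(A,B,C,D);`:
evidence exactly balanced, no side taken. Scoring either most-parsimonious
tree against the inputs gives the contested clade `s = 1, q = 1`, hence
`V = 0`.

The `examples/` directory has one short runnable script per capability
(pipeline, curation weights, matrix coding, search and consensus, V/V⁺
support, partitions, coverage reporting), and the same pipeline is scriptable
from the shell:

```sh
mrptree simulate --n-taxa 24 --n-trees 10 --seed 11 --out bundle/
mrptree run-all --config config.yaml
```

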