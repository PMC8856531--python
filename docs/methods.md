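# Methods

## The problem and the model

A supertree synthesizes a set of published *input trees* — rooted,
leaf-labeled, possibly multifurcating phylogenies over partially
overlapping taxon sets — into one tree over their union. `mrptree`
implements the matrix-representation-with-parsimony (MRP) route: each
internal non-root node of each input tree is coded as a binary character
(1 = taxon inside the clade, 0 = taxon elsewhere in that tree, `?` = taxon
not sampled by that tree), the characters are concatenated into one matrix,
and the supertree is a most-parsimonious tree (MPT) for that matrix.

Everything is purely topological: branch lengths and internal labels are
read and discarded. Trees are treated as rooted exactly as published — the
coding is clade-based, which presumes rootedness — and never rerooted.
Taxon labels are normalized (whitespace trimmed and unified to
underscores); label matching across studies is exact after normalization,
with synonymy handled only through an explicit caller-supplied rename
table.

Because clade characters are only meaningful on rooted trees, a synthetic
all-zero outgroup row (`MRP_OUTGROUP`) is added to every matrix and
stripped from every reported tree. The search space of rooted ingroup
topologies is then exactly the space of unrooted topologies over
ingroup + outgroup, and parsimony scores are rooting-invariant.

## Curation protocol

Input trees carry metadata: study id, year, and one or more data-type tags
("same underlying data" is operationalized as sharing at least one tag;
tags are caller-supplied metadata, as the judgment is ultimately about how
the source studies built their matrices).

* **Overlap rule.** Two trees of a shared data type are in conflict when
  the shared taxa exceed half of either tree's leaf set (both fractions
  ≤ 1/2 ⇒ both trees stay). Conflict sets are the transitive closure of
  pairwise conflicts, which makes the outcome independent of processing
  order.
* **Resolution.** Within a conflict set, the most comprehensive tree
  (largest leaf count as published) is kept at weight 1. When the set is a
  single study's alternative trees, or several trees tie on leaf count,
  all *n* tied trees are kept at weight 1/*n* each — exact rationals, so a
  group of alternatives always sums to exactly one tree of evidence.
* **Singletons.** Taxa occurring in exactly one retained tree are pruned;
  a tree left with fewer than 3 leaves carries no character and is
  dropped; the census is recomputed to a fixed point.
* **Representation filter.** After encoding, taxa present in fewer than
  `min_trees` (default 2) trees or with fewer than `min_cells` (default 2)
  non-missing cells are removed and the matrix re-encoded, again to a
  fixed point. The defaults are deliberate config keys: what counts as
  "too thin to analyse" is data-dependent.
* **Connectivity.** Trees sharing at least two taxa are connected in the
  overlap graph; multiple components mean the supertree cannot be resolved
  across them, which is reported as a warning rather than an error.

## Parsimony scoring and search

Character state sets are subsets of {0, 1}; `?` is the full set. On binary
nodes the score is Fitch's intersection/union rule; on polytomies it is
Hartigan's generalization (keep the states held by the maximum number of
children; pay one step per child short of the maximum). The left-fold
"repeated Fitch" shortcut undercounts on polytomies (children with states
0, 0, 1, 1 cost two steps, the fold reports one), so it is not used; the
implementation is verified in the tests against brute-force enumeration of
all internal-state assignments, including missing-leaf resolutions.

Scores are exact `Fraction`s throughout — 1/*n* curation weights must not
accumulate floating-point error — and characters of equal weight are packed
into integer bit blocks so a tree is scored with a handful of big-integer
operations. Subtree state sets are pure functions of subtree content and
are memoized across the search.

The heuristic search follows the standard recipe: for each replicate, a
random taxon-addition order, stepwise insertion at the score-minimizing
edge (ties broken by the replicate's seeded generator), then
branch-swapping descent. Descent scans the cheap NNI neighborhood first
and consults the full configured neighborhood (SPR or TBR) only at
NNI-local optima; the final tree is therefore a local optimum of the
configured neighborhood. Equal-best topologies are collected in a global
pool swept once to closure (every pool member swapped once; a strictly
better neighbor resets the pool), deduplicated by canonical form and
capped at `max_trees` (default 10000, with a flag when hit). Two exact
facts are exploited: no tree can score below the total character weight
(every informative character needs a step), which allows early exit on
conflict-free data; and the exhaustive enumerator (all rooted binary
ingroup topologies, feasible to 8 ingroup taxa = 135 135 trees) provides
the optimum that every heuristic claim is tested against.

Search effort matters even at small sizes: TBR local optima above the
global optimum exist for 7-taxon matrices, so the oracle-equivalence test
runs 25 addition replicates per instance. Monophyly constraints are
enforced by rejecting violating topologies during both stepwise addition
and swapping; a constraint restricted to the taxa present must be a
cluster, a single leaf, or absent.

## Consensus and support

Strict consensus keeps clusters present in every MPT; majority rule keeps
those with frequency strictly greater than 1/2 (the strict inequality is
what guarantees pairwise compatibility; the boundary convention matters
for even MPT counts). Extended majority rule (adding compatible minority
clusters) is deliberately not implemented.

For support, each input tree is classified against each supertree clade
using only the taxa it shares with the supertree (`In` = clade ∩ input
leaves, `Out` = the rest of the input's shared taxa): *irrelevant* if
|In| < 2 or |Out| < 1; *supports* if `In` is a cluster of the input tree
pruned to In ∪ Out; *conflicts* if some cluster of the pruned tree
properly overlaps `In`; *permits* otherwise (typically a polytomy).
Then V = (s − q)/(s + q) and V⁺ = (s + p − q)/(s + p + q), undefined when
the denominators are zero. Weights do not enter the counts: support asks
how many independent sources back a clade, not how heavily the matrix
weighted them. A clade with V = V⁺ = −1 (s = 0, p = 0, q > 0) is *novel* —
present in no input tree — and `collapse_novel` reduces exactly those
clades to polytomies; since classification depends only on the clade and
the input trees, re-scoring after collapse cannot create new novel clades.

## Partitions

A partition specification is an innermost-first list of named, nested-or-
disjoint taxon sets (≥ 3 members each). Each partition is analysed
independently after reducing every directly nested inner partition to a
single placeholder leaf and pruning to the partition's effective taxa; an
implicit backbone partition over all remaining taxa is appended when
needed. Reduction replaces monophyletic members in place; non-monophyletic
members are pruned and the placeholder attached at the parent of their
most recent common ancestor with a warning (strict mode raises instead —
use it for audit runs). Grafting replaces the placeholder leaf by the
partition's consensus, so the partition members always form a cluster of
the final tree; these constrained clades receive no V score, since the
input trees were never asked about them. Per-partition search seeds are
derived from the configured seed plus the partition index, keeping runs
reproducible.

## Synthetic data: what it emulates and what it does not

The generator starts from a Yule (uniform-split) model tree with taxa
`T001…`, and emulates four features of real input-tree collections:
partial taxon sampling (subsets much smaller than the taxon universe, so
pairwise overlap is low), estimation error (random NNI moves per tree),
unresolved published trees (each internal edge collapsed with probability
`collapse_prob`), and pseudoreplicate groups (cloned taxon sets with ~10%
jitter sharing a study id and data-type tag, drawn from a small vocabulary
of marker categories). Defaults — 32 taxa, 12 trees of 10–14 taxa, no
noise, years 1995–2021 — describe a deliberately small instance of the
genus-level regional-fauna setting. Everything is deterministic given the
seed.

One measured caveat governs the recovery experiments. With *random*
10–14-taxon subsets of a 32-taxon model, the inputs generically
underdetermine the model even without noise: some model edges (typically
cherries whose two taxa are never co-sampled) are witnessed by no
character, the perfect-score MPT set then runs into the hundreds, and its
strict consensus is legitimately less resolved than the model (measured
RF 3–8 across seeds). This is a property of the sampling design, not of
the method — no supertree method can recover an unwitnessed edge. The
recovery tests therefore use `sample_covering_subsets`, a deterministic
edge-witnessing design: every model edge gets a subset holding a leaf from
two different children of its clade, one from its sibling region, and one
from outside its parent, with every taxon placed in at least two subsets
(a taxon sampled once would be singleton-pruned together with its witness
role). Under that premise the pipeline returns the pruned model exactly
(RF 0, single MPT, every clade V = +1). Passing tests on covering fixtures
show the machinery is correct *given determining input*; they do not show
that real low-overlap collections determine their supertree — for real
data the MPT counts, consensus resolution, and V scores are the diagnostic.

The generator does not simulate sequences, branch lengths, or any
estimation-error model beyond topological moves, and the data-type
vocabulary is a label, not a model of marker behavior.

## Numerical and convention choices

* Exact rational arithmetic for weights, scores, frequencies, V indices,
  and coverage percentages (rounded half-up for reporting; all published
  table cells verify under half-up rounding).
* NEXUS emission scales rational weights by the LCM of denominators to
  integers, preserving exact relative weights; character order is trees in
  input order, nodes in preorder; output is byte-stable for a fixed
  matrix.
* Rooted-cluster Robinson–Foulds distance (symmetric difference of
  cluster sets) is the tree metric everywhere; on rooted trees this counts
  each unshared cluster, so two conflicting resolutions of four taxa are
  at distance 4, and a binary tree is at distance *k* from itself with
  *k* edges collapsed.
* Consensus construction, novel-clade collapse, and reduction all go
  through one laminar-family-to-tree builder with children canonically
  ordered by smallest leaf label, so equal topologies serialize
  identically.
* Degenerate inputs are errors with context: trees under 2 leaves,
  duplicate labels, all-star character sets, unsatisfiable constraints,
  partitions under 4 effective taxa, zero coverage denominators.

## Problem sizes used by the test suite

Unit tests run on 3–20-taxon fixtures. The end-to-end suites use: 200
random matrices of 5–8 ingroup taxa against the exhaustive oracle; the
32-taxon/12-tree covering fixture for recovery (50 TBR replicates); a
20-taxon/10-tree fixture for partition consistency; and an 8-taxon
two-tree conflict fixture for novel-clade behavior. The whole suite runs
in a few minutes on one CPU.

## Known limitations

* Parsimony only — no Purvis or irreversible coding variants, no
  compatibility methods, no likelihood supertrees.
* TBR is implemented by bisection/reroot/reinsert with full rescoring per
  candidate; fine at the tens-of-taxa scale this package targets, not at
  hundreds of taxa.
* V and V⁺ only; other support variants (Vv, V−, rQS) are out of scope,
  as are resampling supports (bootstrap/jackknife).
* The pseudoreplication rule depends on caller-supplied data-type tags;
  the package cannot detect shared underlying data from topology alone.
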