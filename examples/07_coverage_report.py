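"""Taxon-coverage bookkeeping for a supertree against a regional checklist.

Given per-rank totals for a fauna and the number represented in the
supertree, report percentage coverage — optionally also relative to the
total excluding a subgroup the supertree treats as a single placeholder.
"""

from mrptree.pipeline import CoverageCounts, coverage_report

counts = [
    CoverageCounts("superfamily", total=5, represented=5),
    CoverageCounts("family", total=12, represented=10, total_excluding=10),
    CoverageCounts("genus", total=479, represented=114, total_excluding=325),
    CoverageCounts("species", total=1096, represented=312, total_excluding=708),
]
for row in coverage_report(counts):
    extra = (
        f"  ({row['percent_excluding']}% of the {row['total_excluding']} "
        "outside the placeholder subgroup)"
        if "percent_excluding" in row else ""
    )
    print(f"{row['rank']:>12}: {row['represented']}/{row['total']}"
          f" = {row['percent']}%{extra}")

# Percentages are exact rational arithmetic rounded half-up: 114/325 genera
# is 35%, 312/708 species is 44%. The parenthetical columns exclude the
# subgroup that enters the supertree only as a single placeholder taxon.
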