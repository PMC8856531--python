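"""End-to-end orchestration and the coverage-report arithmetic.

The pipeline chains: load bundle → rename table → pseudoreplication
resolution → singleton removal → connectivity check → (per partition)
encode → representation filter → search → consensus → support → collapse of
novel clades → graft.  A machine-readable manifest (stage counts, content
hashes, seed, warnings) makes reruns auditable: same bundle + same seed ⇒
identical hashes.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional

import yaml

from . import curation, synthgen
from .consensus import majority_consensus, strict_consensus
from .curation import CurationReport, InputTree
from .mrp import MRPMatrix, encode_matrix, matrix_fill_stats, write_nexus
from .partition import PartitionSpec, run_partitioned
from .search import SearchConfig, heuristic_search
from .support import CladeSupport, collapse_novel, score_supertree, support_table
from .treecore import Tree, prune_to, write_newick

__all__ = [
    "PipelineConfig",
    "CoverageCounts",
    "run_pipeline",
    "curate",
    "encode_with_filter",
    "coverage_report",
    "percent_covered",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    input_dir: str = "."
    output_dir: str = "out"
    overlap_max: str = "1/2"  # fraction as text, exact
    min_trees: int = 2
    min_cells: int = 2
    n_reps: int = 50
    swap: str = "TBR"
    max_trees: int = 10000
    consensus_threshold: str = "1/2"
    partitions: list = field(default_factory=list)  # [{name: ..., taxa: [...]}]
    rename_table: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < Fraction(self.overlap_max) <= 1:
            raise ValueError("overlap_max must be in (0, 1]")
        if Fraction(self.consensus_threshold) < Fraction(1, 2):
            raise ValueError("consensus_threshold must be >= 1/2")
        if self.min_trees < 1 or self.min_cells < 0:
            raise ValueError("representation thresholds out of range")
        SearchConfig(n_reps=self.n_reps, swap=self.swap, max_trees=self.max_trees).validate()

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            n_reps=self.n_reps, swap=self.swap, seed=self.seed, max_trees=self.max_trees
        )

    def partition_spec(self) -> Optional[PartitionSpec]:
        if not self.partitions:
            return None
        return PartitionSpec(
            [(p["name"], frozenset(p["taxa"])) for p in self.partitions]
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass
class CoverageCounts:
    """Numerator/denominator pairs for one taxonomic rank's coverage row."""

    rank: str
    total: int
    represented: int
    total_excluding: Optional[int] = None

    def __post_init__(self):
        if min(self.total, self.represented) < 0:
            raise ValueError("counts must be non-negative")
        if self.represented > self.total:
            raise ValueError(f"{self.rank}: represented exceeds total")


def percent_covered(numerator: int, denominator: int) -> int:
    """Percentage rounded half-up to the nearest integer (exact arithmetic)."""
    if denominator == 0:
        raise ZeroDivisionError("coverage denominator is zero")
    return int(Fraction(100 * numerator, denominator) + Fraction(1, 2))


def coverage_report(counts: list[CoverageCounts]) -> list[dict]:
    """Coverage table: percent represented per rank, with the
    excluding-subgroup variant in a separate column when provided."""
    rows = []
    for c in counts:
        row = {
            "rank": c.rank,
            "total": c.total,
            "represented": c.represented,
            "percent": percent_covered(c.represented, c.total),
        }
        if c.total_excluding is not None:
            row["total_excluding"] = c.total_excluding
            row["percent_excluding"] = percent_covered(c.represented, c.total_excluding)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def apply_renames(trees: list[InputTree], table: dict[str, str]) -> list[InputTree]:
    """Apply a caller-supplied synonymy table (old label -> new label)."""
    from .treecore import Node, Tree, normalize_label

    table = {normalize_label(k): normalize_label(v) for k, v in table.items()}
    out = []
    for t in trees:
        def rec(node):
            if node.is_leaf:
                return Node(table.get(node.label, node.label))
            return Node(children=[rec(c) for c in node.children])

        out.append(replace(t, tree=Tree(rec(t.tree.root))))
    return out


def curate(
    trees: list[InputTree],
    overlap_max: Fraction = Fraction(1, 2),
) -> tuple[list[InputTree], CurationReport]:
    """Pseudoreplication resolution, singleton removal, connectivity check."""
    retained, rep1 = curation.resolve_pseudoreplication(trees, overlap_max)
    retained, rep2 = curation.remove_singletons(retained)
    report = rep1.merge(rep2)
    components = curation.connectivity_check(retained)
    report.n_components = len(components)
    if len(components) > 1:
        report.warnings.append(
            f"overlap graph has {len(components)} components; the supertree will "
            "be unresolved across components"
        )
        log.warning(report.warnings[-1])
    return retained, report


def encode_with_filter(
    trees: list[InputTree],
    min_trees: int = 2,
    min_cells: int = 2,
    report: Optional[CurationReport] = None,
) -> tuple[list[InputTree], MRPMatrix]:
    """Encode, apply the representation filter, re-encode to a fixed point.

    Removing a thin taxon changes the matrix, so the filter is iterated
    until no taxon falls below the thresholds.
    """
    current = list(trees)
    while True:
        matrix = encode_matrix(current)
        stats = matrix_fill_stats(matrix)
        removed = curation.representation_filter(
            {t: n for t, n in stats["per_taxon_trees"].items() if t != "MRP_OUTGROUP"},
            {t: n for t, n in stats["per_taxon_cells"].items() if t != "MRP_OUTGROUP"},
            min_trees=min_trees,
            min_cells=min_cells,
        )
        if not removed:
            if stats["missing_fraction"] > Fraction(9, 10):
                log.warning(
                    "matrix is %.1f%% missing data; the search may struggle",
                    100 * float(stats["missing_fraction"]),
                )
            return current, matrix
        if report is not None:
            for taxon in removed:
                report.removed_taxa[taxon] = "under_represented"
        nxt = []
        for t in current:
            keep = t.taxa - set(removed)
            pruned = prune_to(t.tree, keep) if len(keep) >= 2 else None
            if pruned is None or len(pruned) < 3:
                if report is not None:
                    report.discarded[t.tree_id] = "too_few_leaves"
                    report.retained.pop(t.tree_id, None)
            else:
                nxt.append(replace(t, tree=pruned))
        current = nxt


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``config.output_dir``.

    Returns the manifest (also written as manifest.json).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "warnings": [], "stages": {}, "files": {}}

    def emit(name: str, text: str) -> None:
        (out / name).write_text(text)
        manifest["files"][name] = _sha(text)

    trees, model = synthgen.read_bundle(config.input_dir)
    manifest["stages"]["load"] = {"n_trees": len(trees)}

    if config.rename_table:
        with open(config.rename_table, newline="") as fh:
            table = {row["from"]: row["to"] for row in csv.DictReader(fh)}
        trees = apply_renames(trees, table)

    retained, report = curate(trees, Fraction(config.overlap_max))
    manifest["warnings"].extend(report.warnings)
    manifest["stages"]["curation"] = {
        "retained": len(retained),
        "discarded": len(report.discarded),
        "removed_taxa": len(report.removed_taxa),
        "components": report.n_components,
    }

    spec = config.partition_spec()
    search_config = config.search_config()

    if spec is not None:
        final, results = run_partitioned(retained, spec, search_config)
        # expand placeholder leaves so partition clades live in final-tree
        # coordinates (innermost partitions first, so nesting resolves)
        expansions: dict[str, frozenset] = {}

        def expand(cl: frozenset) -> frozenset:
            out: set = set()
            for x in cl:
                out |= expansions.get(x, frozenset([x]))
            return frozenset(out)

        all_supports = []
        for name, res in results.items():
            expansions[name] = expand(res.majority.tree.leaf_set)
            for cs in res.supports:
                all_supports.append(
                    CladeSupport(
                        clade=expand(cs.clade),
                        s=cs.s,
                        q=cs.q,
                        p=cs.p,
                        r_irrelevant=cs.r_irrelevant,
                    )
                )
            emit(f"partition_{name}_majority.nwk", write_newick(res.majority.tree))
            emit(f"partition_{name}_strict.nwk", write_newick(res.strict.tree))
        manifest["stages"]["search"] = {
            name: {
                "best_score": str(res.search.best_score),
                "n_mpts": len(res.search.mpts),
                "hit_max_trees": res.search.hit_max_trees,
            }
            for name, res in results.items()
        }
        supertree = final
        supports = all_supports
    else:
        retained, matrix = encode_with_filter(
            retained, config.min_trees, config.min_cells, report
        )
        emit("matrix.nex", write_nexus(matrix))
        result = heuristic_search(matrix, search_config)
        manifest["stages"]["search"] = {
            "best_score": str(result.best_score),
            "n_mpts": len(result.mpts),
            "hit_max_trees": result.hit_max_trees,
        }
        strict = strict_consensus(result.mpts)
        majority = majority_consensus(result.mpts, Fraction(config.consensus_threshold))
        emit("strict.nwk", write_newick(strict.tree))
        emit("majority.nwk", majority.newick_with_frequencies())
        supertree = majority.tree
        supports = score_supertree(supertree, retained)
        emit("mpts.nwk", "\n".join(write_newick(t) for t in result.mpts))

    final_tree = collapse_novel(supertree, supports)
    n_novel = sum(1 for cs in supports if cs.novel)
    emit("supertree.nwk", write_newick(supertree))
    emit("supertree_collapsed.nwk", write_newick(final_tree))
    emit("support.csv", support_table(supports).to_csv(index=False))
    manifest["stages"]["support"] = {
        "n_clades_scored": len(supports),
        "n_novel_collapsed": n_novel,
    }

    # curation report artifacts
    lines = ["tree_id,status,weight_or_reason"]
    for tid, w in sorted(report.retained.items()):
        lines.append(f"{tid},retained,{w}")
    for tid, reason in sorted(report.discarded.items()):
        lines.append(f"{tid},discarded,{reason}")
    for taxon, reason in sorted(report.removed_taxa.items()):
        lines.append(f"{taxon},taxon_removed,{reason}")
    emit("curation_report.csv", "\n".join(lines) + "\n")

    if model is not None:
        kept = model.leaf_set & final_tree.leaf_set
        pruned_model = prune_to(model, kept)
        if pruned_model is not None and pruned_model.leaf_set == final_tree.leaf_set:
            from .treecore import rf_distance

            manifest["stages"]["model_check"] = {
                "rf_to_pruned_model": rf_distance(final_tree, pruned_model)
            }

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest_text)
    return manifest
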