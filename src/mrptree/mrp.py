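"""Baum–Ragan matrix representation of a curated tree set.

Every internal non-root node of every input tree becomes one binary
character: taxa inside the clade score 1, taxa elsewhere in that tree score
0, and taxa absent from the tree score '?'.  A synthetic all-zero outgroup
row (MRP_OUTGROUP) roots the parsimony analysis — clade-based coding is only
meaningful on rooted trees — and is stripped from all reported results.
Character weights are carried as exact rationals copied from the source
tree's curation weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .curation import InputTree
from .treecore import Tree

__all__ = [
    "OUTGROUP",
    "Character",
    "MRPMatrix",
    "encode_matrix",
    "matrix_fill_stats",
    "write_nexus",
    "read_nexus",
]

OUTGROUP = "MRP_OUTGROUP"


@dataclass(frozen=True)
class Character:
    """One matrix column: a clade of one source tree, with its weight."""

    tree_id: str
    cluster: frozenset[str]
    in_tree: frozenset[str]  # leaf set of the source tree
    weight: Fraction

    def state(self, taxon: str) -> str:
        if taxon == OUTGROUP:
            return "0"
        if taxon in self.cluster:
            return "1"
        if taxon in self.in_tree:
            return "0"
        return "?"


class MRPMatrix:
    """Taxa x binary characters with missing cells and per-character weights."""

    def __init__(self, taxa: Sequence[str], characters: Sequence[Character]):
        if OUTGROUP in taxa:
            raise ValueError(f"{OUTGROUP} is reserved for the synthetic root row")
        self.taxa: list[str] = list(taxa) + [OUTGROUP]
        self.characters: list[Character] = list(characters)
        ingroup = set(taxa)
        for ch in self.characters:
            if not ch.cluster <= ingroup or not ch.in_tree <= ingroup:
                raise ValueError(
                    f"character from {ch.tree_id} references taxa outside the matrix"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def ingroup(self) -> list[str]:
        return self.taxa[:-1]

    def row(self, taxon: str) -> str:
        return "".join(ch.state(taxon) for ch in self.characters)

    def column(self, i: int) -> dict[str, str]:
        ch = self.characters[i]
        return {t: ch.state(t) for t in self.taxa}

    def total_weight(self) -> Fraction:
        return sum((ch.weight for ch in self.characters), Fraction(0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MRPMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and len(self.characters) == len(other.characters)
            and all(
                a.cluster == b.cluster and a.in_tree == b.in_tree and a.weight == b.weight
                for a, b in zip(self.characters, other.characters)
            )
        )


def encode_matrix(trees: Iterable[InputTree], taxa: Optional[Sequence[str]] = None) -> MRPMatrix:
    """Encode a curated tree set as an MRP matrix.

    Character order is fixed — trees in input order, nodes in preorder — so
    a given tree set always yields byte-identical output.  Raises if no tree
    contributes a character (all stars): no resolution would be possible.
    """
    trees = list(trees)
    if taxa is None:
        union: set[str] = set()
        for t in trees:
            union |= t.taxa
        taxa = sorted(union)
    else:
        taxa = list(taxa)
        union = set().union(*(t.taxa for t in trees)) if trees else set()
        if union - set(taxa):
            raise ValueError(f"taxa missing from ordered list: {sorted(union - set(taxa))}")

    chars: list[Character] = []
    for t in trees:
        leaf_set = t.taxa
        # preorder over internal non-root nodes, mirroring clusters()
        below: dict[int, frozenset[str]] = {}
        for node in t.tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        for node in t.tree.preorder():
            if node.is_leaf or node is t.tree.root:
                continue
            chars.append(
                Character(
                    tree_id=t.tree_id,
                    cluster=below[id(node)],
                    in_tree=leaf_set,
                    weight=t.weight,
                )
            )
    if not chars:
        raise ValueError(
            "no characters: every input tree is a star, no resolution is possible"
        )
    return MRPMatrix(taxa, chars)


def matrix_fill_stats(m: MRPMatrix) -> dict:
    """Missing-data census: overall ?-fraction and per-taxon counts.

    Feeds the representation filter and a fill warning — matrices dominated
    by ?s are the classic failure mode of MRP on low-overlap tree sets.
    """
    per_taxon_cells: dict[str, int] = {t: 0 for t in m.taxa}
    per_taxon_trees: dict[str, set[str]] = {t: set() for t in m.taxa}
    missing = 0
    for ch in m.characters:
        for t in m.taxa:
            s = ch.state(t)
            if s == "?":
                missing += 1
            else:
                per_taxon_cells[t] += 1
                per_taxon_trees[t].add(ch.tree_id)
    total = m.n_taxa * m.n_characters
    return {
        "n_taxa": m.n_taxa,
        "n_characters": m.n_characters,
        "missing_fraction": Fraction(missing, total) if total else Fraction(0),
        "per_taxon_cells": per_taxon_cells,
        "per_taxon_trees": {t: len(s) for t, s in per_taxon_trees.items()},
    }


# ---------------------------------------------------------------------------
# NEXUS emission (PAUP*-compatible) and minimal read-back
# ---------------------------------------------------------------------------

_NEXUS_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.")


def _nexus_label(label: str) -> str:
    if set(label) <= _NEXUS_SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(m: MRPMatrix, constraints: Optional[dict[str, set[str]]] = None) -> str:
    """Serialize to NEXUS with integer-scaled exact weights.

    Rational weights (1/2, 1/4, ...) are scaled by the LCM of their
    denominators so the ASSUMPTIONS block carries exact relative weights as
    integers — no decimal truncation.  Optional monophyly constraints are
    emitted as a PAUP-dialect block.
    """
    lcm = 1
    for ch in m.characters:
        lcm = math.lcm(lcm, ch.weight.denominator)
    weights = [ch.weight * lcm for ch in m.characters]
    assert all(w.denominator == 1 for w in weights)

    width = max(len(_nexus_label(t)) for t in m.taxa)
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};")
    lines.append('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;')
    lines.append("    MATRIX")
    for t in m.taxa:
        lines.append(f"        {_nexus_label(t):<{width}}  {m.row(t)}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN ASSUMPTIONS;")
    groups: dict[int, list[int]] = {}
    for i, w in enumerate(weights):
        groups.setdefault(int(w), []).append(i + 1)
    parts = []
    for w in sorted(groups):
        parts.append(f"{w}: {' '.join(str(i) for i in groups[w])}")
    lines.append(f"    WTSET * mrp_weights = {', '.join(parts)};")
    lines.append("END;")
    if constraints:
        lines.append("")
        lines.append("BEGIN PAUP;")
        for name in sorted(constraints):
            taxa = ", ".join(
                _nexus_label(t) for t in sorted(constraints[name])
            )
            lines.append(f"    constraints {name} (MONOPHYLY) = (({taxa}));")
        lines.append("END;")
    lines.append("")
    return "\n".join(lines)


def read_nexus(text: str) -> tuple[list[str], list[str], list[Fraction]]:
    """Minimal reader for matrices written by :func:`write_nexus`.

    Returns (taxa, rows, weights); exists for round-trip verification, not as
    a general NEXUS parser.
    """
    taxa: list[str] = []
    rows: list[str] = []
    weights: list[Fraction] = []
    in_matrix = False
    nchar = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.upper().startswith("DIMENSIONS"):
            for tok in line.rstrip(";").split():
                if tok.upper().startswith("NCHAR="):
                    nchar = int(tok.split("=")[1])
        if line.upper() == "MATRIX" or line.upper().startswith("MATRIX"):
            in_matrix = True
            continue
        if in_matrix:
            if line == ";":
                in_matrix = False
                continue
            if not line:
                continue
            if line.startswith("'"):
                end = line.index("'", 1)
                label, row = line[1:end], line[end + 1 :].strip()
            else:
                label, row = line.split(None, 1)
            taxa.append(label)
            rows.append(row.replace(" ", ""))
        if line.upper().startswith("WTSET"):
            assert nchar is not None
            ws: list[Fraction] = [Fraction(1)] * nchar
            body = line.split("=", 1)[1].rstrip(";")
            for part in body.split(","):
                w_str, idx_str = part.split(":")
                w = Fraction(w_str.strip())
                for tok in idx_str.split():
                    ws[int(tok) - 1] = w
            weights = ws
    return taxa, rows, weights
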