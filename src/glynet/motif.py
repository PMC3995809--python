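"""Normalization and determinant-motif scanning of IUPAC-condensed glycans.

Printed glycan-array structures mix Greek and Latin anomeric letters
("Neu5Acα2-6Galβ1-4GlcNAc" vs "Neu5Aca2-6Galb1-4GlcNAc"), letter case,
arrow styles and stray whitespace.  :func:`normalize_glycan` canonicalises
all of that so motif matching is spelling-invariant.  Spacer suffixes
(-Sp0..-Sp25, -Asn, peptide tags) are retained: determinants are internal
substrings, so retention is lossless.

Two matching modes are supported:

substring (default)
    The normalized motif must occur contiguously in the normalized structure.

branch_aware
    Additionally allows one parenthesized branch segment (or a lone
    parenthesis) between motif residues, so "Neu5Aca2-3Gal" matches the
    branched "...(Neu5Acα2-3)Galβ1-4Glc..." and "Galb1-4GlcNAc" matches
    "Galβ1-4(6S)GlcNAc".  Every substring match is also a branch-aware match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GlycanStructure",
    "MotifQuery",
    "normalize_glycan",
    "count_glycans_with_motif",
    "first_neighbors",
    "read_glycan_tsv",
]

_GREEK = str.maketrans({"α": "a", "β": "b", "→": "-"})


def normalize_glycan(raw: str) -> str:
    """Canonicalise an IUPAC-condensed structure string.

    Greek α/β become Latin a/b, arrows become "-", all whitespace is removed
    and the result is lower-cased.  Idempotent.
    """
    s = raw.translate(_GREEK)
    s = s.replace("->", "-")
    s = re.sub(r"\s+", "", s)
    return s.lower()


@dataclass
class GlycanStructure:
    """A printed structure string together with its canonical form."""

    glycan_id: str
    raw: str

    @property
    def normalized(self) -> str:
        return normalize_glycan(self.raw)


@dataclass
class MotifQuery:
    """A determinant motif plus the matching mode to apply."""

    motif: str
    mode: Literal["substring", "branch_aware"] = "substring"

    def __post_init__(self) -> None:
        if not normalize_glycan(self.motif):
            raise ValueError("motif is empty after normalization")


def _branch_aware_pattern(motif: str) -> re.Pattern:
    # Allow an optional parenthesis or one full parenthesized branch at each
    # digit->letter boundary of the motif (the residue junctions).
    parts = re.split(r"(?<=\d)(?=[a-z])", motif)
    gap = r"(?:\)|\([^()]*\)|\()?"
    return re.compile(gap.join(re.escape(p) for p in parts))


def count_glycans_with_motif(glycans: Sequence[GlycanStructure],
                             query: MotifQuery) -> tuple[int, list[str]]:
    """Count glycans whose structure contains the determinant motif.

    Each distinct glycan ID is counted once.  Returns the count and the
    matching IDs in first-seen order.
    """
    motif = normalize_glycan(query.motif)
    if not motif:
        raise ValueError("empty motif")
    pattern = _branch_aware_pattern(motif) if query.mode == "branch_aware" else None

    matched: list[str] = []
    seen: set[str] = set()
    for g in glycans:
        if g.glycan_id in seen:
            continue
        seen.add(g.glycan_id)
        text = g.normalized
        if query.mode == "substring":
            hit = motif in text
        elif query.mode == "branch_aware":
            hit = pattern.search(text) is not None
        else:
            raise ValueError(f"unknown mode {query.mode!r}")
        if hit:
            matched.append(g.glycan_id)
    return len(matched), matched


def first_neighbors(net, node_ids: Sequence[str]) -> list[tuple[str, float]]:
    """Glycan neighbors of one or more lectin nodes, RFU-sorted.

    The union of glycan partners over the queried nodes; a glycan shared by
    several queried nodes appears once with the mean RFU over the edges
    present.  Sorted by RFU descending (ties by glycan ID) -- the layout of a
    per-lectin bound-glycan report.
    """
    from .network import PROTEIN_SIDE

    rfus: dict[str, list[float]] = {}
    for node in node_ids:
        if node not in net:
            raise KeyError(f"unknown node ID {node!r}")
        if net.nodes[node].get("side") != PROTEIN_SIDE:
            raise KeyError(f"{node!r} is not a protein node")
        for glycan in net.neighbors(node):
            rfus.setdefault(glycan, []).append(net.edges[node, glycan]["rfu"])
    out = [(g, sum(v) / len(v)) for g, v in rfus.items()]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


def read_glycan_tsv(path: Union[str, Path]) -> list[GlycanStructure]:
    """Read a `glycan_id<TAB>glycan_structure[<TAB>rfu]` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = "glycan_id" if "glycan_id" in df.columns else df.columns[0]
    struct_col = ("glycan_structure" if "glycan_structure" in df.columns
                  else df.columns[1])
    return [GlycanStructure(glycan_id=row[id_col], raw=row[struct_col])
            for _, row in df.iterrows()]
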