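"""Reading, merging and RFU-filtering of glycan-array result files.

A glycan-array experiment probes one lectin (under one condition, e.g. a
specific concentration) against a panel of immobilised glycans and reports a
relative fluorescence unit (RFU) per spot.  One experiment file therefore
corresponds to one *lectin node* of the downstream bipartite network: the same
protein assayed twice carries two distinct node IDs.

The file dialect is a small TSV::

    #lectin_node_id<TAB>1001943
    #protein_name<TAB>Sambucus nigra Agglutinin      (optional)
    #condition<TAB>10 ug/ml                          (optional)
    glycan_id<TAB>glycan_structure<TAB>rfu
    G0001<TAB>Neu5Aca2-6Galb1-4GlcNAcb-Sp8<TAB>51134
    ...

Replicate spots (repeated ``glycan_id`` within one file) are collapsed to
their arithmetic-mean RFU.  Filtering keeps pairs with ``rfu >= cutoff``
(inclusive), so the three standard cutoffs 5000/10000/20000 produce nested
interaction tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "ArrayExperiment",
    "InteractionTable",
    "ArrayFileError",
    "parse_array_file",
    "merge_experiments",
    "filter_by_rfu",
    "read_merged_table",
    "write_merged_table",
]

COLUMNS = ["lectin_node_id", "glycan_id", "rfu"]


class ArrayFileError(ValueError):
    """Raised for malformed array files or inconsistent experiment sets."""


@dataclass
class ArrayExperiment:
    """One lectin-under-condition assayed against a glycan panel.

    ``rows`` is a DataFrame with columns ``glycan_id``, ``glycan_structure``
    and ``rfu``; glycan IDs are unique (replicates already averaged).
    """

    lectin_node_id: str
    protein_name: str = ""
    condition: str = ""
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.lectin_node_id:
            raise ArrayFileError("lectin_node_id must be non-empty")
        if len(self.rows):
            if (self.rows["rfu"] < 0).any():
                raise ArrayFileError("negative RFU value in experiment "
                                     f"{self.lectin_node_id!r}")
            if self.rows["glycan_id"].duplicated().any():
                raise ArrayFileError("duplicate glycan_id after averaging in "
                                     f"{self.lectin_node_id!r}")


@dataclass
class InteractionTable:
    """Merged lectin x glycan interaction records with mean RFU.

    One row per (lectin_node_id, glycan_id) pair.  ``rfu_cutoff_applied`` is
    ``None`` for an unfiltered table.
    """

    records: pd.DataFrame
    rfu_cutoff_applied: Optional[float] = None

    def __post_init__(self) -> None:
        if list(self.records.columns[:3]) != COLUMNS:
            self.records = self.records.reindex(columns=COLUMNS)
        if self.records.duplicated(subset=["lectin_node_id", "glycan_id"]).any():
            raise ArrayFileError("duplicate (lectin, glycan) pair in table")
        if self.rfu_cutoff_applied is not None and len(self.records):
            if (self.records["rfu"] < self.rfu_cutoff_applied).any():
                raise ArrayFileError("record below the applied RFU cutoff")

    def __len__(self) -> int:
        return len(self.records)


def parse_array_file(source: Union[str, Path, io.TextIOBase]) -> ArrayExperiment:
    """Parse one array file into an :class:`ArrayExperiment`.

    Replicate glycan rows are averaged; malformed numeric fields and negative
    RFUs raise :class:`ArrayFileError` with the offending line reported.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return parse_array_file(fh)

    meta: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    header_seen = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            meta[key.strip()] = value.strip()
        elif not header_seen:
            cols = [c.strip() for c in line.split("\t")]
            if cols[:3] != ["glycan_id", "glycan_structure", "rfu"]:
                raise ArrayFileError(
                    f"line {lineno}: expected column header "
                    f"'glycan_id\\tglycan_structure\\trfu', got {line!r}")
            header_seen = True
        else:
            data_lines.append((lineno, line))

    if "lectin_node_id" not in meta or not meta["lectin_node_id"]:
        raise ArrayFileError("missing #lectin_node_id header")
    if not data_lines:
        raise ArrayFileError("empty data section")

    ids, structs, rfus = [], [], []
    for lineno, line in data_lines:
        parts = line.split("\t")
        if len(parts) < 3:
            raise ArrayFileError(f"line {lineno}: expected 3 tab-separated "
                                 f"fields, got {line!r}")
        gid, struct, rfu_text = parts[0].strip(), parts[1].strip(), parts[2].strip()
        try:
            rfu = float(rfu_text)
        except ValueError as exc:
            raise ArrayFileError(
                f"line {lineno}: malformed RFU field {rfu_text!r}") from exc
        if rfu < 0:
            raise ArrayFileError(f"line {lineno}: negative RFU {rfu}")
        ids.append(gid)
        structs.append(struct)
        rfus.append(rfu)

    df = pd.DataFrame({"glycan_id": ids, "glycan_structure": structs, "rfu": rfus})
    # replicate spots -> arithmetic mean RFU; keep first printed structure
    df = (df.groupby("glycan_id", sort=False)
            .agg(glycan_structure=("glycan_structure", "first"),
                 rfu=("rfu", "mean"))
            .reset_index())
    return ArrayExperiment(
        lectin_node_id=meta["lectin_node_id"],
        protein_name=meta.get("protein_name", ""),
        condition=meta.get("condition", ""),
        rows=df,
    )


def merge_experiments(experiments: Sequence[ArrayExperiment]) -> InteractionTable:
    """Concatenate per-lectin experiments into one interaction table.

    Lectin node IDs must be pairwise distinct: two assay conditions of the
    same protein are two different nodes and must carry two IDs.
    """
    seen: set[str] = set()
    frames = []
    for exp in experiments:
        if exp.lectin_node_id in seen:
            raise ArrayFileError(
                f"duplicate lectin_node_id {exp.lectin_node_id!r} across files")
        seen.add(exp.lectin_node_id)
        if len(exp.rows) == 0:
            continue
        frame = exp.rows[["glycan_id", "rfu"]].copy()
        frame.insert(0, "lectin_node_id", exp.lectin_node_id)
        frames.append(frame)
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=COLUMNS)
    return InteractionTable(records=records)


def filter_by_rfu(table: InteractionTable, cutoff: float) -> InteractionTable:
    """Keep exactly the records with ``rfu >= cutoff`` (inclusive boundary).

    Idempotent for a fixed cutoff, and monotone: a higher cutoff yields a
    subset of the records retained by a lower one.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    kept = table.records[table.records["rfu"] >= cutoff].reset_index(drop=True)
    return InteractionTable(records=kept, rfu_cutoff_applied=float(cutoff))


def write_merged_table(table: InteractionTable, path: Union[str, Path]) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_merged_table(path: Union[str, Path],
                      rfu_cutoff_applied: Optional[float] = None) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype={"lectin_node_id": str, "glycan_id": str})
    return InteractionTable(records=df, rfu_cutoff_applied=rfu_cutoff_applied)


def load_experiments(directory: Union[str, Path],
                     pattern: str = "*.tsv") -> list[ArrayExperiment]:
    """Parse every array file matching ``pattern`` under ``directory``."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"array directory {directory} does not exist")
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} array files under {directory}")
    return [parse_array_file(p) for p in paths]
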