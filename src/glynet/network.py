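"""Bipartite lectin-glycan network construction and hub detection.

The network is an unweighted bipartite graph: one side holds lectin nodes
(array IDs, i.e. protein-under-condition), the other glycan nodes.  An edge
means the pair survived the RFU cutoff; the RFU itself is kept as an edge
attribute so neighbor reports can print it, but it plays no role in the
topology.

Hubs are lectins of exceptionally high degree.  The default rule ranks
protein nodes by degree and calls everything above the single largest
consecutive drop within the top of the ranking a hub; a plain degree
threshold rule is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import networkx as nx

from .array_io import InteractionTable

__all__ = [
    "PROTEIN_SIDE",
    "GLYCAN_SIDE",
    "HubReport",
    "build_bipartite",
    "degree_sequence",
    "detect_hubs",
    "to_interaction_frame",
    "write_sif",
    "write_graphml",
]

PROTEIN_SIDE = "protein"
GLYCAN_SIDE = "glycan"


def build_bipartite(table: InteractionTable) -> nx.Graph:
    """Build the bipartite graph from a (deduplicated) interaction table.

    Every record becomes exactly one edge.  Node attribute ``side`` is
    ``"protein"`` or ``"glycan"``; edge attribute ``rfu`` carries the mean
    RFU.  A glycan ID colliding with a lectin node ID is a hard error -- the
    two ID namespaces must be disjoint.
    """
    proteins = set(table.records["lectin_node_id"])
    glycans = set(table.records["glycan_id"])
    clash = proteins & glycans
    if clash:
        raise ValueError(
            f"glycan IDs collide with lectin node IDs: {sorted(clash)[:5]} "
            "-- namespace the two sides (e.g. prefix glycan IDs with 'G')")
    g = nx.Graph()
    g.add_nodes_from(sorted(proteins), side=PROTEIN_SIDE)
    g.add_nodes_from(sorted(glycans), side=GLYCAN_SIDE)
    for lectin, glycan, rfu in table.records.itertuples(index=False):
        g.add_edge(lectin, glycan, rfu=float(rfu))
    return g


def protein_nodes(net: nx.Graph) -> list[str]:
    return sorted(n for n, s in net.nodes(data="side") if s == PROTEIN_SIDE)


def glycan_nodes(net: nx.Graph) -> list[str]:
    return sorted(n for n, s in net.nodes(data="side") if s == GLYCAN_SIDE)


def degree_sequence(net: nx.Graph,
                    side: Literal["protein", "glycan", "all"] = "protein",
                    ) -> list[tuple[str, int]]:
    """Per-node degrees sorted by degree descending, then node ID ascending.

    The deterministic tie-break makes hub calls reproducible across runs and
    node orderings.
    """
    if side == "all":
        nodes = list(net.nodes)
    else:
        nodes = [n for n, s in net.nodes(data="side") if s == side]
    return sorted(((n, net.degree(n)) for n in nodes),
                  key=lambda item: (-item[1], item[0]))


@dataclass
class HubReport:
    """Hub lectins plus the degree ranking they were called from."""

    ranked_degrees: list[tuple[str, int]]
    hubs: set[str] = field(default_factory=set)
    gap_position: Optional[int] = None  # hubs = ranked_degrees[:gap_position]
    rule: str = "degree_gap"
    flag: Optional[str] = None


def detect_hubs(net: nx.Graph,
                rule: Literal["degree_gap", "threshold"] = "degree_gap",
                tail_window: int = 10,
                threshold: Optional[float] = None) -> HubReport:
    """Call hub lectins from the protein-side degree distribution.

    degree_gap
        Inspect the ``tail_window`` highest-degree protein nodes and find the
        position of the largest consecutive drop d(i) - d(i+1); nodes above
        the drop are hubs.  If all inspected degrees are equal there is no
        gap and no hub is called (``flag="no gap found"``).
    threshold
        Hubs are the protein nodes with degree strictly greater than
        ``threshold``.
    """
    ranked = degree_sequence(net, side=PROTEIN_SIDE)
    if not ranked:
        raise ValueError("protein side is empty")

    if rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold")
        hubs = {n for n, d in ranked if d > threshold}
        return HubReport(ranked_degrees=ranked, hubs=hubs, rule="threshold")

    if rule != "degree_gap":
        raise ValueError(f"unknown hub rule {rule!r}")
    if tail_window < 2:
        raise ValueError("tail_window must be >= 2")

    window = ranked[: min(tail_window, len(ranked))]
    if len(window) < 2 or all(d == window[0][1] for _, d in window):
        return HubReport(ranked_degrees=ranked, hubs=set(), gap_position=None,
                         rule="degree_gap", flag="no gap found")
    gaps = [window[i][1] - window[i + 1][1] for i in range(len(window) - 1)]
    best = max(range(len(gaps)), key=lambda i: (gaps[i], -i))
    gap_position = best + 1
    hubs = {n for n, _ in window[:gap_position]}
    return HubReport(ranked_degrees=ranked, hubs=hubs,
                     gap_position=gap_position, rule="degree_gap")


def to_interaction_frame(net: nx.Graph):
    """Flatten the edges back to (lectin, glycan, rfu) records.

    Round-trips :func:`build_bipartite`: rebuilding from the returned frame
    reproduces the same graph.
    """
    import pandas as pd

    rows = []
    for u, v, rfu in net.edges(data="rfu"):
        if net.nodes[u]["side"] == PROTEIN_SIDE:
            rows.append((u, v, rfu))
        else:
            rows.append((v, u, rfu))
    return pd.DataFrame(rows, columns=["lectin_node_id", "glycan_id", "rfu"]) \
             .sort_values(["lectin_node_id", "glycan_id"]) \
             .reset_index(drop=True)


def write_sif(net: nx.Graph, path: Union[str, Path],
              relation: str = "binds") -> None:
    """Cytoscape SIF export: ``protein<TAB>binds<TAB>glycan`` per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges()):
            if net.nodes[u]["side"] != PROTEIN_SIDE:
                u, v = v, u
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(net: nx.Graph, path: Union[str, Path]) -> None:
    """GraphML export with ``side`` node attribute and ``rfu`` edge attribute."""
    nx.write_graphml(net, path)
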