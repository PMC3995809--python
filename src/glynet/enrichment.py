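"""Hypergeometric enrichment of glycan-binding specificities in communities.

Each lectin node maps (via its protein name) to zero or more curated
glycan-binding specificity labels, e.g. "Mannose binding lectin".  For a
community holding n of the network's N lectin nodes, of which k carry a label
carried by K lectin nodes network-wide, the enrichment p-value is the upper
tail of the hypergeometric distribution,

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n),

the chance of drawing at least k labelled lectins when n are sampled without
replacement.  Only communities with at least ``min_protein_nodes`` lectin
nodes are tested (default 10), significance is p <= alpha (default 0.05) on
raw p-values, and a random-partition baseline with the same community sizes
calibrates how many significant (community, specificity) groups arise by
chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .modularity import Partition
from .network import PROTEIN_SIDE, protein_nodes

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "BaselineSummary",
    "hypergeom_pvalue",
    "enrich_clusters",
    "count_significant_groups",
    "random_baseline",
    "read_annotation_file",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """protein_name -> specificity labels, plus lectin node -> protein name.

    A node without an entry (or whose protein has no labels) is unannotated;
    it still counts toward community sizes but can never contribute to k.
    """

    labels: dict[str, set[str]] = field(default_factory=dict)
    node_map: dict[str, str] = field(default_factory=dict)

    def labels_of_node(self, node_id: str) -> set[str]:
        name = self.node_map.get(node_id, node_id)
        return self.labels.get(name, set())

    def annotated_nodes(self, nodes: Iterable[str]) -> list[str]:
        return [n for n in nodes if self.labels_of_node(n)]


def read_annotation_file(path: Union[str, Path],
                         node_map: Optional[dict[str, str]] = None) -> AnnotationMap:
    """Read a `protein_name<TAB>specificity` TSV (one row per label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    labels: dict[str, set[str]] = {}
    for name, spec in df.itertuples(index=False):
        labels.setdefault(name, set()).add(spec)
    return AnnotationMap(labels=labels, node_map=dict(node_map or {}))


@dataclass
class EnrichmentResult:
    """One (community, specificity) test with its hypergeometric quadruple."""

    community: int
    specificity: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    significant: bool = False


@dataclass
class BaselineSummary:
    """Significant-group counts over random same-size partitions."""

    iterations: int
    counts: list[int]
    mean: float
    min: int
    max: int


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric p-value, tail inclusive of i = k.

    Stable for large N (log-space combinatorics inside scipy).  k = 0 gives
    p = 1 since the tail from zero covers the whole distribution.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, "
                         f"n={n}, k={k}")
    if k == 0:
        return 1.0
    # sf(k-1) = P[X >= k]
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_clusters(partition: Partition,
                    net,
                    ann: AnnotationMap,
                    min_protein_nodes: int = 10,
                    alpha: float = 0.05,
                    count_unannotated: bool = True,
                    bh_correction: bool = False) -> list[EnrichmentResult]:
    """Test every (eligible community, present specificity) pair.

    ``count_unannotated=True`` (default) counts every lectin node toward N
    and n, mirroring an annotation table where unannotated entries are listed
    as NA; with ``False`` only annotated nodes define the urn.  Optional
    Benjamini-Hochberg correction adjusts p-values before flagging
    significance; it is off by default so raw p-values are reported.
    """
    if min_protein_nodes < 1:
        raise ValueError("min_protein_nodes must be >= 1")
    proteins = protein_nodes(net)
    if not count_unannotated:
        proteins = ann.annotated_nodes(proteins)
    if not ann.annotated_nodes(proteins):
        warnings.warn("no annotated lectin nodes; enrichment is empty")
        return []

    N = len(proteins)
    label_nodes: dict[str, set[str]] = {}
    for node in proteins:
        for lab in ann.labels_of_node(node):
            label_nodes.setdefault(lab, set()).add(node)

    results: list[EnrichmentResult] = []
    for c in range(partition.n_communities):
        comm_proteins = [p for p in proteins if partition.assignment[p] == c]
        n = len(comm_proteins)
        if n < min_protein_nodes:
            continue
        comm_set = set(comm_proteins)
        for lab in sorted(label_nodes):
            k = len(label_nodes[lab] & comm_set)
            if k < 1:
                continue
            K = len(label_nodes[lab])
            p = hypergeom_pvalue(N, K, n, k)
            results.append(EnrichmentResult(community=c, specificity=lab,
                                            N=N, K=K, n=n, k=k, p_value=p))

    if bh_correction and results:
        order = np.argsort([r.p_value for r in results])
        mtot = len(results)
        adj = np.empty(mtot)
        prev = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = mtot - rank
            prev = min(prev, results[idx].p_value * mtot / i)
            adj[idx] = prev
        for r, a in zip(results, adj):
            r.p_value = float(a)

    for r in results:
        r.significant = r.p_value <= alpha
    return results


def count_significant_groups(results: Sequence[EnrichmentResult],
                             alpha: float = 0.05) -> int:
    """Number of (community, specificity) pairs with p <= alpha (inclusive)."""
    seen = {(r.community, r.specificity) for r in results if r.p_value <= alpha}
    return len(seen)


def random_baseline(net,
                    sizes: Sequence[int],
                    ann: AnnotationMap,
                    iterations: int = 20,
                    seed: int = 0,
                    min_protein_nodes: int = 10,
                    alpha: float = 0.05,
                    count_unannotated: bool = True) -> BaselineSummary:
    """Significant-group counts when nodes are shuffled into fixed-size bins.

    Every node (lectin and glycan) is permuted uniformly at random into
    communities of the given sizes -- typically the sizes found by the
    optimizer -- and the enrichment analysis is repeated.  Deterministic
    given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    nodes = sorted(net.nodes)
    if sum(sizes) != len(nodes):
        raise ValueError(f"sizes sum to {sum(sizes)}, network has {len(nodes)} nodes")
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    for _ in range(iterations):
        perm = rng.permutation(len(nodes))
        labels = np.empty(len(nodes), dtype=int)
        start = 0
        for c, size in enumerate(sizes):
            labels[perm[start:start + size]] = c
            start += size
        partition = Partition.from_labels(nodes, labels.tolist())
        results = enrich_clusters(partition, net, ann,
                                  min_protein_nodes=min_protein_nodes,
                                  alpha=alpha,
                                  count_unannotated=count_unannotated)
        counts.append(count_significant_groups(results, alpha=alpha))
    return BaselineSummary(iterations=iterations, counts=counts,
                           mean=float(np.mean(counts)),
                           min=int(np.min(counts)), max=int(np.max(counts)))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.community, r.specificity, r.N, r.K, r.n, r.k, r.p_value,
          r.significant) for r in results],
        columns=["community", "specificity", "N", "K", "n", "k", "p_value",
                 "significant"])
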