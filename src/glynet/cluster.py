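"""scikit-learn style estimators around the modularity optimizers.

Community detection is clustering, so the two optimizers are exposed as
estimators that follow the sklearn clusterer contract: ``fit(X)`` on a
precomputed adjacency (dense array, sparse matrix, or a networkx graph),
``labels_`` afterwards, ``fit_predict`` sugar, and ``get_params`` /
``set_params`` so they compose with sklearn model selection.  The functional
API in :mod:`glynet.modularity` is the thin layer the pipeline itself uses.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin

from .modularity import (AnnealConfig, Partition, anneal_partition,
                         greedy_partition, modularity)

__all__ = ["AnnealedModularityClustering", "GreedyModularityClustering"]


def _as_graph(X) -> nx.Graph:
    if isinstance(X, nx.Graph):
        return X
    if sparse.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("X must be a square adjacency matrix or a graph")
    if not np.allclose(X, X.T):
        raise ValueError("adjacency matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(range(X.shape[0]))
    for i, j in zip(*np.nonzero(np.triu(X, k=1))):
        g.add_edge(int(i), int(j))
    return g


class _ModularityClusteringBase(ClusterMixin, BaseEstimator):

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_

    def _finish(self, graph: nx.Graph, partition: Partition):
        nodes = sorted(graph.nodes)
        self.node_ids_ = nodes
        self.partition_ = partition
        self.labels_ = np.asarray(partition.labels_for(nodes))
        self.n_communities_ = partition.n_communities
        self.modularity_ = modularity(graph, partition).q
        return self


class AnnealedModularityClustering(_ModularityClusteringBase):
    """Community detection by simulated-annealing modularity maximization.

    Parameters mirror :class:`glynet.modularity.AnnealConfig`; ``random_state``
    seeds every restart, so fits are reproducible.

    Attributes (after ``fit``): ``labels_``, ``n_communities_``,
    ``modularity_``, ``partition_``, ``node_ids_``.
    """

    def __init__(self, initial_temp: float = 0.05, final_temp: float = 1e-3,
                 cooling: float = 0.95, moves_per_node: int = 20,
                 restarts: int = 4, random_state: int = 0):
        self.initial_temp = initial_temp
        self.final_temp = final_temp
        self.cooling = cooling
        self.moves_per_node = moves_per_node
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        graph = _as_graph(X)
        config = AnnealConfig(initial_temp=self.initial_temp,
                              final_temp=self.final_temp,
                              cooling=self.cooling,
                              moves_per_node=self.moves_per_node,
                              restarts=self.restarts)
        partition = anneal_partition(graph, config, seed=self.random_state)
        return self._finish(graph, partition)


class GreedyModularityClustering(_ModularityClusteringBase):
    """Fast-greedy agglomerative modularity clustering (deterministic)."""

    def __init__(self):
        pass

    def fit(self, X, y=None):
        graph = _as_graph(X)
        return self._finish(graph, greedy_partition(graph))
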