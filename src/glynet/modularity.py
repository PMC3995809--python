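"""Modularity scoring and optimization of network partitions.

Modularity of a partition of an unweighted graph with M edges is

    Q = sum_i [ l_i / M - (d_i / 2M)^2 ]

where l_i is the number of edges with both endpoints in community i and d_i
is the summed degree of the community's nodes.  Q lies in [-1, 1]: 0 for the
all-in-one partition (and in expectation for random structure), approaching 1
for strongly modular structure.  The same standard (unipartite) Q is applied
to the bipartite lectin-glycan graph.

Two optimizers are provided:

``anneal_partition``
    Simulated annealing over partitions with three move kinds -- single-node
    reassignment, community merge, and community split by local bisection --
    under geometric cooling, with multiple seeded restarts and a final
    single-node hill-climb.  Deterministic given (graph, config, seed).

``greedy_partition``
    The classic fast-greedy agglomeration: start from singletons and
    repeatedly merge the connected community pair with the largest positive
    modularity gain, with ties broken by the smallest community-index pair.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

__all__ = [
    "Partition",
    "ModularityScore",
    "AnnealConfig",
    "modularity",
    "anneal_partition",
    "greedy_partition",
]


@dataclass
class Partition:
    """Total assignment of every node to exactly one community.

    Community indices are contiguous in ``0..n_communities-1``.
    """

    assignment: dict[str, int]
    n_communities: int

    def __post_init__(self) -> None:
        if self.n_communities < 1:
            raise ValueError("a partition needs at least one community")
        seen = set(self.assignment.values())
        if seen != set(range(self.n_communities)):
            raise ValueError("community indices must be contiguous from 0")

    @classmethod
    def from_labels(cls, nodes: Sequence[str], labels: Sequence[int]) -> "Partition":
        """Build a partition from parallel node/label sequences.

        Labels are compressed to contiguous indices in order of first
        appearance, so the result is deterministic in the node order given.
        """
        remap: dict[int, int] = {}
        assignment: dict[str, int] = {}
        for node, lab in zip(nodes, labels):
            if lab not in remap:
                remap[lab] = len(remap)
            assignment[node] = remap[lab]
        return cls(assignment=assignment, n_communities=len(remap))

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, c in self.assignment.items():
            out[c].add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]

    def labels_for(self, nodes: Sequence[str]) -> list[int]:
        return [self.assignment[n] for n in nodes]


@dataclass
class ModularityScore:
    """Q plus the per-community (l_i, d_i) bookkeeping behind it."""

    q: float
    m: int
    per_community: list[tuple[int, int]] = field(default_factory=list)


def modularity(net: nx.Graph, partition: Partition) -> ModularityScore:
    """Score a partition by Q = sum_i [ l_i/M - (d_i/2M)^2 ].

    The partition must cover every node of ``net``; an empty graph has no
    defined modularity.
    """
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on empty graph")
    missing = set(net.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")

    l = [0] * partition.n_communities
    d = [0] * partition.n_communities
    assign = partition.assignment
    for u, v in net.edges():
        if assign[u] == assign[v]:
            l[assign[u]] += 1
    for node in net.nodes:
        d[assign[node]] += net.degree(node)
    q = sum(li / m - (di / (2.0 * m)) ** 2 for li, di in zip(l, d))
    return ModularityScore(q=q, m=m, per_community=list(zip(l, d)))


@dataclass
class AnnealConfig:
    """Schedule and move mix of the simulated-annealing optimizer.

    Temperatures are on the scale of Q differences (single-node moves change
    Q by O(1/M)), so the defaults anneal from well above to well below the
    typical move size.  ``moves_per_node`` proposals are made per node per
    temperature step; the whole schedule is repeated ``restarts`` times from
    independent random initial partitions and the best-Q partition wins.
    """

    initial_temp: float = 0.05
    final_temp: float = 1e-3
    cooling: float = 0.95
    moves_per_node: int = 20
    restarts: int = 4
    p_single: float = 0.90
    p_merge: float = 0.05
    p_split: float = 0.05

    def validate(self) -> None:
        if not (self.initial_temp > self.final_temp > 0):
            raise ValueError("need initial_temp > final_temp > 0")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0, 1)")
        if self.moves_per_node < 1 or self.restarts < 1:
            raise ValueError("moves_per_node and restarts must be >= 1")
        if min(self.p_single, self.p_merge, self.p_split) < 0:
            raise ValueError("move probabilities must be non-negative")


def _graph_arrays(net: nx.Graph):
    """Index nodes and build adjacency lists for the optimizers."""
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for u, v in net.edges():
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])
    deg = [len(a) for a in adj]
    m = net.number_of_edges()
    return nodes, adj, deg, m


class _AnnealState:
    """Mutable partition state with incremental modularity bookkeeping."""

    def __init__(self, adj, deg, m, labels):
        self.adj = adj
        self.deg = deg
        self.m = m
        self.labels = list(labels)
        self.members: dict[int, set[int]] = {}
        self.d: dict[int, int] = {}
        self.l: dict[int, int] = {}
        for u, c in enumerate(self.labels):
            self.members.setdefault(c, set()).add(u)
            self.d[c] = self.d.get(c, 0) + deg[u]
        for c in self.members:
            self.l[c] = 0
        for u in range(len(self.labels)):
            cu = self.labels[u]
            for v in self.adj[u]:
                if v > u and self.labels[v] == cu:
                    self.l[cu] += 1
        self.next_label = max(self.members) + 1 if self.members else 0

    def q(self) -> float:
        m = self.m
        return sum(self.l[c] / m - (self.d[c] / (2.0 * m)) ** 2
                   for c in self.members)

    def links_to(self, u: int) -> dict[int, int]:
        links: dict[int, int] = {}
        labels = self.labels
        for v in self.adj[u]:
            c = labels[v]
            links[c] = links.get(c, 0) + 1
        return links

    def move_gain(self, u: int, c_to: int, links: dict[int, int]) -> float:
        c_from = self.labels[u]
        e_old = links.get(c_from, 0)
        e_new = links.get(c_to, 0)
        k = self.deg[u]
        d_to = self.d.get(c_to, 0)
        return ((e_new - e_old) / self.m
                - k * (d_to - self.d[c_from] + k) / (2.0 * self.m * self.m))

    def apply_move(self, u: int, c_to: int, links: dict[int, int]) -> None:
        c_from = self.labels[u]
        k = self.deg[u]
        self.members[c_from].discard(u)
        self.d[c_from] -= k
        self.l[c_from] -= links.get(c_from, 0)
        if not self.members[c_from]:
            del self.members[c_from], self.d[c_from], self.l[c_from]
        if c_to not in self.members:
            self.members[c_to] = set()
            self.d[c_to] = 0
            self.l[c_to] = 0
        self.members[c_to].add(u)
        self.d[c_to] += k
        self.l[c_to] += links.get(c_to, 0)
        self.labels[u] = c_to

    def edges_between(self, c1: int, c2: int) -> int:
        small = c1 if len(self.members[c1]) <= len(self.members[c2]) else c2
        other = c2 if small == c1 else c1
        labels = self.labels
        return sum(1 for u in self.members[small] for v in self.adj[u]
                   if labels[v] == other)

    def merge(self, c1: int, c2: int, m12: int) -> None:
        if len(self.members[c2]) > len(self.members[c1]):
            c1, c2 = c2, c1
        for u in self.members[c2]:
            self.labels[u] = c1
        self.members[c1] |= self.members[c2]
        self.d[c1] += self.d[c2]
        self.l[c1] += self.l[c2] + m12
        del self.members[c2], self.d[c2], self.l[c2]

    def split(self, c: int, part: set[int]) -> None:
        """Move ``part`` (a strict subset of community c) to a fresh label."""
        new = self.next_label
        self.next_label += 1
        labels = self.labels
        e_in = 0   # edges inside part
        k_part = 0
        for u in part:
            k_part += self.deg[u]
            for v in self.adj[u]:
                if v in part and v > u:
                    e_in += 1
        e_cross = sum(1 for u in part for v in self.adj[u]
                      if labels[v] == c and v not in part)
        for u in part:
            labels[u] = new
        self.members[c] -= part
        self.members[new] = set(part)
        self.d[c] -= k_part
        self.d[new] = k_part
        self.l[c] -= e_in + e_cross
        self.l[new] = e_in

    def split_gain(self, c: int, part: set[int]) -> float:
        labels = self.labels
        e_cross = sum(1 for u in part for v in self.adj[u]
                      if labels[v] == c and v not in part)
        k_part = sum(self.deg[u] for u in part)
        d_rest = self.d[c] - k_part
        return -e_cross / self.m + k_part * d_rest / (2.0 * self.m * self.m)


def _hill_climb(state: _AnnealState, rng: random.Random,
                max_passes: int = 100) -> None:
    """Greedy single-node best-move passes until a local optimum."""
    n = len(state.labels)
    order = list(range(n))
    for _ in range(max_passes):
        improved = False
        rng.shuffle(order)
        for u in order:
            links = state.links_to(u)
            c_from = state.labels[u]
            best_c, best_gain = c_from, 0.0
            candidates = set(links) | {state.next_label}
            for c_to in candidates:
                if c_to == c_from:
                    continue
                gain = state.move_gain(u, c_to, links)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c_to
            if best_c != c_from:
                if best_c == state.next_label:
                    state.next_label += 1
                state.apply_move(u, best_c, links)
                improved = True
        if not improved:
            break


def _anneal_once(adj, deg, m, config: AnnealConfig, rng: random.Random,
                 init_labels: Optional[list[int]] = None):
    n = len(adj)
    if init_labels is None:
        n_init = max(2, int(round(math.sqrt(n))))
        init_labels = [rng.randrange(n_init) for _ in range(n)]
    state = _AnnealState(adj, deg, m, init_labels)

    best_q = state.q()
    best_labels = list(state.labels)

    temp = config.initial_temp
    p1 = config.p_single
    p2 = p1 + config.p_merge
    total = p1 + config.p_merge + config.p_split
    moves = config.moves_per_node * n
    while temp > config.final_temp:
        for _ in range(moves):
            r = rng.random() * total
            if r < p1 or len(state.members) == 1:
                u = rng.randrange(n)
                links = state.links_to(u)
                c_from = state.labels[u]
                if rng.random() < 0.85 and links:
                    c_to = rng.choice(sorted(links))
                elif len(state.members[c_from]) > 1 and rng.random() < 0.5:
                    c_to = state.next_label
                else:
                    c_to = rng.choice(sorted(state.members))
                if c_to == c_from:
                    continue
                gain = state.move_gain(u, c_to, links)
                if gain >= 0 or rng.random() < math.exp(gain / temp):
                    if c_to == state.next_label:
                        state.next_label += 1
                    state.apply_move(u, c_to, links)
            elif r < p2:
                cs = sorted(state.members)
                c1, c2 = rng.sample(cs, 2)
                m12 = state.edges_between(c1, c2)
                gain = (m12 / m
                        - state.d[c1] * state.d[c2] / (2.0 * m * m))
                if gain >= 0 or rng.random() < math.exp(gain / temp):
                    state.merge(c1, c2, m12)
            else:
                cs = sorted(c for c in state.members
                            if len(state.members[c]) >= 2)
                if not cs:
                    continue
                c = rng.choice(cs)
                part = _local_bisection(state, c, rng)
                if not part or len(part) == len(state.members[c]):
                    continue
                gain = state.split_gain(c, part)
                if gain >= 0 or rng.random() < math.exp(gain / temp):
                    state.split(c, part)
        q = state.q()
        if q > best_q:
            best_q = q
            best_labels = list(state.labels)
        temp *= config.cooling
    return best_q, best_labels


def _local_bisection(state: _AnnealState, c: int,
                     rng: random.Random) -> set[int]:
    """Grow a connected half of community c by BFS from a random seed."""
    members = state.members[c]
    target = len(members) // 2
    seed = rng.choice(sorted(members))
    part = {seed}
    frontier = [seed]
    labels = state.labels
    while frontier and len(part) < target:
        u = frontier.pop()
        for v in state.adj[u]:
            if labels[v] == c and v not in part:
                part.add(v)
                frontier.append(v)
                if len(part) >= target:
                    break
    return part


def anneal_partition(net: nx.Graph,
                     config: Optional[AnnealConfig] = None,
                     seed: int = 0) -> Partition:
    """Find a high-modularity partition by simulated annealing.

    Runs ``config.restarts`` independent annealing runs from random initial
    partitions, keeps the best-Q state seen anywhere along any run, and
    finishes with a single-node hill-climb so the result is a local optimum
    under node moves.  The number of communities is free.  Deterministic
    given (net, config, seed); never returns a partition with lower Q than
    its own initialization.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    config = config or AnnealConfig()
    config.validate()
    nodes, adj, deg, m = _graph_arrays(net)
    if m == 0:
        raise ValueError("modularity optimization undefined with no edges")

    master = random.Random(seed)
    # warm start: the first restart anneals from the fast-greedy solution,
    # the remaining restarts from independent random partitions
    greedy_labels = greedy_partition(net).labels_for(nodes)
    best_q = -math.inf
    best_labels: list[int] = []
    for restart in range(config.restarts):
        rng = random.Random(master.randrange(2**31))
        init = greedy_labels if restart == 0 else None
        q, labels = _anneal_once(adj, deg, m, config, rng, init_labels=init)
        if q > best_q:
            best_q, best_labels = q, labels

    state = _AnnealState(adj, deg, m, best_labels)
    _hill_climb(state, random.Random(master.randrange(2**31)))
    return Partition.from_labels(nodes, state.labels)


def greedy_partition(net: nx.Graph) -> Partition:
    """Fast-greedy agglomerative modularity maximization.

    Starts from singleton communities and repeatedly merges the pair of
    connected communities with the largest modularity gain

        dQ = m_ij / M - d_i * d_j / (2 M^2)

    while the best gain is positive, breaking ties by the lowest community
    index pair.  Returns the partition at the Q maximum of the merge path.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    nodes, adj, deg, m = _graph_arrays(net)
    if m == 0:
        raise ValueError("modularity optimization undefined with no edges")

    d = {i: deg[i] for i in range(len(nodes))}
    parent = {i: i for i in range(len(nodes))}
    # inter-community edge counts keyed by (lo, hi)
    pairs: dict[tuple[int, int], int] = {}
    for u in range(len(nodes)):
        for v in adj[u]:
            if u < v:
                pairs[(u, v)] = pairs.get((u, v), 0) + 1
    # neighbor map community -> set of connected communities
    nbrs: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    for (a, b) in pairs:
        nbrs[a].add(b)
        nbrs[b].add(a)

    members: dict[int, list[int]] = {i: [i] for i in range(len(nodes))}

    while len(members) > 1:
        best_pair = None
        best_gain = 0.0
        # sorted iteration: on dQ ties the lowest community-index pair wins
        for (a, b) in sorted(pairs):
            gain = pairs[(a, b)] / m - d[a] * d[b] / (2.0 * m * m)
            if gain <= 1e-15:
                continue
            if best_pair is None or gain > best_gain + 1e-12:
                best_gain = gain
                best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair  # merge b into a (a < b)
        for u in members[b]:
            parent[u] = a
        members[a].extend(members[b])
        del members[b]
        d[a] += d.pop(b)
        nbrs[b].discard(a)
        nbrs[a].discard(b)
        pairs.pop((a, b))
        for c in nbrs[b]:
            mcb = pairs.pop((min(b, c), max(b, c)))
            key = (min(a, c), max(a, c))
            pairs[key] = pairs.get(key, 0) + mcb
            nbrs[c].discard(b)
            nbrs[c].add(a)
            nbrs[a].add(c)
        del nbrs[b]

    labels = [parent[i] for i in range(len(nodes))]
    return Partition.from_labels(nodes, labels)
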