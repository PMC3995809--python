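import itertools
import random

import networkx as nx
import pytest

from glynet.modularity import (AnnealConfig, Partition, anneal_partition,
                               greedy_partition, modularity)


def pairwise_q(net, partition):
    """Independent oracle: Q = sum_uv (A_uv - k_u k_v / 2M) delta / 2M."""
    m = net.number_of_edges()
    nodes = list(net.nodes)
    q = 0.0
    for u in nodes:
        for v in nodes:
            if partition.assignment[u] != partition.assignment[v]:
                continue
            a = 1.0 if net.has_edge(u, v) else 0.0
            q += a - net.degree(u) * net.degree(v) / (2.0 * m)
    return q / (2.0 * m)


def single_community(net):
    return Partition.from_labels(list(net.nodes), [0] * net.number_of_nodes())


class TestModularityFormula:
    def test_single_community_is_zero(self, planted):
        net = planted["net"]
        assert modularity(net, single_community(net)).q == pytest.approx(0.0, abs=1e-12)

    def test_one_edge_singletons(self):
        net = nx.Graph([("a", "b")])
        part = Partition.from_labels(["a", "b"], [0, 1])
        assert modularity(net, part).q == pytest.approx(-0.5)

    def test_two_six_cycles(self):
        net = nx.disjoint_union(nx.cycle_graph(6), nx.cycle_graph(6))
        labels = [0] * 6 + [1] * 6
        part = Partition.from_labels(list(net.nodes), labels)
        score = modularity(net, part)
        assert score.q == pytest.approx(0.5)
        assert score.q == pytest.approx(pairwise_q(net, part), abs=1e-12)

    def test_empty_graph_is_error(self):
        net = nx.Graph()
        net.add_node("a")
        with pytest.raises(ValueError, match="undefined"):
            modularity(net, Partition.from_labels(["a"], [0]))

    def test_matches_pairwise_oracle_on_random_graphs(self):
        rng = random.Random(0)
        for _ in range(60):
            n = rng.randint(2, 20)
            net = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=rng.randint(0, 10**6))
            if net.number_of_edges() == 0:
                continue
            labels = [rng.randrange(rng.randint(1, 4)) for _ in range(n)]
            part = Partition.from_labels(list(net.nodes), labels)
            assert modularity(net, part).q == pytest.approx(
                pairwise_q(net, part), abs=1e-12)

    def test_matches_networkx_on_planted(self, planted, planted_anneal):
        net = planted["net"]
        q_nx = nx.community.modularity(net, planted_anneal.communities())
        assert modularity(net, planted_anneal).q == pytest.approx(q_nx, abs=1e-12)

    def test_bookkeeping_invariants(self, planted, planted_anneal):
        score = modularity(planted["net"], planted_anneal)
        assert -1.0 <= score.q <= 1.0
        assert sum(l for l, _ in score.per_community) <= score.m
        assert sum(d for _, d in score.per_community) == 2 * score.m


class TestAnneal:
    def test_recovers_two_cliques_optimum(self, two_cliques):
        net = two_cliques
        # exhaustive oracle over all 2-community partitions of 16 nodes
        nodes = sorted(net.nodes)
        best_q = -2.0
        for mask in range(1, 2 ** (len(nodes) - 1)):
            labels = [0] + [(mask >> i) & 1 for i in range(len(nodes) - 1)]
            q = modularity(net, Partition.from_labels(nodes, labels)).q
            best_q = max(best_q, q)
        part = anneal_partition(net, seed=5)
        q_anneal = modularity(net, part).q
        assert q_anneal == pytest.approx(best_q, abs=1e-12)
        assert part.n_communities == 2
        comms = {frozenset(c) for c in part.communities()}
        expected = {frozenset(c) for c in nx.connected_components(net)}
        assert comms == expected

    def test_deterministic_given_seed(self, two_cliques):
        a = anneal_partition(two_cliques, seed=11)
        b = anneal_partition(two_cliques, seed=11)
        assert a.assignment == b.assignment

    def test_planted_recovery_nmi(self, planted, planted_anneal):
        from sklearn.metrics import normalized_mutual_info_score

        net, truth = planted["net"], planted["truth"]
        nodes = sorted(net.nodes)
        nmi = normalized_mutual_info_score(
            [truth.community_of[n] for n in nodes],
            planted_anneal.labels_for(nodes))
        assert nmi >= 0.9

    def test_not_worse_than_initialization(self, planted):
        # the all-random initial partitions have Q near 0; anneal must beat them
        net = planted["net"]
        part = anneal_partition(
            net, AnnealConfig(moves_per_node=2, restarts=1), seed=3)
        assert modularity(net, part).q > 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnealConfig(initial_temp=1e-5, final_temp=1e-3).validate()
        with pytest.raises(ValueError):
            AnnealConfig(cooling=1.5).validate()


class TestGreedy:
    def test_two_cliques_components(self, two_cliques):
        part = greedy_partition(two_cliques)
        comms = {frozenset(c) for c in part.communities()}
        assert comms == {frozenset(c)
                         for c in nx.connected_components(two_cliques)}

    def test_single_edge_merges_to_zero(self):
        net = nx.Graph([("a", "b")])
        part = greedy_partition(net)
        assert part.n_communities == 1
        assert modularity(net, part).q == pytest.approx(0.0)

    def test_deterministic(self, planted):
        a = greedy_partition(planted["net"])
        b = greedy_partition(planted["net"])
        assert a.assignment == b.assignment

    def test_comparable_to_networkx_cnm(self, planted):
        # independent implementation of the same agglomerative scheme
        net = planted["net"]
        q_ours = modularity(net, greedy_partition(net)).q
        nx_comms = nx.community.greedy_modularity_communities(net)
        q_nx = nx.community.modularity(net, nx_comms)
        assert q_ours == pytest.approx(q_nx, abs=0.05)


class TestOptimizerOrdering:
    def test_anneal_at_least_greedy(self, planted, planted_anneal):
        net = planted["net"]
        q_anneal = modularity(net, planted_anneal).q
        q_greedy = modularity(net, greedy_partition(net)).q
        assert q_anneal >= q_greedy - 1e-12

    def test_planted_beats_random_partition(self, planted):
        import random as _random

        net, truth = planted["net"], planted["truth"]
        nodes = sorted(net.nodes)
        q_truth = modularity(net, Partition.from_labels(
            nodes, [truth.community_of[n] for n in nodes])).q
        rng = _random.Random(0)
        labels = [rng.randrange(4) for _ in nodes]
        q_rand = modularity(net, Partition.from_labels(nodes, labels)).q
        assert q_truth > q_rand + 0.2
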