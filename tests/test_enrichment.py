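from fractions import Fraction
from math import comb

import networkx as nx
import pytest

from glynet.enrichment import (AnnotationMap, count_significant_groups,
                               enrich_clusters, hypergeom_pvalue,
                               random_baseline)
from glynet.modularity import Partition


def enumeration_pvalue(N, K, n, k):
    """Exact oracle: tail sum of C(K,i) C(N-K,n-i) / C(N,n) as a Fraction."""
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1))
    return Fraction(tail, total)


class TestHypergeomPvalue:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(50, 10, 5, 0) == 1.0

    def test_known_fraction_10_4_5_3(self):
        # enumeration of all C(10,5) draws counting those with >= 3 marked
        assert enumeration_pvalue(10, 4, 5, 3) == Fraction(66, 252)
        assert hypergeom_pvalue(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-12)

    def test_known_fraction_5_2_2_2(self):
        assert enumeration_pvalue(5, 2, 2, 2) == Fraction(1, 10)
        assert hypergeom_pvalue(5, 2, 2, 2) == pytest.approx(0.1, abs=1e-12)

    def test_agrees_with_enumeration_sample(self):
        for N in (6, 13, 21, 30):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 4):
                    for k in range(0, min(K, n) + 1):
                        expected = float(enumeration_pvalue(N, K, n, k))
                        assert hypergeom_pvalue(N, K, n, k) == pytest.approx(
                            expected, abs=1e-12)

    def test_monotone_in_k(self):
        N, K, n = 40, 12, 15
        ps = [hypergeom_pvalue(N, K, n, k) for k in range(0, min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_stable_at_large_n(self):
        p = hypergeom_pvalue(10_000, 400, 500, 50)
        assert 0.0 < p < 1e-6

    @pytest.mark.parametrize("args", [(5, 6, 2, 1), (5, 2, 6, 1), (5, 2, 2, 3),
                                      (5, 2, 2, -1)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            hypergeom_pvalue(*args)


def toy_network(protein_labels, glycans_per_protein=2):
    """One protein node per entry of protein_labels, each with private glycans."""
    net = nx.Graph()
    labels = {}
    for i, lab in enumerate(protein_labels):
        p = f"L{i:03d}"
        net.add_node(p, side="protein")
        labels[p] = lab
        for j in range(glycans_per_protein):
            g = f"g{i:03d}_{j}"
            net.add_node(g, side="glycan")
            net.add_edge(p, g, rfu=9000.0)
    ann = AnnotationMap(labels={p: ({lab} if lab else set())
                                for p, lab in labels.items()},
                        node_map={p: p for p in labels})
    return net, ann


class TestEnrichClusters:
    def test_small_community_excluded(self):
        net, ann = toy_network(["A"] * 5 + ["B"] * 12)
        nodes = sorted(net.nodes)
        labels = [0 if n < "L005" else 1 for n in nodes]
        part = Partition.from_labels(nodes, labels)
        results = enrich_clusters(part, net, ann, min_protein_nodes=10)
        assert {r.community for r in results} == {1}

    def test_whole_network_community_has_p_one(self):
        net, ann = toy_network(["A"] * 8 + ["B"] * 4)
        part = Partition.from_labels(sorted(net.nodes),
                                     [0] * net.number_of_nodes())
        results = enrich_clusters(part, net, ann, min_protein_nodes=10)
        assert results
        for r in results:
            assert r.k == r.K and r.n == r.N
            assert r.p_value == pytest.approx(1.0)

    def test_planted_dominant_labels_significant(self, planted, planted_anneal):
        truth = planted["truth"]
        results = enrich_clusters(planted_anneal, planted["net"], planted["ann"])
        sig = {(r.community, r.specificity) for r in results if r.significant}
        # map each planted community to the detected community holding most
        # of its proteins, then require its dominant label significant there
        for c, label in truth.dominant_label.items():
            members = [n for n, cc in truth.community_of.items()
                       if cc == c and n in planted_anneal.assignment
                       and planted["net"].nodes.get(n, {}).get("side") == "protein"]
            detected = max(set(planted_anneal.assignment[n] for n in members),
                           key=lambda d: sum(planted_anneal.assignment[n] == d
                                             for n in members))
            assert (detected, label) in sig

    def test_no_annotations_warns_empty(self):
        net, ann = toy_network([None] * 12)
        part = Partition.from_labels(sorted(net.nodes),
                                     [0] * net.number_of_nodes())
        with pytest.warns(UserWarning, match="no annotated"):
            assert enrich_clusters(part, net, ann) == []

    def test_quadruple_invariants(self, planted, planted_anneal):
        for r in enrich_clusters(planted_anneal, planted["net"], planted["ann"]):
            assert 0 <= r.k <= min(r.K, r.n)
            assert r.K <= r.N and r.n <= r.N
            assert 0.0 < r.p_value <= 1.0


class TestCountSignificantGroups:
    def test_empty(self):
        assert count_significant_groups([]) == 0

    def test_boundary_inclusive(self):
        from glynet.enrichment import EnrichmentResult

        results = [EnrichmentResult(0, s, 10, 5, 5, 3, p)
                   for s, p in [("a", 0.01), ("b", 0.05), ("c", 0.06)]]
        assert count_significant_groups(results, alpha=0.05) == 2

    def test_order_invariant(self):
        from glynet.enrichment import EnrichmentResult

        results = [EnrichmentResult(c, s, 10, 5, 5, 3, p)
                   for c, s, p in [(0, "a", 0.01), (1, "b", 0.2), (2, "c", 0.03)]]
        assert count_significant_groups(results) == \
            count_significant_groups(list(reversed(results)))


class TestRandomBaseline:
    def test_identical_labels_never_significant(self):
        net, ann = toy_network(["A"] * 24)
        summary = random_baseline(net, [36, 36], ann, iterations=5, seed=1)
        assert summary.counts == [0] * 5

    def test_deterministic_given_seed(self, planted, planted_anneal):
        net, ann = planted["net"], planted["ann"]
        sizes = planted_anneal.sizes()
        a = random_baseline(net, sizes, ann, iterations=5, seed=3)
        b = random_baseline(net, sizes, ann, iterations=5, seed=3)
        assert a.counts == b.counts

    def test_sizes_mismatch_rejected(self, planted):
        with pytest.raises(ValueError, match="sizes"):
            random_baseline(planted["net"], [1, 2], planted["ann"],
                            iterations=1, seed=0)

    def test_planted_partition_beats_baseline(self, planted, planted_anneal):
        net, ann = planted["net"], planted["ann"]
        results = enrich_clusters(planted_anneal, net, ann)
        pipeline_count = count_significant_groups(results)
        summary = random_baseline(net, planted_anneal.sizes(), ann,
                                  iterations=20, seed=5)
        assert summary.min <= summary.mean <= summary.max
        assert summary.mean < pipeline_count
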