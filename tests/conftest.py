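import networkx as nx
import pytest

import glynet as gn


@pytest.fixture(scope="session")
def planted():
    """Default planted dataset, merged/filtered, with its network and truth."""
    cfg = gn.PlantedConfig(seed=42)
    experiments, ann, truth = gn.generate_planted_dataset(cfg)
    table = gn.merge_experiments(experiments)
    filtered = gn.filter_by_rfu(table, cfg.rfu_cutoff)
    net = gn.build_bipartite(filtered)
    return {"config": cfg, "experiments": experiments, "ann": ann,
            "truth": truth, "table": table, "filtered": filtered, "net": net}


@pytest.fixture(scope="session")
def planted_anneal(planted):
    """One annealed partition of the default planted network (shared)."""
    return gn.anneal_partition(planted["net"], seed=7)


@pytest.fixture()
def two_cliques():
    """Two disconnected bipartite cliques K(4,4): optimum = the components."""
    g = nx.Graph()
    for block, (ps, gs) in enumerate([("abcd", "ABCD"), ("efgh", "EFGH")]):
        for p in ps:
            g.add_node(f"p{p}", side="protein")
        for q in gs:
            g.add_node(f"g{q}", side="glycan")
        for p in ps:
            for q in gs:
                g.add_edge(f"p{p}", f"g{q}", rfu=9000.0)
    return g
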