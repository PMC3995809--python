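# glynet

Community-based analysis of lectin–glycan interaction networks built from
glycan-microarray RFU data.

Glycan microarrays probe a carbohydrate-binding protein (a lectin) against
hundreds of immobilised glycans at once, reporting a relative fluorescence
unit (RFU) per spot. A collection of such experiments defines a bipartite
network — lectin nodes on one side, glycan nodes on the other, an unweighted
edge wherever the RFU clears a cutoff (conventionally 5000, 10000 or 20000).
`glynet` is for glycobiologists and network biologists who want to turn such
a collection into a global picture: which lectins share glycan partners,
which lectins are promiscuous hubs, and whether the groups that emerge are
enriched for known glycan-binding specificities.

## What it computes

* **Communities** by maximizing modularity

  `Q = Σᵢ [ lᵢ/M − (dᵢ/2M)² ]`

  (M edges; community i has lᵢ internal edges and summed degree dᵢ), with a
  seeded simulated-annealing optimizer (single-node moves, community merges
  and splits, geometric cooling, restarts, final hill-climb) and a
  deterministic fast-greedy agglomerative baseline. Both are also exposed as
  scikit-learn style clusterers (`AnnealedModularityClustering`,
  `GreedyModularityClustering`).
* **Hub lectins** from the protein-side degree ranking, via the largest
  consecutive degree gap in the top of the ranking (or a plain threshold).
* **Specificity enrichment** per community with the exact upper-tail
  hypergeometric p-value
  `p = Σ_{i≥k} C(K,i) C(N−K,n−i) / C(N,n)`
  over a curated lectin → specificity annotation table (one is packaged),
  plus a random same-size-partition baseline for the number of significant
  groups.
* **Determinant motifs**: spelling-invariant scanning of IUPAC-condensed
  glycan strings (Greek/Latin anomeric letters, case, arrows all normalized)
  for determinants such as `Neu5Acα2-6Galβ1-4GlcNAc`, optionally across one
  parenthesized branch.
* **Synthetic CFG-like data** with planted communities, hubs and labels, so
  the full pipeline is testable end to end without any download.

## Worked example

```python
import glynet as gn

cfg = gn.PlantedConfig(seed=7)                      # 4 planted communities
experiments, annotations, truth = gn.generate_planted_dataset(cfg)
table = gn.filter_by_rfu(gn.merge_experiments(experiments), cfg.rfu_cutoff)
net = gn.build_bipartite(table)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

partition = gn.anneal_partition(net, seed=7)
print(f"anneal:  {partition.n_communities} communities, "
      f"Q = {gn.modularity(net, partition).q:.3f}")
print(f"greedy:  Q = {gn.modularity(net, gn.greedy_partition(net)).q:.3f}")

hubs = gn.detect_hubs(net, rule="degree_gap")
print(f"hubs:    {sorted(hubs.hubs)}")

results = gn.enrich_clusters(partition, net, annotations)
print(f"enriched groups at p<=0.05: {gn.count_significant_groups(results)}")
base = gn.random_baseline(net, partition.sizes(), annotations,
                          iterations=20, seed=7)
print(f"random baseline mean:       {base.mean}")
```

prints

```
network: 283 nodes, 2130 edges
anneal:  4 communities, Q = 0.480
greedy:  Q = 0.447
hubs:    ['1099000', '1099001', '1099002']
enriched groups at p<=0.05: 4
random baseline mean:       0.25
```

The annealer recovers the 4 planted communities with higher modularity than
the greedy baseline; the degree-gap rule finds exactly the 3 planted hub
lectins; each community is significantly enriched for its planted dominant
specificity (4 significant groups), far above the ~0.3 significant groups a
random partition of the same sizes produces by chance.

Scanning a published bound-glycan list for a determinant:

```python
from glynet.datasets import load_sna_glycans
from glynet.motif import MotifQuery, count_glycans_with_motif

glycans = load_sna_glycans("sna2_community3")   # SNA-II array-node group
count, ids = count_glycans_with_motif(
    glycans, MotifQuery("Neu5Aca2-6Galb1-4GlcNAc"))
print(count, ids)        # -> 2 ['347', '349']
```

Of the mannose-preferring glycans bound by the SNA-II nodes, exactly two
(glycans 347 and 349) carry the sialylated determinant — the SNA-I
signature, not the SNA-II one.

## Command line

```
glynet simulate --out-dir data --seed 1          # planted array collection
glynet build    --array-dir data/arrays --out-dir out
glynet run      --config config.yaml             # full pipeline + exports
glynet motif-scan --glycans glycans.tsv --motif "Neu5Aca2-6Gal"
```

`glynet run` writes the partition TSVs, enrichment report, hub report,
GraphML/SIF exports (Cytoscape-ready) and a `summary.json`; all seeds and
stage timings are logged to stderr.

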