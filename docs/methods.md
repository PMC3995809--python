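# Methods

## The analysis

`glynet` analyses lectin–glycan interaction screens of the kind produced by
printed glycan microarrays: each experiment probes one carbohydrate-binding
protein (a lectin, under one assay condition) against a shared panel of
glycans and reports a relative fluorescence unit (RFU) per spot. The package
turns a collection of such experiments into a bipartite network and asks
which groups of lectins share glycan partners.

The pipeline is: (1) parse per-lectin files and average replicate spots;
(2) merge into one interaction table; (3) keep pairs with RFU ≥ cutoff
(5000 by default; 10000 and 20000 are the other conventional choices, and the
three networks nest); (4) build an unweighted bipartite graph — lectin nodes
on one side, glycan nodes on the other, RFU retained only as an edge
attribute; (5) detect communities by modularity maximization; (6) call hub
lectins from the degree distribution; (7) test each sufficiently large
community for enrichment of curated glycan-binding specificities with the
exact hypergeometric tail, against a random-partition baseline; and
(8) optionally scan any lectin's bound-glycan list for a determinant motif.

## Modularity and its optimizers

For a partition of a graph with `M` edges into communities with `l_i`
internal edges and summed degree `d_i`,

    Q = Σ_i [ l_i/M − (d_i/2M)² ],

i.e. the within-community edge fraction minus its expectation under a
degree-preserving rewiring; Q ∈ [−1, 1], 0 for the all-in-one partition.
The standard unipartite Q is applied directly to the bipartite graph (no
bipartite-specific variant): glycan nodes co-cluster with the lectins that
bind them, which is exactly the grouping of interest.

Two optimizers are provided, both authored here:

* **Simulated annealing** (`anneal_partition`): Metropolis moves of three
  kinds — single-node reassignment (dominant), merge of two communities, and
  split of a community along a BFS-grown local bisection — under geometric
  cooling, multiple restarts, and a final single-node hill-climb. The first
  restart is warm-started from the fast-greedy solution, the rest from
  random partitions; the best-Q state seen anywhere (including every
  initialization) is kept. This makes `q(anneal) ≥ q(greedy)` structural and
  the result never worse than its own initialization. The number of
  communities is free.
* **Fast-greedy agglomeration** (`greedy_partition`): from singletons,
  repeatedly merge the connected pair with the largest
  `ΔQ = m_ij/M − d_i d_j/(2M²)` while positive; ΔQ ties are broken by the
  lowest community-index pair so the method is fully deterministic.

Annealing defaults — initial temperature 0.05, final 1e-3, cooling 0.95,
20·|nodes| proposals per temperature, 4 restarts — were chosen so that one
run on a ~300-node, ~2000-edge network takes on the order of ten seconds in
pure Python while still recovering planted structure essentially perfectly
(NMI ≈ 1.0); temperatures are on the scale of single-move Q changes, O(1/M).
For much larger networks, raise `moves_per_node` and `restarts`. Every
stochastic entry point takes an explicit seed and is reproducible bit for bit.

Single-node move gains are computed incrementally in O(degree):
`ΔQ = (e_new − e_old)/M − k_u(d_new − d_old + k_u)/(2M²)`, with community
degree sums and internal edge counts maintained in place.

## Hub calling

Lectin hubs are called from the protein-side degree ranking (degree
descending, node ID ascending on ties). The default `degree_gap` rule finds
the largest consecutive drop within the top `tail_window` (default 10)
positions and calls everything above it a hub — a formalization of "the few
nodes separated from the rest by the biggest gap at the top of the degree
distribution". A plain `degree > threshold` rule is also available; on a
network with a clean top gap the two agree. If all inspected degrees are
equal there is no gap and no hub is called (flagged, not an error).

## Enrichment and the random baseline

For community of size `n` (protein nodes only), label carried by `K` of the
network's `N` protein nodes and `k` inside the community, the p-value is the
exact upper hypergeometric tail including `i = k` (scipy's log-space
implementation; verified in tests against exhaustive rational-arithmetic
enumeration for all N ≤ 30 to 1e-12). Conventions, each configurable:

* only communities with ≥ 10 protein nodes are tested;
* significance is p ≤ 0.05, boundary inclusive;
* `N` counts **all** protein nodes by default, including unannotated ones
  (they can contribute to `n` but never to `k`); a switch restricts the urn
  to annotated nodes;
* no multiple-testing correction by default (raw per-test p-values are the
  reported quantity); Benjamini–Hochberg is available behind a flag;
* a protein assayed under several conditions counts once per node.

The baseline permutes all nodes uniformly into communities of the same sizes
as the detected partition (20 iterations by default, seeded) and repeats the
count of significant (community, specificity) groups; the detected partition
should beat the baseline mean by a wide margin when real structure exists.

## Motif scanning

Printed IUPAC-condensed structures are inconsistent: Greek α/β mixed with
Latin a/b, mixed case, "→" vs "-", stray spaces. `normalize_glycan` maps
α→a, β→b, arrows to "-", strips whitespace and lower-cases; it is idempotent
and applied to both structures and motifs, so matching is spelling-invariant.
Spacer suffixes (-Sp0…-Sp25, -Asn, peptide tags) are retained — determinants
are internal substrings, so retention is lossless.

`substring` mode (the default, used for the exact published counts) requires
the normalized motif contiguously. `branch_aware` mode additionally permits
one parenthesis or one full parenthesized branch segment at each residue
junction (digit→letter boundary) of the motif, so "Neu5Aca2-3Gal" matches
"…(Neu5Acα2-3)Galβ1-4Glc…" across the branch boundary and "Galb1-4GlcNAc"
matches "Galβ1-4(6S)GlcNAc" across a substituent. Substring matches are a
subset of branch-aware matches by construction. Full IUPAC tree parsing is
out of scope.

## The synthetic generator

Because the original 786-file CFG collection has no public accession, the
generator emulates its statistical shape so every stage is testable offline:

* 4 communities × 30 lectins × 40 community glycans (defaults); within- and
  cross-community super-cutoff edge probabilities `p_in = 0.3`,
  `p_out = 0.02`;
* 3 hub lectins with near-certain binding everywhere (0.95 home community,
  0.80 elsewhere), giving the degree ranking a large recoverable gap above
  the bulk;
* 360 background-only panel glycans (panel of 520, comparable to a real
  array) that receive only sub-cutoff spots — real panels are far wider than
  any one lectin's binding profile, and without them no parameter choice can
  bring the super-cutoff fraction down to the few percent seen in real
  collections;
* RFUs: log-normal, signal `ln N(ln 12000, 0.6²)` truncated to ≥ cutoff,
  background `ln N(ln 300, 1.0²)` truncated to < cutoff — a long right tail
  with zero leakage across the cutoff, so filtering at the generating cutoff
  recovers exactly the planted edge set;
* `background_fill` (probability a non-signal spot is printed) is solved in
  closed form so the expected super-cutoff fraction of printed rows is 3.5%,
  matching the real collection's headline figure;
* specificity labels: with probability `purity = 0.9` a lectin carries its
  community's dominant label, otherwise a uniform draw from an 8-label
  vocabulary of real specificity strings; community glycan structures embed
  a determinant consistent with the community's label.

Everything is deterministic given the seed, down to byte-identical files.

What the generator does **not** emulate: replicate spot noise and %CV
filtering, cross-reactivity structure between related specificities,
heavy-tailed per-lectin panel coverage, and the long tail of rare lectins.
Passing recovery tests therefore demonstrates correctness of the pipeline's
machinery under clean planted structure, not performance guarantees on real
CFG data, where community signal is weaker and annotation is sparse.

## Numerical and degenerate-input choices

* RFU cutoff is inclusive (keep `rfu ≥ cutoff`); replicate averaging is the
  arithmetic mean.
* Modularity is an error on an edgeless graph (undefined), as is community
  detection.
* Partition community indices are always compressed to a contiguous
  `0..Nc−1` in order of first appearance over sorted node order.
* Degree ranking ties, greedy ΔQ ties and annealing candidate orderings are
  all broken deterministically (sorted IDs / lowest index), so every result
  is reproducible across runs and platforms.
* Hypergeometric arguments are validated (`k ≤ min(K, n)`, `K, n ≤ N`);
  `k = 0` short-circuits to `p = 1`.
* Float comparisons in optimizer loops use a 1e-12 improvement margin to
  avoid cycling on ties.

## Problem sizes in tests and the acceptance script

Tests and the acceptance script run on the default planted conditions
(283-node, ~2100-edge network) — large enough that the degree gap, planted
communities and enrichment signal are unambiguous, and small enough that a
20-seed recovery study completes in a few minutes on one CPU. The recovery
study asserts NMI ≥ 0.9, all 4 dominant labels significant and exact hub
recovery in at least 19 of 20 seeds.
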