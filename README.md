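# elsanet

Time-delayed co-occurrence networks from replicated OTU time series, via
extended Local Similarity Analysis (eLSA), with the community statistics
that surround such an analysis in a host-mediated microbiome selection
experiment.

## Who this is for

Microbial ecologists with a replicated 16S time series — for example, a
serial-passage rhizosphere experiment with several selection treatments
sampled over successive host generations — who want to ask: *which OTU
pairs co-vary (possibly with a lag), how do the resulting association
networks differ between treatments, and do composition-level statistics
(diversity, ordination, PERMANOVA) agree?*  The package also ships a
synthetic-data generator with planted ground truth, so every stage of the
analysis can be validated on data where the right answer is known.

## The method

**Local similarity.** For two equal-length series *X*, *Y* (replicates
averaged per time step, then rank-transformed to normal scores), the local
similarity score is computed by dynamic programming over aligned index
pairs (i, j) with |i − j| ≤ D:

    P⁺[i,j] = max(0, P⁺[i−1,j−1] + xᵢ·yⱼ)
    P⁻[i,j] = max(0, P⁻[i−1,j−1] − xᵢ·yⱼ)

    LS(X,Y) = max over all cells of both tables, divided by n

The maximizing run's offset j − i is the reported **delay** (D = 1 by
default, so associations may lead or trail by one generation); whether the
positive or negative table attains the maximum gives the association's
**sign**.  Because every run keeps a constant offset, the DP is equivalent
to a clipped maximal-subarray scan per delay, which is what the fast
kernel implements — and what an exhaustive alignment oracle verifies in
the tests.

**Significance.** The p-value of a pair is the probability that a random
permutation of one series achieves an LS at least as large as observed:
full n! enumeration for short series, otherwise Monte-Carlo with the
add-one correction p = (k+1)/(n_perm+1).  A conservative upper bound
min(1, p·(2D+1)) across the scanned delays is reported alongside.

**Networks.** Per treatment, the graph G(V, Ɛ) has the shared
abundance-filtered OTU set as nodes (max relative abundance ≥ 1 % in any
sample; isolated nodes retained so densities are comparable) and an edge
for every pair with p ≤ α.  Downstream: degree distributions, greedy or
Louvain modularity Q, the two largest modules with taxon composition,
density 2|Ɛ|/(|V|(|V|−1)), average path length over connected pairs,
total and exclusive edges, and a density scan across α thresholds.

**Community statistics.** Rarefaction to a common depth (multivariate
hypergeometric), Shannon diversity H = −Σ pᵢ ln pᵢ with pairwise Welch
tests, Bray–Curtis distances, classical PCoA, a sequential two-factor
PERMANOVA (generation × treatment, adonis-style), top-k family
aggregation and a max-abundance heatmap filter.

## Worked example

```bash
python examples/03_network_comparison.py
```

prints (abridged):

```
86 OTUs pass the 1 % maximum-abundance filter
         density  average_path_length  total_edges  exclusive_vs_control
high       0.257                2.232          939                 884.0
random     0.133                2.541          486                 464.0
control    0.060                3.347          219                   NaN
modularity[high] = 0.176
modularity[random] = 0.288
modularity[control] = 0.510
```

The synthetic gradient preset plants a community-wide association web
whose strength falls from the high-biomass selection treatment to the
control.  The recovered networks show exactly the expected topology
signature: the high-selection network is the densest, has the shortest
average paths, the most total and exclusive edges, and — being diffusely
interconnected rather than compartmentalized — the lowest modularity,
while the sparse control network fragments into small modules with high Q.
The other examples cover simulation (`01`), single-pair scoring with a
lag (`02`), diversity/ordination/PERMANOVA (`04`) and the end-to-end
pipeline with its checksum manifest (`05`).

A thin CLI mirrors the library: `elsanet simulate|lsa|stats|network|run|report`.

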