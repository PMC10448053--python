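# mareco

Ecological inference for habitat-structured microbiome count tables —
built for sediment-vs-seawater 16S rRNA amplicon studies, usable for any
OTU/ASV table with sample group labels.

Given an OTU count table, sample metadata, and optionally a taxonomy
table, a functional annotation flagging sulfate-reducing bacteria (SRB)
and a rooted phylogeny, `mareco` computes:

* **Diversity** — per-sample richness, Shannon H = −Σ fᵢ ln fᵢ and
  Pielou evenness J = H/ln S; Bray–Curtis dissimilarity with PCoA
  ordination; the ANOSIM permutation test (R with exact enumeration for
  small designs); SES.MNTD phylogenetic clustering against a
  tip-shuffling null.
* **Community assembly** — the Sloan neutral model, which predicts a
  taxon's occupancy from its metacommunity mean abundance p via
  `occ(p) = 1 − BetaCDF(d; N_T·m·p, N_T·m·(1−p))`, fit for the single
  migration parameter m by nonlinear least squares; a 95% Wilson band
  partitions taxa into neutral / above / below, giving a
  stochastic:deterministic ratio; a parameter-free binomial sampling
  model is the AIC comparison baseline (1,000 taxon bootstraps).
* **Core microbiome** — occupancy-then-abundance ranking with a
  cumulative Bray–Curtis-numerator contribution curve and a "last 2%
  relative gain" stopping rule; summaries include the core's share of
  taxa and of sequences and SRB enrichment.
* **Co-occurrence networks** — per habitat, pairwise Spearman
  correlations over taxa passing a 0.01% mean-relative-abundance
  filter; edges require |ρ| > 0.6 and Benjamini–Hochberg q < 0.01;
  global (density, mean degree, clustering, path length, diameter,
  Louvain modularity) and node-level (degree, betweenness, closeness,
  eigenvector) topology, with SRB-vs-other rank-sum comparisons.
* **Robustness** — random removal of SRB nodes vs a size-matched random
  control at proportions 10–100%, 50 repetitions each, scored by
  natural connectivity `ln((1/N) Σ exp(λᵢ))` over the adjacency
  spectrum, the fraction of nodes retaining an edge, and average
  degree, summarised by OLS slopes.

A synthetic-data module generates communities with each structure the
pipeline assumes (neutral assembly with known m; latent-factor block
correlation with labeled hub "SRB" taxa; pure-birth trees with optional
clustered clades), so everything is testable without sequence data.

## Worked example

Simulate a structured community, build its network, and run the
keystone-removal experiment:

```
$ mareco simulate structured --out sim --seed 3 --n-samples 60
wrote structured simulation to sim

$ mareco network --otu sim/otu_table.tsv --metadata sim/metadata.tsv \
    --annotations sim/annotations.tsv --out net
community: 46 nodes, 95 edges

$ mareco robustness --network net/community_network.graphml \
    --annotations sim/annotations.tsv --reps 50 --out rob
{"other": {"slope": -0.4887..., ...}, "srb": {"slope": -1.6020..., ...}}
```

The network has 46 nodes (taxa passing the prevalence filter) and 95
significant co-occurrence edges. In the removal experiment the natural
connectivity falls about 3× faster per unit removal proportion when
the SRB hub taxa are deleted (`srb` slope) than under the size-matched
random control (`other` slope) — the hub set carries a disproportionate
share of the network's spectral redundancy.

The full pipeline runs from one INI config:

```
mareco run-all --config analysis.ini --seed 42 --out results/
```

writing rarefied tables, diversity summaries, neutral-model fits, core
selections, GraphML networks with topology tables, robustness
trajectories, and a manifest capturing parameters, child seeds and
input checksums.

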