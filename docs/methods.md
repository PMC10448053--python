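# Methods

This note documents the models, conventions and numerical choices
behind `mareco`, the assumptions each stage makes, and what the
synthetic-data generators do and do not emulate.

## Input model and normalisation

The universal input is an integer OTU count matrix (taxa × samples)
with a habitat label per sample. Rarefaction subsamples each sample to
a common depth without replacement (multivariate hypergeometric per
sample), the standard way to remove depth as a confounder before
occupancy- and rank-based analyses; samples below the target depth are
dropped with a warning, and taxa left with all-zero rows are removed so
that no downstream stage sees occupancy-zero taxa. The default depth
is the *lower* median of per-sample totals: the lower of the two middle
values is always an attainable integer read count, whereas the mean of
the middles may be fractional.

The prevalence filter ahead of network construction keeps taxa whose
relative-abundance share strictly exceeds a threshold (default 0.01%).
"Share" is the mean per-sample fraction by default (`filter.mode =
mean`), which is scale-free in the number of samples; the literal sum
of per-sample fractions is available as `mode = sum`, since both
readings circulate in the literature. The filter is applied after
rarefaction, within each habitat.

## Diversity

Shannon diversity uses the natural log (the ecology-package
convention); Pielou evenness J = H/ln S is flagged undefined for S ≤ 1.
Bray–Curtis, PCoA and ANOSIM operate on the rarefied counts.
PCoA is classical scaling; negative eigenvalues of non-Euclidean
distance matrices are reported as-is (no Cailliez/Lingoes correction),
since downstream use is visual ordination only. ANOSIM uses
R = (r̄_between − r̄_within)/(M/2) over the M = n(n−1)/2 ranked
distances; the p-value enumerates all distinct label arrangements when
there are at most 10,000 of them and otherwise uses 999 seeded
permutations with the +1 correction.

SES.MNTD measures phylogenetic clustering per sample: observed mean
nearest-taxon distance against a null that shuffles tip labels across
the whole tree ("taxa-labels" null, 999 draws by default), so a null
draw assigns the sample's taxa to a uniformly random tip subset of the
same size. MNTD is presence/absence-based (abundance weighting off, as
the weighting choice is a configuration, not a default). Null moments
are cached per sample richness, since the null depends only on the
number of taxa present. A community occupying every tip (null SD 0) is
flagged undefined.

Wilcoxon rank-sum comparisons are two-sided throughout, exact when the
pooled sample holds at most 20 untied observations, tie-corrected
normal approximation otherwise; a pooled sample of identical values
returns p = 1.

## Neutral assembly model

The Sloan model treats a local community of size N_T connected to a
metacommunity by migration rate m: a taxon at metacommunity abundance p
has local relative abundance f ~ Beta(N_T·m·p, N_T·m·(1−p)), and its
expected occupancy is P(f > d) for detection limit d. We estimate m by
bounded nonlinear least squares of observed against predicted occupancy
(m ∈ [1e−6, 1e3], optimised on log m from starts {0.01, 0.1, 1} to
avoid local minima), with N_T equal to the read-equivalent depth (the
reciprocal of the smallest nonzero fraction; exactly the rarefaction
depth on rarefied data).

**Detection limit.** Detection in count data is soft: a taxon at
latent fraction f appears in a sample of N reads with probability
1 − (1−f)^N, which crosses ½ at f = 1 − 2^(−1/N) ≈ ln2/N. The default
detection limit is therefore d = ln2 × (smallest observed nonzero
fraction), which makes the sharp-threshold occupancy curve an unbiased
surrogate for the soft detection process; simulate-and-refit
calibration against the generator below gives median relative error of
m̂ of a few percent across m ∈ {0.05, 0.1, 0.5}, versus an upward bias
of 25–40% under the raw minimum-fraction convention
(`detection_mode = "min_observed"`, also available).

The 95% band around the fitted curve is the Wilson score interval with
n = number of samples. Taxa above the band are deterministically
over-represented, below it under-represented; the
stochastic:deterministic ratio is (#taxa inside)/(#taxa outside) — the
phrase has no universal formula, and this count ratio is recorded in
output metadata. The comparison model is parameter-free binomial
detection of the source community, occupancy = 1 − BinomCDF(⌈N_T·d⌉−1;
N_T, p). Both models are scored by Gaussian-residual AIC,
n·ln(SS/n) + 2k with k = 1 (neutral) and k = 0 (binomial) — the
likelihood behind the published AIC comparison is unstated, so the
functional form is recorded in output metadata; lower AIC is better,
and both values are always surfaced rather than a verdict. Bootstrap
AICs resample taxa with replacement (1,000 replicates by default);
more than 10% failed refits aborts.

## Core microbiome

Taxa are ranked by occupancy descending, ties by mean relative
abundance, remaining ties lexicographically (determinism). The
contribution curve c_r is the share of the Bray–Curtis *numerator*
carried by the top-r taxa, averaged over sample pairs, with the
denominator fixed at the full-community numerator — this makes c_r
nondecreasing with c_last = 1, which a ratio-of-BC definition would
not guarantee. The core is the shortest prefix after which the
relative gain (c_{r+1} − c_r)/c_r stays below 2% (configurable), the
"last 2% increase" rule of the abundance-occupancy core method. Core
summaries report the core's share of taxa (exact rational arithmetic
before rounding), the per-sample mean share of sequences (the
"average across samples" reading), and SRB counts in and out of the
core.

## Co-occurrence networks

Within one habitat, pairwise Spearman correlations (average ranks, t
approximation for p) are computed on rarefied counts — rank-equivalent
to relative abundances at equal depth. Benjamini–Hochberg correction
spans all C(K,2) tested pairs of that habitat's filtered taxa. An edge
requires |ρ| > 0.6 and q < 0.01, both strict. Zero-variance taxa are
dropped with a warning. Isolated nodes (taxa passing the filter with
no significant edge) stay in the node set with an `isolated` flag, and
node counts with and without them are reported, since published node
counts rarely state the convention.

Topology conventions (all recorded in output metadata): clustering
coefficient is the mean of local coefficients with degree-<2 nodes
contributing 0; average path length and diameter are over connected
pairs only; modularity uses seeded Louvain (greedy agglomerative
available); betweenness is unnormalised pair counts; closeness uses
the Wasserman–Faust component-size correction; eigenvector centrality
is the principal eigenvector of the largest component's adjacency,
max-normalised, 0 elsewhere. Edge sign is kept as an attribute but all
metrics treat the graph as unweighted and unsigned.

## Robustness

Natural connectivity λ̄ = ln((1/N) Σ exp(λ_i)) over the adjacency
eigenvalues is a spectral measure of closed-walk redundancy that is
monotone non-increasing under edge deletion at fixed node set. It is
computed with a log-sum-exp (no overflow for large hubs) over *all*
kept nodes including isolated ones, which preserves the monotonicity
property; restriction to the largest component is a config option.
The empty graph scores 0 by convention.

The removal experiment deletes round(f·|SRB|) nodes (half away from
zero; all of them at f = 1) at each proportion f ∈ {0.1, …, 1.0},
either from the SRB set or — the control — the same count from the
non-SRB pool, 50 repetitions each. "Proportion of remaining nodes"
counts kept nodes that retain at least one edge, over the original
node count: with fixed removal counts this is the only reading under
which the quantity varies between schemes. Each (scheme, proportion,
repetition) cell derives its own child seed from the master seed, so
any slice of the experiment reproduces independently. Trajectories are
summarised by per-scheme OLS slopes of natural connectivity against
proportion and per-proportion means ± SD.

## Synthetic data

The generators produce the exact statistical structures the analyses
assume, so every stage is testable without sequence data. All are
bit-reproducible under a fixed seed.

*Neutral communities*: log-normal source abundances (σ = 2, a typical
amplicon rank-abundance spread), independent Beta(N·m·p, N·m·(1−p))
draws per sample renormalised across taxa, multinomial reads at fixed
depth. This is the stationary approximation the Sloan fit assumes — a
fair round-trip test for m recovery — not a forward Moran/Hubbell
simulation; it has no time dynamics, no selection, and samples are
exchangeable. Reference conditions for the recovery study: 500 taxa,
200 samples, depth 2,000.

*Structured communities*: a latent Gaussian factor copula. Block
members load √ρ_block on their block factor (within-block latent
correlation exactly ρ_block, default 0.9); hub taxa — the labeled
"SRB" keystone set — load 0.92 on a home factor cycled over the first
two blocks and the residual √(1−0.92²) on a random secondary block.
This puts hubs inside the densest clusters (latent correlation
0.92·√ρ_block ≈ 0.87 to home-block members and 0.85 to co-resident
hubs) with a weak cross-block bridge; with the 0.6/0.01 edge
thresholds and count noise at depth 1,000 over ~46 taxa, that is the
regime in which hubs reliably acquire above-median degree. A design
with hubs spreading equal loadings over many blocks cannot work under
these thresholds: members spend √0.9 of their unit variance on their
own factor, capping any external node's latent correlation to a member
at 0.9/√(#blocks), below the edge threshold for two or more blocks
once sampling attenuation (~0.1 on Spearman ρ at ~20 reads/taxon) is
accounted for. Latent z-scores map through log-normal marginals
(per-taxon base abundance σ = 0.5, per-sample spread σ = 1) to
multinomial reads; Spearman inference sees the latent rank structure
attenuated only by count noise. Ground-truth edges are pairs with
latent |correlation| ≥ ρ_block — the within-block pairs. ρ_block = 0
yields a fully unstructured community (hub loadings included), the
null for false-discovery tests. The factor construction is positive
semidefinite by design; no eigenvalue clipping ever occurs silently.

*Trees*: pure-birth (Yule) trees with exponential waiting times; an
optional tip subset is grafted as a shallow subtree (depth 0.05 by
default) in place of one backbone tip, guaranteeing monophyly — the
known-clustered community for SES.MNTD tests.

What the generators do **not** emulate: compositional coupling beyond
the simplex constraint, overdispersion from PCR/sequencing bias,
chimeras, taxa absent from the reference tree, spatial or temporal
autocorrelation between samples, and genuinely sparse ecological
interaction graphs. Passing tests therefore demonstrate correctness of
the inference machinery under its own assumptions, not robustness of
the biological conclusions to violations of those assumptions.

## Problem sizes and defaults

Test-suite and acceptance-script experiments use the generator
defaults above (46–48 taxa, 100–200 samples, depths 1,000–2,000;
migration-recovery study at 500 taxa × 200 samples × depth 2,000 over
m ∈ {0.05, 0.1, 0.5}); the pipeline itself has no size limits beyond
memory. The exhaustive natural-connectivity validation covers every
labeled graph on up to 6 nodes, all non-isomorphic 7-node graphs, and
seeded random 8-node graphs, against an independent
matrix-exponential-trace oracle at 1e−10.

## Known limitations

Spearman co-occurrence on compositional data is not a causal or even
compositional-aware association measure (no SparCC/SPIEC-EASI here, by
scope); the neutral fit assumes independent taxa and one detection
limit for all; the robustness score measures resistance, not
resilience; Louvain modularity is seed-dependent across seeds (fixed
seed ⇒ fixed partition); BIOM input is not supported — convert to TSV
upstream.
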