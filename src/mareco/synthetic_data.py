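"""Synthetic OTU tables, trees and annotations for end-to-end testing.

Three generators cover the statistical structure the pipeline assumes:

* :func:`simulate_neutral_table` draws communities from the stationary
  approximation of the neutral assembly model (independent Beta
  marginals around a shared source community, then multinomial read
  sampling), so migration-rate recovery by the fitting routine is a fair
  round trip.
* :func:`simulate_structured_table` builds a latent Gaussian factor
  copula with block correlation plus designated hub ("SRB") taxa that
  load on several blocks, mapped through log-normal marginals to read
  counts; it returns the ground-truth edge set implied by the latent
  correlations.
* :func:`simulate_tree` grows a pure-birth phylogeny, optionally forcing
  a named subset of tips into a single shallow clade (a known
  phylogenetically clustered group).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import OtuTable


@dataclass
class NeutralSimSpec:
    """Parameters of the neutral-assembly community generator.

    ``migration`` is the Sloan immigration parameter m; ``reads_per_sample``
    doubles as the local community size N_T.  Source-community abundances
    are log-normal with spread ``source_sigma``, normalised to sum to 1.
    """

    n_taxa: int = 500
    n_samples: int = 200
    reads_per_sample: int = 2000
    migration: float = 0.1
    source_sigma: float = 2.0
    group: str = "community"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.migration <= 0:
            raise ValueError("migration rate m must be > 0")
        if self.n_taxa < 2 or self.n_samples < 1 or self.reads_per_sample < 1:
            raise ValueError("invalid community dimensions")


@dataclass
class StructuredSimSpec:
    """Parameters of the block/hub correlated community generator.

    Regular taxa form ``n_blocks`` blocks whose members share a latent
    factor (within-block latent correlation ``rho_block``).  Hub taxa —
    the designated "SRB" keystone set — load strongly (``hub_home_load``)
    on a home factor cycled over the first ``n_home_blocks`` blocks and
    weakly on one random secondary block, so they sit inside the densest
    clusters, acquire above-median degree, and bridge blocks.  Noise
    taxa are uncorrelated.
    """

    n_blocks: int = 6
    block_size: int = 5
    n_hubs: int = 6
    n_home_blocks: int = 2
    hub_home_load: float = 0.92
    rho_block: float = 0.9
    n_samples: int = 100
    reads_per_sample: int = 1000
    n_noise_taxa: int = 10
    marginal_sigma: float = 1.0
    base_sigma: float = 0.5
    group: str = "community"
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho_block) < 1:
            raise ValueError("|rho_block| must be < 1")
        if not 0 <= self.hub_home_load <= 1:
            raise ValueError("hub_home_load must be in [0, 1]")
        if self.n_home_blocks > self.n_blocks:
            raise ValueError("n_home_blocks cannot exceed n_blocks")

    @property
    def n_taxa(self) -> int:
        return self.n_blocks * self.block_size + self.n_hubs + self.n_noise_taxa


@dataclass
class TreeSimSpec:
    """Parameters of the pure-birth tree generator."""

    n_tips: int = 32
    clustered_tips: list[str] = field(default_factory=list)
    cluster_depth: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("a tree needs at least 2 tips")
        if len(self.clustered_tips) > self.n_tips:
            raise ValueError("clustered subset larger than the tree")


# ---------------------------------------------------------------------------
# neutral communities
# ---------------------------------------------------------------------------


def source_abundances(n_taxa: int, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Log-normal source-community relative abundances, summing to 1."""
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    return raw / raw.sum()


def simulate_neutral_table(spec: NeutralSimSpec) -> OtuTable:
    """Draw an OTU table from the stationary neutral-assembly model.

    For taxon i with source abundance p_i, each sample's local relative
    abundance is Beta(N*m*p_i, N*m*(1-p_i)) — the stationary distribution
    under immigration-limited drift — renormalised across taxa, then
    reads are drawn multinomially at the sample depth.
    """
    rng = np.random.default_rng(spec.seed)
    p = source_abundances(spec.n_taxa, spec.source_sigma, rng)
    nm = spec.reads_per_sample * spec.migration
    a = nm * p
    b = nm * (1.0 - p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("Beta shape parameters must be positive; "
                         "check m, depth and source abundances")
    counts = np.empty((spec.n_taxa, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        local = rng.beta(a, b)
        local = local / local.sum()
        counts[:, j] = rng.multinomial(spec.reads_per_sample, local)
    taxa = [f"OTU{i + 1:05d}" for i in range(spec.n_taxa)]
    samples = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    groups = pd.Series(spec.group, index=samples)
    return OtuTable(pd.DataFrame(counts, index=taxa, columns=samples), groups)


# ---------------------------------------------------------------------------
# block/hub structured communities
# ---------------------------------------------------------------------------


def _structured_loadings(spec: StructuredSimSpec,
                         rng: np.random.Generator) -> tuple[np.ndarray, list[list[int]]]:
    """Factor-loading matrix (taxa x blocks) of the latent Gaussian model.

    Block members load sqrt(rho_block) on their own factor.  Hub taxa
    load ``hub_home_load`` on a home factor (cycled over the first
    ``n_home_blocks`` blocks) and put their remaining unit variance on a
    random secondary block, giving them latent correlation
    ``hub_home_load * sqrt(rho_block)`` with every home-block member and
    ``hub_home_load**2`` with hubs sharing the home.  A factor
    construction is positive semidefinite by design.
    """
    n = spec.n_taxa
    load = np.zeros((n, spec.n_blocks))
    if spec.rho_block == 0:  # fully null community: no latent structure
        return load, []
    root = np.sqrt(abs(spec.rho_block))
    for b in range(spec.n_blocks):
        lo = b * spec.block_size
        load[lo:lo + spec.block_size, b] = root
    hub_rows = range(spec.n_blocks * spec.block_size,
                     spec.n_blocks * spec.block_size + spec.n_hubs)
    hub_blocks: list[list[int]] = []
    for idx, h in enumerate(hub_rows):
        home = idx % max(spec.n_home_blocks, 1)
        load[h, home] = spec.hub_home_load
        others = [b for b in range(spec.n_blocks) if b != home]
        blocks = [home]
        if others and spec.hub_home_load < 1:
            sec = int(rng.choice(others))
            load[h, sec] = np.sqrt(1.0 - spec.hub_home_load ** 2)
            blocks.append(sec)
        hub_blocks.append(blocks)
    return load, hub_blocks


def latent_correlation(spec: StructuredSimSpec,
                       rng: np.random.Generator | None = None,
                       loadings: np.ndarray | None = None) -> np.ndarray:
    """Exact latent correlation matrix implied by the factor model."""
    if loadings is None:
        rng = np.random.default_rng(spec.seed) if rng is None else rng
        loadings, _ = _structured_loadings(spec, rng)
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("latent correlation matrix is not positive "
                         "semidefinite; reduce loadings")
    return corr


def simulate_structured_table(spec: StructuredSimSpec) -> tuple[OtuTable, set[frozenset[str]]]:
    """Simulate a community with known co-occurrence block/hub structure.

    Returns the OTU table and the ground-truth edge set: unordered taxon
    pairs whose latent correlation is at least ``rho_block`` (i.e. the
    within-block pairs; hub-member links sit below that threshold unless
    ``blocks_per_hub == 1``).
    """
    rng = np.random.default_rng(spec.seed)
    loadings, _ = _structured_loadings(spec, rng)
    corr = latent_correlation(spec, loadings=loadings)
    n = spec.n_taxa
    taxa = [f"OTU{i + 1:05d}" for i in range(n)]

    resid = np.sqrt(np.clip(1.0 - (loadings ** 2).sum(axis=1), 0.0, None))
    factors = rng.standard_normal((spec.n_blocks, spec.n_samples))
    eps = rng.standard_normal((n, spec.n_samples))
    z = loadings @ factors + resid[:, None] * eps

    base = rng.lognormal(mean=0.0, sigma=spec.base_sigma, size=n)
    weights = base[:, None] * np.exp(spec.marginal_sigma * z)
    weights = weights / weights.sum(axis=0)
    counts = np.empty((n, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        counts[:, j] = rng.multinomial(spec.reads_per_sample, weights[:, j])

    truth: set[frozenset[str]] = set()
    if spec.rho_block != 0:
        thresh = abs(spec.rho_block) - 1e-9
        ii, jj = np.triu_indices(n, k=1)
        for i, j in zip(ii, jj):
            if abs(corr[i, j]) >= thresh:
                truth.add(frozenset((taxa[i], taxa[j])))

    samples = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    groups = pd.Series(spec.group, index=samples)
    table = OtuTable(pd.DataFrame(counts, index=taxa, columns=samples), groups)
    return table, truth


def hub_taxon_ids(spec: StructuredSimSpec) -> list[str]:
    """Taxon ids of the designated hub ("SRB") set of a structured spec."""
    start = spec.n_blocks * spec.block_size
    return [f"OTU{i + 1:05d}" for i in range(start, start + spec.n_hubs)]


def hub_annotations(spec: StructuredSimSpec) -> pd.Series:
    """Boolean SRB flags marking the hub taxa of a structured simulation."""
    taxa = [f"OTU{i + 1:05d}" for i in range(spec.n_taxa)]
    hubs = set(hub_taxon_ids(spec))
    return pd.Series([t in hubs for t in taxa], index=taxa)


def two_habitat_study(seed: int = 0,
                      sediment: StructuredSimSpec | None = None,
                      seawater: StructuredSimSpec | None = None
                      ) -> tuple[OtuTable, pd.Series, TreeNode,
                                 dict[str, set[frozenset[str]]]]:
    """A paired sediment/seawater synthetic study over one taxon pool.

    Both habitats draw from structured communities over the same taxon
    ids but with independent seeds (hence different base-abundance
    profiles and factor realisations), so compositions separate by
    habitat while the taxon pool is shared.  Seawater defaults to a
    denser community (more hubs) than sediment.  Returns the combined
    table, SRB annotations (hub taxa), a phylogeny over the pool with
    each block forced monophyletic, and per-habitat ground-truth edges.
    """
    ss = np.random.SeedSequence(seed)
    s_sed, s_sea, s_tree = [int(x.generate_state(1)[0] % (2 ** 31))
                            for x in ss.spawn(3)]
    if sediment is None:
        sediment = StructuredSimSpec(group="sediment", seed=s_sed,
                                     n_hubs=4, n_noise_taxa=14,
                                     n_home_blocks=2)
    if seawater is None:
        seawater = StructuredSimSpec(group="seawater", seed=s_sea,
                                     n_hubs=8, n_noise_taxa=10,
                                     n_home_blocks=2)
    if sediment.n_taxa != seawater.n_taxa:
        raise ValueError("habitat specs must share one taxon pool size")
    tab_sed, truth_sed = simulate_structured_table(sediment)
    tab_sea, truth_sea = simulate_structured_table(seawater)
    counts = pd.concat([
        tab_sed.counts.rename(columns=lambda s: f"sed_{s}"),
        tab_sea.counts.rename(columns=lambda s: f"sea_{s}"),
    ], axis=1)
    groups = pd.Series(
        ["sediment"] * tab_sed.n_samples + ["seawater"] * tab_sea.n_samples,
        index=counts.columns)
    table = OtuTable(counts, groups)
    annotations = hub_annotations(seawater) | hub_annotations(sediment)
    taxa = list(counts.index)
    block_tips = taxa[: sediment.n_blocks * sediment.block_size
                      ][: sediment.block_size]
    tree = simulate_tree(TreeSimSpec(n_tips=len(taxa),
                                     clustered_tips=block_tips,
                                     seed=s_tree))
    return table, annotations, tree, {"sediment": truth_sed,
                                      "seawater": truth_sea}


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _pure_birth(labels: list[str], rng: np.random.Generator,
                rate: float = 1.0) -> TreeNode:
    """Yule process: split a uniformly chosen tip until all labels placed."""
    root = TreeNode(name=None)
    a, b = TreeNode(length=0.0), TreeNode(length=0.0)
    root.extend([a, b])
    tips = [a, b]
    while len(tips) < len(labels):
        dt = rng.exponential(1.0 / (rate * len(tips)))
        for t in tips:
            t.length += dt
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        c1, c2 = TreeNode(length=0.0), TreeNode(length=0.0)
        parent.extend([c1, c2])
        tips.extend([c1, c2])
    dt = rng.exponential(1.0 / (rate * len(tips)))
    for t in tips:
        t.length += dt
    order = rng.permutation(len(labels))
    for tip, k in zip(tips, order):
        tip.name = labels[k]
    return root


def simulate_tree(spec: TreeSimSpec) -> TreeNode:
    """Pure-birth tree; an optional tip subset is forced monophyletic.

    Clustered tips are grafted as a shallow pure-birth subtree (total
    depth ``cluster_depth``) in place of a single tip of the backbone
    tree, guaranteeing monophyly and short internal distances.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [f"OTU{i + 1:05d}" for i in range(spec.n_tips)]
    cluster = [t for t in spec.clustered_tips]
    unknown = set(cluster) - set(labels)
    if unknown:
        labels = labels[: spec.n_tips - len(cluster)] + cluster
    if not cluster or len(cluster) < 2:
        return _pure_birth(labels, rng)

    backbone = [t for t in labels if t not in set(cluster)]
    placeholder = "__cluster__"
    tree = _pure_birth(backbone + [placeholder], rng)
    sub = _pure_birth(cluster, rng, rate=1.0 / spec.cluster_depth)
    # scale the subtree so its root-to-tip depth equals cluster_depth
    depths = [sub.distance(t) for t in sub.tips()]
    scale = spec.cluster_depth / max(depths) if max(depths) > 0 else 1.0
    for node in sub.traverse(include_self=False):
        node.length = (node.length or 0.0) * scale
    target = next(t for t in tree.tips() if t.name == placeholder)
    sub.length = max((target.length or 0.0) - spec.cluster_depth, 1e-6)
    parent = target.parent
    parent.remove(target)
    parent.append(sub)
    return tree
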