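"""Co-occurrence network inference and topology.

Edges are pairwise Spearman correlations between OTUs across the samples
of one habitat, kept when |rho| exceeds a threshold (0.6) and the
Benjamini-Hochberg-adjusted p-value stays below another (0.01).  The
resulting simple undirected graph carries rho/p/q/sign per edge and
SRB/phylum attributes per node; topology is computed unweighted and
unsigned.  Global metrics follow the conventions recorded in the result
metadata: clustering coefficient = mean of local coefficients (degree<2
counts 0), average path length and diameter over connected pairs only,
modularity via seeded Louvain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import diversity
from .tables_io import OtuTable, ValidationError, lineage_rank

RHO_MIN_DEFAULT = 0.6
Q_MAX_DEFAULT = 0.01


def spearman_matrix(table: OtuTable,
                    taxa: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and raw p over taxa, across samples.

    Uses average ranks (tie-corrected) and the t-distribution
    approximation for p.  Zero-variance taxa are dropped with a warning
    (their correlations are undefined).
    """
    if taxa is None:
        taxa = table.taxon_ids
    if table.n_samples < 4:
        raise ValidationError("need >= 4 samples for Spearman correlations")
    x = table.counts.loc[taxa].to_numpy(dtype=float)
    variable = x.std(axis=1) > 0
    if not variable.all():
        dropped = [t for t, v in zip(taxa, variable) if not v]
        warnings.warn(f"dropping {len(dropped)} zero-variance taxa from "
                      "correlation analysis", stacklevel=2)
        taxa = [t for t, v in zip(taxa, variable) if v]
        x = x[variable]
    if len(taxa) < 2:
        raise ValidationError("fewer than 2 variable taxa")
    rho, p = stats.spearmanr(x, axis=1)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-variable case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    return (pd.DataFrame(rho, index=taxa, columns=taxa),
            pd.DataFrame(p, index=taxa, columns=taxa))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def build_network(rho: pd.DataFrame, q: pd.DataFrame,
                  rho_min: float = RHO_MIN_DEFAULT,
                  q_max: float = Q_MAX_DEFAULT,
                  annotations: pd.Series | None = None,
                  taxonomy: pd.Series | None = None,
                  p: pd.DataFrame | None = None) -> nx.Graph:
    """Threshold correlation matrices into a simple undirected graph.

    All filtered taxa become nodes (isolated ones keep an
    ``isolated=True`` flag); an edge requires |rho| > rho_min and
    q < q_max strictly.
    """
    taxa = list(rho.index)
    g = nx.Graph(rho_min=rho_min, q_max=q_max)
    for t in taxa:
        phylum = None
        if taxonomy is not None and t in taxonomy.index:
            phylum = lineage_rank(taxonomy[t], 1)
        g.add_node(t,
                   is_srb=bool(annotations.get(t, False))
                   if annotations is not None else False,
                   phylum=phylum)
    r = rho.to_numpy()
    qv = q.to_numpy()
    pv = p.to_numpy() if p is not None else None
    ii, jj = np.triu_indices(len(taxa), k=1)
    for i, j in zip(ii, jj):
        if abs(r[i, j]) > rho_min and qv[i, j] < q_max:
            attrs = {"rho": float(r[i, j]), "q": float(qv[i, j]),
                     "sign": 1 if r[i, j] > 0 else -1}
            if pv is not None:
                attrs["p"] = float(pv[i, j])
            g.add_edge(taxa[i], taxa[j], **attrs)
    for t in taxa:
        g.nodes[t]["isolated"] = g.degree(t) == 0
    return g


def infer_network(table: OtuTable, taxa: list[str],
                  rho_min: float = RHO_MIN_DEFAULT,
                  q_max: float = Q_MAX_DEFAULT,
                  annotations: pd.Series | None = None,
                  taxonomy: pd.Series | None = None) -> nx.Graph:
    """spearman_matrix + BH adjustment + thresholding in one call.

    BH correction spans all C(K,2) tested pairs of the filtered taxa.
    """
    rho, p = spearman_matrix(table, taxa)
    k = len(rho)
    iu = np.triu_indices(k, k=1)
    q_flat = bh_adjust(p.to_numpy()[iu])
    q = np.ones((k, k))
    q[iu] = q_flat
    q.T[iu] = q_flat
    qdf = pd.DataFrame(q, index=rho.index, columns=rho.columns)
    return build_network(rho, qdf, rho_min, q_max, annotations, taxonomy, p=p)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclass
class GlobalTopology:
    n_nodes: int
    n_edges: int
    n_isolated: int
    density: float
    mean_degree: float
    clustering_coefficient: float
    average_path_length: float
    diameter: float
    modularity: float
    n_modules: int
    modules: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("modules")
        return d


def global_topology(g: nx.Graph, seed: int = 0,
                    method: str = "louvain") -> GlobalTopology:
    """Whole-network metrics; path metrics average over connected pairs."""
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        return GlobalTopology(0, 0, 0, float("nan"), float("nan"),
                              float("nan"), float("nan"), float("nan"),
                              float("nan"), 0)
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_degree = 2 * e / n
    cc = float(np.mean(list(nx.clustering(g).values())))

    total, pairs, diam = 0.0, 0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.shortest_path_length(sub):
            for dd in dists.values():
                if dd > 0:
                    total += dd
                    pairs += 1
                    diam = max(diam, dd)
    apl = total / pairs if pairs else float("nan")

    if e == 0:
        q_mod, communities = float("nan"), [set([v]) for v in g.nodes]
    elif method == "louvain":
        communities = nx.community.louvain_communities(g, seed=seed)
        q_mod = nx.community.modularity(g, communities)
    elif method == "greedy":
        communities = list(nx.community.greedy_modularity_communities(g))
        q_mod = nx.community.modularity(g, communities)
    else:
        raise ValueError(f"unknown modularity method {method!r}")
    modules = {v: i for i, comm in enumerate(communities) for v in comm}
    n_isolated = sum(1 for v in g.nodes if g.degree(v) == 0)
    return GlobalTopology(
        n_nodes=n, n_edges=e, n_isolated=n_isolated, density=density,
        mean_degree=mean_degree, clustering_coefficient=cc,
        average_path_length=apl, diameter=float(diam) if pairs else float("nan"),
        modularity=q_mod, n_modules=len(communities), modules=modules)


def node_topology(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness, eigenvector centrality per node.

    Betweenness is unnormalized pair counts; closeness uses the
    Wasserman-Faust component-size correction; eigenvector centrality is
    computed on the largest connected component and max-normalized to 1
    (0 elsewhere).  Edge weights/signs are ignored.
    """
    nodes = list(g.nodes)
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=True)
    eig = {v: 0.0 for v in nodes}
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if comps and len(comps[0]) > 1:
        giant_nodes = sorted(comps[0], key=str)
        a = nx.to_numpy_array(g.subgraph(giant_nodes), nodelist=giant_nodes,
                              weight=None)
        w, vecs = np.linalg.eigh(a)
        principal = np.abs(vecs[:, np.argmax(w)])
        principal /= principal.max()
        for v, x in zip(giant_nodes, principal):
            eig[v] = float(x)
    return pd.DataFrame({
        "degree": pd.Series(deg, dtype=int),
        "betweenness": pd.Series(btw),
        "closeness": pd.Series(clo),
        "eigenvector": pd.Series(eig),
        "is_srb": pd.Series({v: g.nodes[v].get("is_srb", False)
                             for v in nodes}),
    }).loc[nodes]


def compare_srb_topology(node_table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided rank-sum tests of SRB vs other nodes per metric."""
    srb = node_table[node_table["is_srb"]]
    other = node_table[~node_table["is_srb"]]
    if len(srb) == 0 or len(other) == 0:
        raise ValidationError("need at least one SRB and one non-SRB node")
    rows = {}
    for metric in ("degree", "betweenness", "closeness", "eigenvector"):
        stat, p = diversity.wilcoxon_rank_sum(srb[metric].to_numpy(),
                                              other[metric].to_numpy())
        rows[metric] = {
            "statistic": stat, "p_value": p,
            "median_srb": float(srb[metric].median()),
            "median_other": float(other[metric].median()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [{"source": u, "target": v,
             "rho": d.get("rho"), "p": d.get("p"), "q": d.get("q"),
             "sign": d.get("sign")}
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q",
                                       "sign"])


def write_graphml(g: nx.Graph, path) -> None:
    clean = g.copy()
    for _, d in clean.nodes(data=True):
        for k, v in list(d.items()):
            if v is None:
                d[k] = ""
    nx.write_graphml(clean, path)
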