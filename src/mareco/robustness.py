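"""Node-removal robustness of co-occurrence networks.

Stability is scored by natural connectivity — the log-mean of the
exponentiated adjacency eigenvalues, a spectral measure of redundancy of
closed walks that decreases monotonically as edges are lost.  The
removal experiment mirrors a keystone-taxon knockout: at each proportion
f of the SRB set, either f of the SRB nodes ("srb" scheme) or an equal
number of non-SRB nodes ("other" scheme, the size-matched control) are
deleted uniformly at random, 50 times per proportion, and natural
connectivity, the fraction of original nodes still connected, and the
average degree of the kept subgraph are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import diversity
from .tables_io import ValidationError

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
SCHEMES = ("srb", "other")


@dataclass
class RemovalScheme:
    """Configuration of one removal experiment arm."""

    scheme: str = "srb"
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    repetitions: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(not 0 < f <= 1 for f in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")


def natural_connectivity(g: nx.Graph, scope: str = "all") -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    ``scope="all"`` (default) uses every node including isolated ones;
    ``scope="giant"`` restricts to the largest connected component.
    The empty graph scores 0 by convention.  Computed with a
    log-sum-exp so large eigenvalues cannot overflow.
    """
    if scope == "giant" and g.number_of_nodes():
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        g = g.subgraph(comps[0])
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    a = nx.to_numpy_array(g, weight=None)
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def remove_nodes(g: nx.Graph, scheme: RemovalScheme,
                 srb_nodes: list[str] | set[str],
                 scope: str = "all") -> pd.DataFrame:
    """Run one removal arm; returns long-format trajectory records.

    The removal count at proportion f is round(f * |SRB|) (half away
    from zero) for both schemes, drawn from the SRB pool ("srb") or the
    non-SRB pool ("other").  Metrics are computed on the induced
    subgraph of all kept nodes; ``remaining_fraction`` counts kept nodes
    that still have at least one edge, relative to the original node
    count.  Each (scheme, proportion, repetition) cell derives its own
    child seed from the master seed, so any subset of the experiment is
    independently reproducible.
    """
    nodes = set(g.nodes)
    srb = sorted(set(srb_nodes) & nodes)
    other_pool = sorted(nodes - set(srb))
    if not srb:
        raise ValidationError("removal experiment needs >= 1 SRB node "
                              "in the network")
    n_original = g.number_of_nodes()
    scheme_idx = SCHEMES.index(scheme.scheme)
    records = []
    for pi, f in enumerate(scheme.proportions):
        k = _round_half_away(f * len(srb))
        pool = srb if scheme.scheme == "srb" else other_pool
        if k > len(pool):
            raise ValidationError(
                f"cannot remove {k} nodes from a pool of {len(pool)} "
                f"({scheme.scheme!r} scheme, proportion {f})")
        for rep in range(scheme.repetitions):
            ss = np.random.SeedSequence(
                entropy=scheme.seed, spawn_key=(scheme_idx, pi, rep))
            rng = np.random.default_rng(ss)
            removed = set(rng.choice(pool, size=k, replace=False)) if k else set()
            kept = g.subgraph(nodes - removed)
            n_kept = kept.number_of_nodes()
            e_kept = kept.number_of_edges()
            connected = sum(1 for v in kept.nodes if kept.degree(v) > 0)
            records.append({
                "scheme": scheme.scheme,
                "proportion": float(f),
                "repetition": rep,
                "natural_connectivity": natural_connectivity(kept, scope),
                "remaining_fraction": connected / n_original,
                "average_degree": 2 * e_kept / n_kept if n_kept else 0.0,
            })
    return pd.DataFrame.from_records(records)


def robustness_experiment(g: nx.Graph, srb_nodes,
                          proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
                          repetitions: int = 50, seed: int = 0,
                          scope: str = "all") -> pd.DataFrame:
    """Both arms (SRB-targeted and size-matched random control)."""
    frames = [
        remove_nodes(g, RemovalScheme(scheme=s, proportions=proportions,
                                      repetitions=repetitions, seed=seed),
                     srb_nodes, scope=scope)
        for s in SCHEMES
    ]
    return pd.concat(frames, ignore_index=True)


def summarize_trajectory(traj: pd.DataFrame) -> dict:
    """Per-scheme OLS slope of natural connectivity vs removal proportion,
    plus per-(scheme, proportion) means and SDs for plotting."""
    if traj["proportion"].nunique() < 2:
        raise ValidationError("need >= 2 proportions to fit a slope")
    slopes = {}
    for scheme, sub in traj.groupby("scheme"):
        slope, intercept, r, p = diversity.ols_fit(
            sub["proportion"].to_numpy(),
            sub["natural_connectivity"].to_numpy())
        slopes[scheme] = {"slope": slope, "intercept": intercept,
                          "r": r, "p_value": p}
    means = (traj.groupby(["scheme", "proportion"])
             [["natural_connectivity", "remaining_fraction", "average_degree"]]
             .agg(["mean", "std"]))
    return {"slopes": slopes, "per_proportion": means}
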