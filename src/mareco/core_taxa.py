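"""Abundance-occupancy core-microbiome selection.

Taxa are ranked by occupancy (ties broken by mean relative abundance,
then lexicographically by id), and the cumulative contribution of the
top-r taxa to beta diversity is measured as the share of the Bray-Curtis
numerator they carry, averaged over all sample pairs with the full-
community numerator held fixed in the denominator (which makes the curve
monotone).  The core is the shortest prefix after which the relative
gain in explained beta diversity stays below a threshold (2% by
default — the "last 2% increase" stopping rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import (OtuTable, RelativeAbundanceView, ValidationError,
                        exact_percent, to_relative)


@dataclass
class CoreSelection:
    """Ranked taxa, contribution curve, stopping rank and summary."""

    ranked: list[str]
    curve: np.ndarray          # c_r for r = 1..n_taxa, nondecreasing
    stop_rank: int
    core: list[str]
    summary: dict

    def table(self, view: RelativeAbundanceView) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.ranked) + 1),
            "taxon_id": self.ranked,
            "occupancy": view.occupancy.loc[self.ranked].to_numpy(),
            "mean_abundance": view.mean_abundance.loc[self.ranked].to_numpy(),
            "contribution": self.curve,
            "in_core": [t in set(self.core) for t in self.ranked],
        })


def rank_by_occupancy(view: RelativeAbundanceView) -> list[str]:
    """Occupancy-descending order; ties by mean abundance, then by id."""
    df = pd.DataFrame({"occ": view.occupancy, "abund": view.mean_abundance})
    # stable sort of a lexicographically pre-sorted index resolves final ties
    df = df.loc[sorted(df.index)].sort_values(
        ["occ", "abund"], ascending=[False, False], kind="mergesort")
    return list(df.index)


def contribution_curve(table: OtuTable, ranked: list[str]) -> np.ndarray:
    """Cumulative share of the Bray-Curtis numerator carried by top-r taxa.

    c_r = mean over sample pairs (j,k) of
    sum_{i<=r} |x_ij - x_ik| / sum_all_i |x_ij - x_ik|.
    Identical-sample pairs (zero denominator) are skipped with a warning.
    """
    if set(ranked) != set(table.taxon_ids):
        raise ValidationError("ranked list must cover exactly the table taxa")
    x = table.counts.loc[ranked].to_numpy(dtype=float)
    n = x.shape[1]
    shares = []
    skipped = 0
    for j in range(n):
        for k in range(j + 1, n):
            diff = np.abs(x[:, j] - x[:, k])
            total = diff.sum()
            if total == 0:
                skipped += 1
                continue
            shares.append(np.cumsum(diff) / total)
    if skipped:
        warnings.warn(f"contribution_curve: skipped {skipped} identical "
                      "sample pair(s)", stacklevel=2)
    if not shares:
        raise ValidationError("all sample pairs are identical")
    return np.mean(shares, axis=0)


def select_core(curve: np.ndarray, threshold: float = 0.02) -> int:
    """Smallest rank after which every relative gain stays below threshold.

    The relative gain at rank r is (c_{r+1} - c_r) / c_r; the stopping
    rank is one past the last rank with gain >= threshold (rank 1 if the
    curve never gains that much).
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 2:
        return len(curve)
    prev, nxt = curve[:-1], curve[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = np.where(prev > 0, (nxt - prev) / prev,
                         np.where(nxt > prev, np.inf, 0.0))
    qualifying = np.nonzero(gains >= threshold)[0]
    if len(qualifying) == 0:
        return 1
    return int(qualifying[-1]) + 2  # gain at index i links rank i+1 -> i+2


def summarize_core(core: list[str], table: OtuTable,
                   annotations: pd.Series | None = None) -> dict:
    """Core share of taxa, of sequences, and SRB enrichment.

    The taxon fraction uses exact rational arithmetic before rounding;
    the sequence fraction is the per-sample mean of the core read share,
    in percent.
    """
    core_set = set(core)
    unknown = core_set - set(table.taxon_ids)
    if unknown:
        raise ValidationError(f"core taxa not in table: {sorted(unknown)[:3]}")
    n_taxa = table.n_taxa
    counts = table.counts
    core_mask = counts.index.isin(core_set)
    per_sample_share = (counts.loc[core_mask].sum(axis=0)
                        / counts.sum(axis=0))
    out = {
        "n_core": len(core_set),
        "n_taxa": n_taxa,
        "core_fraction_of_taxa_pct": exact_percent(len(core_set), n_taxa),
        "core_fraction_of_sequences_pct": round(
            float(per_sample_share.mean()) * 100, 2),
    }
    if annotations is not None:
        srb_all = [t for t in table.taxon_ids if annotations.get(t, False)]
        srb_core = [t for t in core if annotations.get(t, False)]
        out.update({
            "srb_in_core": len(srb_core),
            "srb_total": len(srb_all),
            "srb_share_core_pct": exact_percent(len(srb_core), len(core_set))
            if core_set else 0.0,
            "srb_share_overall_pct": exact_percent(len(srb_all), n_taxa),
        })
    return out


def core_selection(table: OtuTable, annotations: pd.Series | None = None,
                   threshold: float = 0.02) -> CoreSelection:
    """Full abundance-occupancy core workflow on one habitat's table."""
    view = to_relative(table)
    ranked = rank_by_occupancy(view)
    curve = contribution_curve(table, ranked)
    r_star = select_core(curve, threshold)
    core = ranked[:r_star]
    return CoreSelection(ranked=ranked, curve=curve, stop_rank=r_star,
                         core=core,
                         summary=summarize_core(core, table, annotations))
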