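"""Input/output, validation, rarefaction and abundance filtering of OTU tables.

The central container is :class:`OtuTable`, an integer count matrix
(taxa x samples) paired with a habitat label per sample.  All downstream
modules consume either an ``OtuTable`` or the derived
:class:`RelativeAbundanceView` (per-sample fractions, per-taxon mean
abundance and occupancy).

File formats are deliberately plain: tab-separated tables with a header
row (taxa as rows, samples as columns), two-column TSVs for metadata /
taxonomy / functional annotation, and Newick for trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class TableParseError(ValueError):
    """Raised when a file cannot be parsed into the expected table shape."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Integer OTU count matrix (taxa x samples) with sample habitat labels.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample id.
        Entries must be finite non-negative integers.
    sample_group
        Series mapping every sample id to a habitat/group label
        (e.g. ``"sediment"`` / ``"seawater"``).
    """

    counts: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate taxon id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValidationError("counts must be finite")
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        missing = [s for s in cols if s not in self.sample_group.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        self.sample_group = self.sample_group.reindex(cols)

    # -- basic accessors ----------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_group:
            seen.setdefault(g, None)
        return list(seen)

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        return OtuTable(self.counts[list(sample_ids)].copy(),
                        self.sample_group.loc[list(sample_ids)].copy())

    def subset_taxa(self, taxon_ids: list[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(taxon_ids)].copy(),
                        self.sample_group.copy())

    def per_group(self):
        """Yield ``(group_label, OtuTable)`` pairs, one per habitat."""
        for g in self.groups:
            ids = [s for s in self.sample_ids if self.sample_group[s] == g]
            yield g, self.subset_samples(ids)

    def drop_empty_taxa(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(self.counts.loc[keep].copy(), self.sample_group.copy())


@dataclass
class RelativeAbundanceView:
    """Per-sample relative abundances with per-taxon summaries.

    ``fractions`` columns each sum to 1; ``mean_abundance`` is the mean of
    the per-sample fractions of a taxon (its metacommunity abundance
    estimate p_i); ``occupancy`` is the fraction of samples where the
    taxon was detected (count > 0).
    """

    fractions: pd.DataFrame
    mean_abundance: pd.Series
    occupancy: pd.Series

    @property
    def n_samples(self) -> int:
        return self.fractions.shape[1]

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fractions.index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_otu_table(path: str | Path, metadata_path: str | Path,
                   format: str = "tsv") -> OtuTable:
    """Read an OTU count table plus sample metadata.

    The table is a TSV with the taxon id in the first column and one
    column per sample; metadata is a two-column TSV (sample_id, group).
    """
    if format != "tsv":
        raise NotImplementedError(
            "only the TSV table format is supported; convert BIOM input "
            "upstream (e.g. 'biom convert --to-tsv')")
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"cannot parse {path}: {exc}") from exc
    for col in counts.columns:
        bad = pd.to_numeric(counts[col], errors="coerce")
        if bad.isna().any():
            row = counts.index[bad.isna().to_numpy().nonzero()[0][0]]
            raise TableParseError(
                f"non-numeric cell at row {row!r}, column {col!r}")
    counts.index.name = None
    counts.columns.name = None
    meta = read_sample_metadata(metadata_path)
    return OtuTable(counts, meta)


def read_sample_metadata(path: str | Path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
    return meta.iloc[:, 0].astype(str)


def write_otu_table(table: OtuTable, path: str | Path,
                    metadata_path: str | Path | None = None) -> None:
    table.counts.to_csv(path, sep="\t", index_label="taxon_id")
    if metadata_path is not None:
        table.sample_group.rename("group").to_csv(
            metadata_path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> pd.Series:
    """Two-column TSV (taxon_id, lineage); lineage ranks joined by '; '."""
    tax = pd.read_csv(path, sep="\t", index_col=0)
    if tax.index.has_duplicates:
        dup = tax.index[tax.index.duplicated()][0]
        raise ValidationError(f"duplicate taxon id in taxonomy: {dup!r}")
    return tax.iloc[:, 0].astype(str)


def lineage_rank(lineage: str, level: int) -> str | None:
    """Extract one rank (0 = domain) from a '; '-separated lineage string."""
    parts = [p.strip() for p in lineage.split(";")]
    if level < len(parts) and parts[level]:
        return parts[level]
    return None


def read_annotations(path: str | Path) -> pd.Series:
    """Two-column TSV (taxon_id, 0/1 flag) marking SRB taxa.

    Taxa absent from the file are implicitly non-SRB; callers use
    ``annotations.get(taxon, False)`` semantics via :func:`is_srb`.
    """
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValidationError(f"duplicate taxon id in annotations: {dup!r}")
    return ann.iloc[:, 0].astype(int).astype(bool)


def write_annotations(annotations: pd.Series, path: str | Path) -> None:
    annotations.astype(int).rename("is_srb").to_csv(
        path, sep="\t", index_label="taxon_id")


def is_srb(annotations: pd.Series | None, taxon: str) -> bool:
    if annotations is None:
        return False
    return bool(annotations.get(taxon, False))


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError("tree has a negative branch length")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# rarefaction and normalisation
# ---------------------------------------------------------------------------


def median_depth(table: OtuTable) -> int:
    """Lower median of per-sample read totals.

    For an even number of samples the lower of the two middle values is
    used so that the result is always an attainable integer depth.
    """
    if table.n_samples == 0:
        raise ValidationError("empty table has no median depth")
    sums = np.sort(table.counts.sum(axis=0).to_numpy())
    return int(sums[(len(sums) - 1) // 2])


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a
    warning); taxa left with all-zero rows are dropped.  Sampling is
    multivariate hypergeometric per sample, so the output is always a
    sub-multiset of the input reads.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not keep:
        raise ValidationError(
            f"no samples retained: every sample has < {depth} reads")
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) with < {depth} "
            f"reads: {dropped}", stacklevel=2)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if totals[s] == depth:
            out[s] = col.copy()
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    sub = pd.DataFrame(out, index=table.counts.index)
    sub = sub.loc[sub.sum(axis=1) > 0]
    return OtuTable(sub, table.sample_group.loc[keep].copy())


def to_relative(table: OtuTable) -> RelativeAbundanceView:
    """Convert counts to per-sample fractions plus per-taxon summaries."""
    totals = table.counts.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise ValidationError(
            f"all-zero sample(s) {list(empty.index)}; rarefy or drop them "
            "before computing relative abundances")
    fractions = table.counts / totals
    return RelativeAbundanceView(
        fractions=fractions,
        mean_abundance=fractions.mean(axis=1),
        occupancy=(table.counts > 0).mean(axis=1),
    )


def abundance_filter(view: RelativeAbundanceView, threshold: float,
                     mode: str = "mean") -> list[str]:
    """Taxa whose relative-abundance share strictly exceeds ``threshold``.

    ``mode="mean"`` compares the mean per-sample fraction (scale-free in
    the number of samples); ``mode="sum"`` compares the raw sum of
    per-sample fractions.  The default prevalence cut used for network
    construction is ``threshold=1e-4`` (0.01%) in ``mean`` mode.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if mode == "mean":
        share = view.mean_abundance
    elif mode == "sum":
        share = view.fractions.sum(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return [t for t in view.taxon_ids if share[t] > threshold]


def exact_percent(numerator: int, denominator: int, digits: int = 2) -> float:
    """Percentage via exact rational arithmetic, rounded to ``digits``."""
    frac = Fraction(numerator, denominator) * 100
    return round(float(frac), digits)
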