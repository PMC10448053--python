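"""Alpha/beta diversity, phylogenetic clustering and comparison statistics.

Covers per-sample richness / Shannon / Pielou evenness, Bray-Curtis
distances with PCoA ordination, the ANOSIM permutation test (with exact
enumeration for small designs), SES.MNTD phylogenetic clustering against
a tip-label-shuffling null, and the two scalar statistics used to compare
groups throughout the pipeline (two-sided Wilcoxon rank-sum, OLS fit).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .tables_io import OtuTable, ValidationError

# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def richness(counts: np.ndarray) -> int:
    """Number of taxa with count > 0."""
    counts = np.asarray(counts)
    return int((counts > 0).sum())


def shannon(counts: np.ndarray, base: float = math.e) -> float:
    """Shannon-Wiener diversity H = -sum f ln f (natural log by default)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValidationError("Shannon diversity of an all-zero sample")
    f = counts / counts.sum()
    f = f[f > 0]
    h = float(-(f * np.log(f)).sum())
    if base != math.e:
        h /= math.log(base)
    return h


def pielou_evenness(counts: np.ndarray) -> float:
    """J = H / ln S; NaN when S <= 1 (evenness undefined)."""
    s = richness(counts)
    if s <= 1:
        return float("nan")
    return shannon(counts) / math.log(s)


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon H and Pielou J, with the group label."""
    rows = {}
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        rows[s] = {
            "richness": richness(col),
            "shannon": shannon(col),
            "evenness": pielou_evenness(col),
            "group": table.sample_group[s],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity D = sum|x-y| / sum(x+y) between samples."""
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs >= 2 samples")
    x = table.counts.to_numpy(dtype=float).T
    if (x.sum(axis=1) == 0).any():
        raise ValidationError("Bray-Curtis undefined for an all-zero sample")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame       # samples x axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are reported as-is,
    not corrected.  If ``k`` exceeds the embedding rank the result is
    truncated with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigvals
        res = _skbio_pcoa(dm, method="eigh", inplace=False)
    eig = res.eigvals.to_numpy()
    rank = int((eig > 1e-10).sum())
    if k > rank:
        warnings.warn(f"requested {k} axes but rank is {rank}; truncating",
                      stacklevel=2)
        k = rank
    coords = res.samples.iloc[:, :k]
    coords.index = list(dm.ids)
    return PcoaResult(coordinates=coords, eigenvalues=eig,
                      proportion_explained=res.proportion_explained.to_numpy())


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return (r_between - r_within) / (m / 2.0)


def _n_arrangements(group_sizes: list[int]) -> int:
    n = sum(group_sizes)
    total = math.factorial(n)
    for g in group_sizes:
        total //= math.factorial(g)
    return total


def _distinct_labelings(labels: np.ndarray):
    """Yield all distinct permutations of a label vector (multiset perms)."""
    n = len(labels)
    uniq = sorted(set(labels))
    def rec(remaining_idx: list[int], remaining_labels: list):
        if not remaining_labels:
            yield {}
            return
        lab = remaining_labels[0]
        count = sum(1 for l in labels if l == lab)
        for combo in itertools.combinations(remaining_idx, count):
            rest = [i for i in remaining_idx if i not in set(combo)]
            for assignment in rec(rest, remaining_labels[1:]):
                out = dict(assignment)
                for i in combo:
                    out[i] = lab
                yield out
    for assignment in rec(list(range(n)), uniq):
        yield np.array([assignment[i] for i in range(n)])


def anosim(dm: DistanceMatrix, groups: pd.Series | dict | list,
           n_perm: int = 999, seed: int = 0,
           exact_limit: int = 10000) -> tuple[float, float]:
    """ANOSIM R and permutation p-value for grouped samples.

    R = (mean between-group rank - mean within-group rank) / (M/2) over
    the M = n(n-1)/2 ranked pairwise distances.  The p-value enumerates
    all distinct label arrangements when there are at most
    ``exact_limit`` of them, otherwise uses ``n_perm`` seeded random
    permutations with the +1 correction.
    """
    ids = list(dm.ids)
    if isinstance(groups, (pd.Series, dict)):
        labels = np.array([groups[i] for i in ids])
    else:
        labels = np.asarray(groups)
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2:
        raise ValidationError("ANOSIM needs >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError("every ANOSIM group needs >= 2 samples")

    cond = squareform(dm.data, checks=False)
    ranks = stats.rankdata(cond)
    n = len(ids)
    iu = np.triu_indices(n, k=1)

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(ranks, within_mask(labels))

    if _n_arrangements(sizes.tolist()) <= exact_limit:
        stats_null = np.array([_anosim_r(ranks, within_mask(lab))
                               for lab in _distinct_labelings(labels)])
        p = float((stats_null >= r_obs - 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _anosim_r(ranks, within_mask(perm)) >= r_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# SES.MNTD
# ---------------------------------------------------------------------------


@dataclass
class SesMntdResult:
    """Per-sample observed MNTD, null mean/SD and SES z-score."""

    table: pd.DataFrame  # columns: mntd_obs, null_mean, null_sd, ses, defined
    n_null: int


def _mntd(dist: np.ndarray, present: np.ndarray) -> float:
    sub = dist[np.ix_(present, present)].astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def ses_mntd(table: OtuTable, tree: TreeNode, n_null: int = 999,
             seed: int = 0) -> SesMntdResult:
    """Standardised effect size of mean nearest-taxon distance per sample.

    The null model shuffles tip labels across the whole tree (the
    "taxa.labels" null): each null draw assigns the sample's taxa to a
    uniformly random tip subset of the same size.  Negative SES values
    mean the community is phylogenetically clustered.  Presence/absence
    only (unweighted MNTD).
    """
    tip_names = [t.name for t in tree.tips()]
    missing = set(table.taxon_ids) - set(tip_names)
    if missing:
        raise ValidationError(
            f"{len(missing)} community taxa are not tips of the tree, "
            f"e.g. {sorted(missing)[:3]}")
    dm = tree.tip_tip_distances()
    order = {name: i for i, name in enumerate(dm.ids)}
    dist = dm.data
    n_tips = len(dm.ids)
    taxon_idx = np.array([order[t] for t in table.taxon_ids])

    rng = np.random.default_rng(seed)
    rows = {}
    null_cache: dict[int, tuple[float, float]] = {}
    for s in table.sample_ids:
        present = taxon_idx[(table.counts[s] > 0).to_numpy()]
        if len(present) < 2:
            rows[s] = dict(mntd_obs=np.nan, null_mean=np.nan,
                           null_sd=np.nan, ses=np.nan, defined=False)
            continue
        obs = _mntd(dist, present)
        k = len(present)
        if k not in null_cache:
            null = np.array([
                _mntd(dist, rng.choice(n_tips, size=k, replace=False))
                for _ in range(n_null)])
            null_cache[k] = (float(null.mean()), float(null.std(ddof=1)))
        mu, sd = null_cache[k]
        if sd <= 1e-12 * max(1.0, abs(mu)):  # degenerate null (e.g. all tips)
            rows[s] = dict(mntd_obs=obs, null_mean=mu, null_sd=0.0,
                           ses=np.nan, defined=False)
        else:
            rows[s] = dict(mntd_obs=obs, null_mean=mu, null_sd=sd,
                           ses=(obs - mu) / sd, defined=True)
    return SesMntdResult(pd.DataFrame.from_dict(rows, orient="index"),
                         n_null=n_null)


# ---------------------------------------------------------------------------
# scalar comparisons
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples together hold at most 20
    observations and there are no ties; otherwise the tie-corrected
    normal approximation.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x, y) -> tuple[float, float, float, float]:
    """Least-squares line fit: (slope, intercept, Pearson r, slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("OLS needs >= 3 points")
    if np.var(x) == 0:
        raise ValidationError("OLS needs var(x) > 0")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))
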