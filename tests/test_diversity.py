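import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from mareco import diversity
from mareco.diversity import (alpha_diversity_table, anosim, bray_curtis,
                              ols_fit, pcoa, pielou_evenness, richness,
                              ses_mntd, shannon, wilcoxon_rank_sum)
from mareco.synthetic_data import (NeutralSimSpec, TreeSimSpec,
                                   simulate_neutral_table, simulate_tree)
from mareco.tables_io import OtuTable, ValidationError


class TestAlpha:
    @pytest.mark.parametrize("counts, expected", [
        ([25, 25, 25, 25], math.log(4)),
        ([10, 0, 0], 0.0),
        ([1, 2, 3, 4], -sum(f * math.log(f) for f in (0.1, 0.2, 0.3, 0.4))),
    ])
    def test_shannon_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_empty(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    def test_evenness_and_richness(self):
        assert pielou_evenness([7, 7, 7]) == pytest.approx(1.0)
        assert pielou_evenness([9, 1]) < pielou_evenness([5, 5])
        assert richness([3, 0, 7]) == 2
        assert math.isnan(pielou_evenness([5, 0, 0]))

    def test_shannon_bounded_by_log_richness(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=12)
            if counts.sum() == 0 or richness(counts) == 0:
                continue
            assert shannon(counts) <= math.log(max(richness(counts), 1)) + 1e-12

    def test_alpha_table_carries_groups(self, small_table):
        tab = alpha_diversity_table(small_table)
        assert list(tab.columns) == ["richness", "shannon", "evenness",
                                     "group"]
        assert tab.loc["s1", "group"] == "sediment"


class TestBrayCurtis:
    def test_hand_example(self):
        t = OtuTable(pd.DataFrame({"j": [2, 2], "k": [1, 3]},
                                  index=["a", "b"]),
                     pd.Series({"j": "g", "k": "g"}))
        assert bray_curtis(t)["j", "k"] == pytest.approx(0.25)

    def test_identical_and_disjoint(self):
        t = OtuTable(pd.DataFrame({"a": [3, 0], "b": [3, 0], "c": [0, 5]},
                                  index=["x", "y"]),
                     pd.Series({"a": "g", "b": "g", "c": "g"}))
        dm = bray_curtis(t)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_bounds_symmetry_on_random_tables(self, neutral_table):
        dm = bray_curtis(neutral_table)
        d = dm.data
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1


class TestPcoa:
    def test_recovers_collinear_points(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(5)])
        res = pcoa(dm, k=1)
        emb = res.coordinates.to_numpy()
        _, _, disparity = procrustes(x[:, None], emb)
        assert disparity < 1e-8

    def test_equilateral_triangle_has_equal_eigenvalues(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")), k=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_duplicated_sample_coincides(self):
        pts = np.array([[0.0], [0.0], [3.0]])
        d = np.abs(pts - pts.T)
        res = pcoa(DistanceMatrix(d, ids=list("abc")), k=1)
        c = res.coordinates.to_numpy()
        assert c[0, 0] == pytest.approx(c[1, 0], abs=1e-10)

    def test_k_beyond_rank_truncates_with_warning(self):
        d = np.array([[0, 2], [2, 0]], dtype=float)
        with pytest.warns(UserWarning, match="rank"):
            res = pcoa(DistanceMatrix(d, ids=list("ab")), k=5)
        assert res.coordinates.shape[1] == 1

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(6)]), k=3)
        emb = res.coordinates.to_numpy()
        d2 = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-8)


class TestAnosim:
    def _separated(self):
        # two tight clusters far apart: all between > all within
        d = np.array([
            [0.0, 0.1, 0.9, 1.0],
            [0.1, 0.0, 0.8, 0.95],
            [0.9, 0.8, 0.0, 0.05],
            [1.0, 0.95, 0.05, 0.0]])
        return DistanceMatrix(d, ids=list("abcd"))

    def test_perfect_separation_gives_r_one(self):
        r, p = anosim(self._separated(), {"a": "g1", "b": "g1",
                                          "c": "g2", "d": "g2"})
        assert r == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_exact_enumeration_matches_brute_force(self):
        dm = self._separated()
        labels = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        r_obs, p = anosim(dm, labels)
        # independent brute force over all 4!/(2!2!) = 6 labelings
        from scipy.spatial.distance import squareform
        from scipy.stats import rankdata
        ranks = rankdata(squareform(dm.data, checks=False))
        ids = list(dm.ids)
        stats_all = []
        for combo in itertools.combinations(range(4), 2):
            lab = np.array(["g2"] * 4)
            for i in combo:
                lab[i] = "g1"
            iu = np.triu_indices(4, 1)
            within = lab[iu[0]] == lab[iu[1]]
            m = len(ranks)
            stats_all.append((ranks[~within].mean() - ranks[within].mean())
                             / (m / 2))
        expect_p = np.mean([s >= r_obs - 1e-12 for s in stats_all])
        assert p == pytest.approx(expect_p)

    def test_null_distance_matrix_gives_small_r(self, rng):
        n = 16
        pts = rng.normal(size=(n, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
        labels = {str(i): ("g1" if i < 8 else "g2") for i in range(n)}
        r, p = anosim(dm, labels, n_perm=199, seed=1)
        assert abs(r) < 0.25
        assert p > 0.05

    def test_matches_skbio_r_statistic(self, rng):
        n = 12
        pts = rng.normal(size=(n, 4))
        pts[:6] += 1.5
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [str(i) for i in range(n)]
        dm = DistanceMatrix(d, ids=ids)
        grouping = ["g1"] * 6 + ["g2"] * 6
        r, _ = anosim(dm, dict(zip(ids, grouping)), n_perm=99, seed=0)
        ref = skbio_anosim(dm, grouping=grouping, permutations=0)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValidationError):
            anosim(self._separated(), {"a": "g1", "b": "g2", "c": "g2",
                                       "d": "g2"})


class TestSesMntd:
    def test_saturated_community_flagged_undefined(self):
        tree = simulate_tree(TreeSimSpec(n_tips=6, seed=0))
        taxa = sorted(t.name for t in tree.tips())
        counts = pd.DataFrame({"s1": [1] * 6}, index=taxa)
        table = OtuTable(counts, pd.Series({"s1": "g"}))
        res = ses_mntd(table, tree, n_null=49, seed=0)
        assert not res.table.loc["s1", "defined"]

    def test_clustered_community_negative_ses(self):
        cluster = [f"OTU{i + 1:05d}" for i in range(5)]
        tree = simulate_tree(TreeSimSpec(n_tips=40, clustered_tips=cluster,
                                         cluster_depth=0.02, seed=3))
        counts = pd.DataFrame({f"s{j}": [1 if t in cluster else 0
                                         for t in sorted(x.name for x in
                                                         tree.tips())]
                               for j in range(3)},
                              index=sorted(x.name for x in tree.tips()))
        table = OtuTable(counts.loc[(counts.sum(axis=1) > 0)],
                         pd.Series({f"s{j}": "g" for j in range(3)}))
        hits = 0
        for seed in range(10):
            res = ses_mntd(table, tree, n_null=199, seed=seed)
            hits += (res.table["ses"] < 0).all()
        assert hits >= 9

    def test_sample_with_one_taxon_flagged(self):
        tree = simulate_tree(TreeSimSpec(n_tips=5, seed=1))
        taxa = sorted(t.name for t in tree.tips())
        counts = pd.DataFrame({"s1": [3, 0, 0, 0, 0]}, index=taxa)
        table = OtuTable(counts, pd.Series({"s1": "g"}))
        res = ses_mntd(table, tree, n_null=19, seed=0)
        assert not res.table.loc["s1", "defined"]

    def test_random_communities_center_near_zero(self):
        tree = simulate_tree(TreeSimSpec(n_tips=30, seed=4))
        taxa = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(8)
        cols = {f"s{j}": (rng.random(30) < 0.4).astype(int)
                for j in range(50)}
        counts = pd.DataFrame(cols, index=taxa)
        counts = counts.loc[:, counts.sum(axis=0) >= 2]
        table = OtuTable(counts,
                         pd.Series({c: "g" for c in counts.columns}))
        res = ses_mntd(table, tree, n_null=199, seed=5)
        assert abs(res.table["ses"].mean()) < 0.3


class TestScalarStats:
    def test_wilcoxon_exact_small_sample(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert stat in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_wilcoxon_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_wilcoxon_p_decreases_with_shift(self, rng):
        x = rng.normal(size=30)
        ps = [wilcoxon_rank_sum(x, x + shift)[1]
              for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_ols_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r, p = ols_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_ols_null_r_small(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        _, _, r, p = ols_fit(x, y)
        assert abs(r) < 0.1
        assert p > 0.01

    def test_ols_duplicated_points_same_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 4.0, 8.0])
        s1 = ols_fit(x, y)[0]
        s2 = ols_fit(np.tile(x, 2), np.tile(y, 2))[0]
        assert s1 == pytest.approx(s2)

    def test_ols_degenerate_x_rejected(self):
        with pytest.raises(ValidationError):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
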