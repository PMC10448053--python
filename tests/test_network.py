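import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mareco.network import (bh_adjust, build_network, compare_srb_topology,
                            global_topology, infer_network, node_topology,
                            spearman_matrix, edge_table, write_graphml)
from mareco.tables_io import OtuTable, ValidationError


def _table(rows: dict) -> OtuTable:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return OtuTable(df, pd.Series({c: "g" for c in df.columns}))


class TestSpearman:
    def test_monotone_pair_has_rho_one(self):
        x = np.array([1, 2, 3, 4, 5])
        t = _table({"a": x, "b": x ** 3})
        rho, _ = spearman_matrix(t)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_textbook_formula_without_ties(self):
        a = np.array([3, 1, 4, 9, 7])
        b = np.array([5, 2, 6, 8, 1])
        t = _table({"a": a, "b": b})
        rho, _ = spearman_matrix(t)
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        d2 = ((ra - rb) ** 2).sum()
        expect = 1 - 6 * d2 / (5 * (25 - 1))
        assert rho.loc["a", "b"] == pytest.approx(expect)

    def test_zero_variance_taxon_dropped(self):
        t = _table({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2],
                    "c": [4, 3, 2, 1]})
        with pytest.warns(UserWarning, match="zero-variance"):
            rho, _ = spearman_matrix(t)
        assert list(rho.index) == ["a", "c"]

    def test_needs_four_samples(self):
        t = _table({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValidationError):
            spearman_matrix(t)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]),
                                   [0.3, 0.3, 0.3])

    def test_q_at_least_p_and_rank_monotone(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestBuildNetwork:
    def _frames(self, rho, q, taxa):
        return (pd.DataFrame(rho, index=taxa, columns=taxa),
                pd.DataFrame(q, index=taxa, columns=taxa))

    def test_all_insignificant_gives_no_edges(self):
        taxa = list("abc")
        rho, q = self._frames(np.full((3, 3), 0.9), np.ones((3, 3)), taxa)
        g = build_network(rho, q)
        assert g.number_of_edges() == 0
        assert all(g.nodes[t]["isolated"] for t in taxa)

    def test_strong_triangle(self):
        taxa = list("abc")
        rho, q = self._frames(np.full((3, 3), 0.9),
                              np.full((3, 3), 0.001), taxa)
        g = build_network(rho, q)
        assert g.number_of_edges() == 3
        assert g.edges["a", "b"]["sign"] == 1

    def test_thresholds_are_strict(self):
        taxa = list("ab")
        rho, q = self._frames(np.array([[1, 0.6], [0.6, 1]]),
                              np.array([[0, 0.001], [0.001, 0]]), taxa)
        assert build_network(rho, q).number_of_edges() == 0

    def test_relabeling_preserves_edge_count(self, structured_sim):
        _, table, _, ann, _ = structured_sim
        g1 = infer_network(table, table.taxon_ids, annotations=ann)
        renamed = OtuTable(
            table.counts.rename(index=lambda t: "X" + t),
            table.sample_group)
        g2 = infer_network(renamed, renamed.taxon_ids)
        assert g1.number_of_edges() == g2.number_of_edges()


class TestGlobalTopology:
    def test_complete_graph(self):
        topo = global_topology(nx.complete_graph(5))
        assert topo.density == pytest.approx(1.0)
        assert topo.mean_degree == pytest.approx(4.0)
        assert topo.clustering_coefficient == pytest.approx(1.0)
        assert topo.average_path_length == pytest.approx(1.0)
        assert topo.diameter == 1

    def test_path_graph_shortest_paths(self):
        topo = global_topology(nx.path_graph(4))
        assert topo.average_path_length == pytest.approx(5 / 3)
        assert topo.diameter == 3

    def test_two_triangles_modularity_matches_brute_force(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        topo = global_topology(g, seed=0)
        # exhaustive search over all partitions of 6 nodes
        def partitions(nodes):
            if not nodes:
                yield []
                return
            head, *rest = nodes
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [part[i] | {head}] + part[i + 1:]
                yield part + [{head}]
        best = max(nx.community.modularity(g, p)
                   for p in partitions(list(g.nodes)))
        assert topo.modularity == pytest.approx(best, abs=1e-12)

    def test_seeded_louvain_reproducible(self, structured_sim):
        _, table, _, ann, _ = structured_sim
        g = infer_network(table, table.taxon_ids, annotations=ann)
        t1 = global_topology(g, seed=5)
        t2 = global_topology(g, seed=5)
        assert t1.modules == t2.modules
        assert t1.modularity == t2.modularity

    def test_empty_graph_flagged(self):
        topo = global_topology(nx.Graph())
        assert topo.n_nodes == 0 and np.isnan(topo.density)


class TestNodeTopology:
    def test_star_betweenness(self):
        g = nx.star_graph(3)  # center 0, leaves 1-3
        nt = node_topology(g)
        assert nt.loc[0, "betweenness"] == pytest.approx(3.0)
        assert (nt.loc[1:, "betweenness"] == 0).all()

    def test_cycle_symmetry(self):
        nt = node_topology(nx.cycle_graph(4))
        assert (nt["degree"] == 2).all()
        for col in ("betweenness", "closeness", "eigenvector"):
            assert nt[col].max() - nt[col].min() < 1e-9

    def test_complete_graph_eigenvector_all_one(self):
        nt = node_topology(nx.complete_graph(6))
        np.testing.assert_allclose(nt["eigenvector"], 1.0, atol=1e-9)

    def test_isolated_node_zeroed(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        nt = node_topology(g)
        assert nt.loc["c", "closeness"] == 0.0
        assert nt.loc["c", "eigenvector"] == 0.0


class TestSrbComparison:
    def test_hub_srb_have_higher_degree(self, structured_sim):
        _, table, _, ann, _ = structured_sim
        g = infer_network(table, table.taxon_ids, annotations=ann)
        nt = node_topology(g)
        comp = compare_srb_topology(nt)
        assert comp.loc["degree", "median_srb"] > \
            comp.loc["degree", "median_other"]

    def test_all_false_annotations_rejected(self):
        nt = pd.DataFrame({"degree": [1, 2], "betweenness": [0, 0],
                           "closeness": [0.5, 0.5],
                           "eigenvector": [1, 1],
                           "is_srb": [False, False]})
        with pytest.raises(ValidationError):
            compare_srb_topology(nt)

    def test_identical_values_give_p_one(self):
        nt = pd.DataFrame({"degree": [2, 2, 2, 2],
                           "betweenness": [0.0] * 4,
                           "closeness": [0.5] * 4,
                           "eigenvector": [1.0] * 4,
                           "is_srb": [True, True, False, False]})
        comp = compare_srb_topology(nt)
        assert (comp["p_value"] == 1.0).all()


def test_exports_round_trip(tmp_path, structured_sim):
    _, table, _, ann, _ = structured_sim
    g = infer_network(table, table.taxon_ids, annotations=ann)
    et = edge_table(g)
    assert len(et) == g.number_of_edges()
    assert set(et.columns) == {"source", "target", "rho", "p", "q", "sign"}
    path = tmp_path / "net.graphml"
    write_graphml(g, path)
    back = nx.read_graphml(path)
    assert back.number_of_edges() == g.number_of_edges()
    assert nx.get_node_attributes(back, "is_srb")  # attributes preserved
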