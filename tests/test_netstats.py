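import math

import networkx as nx
import numpy as np
import pytest

import oracles
from axoaxonic.connectome import NeuronClass
from axoaxonic.netstats import (
    MotifGraph,
    build_motif_graph,
    degree_histograms,
    expected_random_path,
    graph_metrics,
    input_summary,
    laterality,
    nt_composition,
    rich_club,
)
from conftest import make_table


def _digraph_from_adj(adj):
    g = nx.DiGraph()
    g.add_nodes_from(range(len(adj)))
    for i, j in zip(*np.nonzero(adj)):
        g.add_edge(int(i), int(j), weight=1)
    return g


class TestBuildMotifGraph:
    def test_restricts_to_pre_classes(self):
        t = make_table(
            [
                (1, "DN", "a", "acetylcholine", "L"),
                (2, "DN", "b", "acetylcholine", "R"),
                (3, "AN", "c", "gaba", "L"),
            ],
            [(1, 2, 6), (3, 2, 6)],
        )
        dn_only = build_motif_graph(t, {NeuronClass.DN})
        assert dn_only.n_edges == 1
        assert (1, 2) in dn_only.graph.edges

    def test_merged_graph_is_union_of_motifs(self, synth_table):
        merged = build_motif_graph(
            synth_table, {NeuronClass.DN, NeuronClass.AN, NeuronClass.IN}
        )
        separate = set()
        for cls in (NeuronClass.DN, NeuronClass.AN, NeuronClass.IN):
            separate |= set(build_motif_graph(synth_table, {cls}).graph.edges)
        assert set(merged.graph.edges) == separate

    def test_isolated_neurons_excluded(self):
        t = make_table(
            [
                (1, "DN", "a", "acetylcholine", "L"),
                (2, "DN", "b", "acetylcholine", "R"),
                (3, "DN", "c", "gaba", "L"),  # isolated
            ],
            [(1, 2, 6)],
        )
        g = build_motif_graph(t, {NeuronClass.DN})
        assert 3 not in g.graph


class TestExpectedRandomPath:
    def test_direct_evaluation(self):
        assert expected_random_path(100, 300) == pytest.approx(math.log(100) / math.log(3))

    def test_mean_degree_one_boundary(self):
        with pytest.raises(ValueError):
            expected_random_path(10, 10)

    def test_published_scale(self):
        assert expected_random_path(884, 2757) == pytest.approx(5.9646, abs=1e-3)


class TestGraphMetrics:
    def test_path_graph_average(self):
        g = nx.DiGraph([(0, 1), (1, 2)])
        m = graph_metrics(g)
        assert m.avg_shortest_path == pytest.approx(4 / 3)

    def test_degree_mean_identity(self, synth_table):
        motif = build_motif_graph(synth_table, {NeuronClass.DN})
        m = graph_metrics(motif)
        assert m.degree_mean == pytest.approx(2 * m.n_edges / m.n_nodes)

    def test_density_conventions(self):
        g = nx.DiGraph([(0, 1), (1, 0), (1, 2)])
        m = graph_metrics(g)
        assert m.density_ordered_pairs == pytest.approx(3 / 6)
        assert m.density_undirected_pairs == pytest.approx(3 / 3)

    def test_louvain_reproducible(self, synth_table):
        motif = build_motif_graph(synth_table, {NeuronClass.DN})
        m1 = graph_metrics(motif, louvain_seed=0)
        m2 = graph_metrics(motif, louvain_seed=0)
        assert m1.n_communities == m2.n_communities
        assert m1.modularity == pytest.approx(m2.modularity)
        assert m1.modularity >= 0

    def test_single_node_sentinels(self):
        g = nx.DiGraph()
        g.add_node(0)
        m = graph_metrics(g)
        assert math.isnan(m.avg_shortest_path)
        assert math.isnan(m.clustering_coefficient)

    def test_oracle_agreement_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            adj = rng.random((7, 7)) < 0.3
            np.fill_diagonal(adj, False)
            g = _digraph_from_adj(adj)
            if g.number_of_nodes() == 0:
                continue
            m = graph_metrics(g)
            expected = oracles.avg_shortest_path_undirected_lcc(adj)
            if expected is None:
                assert math.isnan(m.avg_shortest_path)
            else:
                assert m.avg_shortest_path == pytest.approx(expected)
            assert m.clustering_coefficient == pytest.approx(
                oracles.average_clustering_undirected(adj)
            )


class TestRichClub:
    def test_complete_graph_is_one_everywhere(self):
        g = nx.complete_graph(4, nx.DiGraph())
        rc = rich_club(g)
        assert all(phi == pytest.approx(1.0) for phi in rc.phi)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            adj = rng.random((6, 6)) < 0.4
            np.fill_diagonal(adj, False)
            g = _digraph_from_adj(adj)
            rc = rich_club(g)
            ks, phis = oracles.rich_club_curve(adj)
            assert rc.thresholds == ks
            assert rc.phi == pytest.approx(phis)

    def test_truncates_below_two_nodes(self):
        g = nx.DiGraph([(0, 1)])
        g.add_node(2)
        rc = rich_club(g)
        # at k=1 only nodes 0,1 qualify; at k=2 fewer than 2 nodes remain
        assert rc.thresholds[-1] <= 1


class TestInputSummary:
    def test_hand_tally(self):
        t = make_table(
            [
                (1, "AN", "a", "acetylcholine", "L"),
                (2, "IN", "b", "gaba", "L"),
                (3, "DN", "c", "acetylcholine", "L"),
                (4, "DN", "d", "acetylcholine", "R"),
            ],
            [(1, 3, 6), (2, 3, 10), (1, 4, 7)],
        )
        s = input_summary(t)
        row3 = s.per_dn.set_index("neuron_id").loc[3]
        assert row3.partner_count == 2 and row3.total_strength == 16
        row4 = s.per_dn.set_index("neuron_id").loc[4]
        assert row4.partner_count == 1 and row4.total_strength == 7

    def test_collinear_gives_r_one(self):
        t = make_table(
            [
                (1, "AN", "a", "acetylcholine", "L"),
                (2, "AN", "b", "acetylcholine", "L"),
                (6, "AN", "f", "acetylcholine", "R"),
                (3, "DN", "c", "acetylcholine", "L"),
                (4, "DN", "d", "acetylcholine", "R"),
                (5, "DN", "e", "acetylcholine", "R"),
            ],
            # strengths exactly 6 × partner count: (1,6), (2,12), (3,18)
            [(1, 3, 6), (1, 4, 6), (2, 4, 6), (1, 5, 6), (2, 5, 6), (6, 5, 6)],
        )
        s = input_summary(t)
        assert s.pearson_r == pytest.approx(1.0)

    def test_hub_has_max_partner_count(self, synth_table, synth_truth):
        s = input_summary(synth_table)
        top = s.per_dn.sort_values("partner_count", ascending=False).iloc[:2]
        assert set(top.neuron_id) == set(synth_truth.hub_ids)


class TestComposition:
    def test_fractions_sum_to_one(self, synth_table):
        motif = build_motif_graph(synth_table, {NeuronClass.DN})
        for grouping in ("homotypic", "heterotypic", "all"):
            comp = nt_composition(motif, grouping)
            assert sum(comp.values()) == pytest.approx(1.0)

    def test_toy_fractions(self):
        t = make_table(
            [
                (1, "DN", "a", "acetylcholine", "L"),
                (2, "DN", "b", "acetylcholine", "L"),
                (3, "DN", "c", "gaba", "L"),
                (4, "DN", "d", "glutamate", "L"),
                (5, "DN", "e", "acetylcholine", "R"),
            ],
            [(1, 5, 6), (2, 5, 6), (3, 5, 6), (4, 5, 6)],
        )
        comp = nt_composition(build_motif_graph(t, {NeuronClass.DN}), "all")
        assert comp == {
            "acetylcholine": pytest.approx(0.5),
            "gaba": pytest.approx(0.25),
            "glutamate": pytest.approx(0.25),
        }

    def test_homotypic_cholinergic_near_target(self, synth_table):
        motif = build_motif_graph(synth_table, {NeuronClass.DN})
        comp = nt_composition(motif, "homotypic")
        assert comp["acetylcholine"] == pytest.approx(0.9, abs=0.08)


class TestLaterality:
    def test_edge_classification(self):
        t = make_table(
            [
                (1, "DN", "a", "acetylcholine", "L"),
                (2, "DN", "b", "acetylcholine", "R"),
                (3, "DN", "c", "gaba", "L"),
                (4, "DN", "d", "gaba", "unknown"),
            ],
            [(1, 2, 6), (1, 3, 6), (1, 4, 6)],
        )
        lat = laterality(build_motif_graph(t, {NeuronClass.DN}))
        assert lat["contralateral_fraction"] == pytest.approx(0.5)
        assert lat["ipsilateral_fraction"] == pytest.approx(0.5)
        assert lat["n_excluded"] == 1

    def test_hub_mirror_edges_contralateral(self, synth_table, synth_truth):
        a, b = synth_truth.hub_ids
        motif = build_motif_graph(synth_table, {NeuronClass.DN})
        g = motif.graph
        hub_edges = [e for e in g.edges if set(e) == {a, b}]
        for u, v in hub_edges:
            assert g.nodes[u]["side"] != g.nodes[v]["side"]


def test_exports_round_trip(tmp_path, synth_table):
    from axoaxonic.netstats import export_adjacency_csv, export_graphml
    import pandas as pd

    motif = build_motif_graph(synth_table, {NeuronClass.DN})
    export_graphml(motif, tmp_path / "g.graphml")
    back = nx.read_graphml(tmp_path / "g.graphml")
    assert back.number_of_edges() == motif.n_edges
    export_adjacency_csv(motif, tmp_path / "a.csv")
    mat = pd.read_csv(tmp_path / "a.csv", index_col=0)
    assert int(mat.to_numpy().astype(bool).sum()) == motif.n_edges


class TestDegreeHistograms:
    def test_star_graph(self):
        t = make_table(
            [(i, "DN", f"t{i}", "acetylcholine", "L") for i in range(6)],
            [(i, 0, 6) for i in range(1, 6)],
        )
        h = degree_histograms(build_motif_graph(t, {NeuronClass.DN}))
        assert h["in_degree"][5] == 1    # the center
        assert h["out_degree"][1] == 5   # the leaves

    def test_empty_graph(self):
        t = make_table([(1, "DN", "a", "acetylcholine", "L")], [])
        h = degree_histograms(build_motif_graph(t, {NeuronClass.DN}))
        assert h == {"in_degree": {}, "out_degree": {}}
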