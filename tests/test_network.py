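import networkx as nx
import numpy as np
import pytest

from epimir.consensus import ConsensusInteraction
from epimir.errors import ParameterError, ValidationError
from epimir.network import (
    build_network,
    export_graph,
    find_hubs,
    import_graph,
    mcl_cluster,
    mcl_step,
)

from oracles import reference_mcl


def interaction(mirna, gene, direction=1, cum=1.5):
    return ConsensusInteraction(mirna, direction, gene, 60.0, cum - 0.6, cum, False)


def barbell(weight=1.0):
    """Two 4-cliques joined by a single unit edge (bridge 3-4)."""
    graph = nx.Graph()
    for block in (range(4), range(4, 8)):
        for u in block:
            for v in block:
                if u < v:
                    graph.add_edge(f"n{u}", f"n{v}", weight=weight)
    graph.add_edge("n3", "n4", weight=weight)
    return graph


class TestBuildNetwork:
    def test_single_interaction(self):
        graph = build_network([interaction("mir-1", "Gene1")])
        assert graph.number_of_nodes() == 2 and graph.number_of_edges() == 1
        assert graph.nodes["mir-1"]["kind"] == "mirna"
        assert graph.nodes["mir-1"]["direction"] == 1
        assert graph.edges["mir-1", "Gene1"]["weight"] == 1.5

    def test_bipartite_no_same_kind_edges_and_degree_sum(self, fixture_consensus):
        graph = build_network(fixture_consensus)
        kinds = nx.get_node_attributes(graph, "kind")
        assert all(kinds[u] != kinds[v] for u, v in graph.edges)
        assert sum(d for _, d in graph.degree()) == 2 * graph.number_of_edges()
        assert min(d for _, d in graph.degree()) >= 1

    def test_duplicate_interaction_rejected(self):
        pair = interaction("mir-1", "Gene1")
        with pytest.raises(ValidationError):
            build_network([pair, pair])


class TestHubs:
    def test_degree_boundary(self):
        star = build_network([interaction("mir-1", f"Gene{i}") for i in range(4)])
        assert find_hubs(star, min_degree=5) == set()
        assert find_hubs(star, min_degree=4) == {"mir-1"}

    def test_min_degree_must_be_positive(self):
        with pytest.raises(ParameterError):
            find_hubs(nx.Graph(), min_degree=0)


class TestMCL:
    def test_two_disjoint_triangles_stay_separate(self):
        graph = nx.Graph()
        for offset in (0, 3):
            for i in range(3):
                graph.add_edge(f"t{offset + i}", f"t{offset + (i + 1) % 3}", weight=1.0)
        result = mcl_cluster(graph, inflation=3)
        assert set(result.clusters) == {
            frozenset({"t0", "t1", "t2"}),
            frozenset({"t3", "t4", "t5"}),
        }
        assert result.converged

    def test_single_isolated_node(self):
        graph = nx.Graph()
        graph.add_node("solo", kind="gene")
        result = mcl_cluster(graph)
        assert result.clusters == (frozenset({"solo"}),)

    def test_barbell_splits_at_bridge_like_reference(self):
        graph = barbell()
        result = mcl_cluster(graph, inflation=3)
        nodes = sorted(graph.nodes, key=lambda n: (graph.nodes[n].get("kind", ""), n))
        adjacency = nx.to_numpy_array(graph, nodelist=nodes)
        expected = {
            frozenset(nodes[i] for i in cluster)
            for cluster in reference_mcl(adjacency, inflation=3)
        }
        assert set(result.clusters) == expected
        assert len(result.clusters) == 2
        assert frozenset({"n0", "n1", "n2", "n3"}) in result.clusters

    def test_columns_stay_stochastic_across_iterations(self):
        adjacency = nx.to_numpy_array(barbell())
        np.fill_diagonal(adjacency, adjacency.max(axis=0))
        matrix = adjacency / adjacency.sum(axis=0)
        for _ in range(20):
            matrix = mcl_step(matrix, inflation=3)
            np.testing.assert_allclose(matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_partition_covers_all_nodes_exactly_once(self, fixture_consensus):
        graph = build_network(fixture_consensus)
        result = mcl_cluster(graph, inflation=3)
        labelled = [n for cluster in result.clusters for n in cluster]
        assert sorted(labelled) == sorted(graph.nodes)

    def test_clusters_never_cross_components(self, fixture_consensus):
        graph = build_network(fixture_consensus)
        result = mcl_cluster(graph, inflation=3)
        component_of = {}
        for k, comp in enumerate(nx.connected_components(graph)):
            for n in comp:
                component_of[n] = k
        for cluster in result.clusters:
            assert len({component_of[n] for n in cluster}) == 1

    def test_high_inflation_still_splits_barbell(self):
        result = mcl_cluster(barbell(), inflation=20)
        assert len(result.clusters) >= 2

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            mcl_cluster(barbell(), inflation=1.0)
        with pytest.raises(ValidationError):
            mcl_cluster(nx.Graph())


class TestExport:
    def test_sif_single_edge(self, tmp_path):
        graph = build_network([interaction("mir-1", "Gene1")])
        path = tmp_path / "net.sif"
        export_graph(graph, "sif", path)
        assert path.read_text() == "mir-1\ttargets\tGene1\n"

    def test_round_trip_preserves_fixture_counts(self, fixture_consensus, tmp_path):
        graph = build_network(fixture_consensus)
        for fmt in ("sif", "graphml"):
            path = tmp_path / f"net.{fmt}"
            export_graph(graph, fmt, path)
            back = import_graph(fmt, path)
            assert set(back.nodes) == set(graph.nodes)
            assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in graph.edges}

    def test_graphml_keeps_weight_and_attributes(self, tmp_path):
        graph = build_network(
            [
                ConsensusInteraction("mir-1", 1, "Gene1", 100.0, 0.94, 1.94, True),
            ]
        )
        path = tmp_path / "net.graphml"
        export_graph(graph, "graphml", path)
        back = import_graph("graphml", path)
        assert back.edges["mir-1", "Gene1"]["weight"] == pytest.approx(1.94)
        assert back.nodes["mir-1"]["kind"] == "mirna"

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ParameterError):
            export_graph(nx.Graph(), "gexf", tmp_path / "x")
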