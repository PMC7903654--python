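"""Correlation, thresholding, topology metrics, degree KDE, and exports."""
import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from diffconet import (
    build_network,
    correlation_matrix,
    degree_density_curve,
    topology_summary,
)
from diffconet.coexpr_network import (
    NetworkError,
    read_network,
    topology_table,
    write_network,
    write_sif,
)
from diffconet.harmonize import DISEASE, NORMAL

from conftest import make_dataset, net_from_edges


class TestCorrelationMatrix:
    def test_frozen_hand_value(self):
        # x=[1,2,3,4], y=[1,3,2,4]: r = 0.8 exactly
        ds = make_dataset(np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]]))
        corr = correlation_matrix(ds)
        assert corr.loc["g1", "g2"] == pytest.approx(0.8, abs=1e-12)
        assert corr.loc["g1", "g1"] == 1.0

    def test_matches_numpy_corrcoef(self, rng):
        x = rng.normal(size=(8, 20))
        ds = make_dataset(x)
        corr = correlation_matrix(ds)
        assert np.allclose(corr.to_numpy(), np.corrcoef(x), atol=1e-12)

    def test_constant_gene_rows_are_nan(self):
        ds = make_dataset(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        corr = correlation_matrix(ds)
        assert np.isnan(corr.loc["g2"]).all()
        assert np.isnan(corr["g2"]).all()
        assert corr.loc["g1", "g1"] == 1.0

    def test_condition_slice_and_subset(self, rng):
        x = rng.normal(size=(4, 10))
        ds = make_dataset(x, conditions=[NORMAL] * 5 + [DISEASE] * 5)
        corr = correlation_matrix(ds, gene_subset=["g2", "g4"], condition=NORMAL)
        assert list(corr.index) == ["g2", "g4"]
        expected = np.corrcoef(x[[1, 3]][:, :5])
        assert np.allclose(corr.to_numpy(), expected, atol=1e-12)

    def test_errors(self):
        ds = make_dataset(np.ones((2, 2)) + np.arange(4).reshape(2, 2))
        with pytest.raises(NetworkError):
            correlation_matrix(ds)  # only 2 samples
        ds3 = make_dataset(np.arange(12.0).reshape(3, 4))
        with pytest.raises(NetworkError):
            correlation_matrix(ds3, gene_subset=["nope"])


class TestBuildNetwork:
    def _ds(self):
        # g1 ~ g2 (r=1), g3 = -g1 (r=-1), g4 independent noise
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        values = np.vstack([base, base * 2 + 1, -base, [0.0, 5.0, -3.0, 2.0, -4.0, 1.0]])
        return make_dataset(values)

    def test_abs_mode_keeps_negative_correlations(self):
        net = build_network(self._ds(), r_threshold=0.99, mode="abs")
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        assert net.graph["g1"]["g3"]["weight"] == pytest.approx(-1.0)

    def test_positive_mode_drops_negative_correlations(self):
        net = build_network(self._ds(), r_threshold=0.99, mode="positive")
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("g1", "g2")}

    def test_threshold_is_inclusive(self):
        # construct r exactly 0.5 between g1 and g2
        ds = make_dataset(
            np.array([[1.0, -1.0, 1.0, -1.0], [1.0, -1.0, -1.0, 1.0],
                      [1.0, 1.0, -1.0, -1.0], [2.0, 0.0, 0.0, -2.0]])
        )
        corr = correlation_matrix(ds)
        r = corr.loc["g1", "g4"]
        net = build_network(ds, r_threshold=abs(r))
        assert net.graph.has_edge("g1", "g4")

    def test_unconnected_genes_counted_not_noded(self):
        net = build_network(self._ds(), r_threshold=0.99)
        assert "g4" not in net.graph
        assert net.universe == ("g1", "g2", "g3", "g4")
        assert topology_summary(net).n_unconnected == 1

    def test_bad_mode(self):
        with pytest.raises(NetworkError):
            build_network(self._ds(), mode="signed")


class TestTopology:
    def test_k4_minus_one_edge_closed_form(self):
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        s = topology_summary(net_from_edges(edges))
        assert s.n_nodes == 4 and s.n_edges == 5
        assert s.clustering_coefficient == pytest.approx(5.0 / 6.0)
        assert s.density == pytest.approx(5.0 / 6.0)
        assert s.centralization == pytest.approx(1.0 / 3.0)

    def test_star_is_maximally_centralized(self):
        edges = [("h", x) for x in "abcd"]
        s = topology_summary(net_from_edges(edges))
        assert s.centralization == pytest.approx(1.0)
        assert s.clustering_coefficient == 0.0

    def test_triangle(self):
        s = topology_summary(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert s.clustering_coefficient == 1.0
        assert s.density == 1.0
        assert s.centralization == 0.0

    def test_empty_network(self):
        net = net_from_edges([], universe=["a", "b", "c"])
        s = topology_summary(net)
        assert (s.n_nodes, s.n_edges, s.n_unconnected) == (0, 0, 3)
        assert s.clustering_coefficient == s.density == s.centralization == 0.0

    def test_brute_force_oracle_on_random_graphs(self, rng):
        """All four metrics vs direct-from-definition computation."""
        for trial in range(60):
            n = int(rng.integers(3, 18))
            p = float(rng.uniform(0.1, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 3:
                continue
            net = net_from_edges(list(g.edges), universe=sorted(g.nodes))
            s = topology_summary(net)
            nodes = list(g.nodes)
            m = len(nodes)
            # clustering from triangle counting
            cs = []
            for v in nodes:
                nbrs = list(g.neighbors(v))
                k = len(nbrs)
                if k < 2:
                    cs.append(0.0)
                    continue
                links = sum(
                    1 for u, w in itertools.combinations(nbrs, 2) if g.has_edge(u, w)
                )
                cs.append(2.0 * links / (k * (k - 1)))
            degs = np.array([g.degree(v) for v in nodes])
            assert s.clustering_coefficient == pytest.approx(np.mean(cs), abs=1e-12)
            assert s.density == pytest.approx(
                2.0 * g.number_of_edges() / (m * (m - 1)), abs=1e-12
            )
            assert s.centralization == pytest.approx(
                (degs.max() - degs).sum() / ((m - 1) * (m - 2)), abs=1e-12
            )


class TestDegreeDensity:
    def test_star_variance_and_histogram(self):
        dd = degree_density_curve(net_from_edges([("h", x) for x in "abcd"]))
        assert sorted(dd.degrees) == [1, 1, 1, 1, 4]
        assert dd.histogram.tolist() == [0, 4, 0, 0, 1]
        assert dd.degree_variance == pytest.approx(1.8)

    def test_path_graph_variance(self):
        dd = degree_density_curve(net_from_edges([("a", "b"), ("b", "c")]))
        assert dd.degree_variance == pytest.approx(1.0 / 3.0)

    def test_regular_graph_has_no_kde(self):
        dd = degree_density_curve(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert dd.degree_variance == 0.0
        assert dd.grid is None and dd.density is None

    def test_kde_matches_scipy_silverman(self):
        edges = [("h", x) for x in "abcdef"] + [("a", "b")]
        dd = degree_density_curve(net_from_edges(edges))
        ref = stats.gaussian_kde(dd.degrees.astype(float), bw_method="silverman")
        assert np.allclose(dd.density, ref(dd.grid), atol=1e-12)
        assert dd.grid[0] == 0.0

    def test_empty_errors(self):
        with pytest.raises(NetworkError):
            degree_density_curve(net_from_edges([], universe=["a"]))


class TestExports:
    def test_sif_format_and_order(self, tmp_path):
        net = net_from_edges([("b", "a"), ("c", "a")])
        write_sif(net, tmp_path / "n.sif")
        assert (tmp_path / "n.sif").read_text() == "a\tcoexp\tb\na\tcoexp\tc\n"

    def test_network_round_trip(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(10, 12)))
        net = build_network(ds, r_threshold=0.3, tissue="ACC", condition=None)
        write_network(net, tmp_path / "e.tsv", tmp_path / "m.json")
        back = read_network(tmp_path / "e.tsv", tmp_path / "m.json")
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        assert back.universe == net.universe
        assert back.r_threshold == net.r_threshold
        for a, b in net.graph.edges:
            assert back.graph[a][b]["weight"] == pytest.approx(
                net.graph[a][b]["weight"], abs=1e-12
            )

    def test_topology_table_shape(self):
        s = topology_summary(net_from_edges([("a", "b")]))
        table = topology_table({"ACC normal": s, "ACC disease": s})
        assert list(table.columns) == ["ACC normal", "ACC disease"]
        assert table.loc["Edges", "ACC normal"] == 1
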