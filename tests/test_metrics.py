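"""Graph metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from fcnet import connectivity as conn
from fcnet import metrics as met
from fcnet.connectivity import BinaryGraph

from . import oracles


def G(adj):
    return BinaryGraph(np.asarray(adj))


class TestClosedForms:
    def test_degree_star_and_complete(self, toy_graphs):
        star = toy_graphs["star_k1_5"].adjacency
        assert met.degree_centrality(G(star)).tolist() == [5, 1, 1, 1, 1, 1]
        k5 = toy_graphs["complete_k5"].adjacency
        assert met.degree_centrality(G(k5)).tolist() == [4] * 5

    def test_clustering_triangle_and_star(self, toy_graphs):
        tri = np.ones((3, 3)) - np.eye(3)
        assert met.clustering_coefficient(G(tri))[1] == pytest.approx(1.0)
        star = toy_graphs["star_k1_5"].adjacency
        assert met.clustering_coefficient(G(star))[1] == pytest.approx(0.0)

    def test_path_length_conventions(self, toy_graphs):
        k5 = toy_graphs["complete_k5"].adjacency
        assert met.characteristic_path_length(G(k5)) == pytest.approx(1.0)
        p3 = toy_graphs["path_p3"].adjacency
        assert met.characteristic_path_length(G(p3)) == pytest.approx(4 / 3)
        # disconnected: only within-component pairs enter the mean
        two_tri = np.zeros((6, 6), int)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            two_tri[i, j] = two_tri[j, i] = 1
        assert met.characteristic_path_length(G(two_tri)) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="edgeless"):
            met.characteristic_path_length(G(np.zeros((4, 4), int)))

    def test_global_efficiency(self, toy_graphs):
        k4 = toy_graphs["complete_k4"].adjacency
        assert met.global_efficiency(G(k4)) == pytest.approx(1.0)
        p3 = toy_graphs["path_p3"].adjacency
        assert met.global_efficiency(G(p3)) == pytest.approx(5 / 6)
        assert met.global_efficiency(G(np.zeros((5, 5), int))) == 0.0

    def test_local_efficiency(self, toy_graphs):
        k4 = toy_graphs["complete_k4"].adjacency
        assert met.local_efficiency(G(k4))[1] == pytest.approx(1.0)
        star = toy_graphs["star_k1_5"].adjacency
        assert met.local_efficiency(G(star))[1] == pytest.approx(0.0)

    def test_betweenness_star_center_and_complete(self, toy_graphs):
        star3 = np.zeros((4, 4), int)
        for leaf in (1, 2, 3):
            star3[0, leaf] = star3[leaf, 0] = 1
        bc = met.betweenness_centrality(G(star3))
        assert bc[0] == pytest.approx(3.0)
        assert np.all(bc[1:] == 0)
        k5 = toy_graphs["complete_k5"].adjacency
        assert np.all(met.betweenness_centrality(G(k5)) == 0)

    def test_nodal_efficiency(self, toy_graphs):
        k5 = toy_graphs["complete_k5"].adjacency
        np.testing.assert_allclose(met.nodal_efficiency(G(k5)), 1.0)
        p3 = toy_graphs["path_p3"].adjacency
        ne = met.nodal_efficiency(G(p3))
        assert ne[0] == pytest.approx(0.75)
        isolated = np.zeros((3, 3), int)
        isolated[0, 1] = isolated[1, 0] = 1
        assert met.nodal_efficiency(G(isolated))[2] == 0.0


class TestOracleEquivalence:
    """Every metric equals an independent brute-force implementation on
    all fixture graphs of <= 12 nodes."""

    def test_all_metrics_match_brute_force(self, small_fixture_graphs):
        for name, adj in small_fixture_graphs.items():
            g = G(adj)
            np.testing.assert_allclose(
                met.degree_centrality(g), oracles.brute_degree(adj), err_msg=name
            )
            np.testing.assert_allclose(
                met.clustering_coefficient(g)[0],
                oracles.brute_clustering(adj),
                atol=1e-9,
                err_msg=name,
            )
            if np.asarray(adj).sum() > 0:
                assert met.characteristic_path_length(g) == pytest.approx(
                    oracles.brute_lp(adj), abs=1e-9
                ), name
            assert met.global_efficiency(g) == pytest.approx(
                oracles.brute_eg(adj), abs=1e-9
            ), name
            np.testing.assert_allclose(
                met.local_efficiency(g)[0],
                oracles.brute_eloc(adj),
                atol=1e-9,
                err_msg=name,
            )
            np.testing.assert_allclose(
                met.betweenness_centrality(g),
                oracles.brute_betweenness(adj),
                atol=1e-9,
                err_msg=name,
            )
            np.testing.assert_allclose(
                met.nodal_efficiency(g), oracles.brute_ne(adj), atol=1e-9, err_msg=name
            )

    def test_handshake_identity_on_er_fixture(self, toy_graphs):
        adj = toy_graphs["er_100_p10"].adjacency
        assert met.degree_centrality(G(adj)).sum() == adj.sum()


class TestNullModels:
    def test_nulls_preserve_degree_sequence(self, toy_graphs):
        g = G(toy_graphs["er_100_p10"].adjacency)
        for null in met.random_null_graphs(g, 5, seed=0):
            np.testing.assert_array_equal(
                met.degree_centrality(null), met.degree_centrality(g)
            )

    def test_rewiring_destroys_lattice_clustering(self, toy_graphs):
        g = G(toy_graphs["ring_lattice_20_4"].adjacency)
        nulls = met.random_null_graphs(g, 20, seed=1)
        null_cp = np.mean([met.clustering_coefficient(h)[1] for h in nulls])
        assert null_cp < met.clustering_coefficient(g)[1]

    def test_zero_null_count_rejected(self, toy_graphs):
        g = G(toy_graphs["complete_k5"].adjacency)
        with pytest.raises(ValueError, match="n_rand"):
            met.random_null_graphs(g, 0, seed=0)

    def test_nulls_deterministic_per_seed(self, toy_graphs):
        g = G(toy_graphs["er_100_p10"].adjacency)
        a = met.random_null_graphs(g, 3, seed=42)
        b = met.random_null_graphs(g, 3, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)


class TestNormalizedMetrics:
    def test_self_null_is_identity(self, toy_graphs):
        g = G(toy_graphs["ring_lattice_20_4"].adjacency)
        gamma, lam, sigma = met.normalized_metrics(g, [g, g, g])
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_er_graph_is_its_own_null_class(self, toy_graphs):
        g = G(toy_graphs["er_100_p10"].adjacency)
        nulls = met.random_null_graphs(g, 10, seed=3)
        _, _, sigma = met.normalized_metrics(g, nulls)
        assert sigma == pytest.approx(1.0, abs=0.1)

    def test_lattice_has_elevated_gamma(self, toy_graphs):
        g = G(toy_graphs["ring_lattice_20_4"].adjacency)
        nulls = met.random_null_graphs(g, 20, seed=4)
        gamma, lam, sigma = met.normalized_metrics(g, nulls)
        assert gamma > 1.0
        assert sigma * lam == pytest.approx(gamma, abs=1e-12)

    def test_empty_null_list_rejected(self, toy_graphs):
        with pytest.raises(ValueError):
            met.normalized_metrics(G(toy_graphs["complete_k4"].adjacency), [])


class TestAUC:
    def test_constant_curve(self):
        grid = conn.DensityGrid.default()
        curve = np.full(len(grid), 2.0)
        assert met.auc_over_densities(curve, grid) == pytest.approx(0.62)

    def test_linear_curve(self):
        x = np.linspace(0.06, 0.37, 32)
        y = np.linspace(0.0, 1.0, 32)
        assert met.auc_over_densities(y, x) == pytest.approx(0.155)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            met.auc_over_densities([1.0], [0.1])
        with pytest.raises(ValueError, match="match"):
            met.auc_over_densities([1.0, 2.0, 3.0], [0.1, 0.2])


@pytest.fixture(scope="module")
def profile_and_fc():
    rng = np.random.default_rng(9)
    ts = rng.normal(size=(120, 24))
    fc = conn.pearson_fc(ts)
    grid = conn.DensityGrid.from_range(0.08, 0.32, 0.04)
    prof = met.metric_profile(fc, grid, null_count=5, seed=11)
    return prof, fc, grid


class TestMetricProfile:

    def test_degree_curves_nondecreasing_in_density(self, profile_and_fc):
        prof, _, _ = profile_and_fc
        dc = prof.nodal_curves["Dc"]
        assert np.all(np.diff(dc, axis=0) >= 0)
        eg = prof.global_curves["Eg"]
        assert np.all(np.diff(eg) >= 0)

    def test_handshake_at_every_density(self, profile_and_fc):
        prof, fc, grid = profile_and_fc
        for di, dens in enumerate(grid):
            g = conn.threshold_at_density(fc, dens)
            assert prof.nodal_curves["Dc"][di].sum() == 2 * g.n_edges

    def test_sigma_identity_along_curve(self, profile_and_fc):
        prof, _, _ = profile_and_fc
        np.testing.assert_allclose(
            prof.global_curves["sigma"] * prof.global_curves["lambda"],
            prof.global_curves["gamma"],
            atol=1e-12,
        )

    def test_profile_deterministic(self, profile_and_fc):
        _, fc, grid = profile_and_fc
        a = met.metric_profile(fc, grid, null_count=3, seed=5)
        b = met.metric_profile(fc, grid, null_count=3, seed=5)
        for m in a.global_curves:
            np.testing.assert_array_equal(a.global_curves[m], b.global_curves[m])
        np.testing.assert_array_equal(a.nodal_auc["Bc"], b.nodal_auc["Bc"])
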