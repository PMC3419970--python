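import numpy as np
import pytest

from adhdml import funcfeat as ff
from adhdml import graphnet as gn

import oracles


def make_matrix(z: np.ndarray) -> ff.ConnectivityMatrix:
    z = np.asarray(z, dtype=float)
    np.fill_diagonal(z, 0.0)
    return ff.ConnectivityMatrix(
        z=(z + z.T) / 2, roi_names=[f"r{i}" for i in range(z.shape[0])]
    )


def random_graph(rng, n=None, mode="weighted"):
    n = n or int(rng.integers(4, 9))
    z = rng.uniform(-1, 1, size=(n, n))
    m = make_matrix(z)
    p = float(rng.uniform(0.2, 0.8))
    return gn.threshold_proportional(m, p, mode=mode)


class TestThresholding:
    def test_edge_count_rule(self, rng):
        z = rng.uniform(0.1, 1.0, size=(10, 10))
        g = gn.threshold_proportional(make_matrix(z), 0.2)
        assert g.n_edges == round(0.2 * 45)

    def test_retained_set_matches_sort_oracle(self, rng):
        z = rng.uniform(-1, 1, size=(8, 8))
        m = make_matrix(z)
        g = gn.threshold_proportional(m, 0.3)
        iu, ju = np.triu_indices(8, 1)
        w = m.z[iu, ju]
        n_keep = round(0.3 * 28)
        expected = set(
            map(tuple, np.column_stack([iu, ju])[np.argsort(-w)[:n_keep]])
        )
        kept = set(zip(*np.nonzero(np.triu(g.adjacency, 1))))
        assert kept == expected

    def test_p_one_keeps_positives_drops_negatives(self, rng):
        z = rng.uniform(-1, 1, size=(6, 6))
        m = make_matrix(z)
        with pytest.warns(UserWarning):
            g = gn.threshold_proportional(m, 1.0)
        iu, ju = np.triu_indices(6, 1)
        assert g.n_edges == int((m.z[iu, ju] > 0).sum())
        assert (g.adjacency >= 0).all()

    def test_binarized_weights_are_unit(self, rng):
        g = random_graph(rng, mode="binarized")
        w = g.adjacency[g.adjacency > 0]
        assert (w == 1.0).all()


class TestGlobalMetrics:
    def test_complete_graph_closed_form(self):
        A = 1.0 - np.eye(4)
        g = gn.BrainGraph(adjacency=A, roi_names=list("abcd"), mode="binarized")
        m = gn.global_graph_metrics(g)
        assert m.CC == pytest.approx(1.0)
        assert m.CPL == pytest.approx(1.0)
        assert m.E_glob == pytest.approx(1.0)

    def test_six_ring(self):
        A = np.zeros((6, 6))
        for i in range(6):
            A[i, (i + 1) % 6] = A[(i + 1) % 6, i] = 1.0
        g = gn.BrainGraph(adjacency=A, roi_names=list("abcdef"), mode="binarized")
        m = gn.global_graph_metrics(g)
        assert m.CPL == pytest.approx(1.8)
        assert m.CC == pytest.approx(0.0)

    def test_edgeless_graph_flagged(self):
        g = gn.BrainGraph(adjacency=np.zeros((4, 4)), roi_names=list("abcd"),
                          mode="binarized")
        m = gn.global_graph_metrics(g)
        assert m.CC == 0.0 and m.E_glob == 0.0
        assert np.isinf(m.CPL)
        assert "no_edges" in m.flags

    @pytest.mark.parametrize("mode", ["weighted", "binarized"])
    def test_matches_oracles_random_graphs(self, rng, mode):
        for _ in range(25):
            g = random_graph(rng, mode=mode)
            weighted = mode == "weighted"
            m = gn.global_graph_metrics(g)
            A = g.adjacency
            assert m.CPL == pytest.approx(oracles.cpl_oracle(A, weighted), abs=1e-9)
            assert m.E_glob == pytest.approx(oracles.eglob_oracle(A, weighted), abs=1e-9)
            assert m.CC == pytest.approx(
                oracles.clustering_oracle(A, weighted).mean(), abs=1e-9
            )
            assert m.E_loc == pytest.approx(
                oracles.local_efficiency_oracle(A, weighted).mean(), abs=1e-9
            )

    def test_modularity_beats_trivial_partition(self, rng):
        for _ in range(5):
            g = random_graph(rng)
            m = gn.global_graph_metrics(g)
            assert m.Q >= 0.0 - 1e-12

    def test_node_relabeling_invariance(self, rng):
        g = random_graph(rng, n=7)
        perm = rng.permutation(7)
        A2 = g.adjacency[np.ix_(perm, perm)]
        g2 = gn.BrainGraph(adjacency=A2, roi_names=[g.roi_names[i] for i in perm],
                           mode=g.mode)
        m1, m2 = gn.global_graph_metrics(g), gn.global_graph_metrics(g2)
        for key in ("CC", "E_loc", "CPL", "E_glob"):
            assert m1.as_dict()[key] == pytest.approx(m2.as_dict()[key], abs=1e-9)


class TestNodalMetrics:
    def test_star_betweenness(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        g = gn.BrainGraph(adjacency=A, roi_names=list("abcde"), mode="binarized")
        nm = gn.nodal_graph_metrics(g)
        assert nm["BC"][0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm["BC"][1:], 0.0)

    def test_complete_graph_regional_efficiency(self):
        A = 1.0 - np.eye(4)
        g = gn.BrainGraph(adjacency=A, roi_names=list("abcd"), mode="binarized")
        nm = gn.nodal_graph_metrics(g)
        np.testing.assert_allclose(nm["E_reg"], 1.0)

    def test_isolated_node_all_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        g = gn.BrainGraph(adjacency=A, roi_names=list("abcd"), mode="binarized")
        nm = gn.nodal_graph_metrics(g)
        for key in ("strength", "degree", "CC", "E_loc", "E_reg", "BC"):
            assert nm[key][3] == 0.0

    @pytest.mark.parametrize("mode", ["weighted", "binarized"])
    def test_matches_oracles_random_graphs(self, rng, mode):
        for _ in range(15):
            g = random_graph(rng, mode=mode)
            weighted = mode == "weighted"
            nm = gn.nodal_graph_metrics(g)
            A = g.adjacency
            np.testing.assert_allclose(nm["strength"], A.sum(axis=1), atol=1e-12)
            np.testing.assert_allclose(
                nm["CC"], oracles.clustering_oracle(A, weighted), atol=1e-9
            )
            np.testing.assert_allclose(
                nm["E_reg"], oracles.ereg_oracle(A, weighted), atol=1e-9
            )
            np.testing.assert_allclose(
                nm["BC"], oracles.betweenness_oracle(A, weighted), atol=1e-8
            )


class TestNormalizedMetrics:
    def test_random_graph_gamma_lambda_near_one(self, rng):
        # a dense random graph is its own null: gamma, lambda ~ 1
        n = 12
        z = rng.uniform(0.1, 1.0, size=(n, n))
        g = gn.threshold_proportional(make_matrix(z), 0.5, mode="binarized")
        gamma, lam, sigma = gn.normalized_metrics(g, n_random=30, seed=0)
        assert gamma == pytest.approx(1.0, abs=0.35)
        assert lam == pytest.approx(1.0, abs=0.15)
        assert sigma == pytest.approx(gamma / lam)

    def test_ring_lattice_gamma_above_one(self):
        n = 16
        A = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                A[i, (i + d) % n] = A[(i + d) % n, i] = 1.0
        g = gn.BrainGraph(adjacency=A, roi_names=[str(i) for i in range(n)],
                          mode="binarized")
        gamma, lam, sigma = gn.normalized_metrics(g, n_random=20, seed=1)
        assert gamma > 1.0

    def test_deterministic_given_seed(self, rng):
        g = random_graph(rng, n=8, mode="binarized")
        a = gn.normalized_metrics(g, n_random=10, seed=5)
        b = gn.normalized_metrics(g, n_random=10, seed=5)
        assert a == b

    def test_rewiring_preserves_degree_sequence(self, rng):
        g = random_graph(rng, n=8, mode="binarized")
        Gr = gn._rewired_ensemble_graph(g, np.random.default_rng(0), "rewire")
        orig = sorted(d for _, d in g.to_networkx().degree())
        new = sorted(d for _, d in Gr.degree())
        assert orig == new


class TestAcrossSparsities:
    def test_average_equals_per_level_mean(self, rng):
        z = rng.uniform(-1, 1, size=(10, 10))
        m = make_matrix(z)
        levels = (0.2, 0.3)
        combined = gn.metrics_across_sparsities(
            m, levels=levels, mode="binarized", include_normalized=False
        )
        per_level = [
            gn.global_graph_metrics(gn.threshold_proportional(m, p, "binarized"))
            for p in levels
        ]
        for key in ("CC", "E_glob"):
            expected = np.mean([pl.as_dict()[key] for pl in per_level])
            assert combined[f"global_{key}"] == pytest.approx(expected)

    def test_eglob_nondecreasing_in_sparsity(self, rng):
        for _ in range(5):
            z = rng.uniform(-1, 1, size=(9, 9))
            m = make_matrix(z)
            e = [
                gn.global_graph_metrics(
                    gn.threshold_proportional(m, p, "binarized")
                ).E_glob
                for p in (0.1, 0.2, 0.3, 0.4)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(e, e[1:]))

    def test_nodal_columns_present(self, rng):
        z = rng.uniform(0, 1, size=(6, 6))
        m = make_matrix(z)
        out = gn.metrics_across_sparsities(
            m, levels=(0.3,), include_normalized=False
        )
        assert "nodal_BC_r0" in out and "global_Q" in out
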