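"""Laplacian, diffusion kernel, and network surgery."""

import numpy as np
import pytest

from netrank import (
    GeneUniverse,
    Network,
    diffusion_kernel,
    inject_noise,
    laplacian,
    merge_networks,
    permute_labels,
)
from netrank.kernel import raw_diffusion

from conftest import random_network


def _net(genes, edges):
    return Network(GeneUniverse(genes), edges)


class TestLaplacian:
    def test_single_edge(self):
        L = laplacian(_net(["a", "b"], [("a", "b")]))
        np.testing.assert_array_equal(L, [[1, -1], [-1, 1]])

    def test_isolated_node_row_is_zero(self):
        L = laplacian(_net(["a", "b", "c"], [("a", "b")]))
        np.testing.assert_array_equal(L[2], [0, 0, 0])

    def test_triangle(self):
        L = laplacian(_net(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")]))
        assert np.all(np.diag(L) == 2)
        assert np.all(L[~np.eye(3, dtype=bool)] == -1)

    def test_rows_sum_to_zero(self):
        net = random_network(20, 0.2, np.random.default_rng(0))
        np.testing.assert_allclose(laplacian(net).sum(axis=1), 0, atol=1e-12)


class TestDiffusionKernel:
    def test_tau_zero_is_identity(self):
        K = diffusion_kernel(_net(["a", "b", "c"], [("a", "b")]), 0.0)
        np.testing.assert_array_equal(K.values, np.eye(3))

    def test_two_node_closed_form(self):
        # eigenvalues of the 2-node Laplacian are {0, 2}
        for tau in (0.3, 1.0, 2.5):
            K = diffusion_kernel(_net(["a", "b"], [("a", "b")]), tau)
            expected = (1 - np.exp(-2 * tau)) / (1 + np.exp(-2 * tau))
            assert K.values[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_isolated_node_block(self):
        net = _net(["a", "b", "u"], [("a", "b")])
        K = diffusion_kernel(net, 1.0)
        assert K.values[2, 2] == 1.0
        assert K.values[2, 0] == K.values[2, 1] == 0.0

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            diffusion_kernel(_net(["a", "b"], [("a", "b")]), -0.1)

    def test_random_graph_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(2, 40))
            net = random_network(n, float(rng.uniform(0.05, 0.5)), rng)
            tau = float(rng.uniform(0, 2))
            S = raw_diffusion(net, tau)
            np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-9)
            assert S.min() > -1e-10
            K = diffusion_kernel(net, tau).values
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(K), 1.0)
            assert K.min() >= 0.0 and K.max() <= 1.0
            # PSD with unit diagonal
            assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_kernel_conjugates_under_label_permutation(self):
        rng = np.random.default_rng(21)
        net = random_network(15, 0.25, rng)
        permuted = permute_labels(net, seed=5)
        K = diffusion_kernel(net, 0.7).values
        Kp = diffusion_kernel(permuted, 0.7).values
        # recover the relabeling applied by permute_labels(seed=5)
        perm = np.random.default_rng(5).permutation(15)
        P = np.zeros((15, 15))
        P[perm, np.arange(15)] = 1.0
        np.testing.assert_allclose(Kp, P @ K @ P.T, atol=1e-10)


class TestMergeNetworks:
    def test_union(self):
        merged = merge_networks(
            [_net(["a", "b"], [("a", "b")]), _net(["b", "c"], [("b", "c")])]
        )
        assert set(merged.universe.genes) == {"a", "b", "c"}
        assert merged.edges == {frozenset(("a", "b")), frozenset(("b", "c"))}

    def test_idempotent(self):
        net = _net(["a", "b", "c"], [("a", "b"), ("b", "c")])
        merged = merge_networks([net, net])
        assert merged.edges == net.edges

    def test_edge_count_bound(self):
        n1 = _net(["a", "b", "c"], [("a", "b"), ("b", "c")])
        n2 = _net(["a", "b", "d"], [("a", "b"), ("a", "d")])
        merged = merge_networks([n1, n2])
        assert merged.n_edges == 3 <= n1.n_edges + n2.n_edges

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_networks([])


class TestPermuteLabels:
    def test_degree_multiset_preserved(self):
        net = random_network(30, 0.2, np.random.default_rng(9))
        out = permute_labels(net, seed=4)
        assert sorted(out.degrees()) == sorted(net.degrees())
        assert out.n_edges == net.n_edges

    def test_deterministic(self):
        net = random_network(25, 0.2, np.random.default_rng(2))
        assert permute_labels(net, seed=8).edges == permute_labels(net, seed=8).edges

    def test_single_node_unchanged(self):
        net = _net(["a"], [])
        assert permute_labels(net, seed=1).edges == set()


class TestInjectNoise:
    def test_alpha_zero_identity(self):
        net = random_network(20, 0.3, np.random.default_rng(1))
        assert inject_noise(net, 0.0, seed=3).edges == net.edges

    def test_alpha_100_disjoint(self):
        net = random_network(30, 0.1, np.random.default_rng(5))
        out = inject_noise(net, 100.0, seed=3)
        assert out.n_edges == net.n_edges
        assert not (out.edges & net.edges)

    def test_edge_count_conserved(self):
        net = random_network(40, 0.2, np.random.default_rng(6))
        for alpha in (10.0, 20.0, 40.0):
            out = inject_noise(net, alpha, seed=11)
            assert out.n_edges == net.n_edges
            n_kept = len(out.edges & net.edges)
            assert n_kept == net.n_edges - int(round(alpha / 100 * net.n_edges))

    def test_alpha_out_of_range_rejected(self):
        net = random_network(10, 0.3, np.random.default_rng(0))
        for alpha in (-1.0, 101.0):
            with pytest.raises(ValueError):
                inject_noise(net, alpha, seed=0)

    def test_not_enough_non_edges_rejected(self):
        genes = ["a", "b", "c", "d"]
        complete = _net(genes, [(u, v) for i, u in enumerate(genes) for v in genes[i + 1:]])
        with pytest.raises(ValueError, match="non-edges"):
            inject_noise(complete, 50.0, seed=0)

    def test_no_self_loops_and_deterministic(self):
        net = random_network(25, 0.15, np.random.default_rng(8))
        out1 = inject_noise(net, 40.0, seed=13)
        out2 = inject_noise(net, 40.0, seed=13)
        assert out1.edges == out2.edges
        assert all(len(e) == 2 for e in out1.edges)
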