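"""Connectivity graph and spectral machinery: correlation adjacency,
sparsification, Laplacian identities, graph Fourier transform, exact vs
Chebyshev filtering."""

import json

import numpy as np
import pytest

import emograph as eg
from emograph.graph import (cheb_t_stack, graph_to_json, graph_from_json,
                            ChannelGraph)
from conftest import random_graph


class TestCorrelationAdjacency:
    def test_identical_channels_give_unit_weight(self):
        x = np.random.default_rng(0).random(100)
        g = eg.correlation_adjacency(np.stack([x, x, 2 * x]))
        off = g.W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.linspace(0, 2 * np.pi, 1001)[:-1]
        g = eg.correlation_adjacency(np.stack([np.sin(t), np.cos(t)]))
        assert g.W[0, 1] < 1e-6

    def test_matches_naive_pearson_loop(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 1000))
        g = eg.correlation_adjacency(x)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert g.W[i, j] == 0.0
                    continue
                a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
                assert abs(g.W[i, j] - abs(r)) < 1e-12

    def test_constant_channel_zeroed_with_warning(self):
        x = np.vstack([np.ones(50), np.random.default_rng(0).random((2, 50))])
        with pytest.warns(UserWarning):
            g = eg.correlation_adjacency(x)
        assert np.all(g.W[0] == 0) and np.all(g.W[:, 0] == 0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            eg.correlation_adjacency(np.zeros((3, 1)))


class TestSparsify:
    def test_zero_threshold_is_identity(self):
        W = np.array([[0, .2, .9], [.2, 0, .5], [.9, .5, 0]])
        assert np.array_equal(eg.sparsify(W, 0.0), W)

    def test_elementwise_threshold(self):
        W = np.array([[0, .2, .9], [.2, 0, .5], [.9, .5, 0]])
        out = eg.sparsify(W, 0.4)
        assert np.array_equal(out, np.array([[0, 0, .9], [0, 0, .5],
                                             [.9, .5, 0]]))

    def test_unit_threshold_keeps_only_exact_ones(self):
        W = np.array([[0, 1.0], [1.0, 0]])
        assert np.array_equal(eg.sparsify(W, 1.0), W)
        with pytest.warns(UserWarning):
            out = eg.sparsify(np.array([[0, .99], [.99, 0]]), 1.0)
        assert np.all(out == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        W = rng.random((5, 5)); W = (W + W.T) / 2; np.fill_diagonal(W, 0)
        once = eg.sparsify(W, 0.3)
        assert np.array_equal(eg.sparsify(once, 0.3), once)

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            eg.sparsify(np.zeros((2, 2)), 1.5)


class TestLaplacian:
    def test_complete_unit_triangle_eigenvalues(self):
        # L = D - W = 2I - (J - I) = 3I - J; charpoly gives lambda = 0, 3, 3
        W = np.ones((3, 3)) - np.eye(3)
        g = eg.laplacian(W)
        assert np.allclose(g.L, 3 * np.eye(3) - np.ones((3, 3)))
        assert np.allclose(g.lam, [0.0, 3.0, 3.0], atol=1e-10)

    def test_empty_graph_all_zero(self):
        g = eg.laplacian(np.zeros((3, 3)))
        assert np.allclose(g.L, 0) and np.allclose(g.lam, 0)

    def test_laplacian_identities_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_graph(rng, rng.integers(3, 8))
            assert np.allclose(g.L.sum(axis=1), 0, atol=1e-12)
            for _ in range(5):
                x = rng.standard_normal(g.n_nodes)
                assert x @ g.L @ x >= -1e-10
            assert np.allclose(g.U.T @ g.U, np.eye(g.n_nodes), atol=1e-10)
            assert np.all(np.diff(g.lam) >= -1e-12)

    def test_connected_graph_null_eigenvector_constant(self):
        W = np.ones((4, 4)) - np.eye(4)
        g = eg.laplacian(W)
        assert abs(g.lam[0]) < 1e-9
        u0 = g.U[:, 0]
        assert np.allclose(u0, u0[0], atol=1e-9)

    def test_eigenvector_sign_convention(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 5)
        for k in range(5):
            j = np.argmax(np.abs(g.U[:, k]))
            assert g.U[j, k] > 0

    def test_asymmetric_adjacency_rejected(self):
        W = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            eg.laplacian(W)


class TestFourier:
    def test_identity_basis_is_identity_transform(self):
        q = np.arange(3.0)
        assert np.array_equal(eg.gft(q, np.eye(3)), q)

    def test_roundtrip_and_parseval(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, 6)
        for q in (rng.standard_normal(6), rng.standard_normal((6, 4))):
            qh = eg.gft(q, g.U)
            assert np.abs(eg.igft(qh, g.U) - q).max() < 1e-10
            assert abs(np.linalg.norm(qh) - np.linalg.norm(q)) < 1e-10

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            eg.gft(np.zeros(4), np.eye(3))


class TestSpectralFilter:
    def test_unit_response_identity(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 3)
        x = rng.standard_normal((3, 5))
        assert np.allclose(eg.spectral_filter(x, lambda l: 1.0, g), x)

    def test_zero_response_annihilates(self):
        g = random_graph(np.random.default_rng(1), 4)
        x = np.random.default_rng(2).standard_normal((4, 2))
        assert np.allclose(eg.spectral_filter(x, lambda l: 0.0, g), 0)

    def test_lambda_response_equals_laplacian_action(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, 5)
        x = rng.standard_normal((5, 3))
        y = eg.spectral_filter(x, lambda l: l, g)
        assert np.abs(y - g.L @ x).max() < 1e-10


class TestChebFilter:
    def test_first_coefficient_only_is_identity(self):
        g = random_graph(np.random.default_rng(0), 3)
        x = np.random.default_rng(1).standard_normal((3, 4))
        assert np.allclose(eg.cheb_filter(x, [1.0], g), x)

    def test_zero_coefficients_annihilate(self):
        g = random_graph(np.random.default_rng(2), 3)
        x = np.random.default_rng(3).standard_normal((3, 4))
        assert np.allclose(eg.cheb_filter(x, [0.0, 0.0, 0.0], g), 0)

    def test_empty_coefficients_rejected(self):
        g = random_graph(np.random.default_rng(2), 3)
        with pytest.raises(ValueError):
            eg.cheb_filter(np.zeros((3, 1)), [], g)

    def test_equals_exact_spectral_path_on_many_random_graphs(self):
        """Chebyshev recurrence path == eigendecomposition path for any
        degree-<K response expressed in the Chebyshev basis."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(500):
            n = int(rng.integers(3, 9))
            g = random_graph(rng, n)
            K = int(rng.integers(1, 6))
            theta = rng.standard_normal(K)
            x = rng.standard_normal((n, 3))
            y_cheb = eg.cheb_filter(x, theta, g)
            lmax = g.lambda_max
            y_exact = eg.spectral_filter(
                x, lambda l: np.polynomial.chebyshev.chebval(
                    2 * l / lmax - 1, theta), g)
            worst = max(worst, float(np.abs(y_cheb - y_exact).max()))
        assert worst < 1e-8

    def test_t_stack_matches_recurrence_filtering(self):
        g = random_graph(np.random.default_rng(9), 4)
        theta = np.array([0.3, -1.2, 0.7])
        T = cheb_t_stack(g, 3)
        x = np.random.default_rng(10).standard_normal((4, 6))
        direct = sum(t * (Tk @ x) for t, Tk in zip(theta, T))
        assert np.allclose(direct, eg.cheb_filter(x, theta, g), atol=1e-12)


class TestBuildAndSerialize:
    def test_build_graph_pipeline(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal(2000)
        sig = np.stack([base + 0.1 * rng.standard_normal(2000),
                        base + 0.1 * rng.standard_normal(2000),
                        rng.standard_normal(2000)])
        g = eg.build_graph(sig, tau=0.3)
        assert g.W[0, 1] > 0.9
        assert g.lam is not None and g.tau == 0.3

    def test_json_roundtrip_bit_exact(self):
        g = eg.build_graph(np.random.default_rng(1).standard_normal((3, 500)),
                           tau=0.2)
        s = graph_to_json(g)
        r = graph_from_json(s)
        assert r.W.tobytes() == g.W.tobytes()
        assert r.tau == g.tau
        assert np.allclose(r.lam, g.lam)

    def test_json_file_roundtrip(self, tmp_path):
        g = eg.laplacian(np.ones((3, 3)) - np.eye(3))
        path = tmp_path / "g.json"
        graph_to_json(g, path)
        r = graph_from_json(path)
        assert np.array_equal(r.W, g.W)
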