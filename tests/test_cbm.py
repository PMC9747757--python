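"""Cortical branching model: wiring, weighting, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from quasicrit import cbm
from quasicrit.errors import InvalidArgumentError


class TestWeightingProbabilities:
    def test_zero_bias_is_homogeneous(self):
        np.testing.assert_allclose(
            cbm.weighting_probabilities(5, 0.0), np.full(5, 0.2)
        )

    def test_single_input_forces_unity(self):
        np.testing.assert_allclose(cbm.weighting_probabilities(1, 3.7), [1.0])

    def test_reference_value_at_bias_1p8(self):
        # e^{-1.8}/sum_{n=1..5} e^{-1.8 n}, computed by hand
        p = cbm.weighting_probabilities(5, 1.8)
        expect = np.exp(-1.8) / np.exp(-1.8 * np.arange(1, 6)).sum()
        assert p[0] == pytest.approx(expect, abs=1e-12)
        assert p[0] == pytest.approx(0.835, abs=5e-4)

    @given(k=hst.integers(1, 20), bias=hst.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_normalised_and_monotone(self, k, bias):
        p = cbm.weighting_probabilities(k, bias)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        if bias > 1e-6:
            assert k == 1 or np.all(np.diff(p) < 0)
        else:
            np.testing.assert_allclose(p, 1.0 / k, atol=1e-6)

    def test_rejects_bad_arguments(self):
        with pytest.raises(InvalidArgumentError):
            cbm.weighting_probabilities(0, 1.0)
        with pytest.raises(InvalidArgumentError):
            cbm.weighting_probabilities(5, -0.1)


class TestBuildNetwork:
    def test_inbound_structure_and_normalisation(self):
        cfg = cbm.CBMConfig(n_nodes=256, k_in=5, kappa=1.07, bias=1.8, seed=3)
        net = cbm.build_network(cfg)
        assert net.in_neighbors.shape == (256, 5)
        for j in range(256):
            srcs = net.in_neighbors[j]
            assert len(set(srcs.tolist())) == 5
            assert j not in srcs
        # unscaled inbound weights sum to one per node; scaled sum to kappa
        np.testing.assert_allclose(
            net.unscaled_in_weights().sum(axis=1), 1.0, atol=1e-12
        )
        np.testing.assert_allclose(net.in_weights.sum(axis=1), 1.07, atol=1e-10)
        assert net.in_weights.max() <= 1.07 + 1e-12

    def test_two_node_network_is_mutual(self):
        cfg = cbm.CBMConfig(n_nodes=2, k_in=1, kappa=1.0, bias=0.0, seed=0)
        net = cbm.build_network(cfg)
        assert net.in_neighbors[0, 0] == 1 and net.in_neighbors[1, 0] == 0
        np.testing.assert_allclose(net.in_weights, 1.0)

    def test_same_seed_reproduces_wiring(self):
        cfg = cbm.CBMConfig(n_nodes=64, k_in=4, seed=9)
        a, b = cbm.build_network(cfg), cbm.build_network(cfg)
        np.testing.assert_array_equal(a.in_neighbors, b.in_neighbors)

    def test_undirected_connectivity(self, small_network):
        _, net = small_network
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n = net.n_nodes
        rows = net.in_neighbors.ravel()
        cols = np.repeat(np.arange(n), net.k_in)
        adj = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
        assert n_comp == 1

    def test_rejects_kin_not_below_n(self):
        with pytest.raises(InvalidArgumentError):
            cbm.CBMConfig(n_nodes=4, k_in=4)


class TestStep:
    def test_all_quiescent_is_absorbing_without_noise(self, small_network):
        _, net = small_network
        rng = np.random.default_rng(0)
        phase = cbm.initial_state(net.n_nodes)
        out = cbm.step(phase, net, p_s=0.0, rng=rng)
        assert not out.any()

    def test_certain_transmission_activates_target(self):
        cfg = cbm.CBMConfig(n_nodes=2, k_in=1, kappa=1.0, bias=0.0, seed=0)
        net = cbm.build_network(cfg)  # mutual wiring with P = 1
        phase = np.array([1, 0], dtype=np.int8)
        out = cbm.step(phase, net, p_s=0.0, rng=np.random.default_rng(0))
        assert out[1] == cbm.ACTIVE

    def test_refractory_node_cannot_reactivate(self):
        cfg = cbm.CBMConfig(n_nodes=2, k_in=1, kappa=1.0, bias=0.0, seed=0)
        net = cbm.build_network(cfg)
        phase = np.array([1, 1], dtype=np.int8)
        # both active with P = 1 and certain spontaneous drive: neither can
        # fire at t+1 because both are refractory
        out = cbm.step(phase, net, p_s=1.0, rng=np.random.default_rng(0), refractory=1)
        assert not (out == cbm.ACTIVE).any()
        out2 = cbm.step(out, net, p_s=1.0, rng=np.random.default_rng(0), refractory=1)
        assert (out2 == cbm.ACTIVE).all()  # refractory expired, noise refires


class TestSimulate:
    def test_zero_noise_from_rest_stays_silent(self):
        cfg = cbm.CBMConfig(n_nodes=16, k_in=3, kappa=0.9, p_s=0.0, seed=1, n_steps=200)
        raster = cbm.simulate(cfg)
        assert raster.data.sum() == 0

    def test_certain_noise_forces_alternation(self):
        # p_s = 1, tau_r = 1: after onset every node alternates
        # active/refractory, so the activity density settles at 1/2
        cfg = cbm.CBMConfig(
            n_nodes=3, k_in=2, kappa=0.0, p_s=1.0, refractory=1, seed=5, n_steps=400
        )
        raster = cbm.simulate(cfg)
        rho = raster.counts()[10:] / 3
        assert rho.mean() == pytest.approx(0.5, abs=1e-6)
        # alternation: consecutive steps are complementary per node
        assert not (raster.data[:, 10:-1] & raster.data[:, 11:]).any()

    def test_identical_seed_gives_identical_raster(self):
        cfg = cbm.CBMConfig(n_nodes=32, k_in=3, kappa=1.0, bias=0.4, seed=8, n_steps=2000)
        a, b = cbm.simulate(cfg), cbm.simulate(cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_reference_conditions_produce_intermittent_activity(self):
        cfg = cbm.CBMConfig(kappa=1.07, bias=1.8, seed=2, n_steps=50_000)
        counts = cbm.simulate_counts(cfg, burn_in=1000)
        occupied = (counts > 0).mean()
        # activity is nearly sustained but still punctuated by silent bins
        # (avalanche boundaries), and far from all-node saturation
        assert 0.5 < occupied < 1.0
        assert (counts == 0).sum() > 10
        assert counts.max() > 10
        assert counts.mean() / cfg.n_nodes < 0.5

    def test_counts_match_full_raster(self):
        cfg = cbm.CBMConfig(n_nodes=32, k_in=3, kappa=1.0, bias=0.4, seed=8, n_steps=2000)
        raster = cbm.simulate(cfg)
        counts = cbm.simulate_counts(cfg, burn_in=0)
        np.testing.assert_array_equal(raster.counts(), counts)


class TestDynamicsProperties:
    def test_branching_process_mean_size(self):
        # subcritical single-seed avalanches follow the Galton-Watson
        # closed form 1/(1-kappa) when collisions are rare
        cfg = cbm.CBMConfig(n_nodes=2048, k_in=5, kappa=0.8, p_s=0.0, bias=0.0, seed=6)
        sizes = cbm.seeded_avalanche_sizes(cfg, 10_000)
        assert sizes.mean() == pytest.approx(5.0, rel=0.05)

    def test_more_noise_concatenates_avalanches(self):
        # raising p_s merges formerly distinct avalanches, so the mean
        # avalanche duration cannot decrease
        from quasicrit.avalanches import extract_avalanches

        means = []
        for p_s in (1e-4, 1e-2):
            cfg = cbm.CBMConfig(kappa=1.0, bias=0.6, p_s=p_s, seed=13, n_steps=300_000)
            counts = cbm.simulate_counts(cfg)
            means.append(extract_avalanches(counts).durations.mean())
        assert means[1] >= means[0]

    def test_susceptibility_peak_shifts_left_with_noise(self):
        grid = np.round(np.arange(0.94, 1.14, 0.03), 3)
        stars = []
        for p_s in (1e-3, 1e-2):
            cfg = cbm.CBMConfig(bias=1.8, p_s=p_s, seed=17, n_steps=150_000)
            stars.append(cbm.kappa_sweep(cfg, grid, reps=2).kappa_star_quadratic)
        assert stars[0] > stars[1]

    def test_sweep_rejects_empty_grid(self):
        with pytest.raises(InvalidArgumentError):
            cbm.kappa_sweep(cbm.CBMConfig(), [], reps=1)
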