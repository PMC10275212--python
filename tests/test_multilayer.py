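"""Supra-adjacency assembly and single/multilayer centralities."""

import numpy as np
import pytest
from scipy.linalg import eigh

from brainmux.atlas import make_atlas
from brainmux.backbone import BackboneGraph, mst_backbone
from brainmux.connectivity import ConnectivityMatrix
from brainmux.multilayer import (
    build_supra_adjacency,
    multilayer_degree,
    multilayer_ec,
    single_layer_ec,
    subnetwork_mean,
)

from conftest import random_connectivity


def random_tree(n, rng, labels=()):
    """Random spanning tree adjacency from a random Prüfer-like attachment."""
    adj = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    for k in range(1, n):
        parent = order[rng.integers(0, k)]
        adj[order[k], parent] = adj[parent, order[k]] = 1
    return BackboneGraph(adj, region_labels=labels)


def star(n):
    adj = np.zeros((n, n), dtype=np.int8)
    adj[0, 1:] = adj[1:, 0] = 1
    return BackboneGraph(adj)


def path(n):
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return BackboneGraph(adj)


class TestBuildSupra:
    def test_multiplex_edge_counts_197(self, rng):
        layers = [random_tree(197, rng) for _ in range(8)]
        supra = build_supra_adjacency(layers)
        assert supra.intralayer_edge_count() == 8 * 196 == 1568
        assert supra.interlayer_edge_count() == 197 * 28 == 5516

    def test_single_layer_supra_equals_layer(self, rng):
        layer = random_tree(9, rng)
        supra = build_supra_adjacency([layer])
        assert np.array_equal(supra.matrix.toarray(), layer.adjacency.astype(float))

    def test_symmetric_with_zero_diagonal(self, rng):
        supra = build_supra_adjacency([random_tree(7, rng) for _ in range(3)])
        dense = supra.matrix.toarray()
        assert np.array_equal(dense, dense.T)
        assert np.all(np.diag(dense) == 0)

    def test_offdiagonal_blocks_are_scaled_identity(self, rng):
        omega = 0.7
        supra = build_supra_adjacency([random_tree(6, rng) for _ in range(3)],
                                      interlayer_weight=omega)
        dense = supra.matrix.toarray()
        block = dense[0:6, 6:12]
        assert np.array_equal(block, omega * np.eye(6))

    def test_chain_coupling_only_consecutive(self, rng):
        supra = build_supra_adjacency([random_tree(5, rng) for _ in range(3)],
                                      coupling="chain")
        dense = supra.matrix.toarray()
        assert np.all(dense[0:5, 10:15] == 0)  # layers 0 and 2 uncoupled
        assert np.array_equal(dense[0:5, 5:10], np.eye(5))

    def test_mismatched_layer_sizes_rejected(self, rng):
        with pytest.raises(ValueError, match="same region"):
            build_supra_adjacency([random_tree(5, rng), random_tree(6, rng)])


class TestMultilayerEC:
    def test_identical_layers_reproduce_single_layer_ec(self, rng):
        layer = random_tree(12, rng)
        supra = build_supra_adjacency([layer] * 4)
        ml = multilayer_ec(supra)
        sl = single_layer_ec(layer)
        cos = ml.scores @ sl.scores / (np.linalg.norm(ml.scores) * np.linalg.norm(sl.scores))
        assert cos == pytest.approx(1.0, abs=1e-9)
        # eigenvalue relation for A (x) uniform coupling: lam + omega*(L-1)
        assert ml.eigenvalue == pytest.approx(sl.eigenvalue + 3.0, abs=1e-8)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        # random multiplexes with L*N <= 60, checked entrywise at 1e-9
        for L, n in [(2, 5), (3, 10), (4, 15), (6, 10)]:
            layers = [random_tree(n, rng) for _ in range(L)]
            supra = build_supra_adjacency(layers)
            ml = multilayer_ec(supra)
            dense = supra.matrix.toarray()
            vals, vecs = eigh(dense)
            v = vecs[:, -1]
            v = np.abs(v) / np.linalg.norm(v)  # Perron vector is signless
            expected = v.reshape(L, n).mean(axis=0)
            assert ml.scores == pytest.approx(expected, abs=1e-9)
            assert ml.eigenvalue == pytest.approx(vals[-1], abs=1e-9)

    def test_star_plus_path_small_case(self):
        supra = build_supra_adjacency([star(5), path(5)])
        ml = multilayer_ec(supra)
        dense = supra.matrix.toarray()
        _, vecs = eigh(dense)
        v = np.abs(vecs[:, -1])
        v /= np.linalg.norm(v)
        assert ml.scores == pytest.approx(v.reshape(2, 5).mean(axis=0), abs=1e-9)

    def test_permutation_equivariance(self, rng):
        layers = [random_tree(8, rng) for _ in range(3)]
        perm = rng.permutation(8)
        permuted = [BackboneGraph(l.adjacency[np.ix_(perm, perm)]) for l in layers]
        a = multilayer_ec(build_supra_adjacency(layers)).scores
        b = multilayer_ec(build_supra_adjacency(permuted)).scores
        assert a[perm] == pytest.approx(b, abs=1e-9)

    def test_strictly_positive_on_connected_supra(self, rng):
        supra = build_supra_adjacency([random_tree(10, rng) for _ in range(4)])
        assert np.all(multilayer_ec(supra).scores > 0)

    def test_disconnected_supra_rejected(self):
        # omega = 0 leaves the two layers as disconnected components
        supra = build_supra_adjacency([path(4), path(4)], interlayer_weight=0.0)
        with pytest.raises(ValueError, match="disconnected"):
            multilayer_ec(supra)


class TestSingleLayerEC:
    def test_star_closed_form(self):
        n = 9
        cv = single_layer_ec(star(n))
        assert cv.scores[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert cv.scores[1:] == pytest.approx(
            np.full(n - 1, 1 / np.sqrt(2 * (n - 1))), abs=1e-9)

    def test_cycle_is_uniform(self):
        n = 8
        adj = np.zeros((n, n))
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1.0
        cv = single_layer_ec(ConnectivityMatrix(adj))
        assert cv.scores == pytest.approx(np.full(n, 1 / np.sqrt(n)), abs=1e-9)

    def test_matches_power_iteration_oracle(self, rng):
        m = random_connectivity(12, rng)
        cv = single_layer_ec(m)
        v = np.full(12, 1 / np.sqrt(12))
        for _ in range(10_000):
            v_new = m.weights @ v
            v_new /= np.linalg.norm(v_new)
            if np.max(np.abs(v_new - v)) < 1e-14:
                v = v_new
                break
            v = v_new
        assert cv.scores == pytest.approx(v, abs=1e-9)

    def test_disconnected_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            single_layer_ec(ConnectivityMatrix(w))


class TestMultilayerDegree:
    def test_total_degree_is_twice_layers_times_edges(self, rng):
        L, n = 5, 11
        supra = build_supra_adjacency([random_tree(n, rng) for _ in range(L)])
        deg = multilayer_degree(supra)
        assert deg.scores.sum() == 2 * L * (n - 1)

    def test_single_layer_reduces_to_ordinary_degree(self, rng):
        layer = random_tree(9, rng)
        supra = build_supra_adjacency([layer])
        assert np.array_equal(multilayer_degree(supra).scores,
                              layer.adjacency.sum(axis=1))

    def test_all_layer_leaf_scores_l(self):
        # node 4 is a leaf in every star layer centred elsewhere
        layers = []
        for centre in (0, 1, 2):
            adj = np.zeros((5, 5), dtype=np.int8)
            for k in range(5):
                if k != centre:
                    adj[centre, k] = adj[k, centre] = 1
            layers.append(BackboneGraph(adj))
        deg = multilayer_degree(build_supra_adjacency(layers))
        assert deg.scores[4] == 3

    def test_interlayer_inclusion_adds_constant_shift(self, rng):
        supra = build_supra_adjacency([random_tree(6, rng) for _ in range(3)])
        base = multilayer_degree(supra).scores
        incl = multilayer_degree(supra, include_interlayer=True).scores
        assert incl - base == pytest.approx(np.full(6, 6.0))  # L*(L-1) = 6


class TestSubnetworkMean:
    def test_uniform_scores_return_constant(self, atlas21):
        from brainmux.multilayer import CentralityVector
        cv = CentralityVector(np.full(21, 0.37), "ec_single_mst")
        for label in atlas21.labels:
            assert subnetwork_mean(cv, atlas21, label) == pytest.approx(0.37)

    def test_two_element_mean(self):
        from brainmux.atlas import AtlasMapping
        from brainmux.multilayer import CentralityVector
        mapping = AtlasMapping(("a", "b", "c"), ("FPN", "FPN", "DMN"))
        cv = CentralityVector(np.array([0.2, 0.4, 0.9]), "ec_multilayer")
        assert subnetwork_mean(cv, mapping, "FPN") == pytest.approx(0.3)

    def test_matches_mask_dot_product_oracle(self, rng, atlas21):
        from brainmux.multilayer import CentralityVector
        scores = rng.uniform(0, 1, 21)
        cv = CentralityVector(scores, "ec_multilayer")
        mask = atlas21.fpn_mask
        assert subnetwork_mean(cv, atlas21, "FPN") == pytest.approx(
            scores @ mask / mask.sum())

    def test_linear_in_centrality_vector(self, rng, atlas21):
        from brainmux.multilayer import CentralityVector
        a = rng.uniform(0, 1, 21)
        b = rng.uniform(0, 1, 21)
        va = subnetwork_mean(CentralityVector(a, "x"), atlas21, "DMN")
        vb = subnetwork_mean(CentralityVector(b, "x"), atlas21, "DMN")
        vab = subnetwork_mean(CentralityVector(2 * a + 3 * b, "x"), atlas21, "DMN")
        assert vab == pytest.approx(2 * va + 3 * vb)

    def test_missing_subnetwork_rejected(self, atlas21):
        from brainmux.multilayer import CentralityVector
        cv = CentralityVector(np.ones(21), "x")
        with pytest.raises(KeyError):
            subnetwork_mean(cv, atlas21, "NOPE")
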