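"""Feature kernels, normalisation, fusion and nonnegative weight fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ennrl import (
    AdjacencyMatrix,
    FeatureKernel,
    KernelWeights,
    fuse_kernels,
    jaccard_kernel,
    load_kernel_matrix,
    normalize_kernel,
    optimize_weights,
    save_kernel_matrix,
    shared_neighbors_kernel,
    to_adjacency,
)
from ennrl.network import network_from_edges

from .conftest import random_adjacency


def random_kernel(m: int, seed: int, name: str = "K") -> FeatureKernel:
    rng = np.random.default_rng(seed)
    v = rng.random((m, m))
    return FeatureKernel((v + v.T) / 2.0, tuple(f"n{i}" for i in range(m)), name)


def random_gtn(m: int, seed: int, p: float = 0.3) -> AdjacencyMatrix:
    return AdjacencyMatrix(random_adjacency(m, p, seed), tuple(f"n{i}" for i in range(m)))


class TestJaccard:
    def test_partial_overlap(self):
        # neighbors(i)={a,b,c}, neighbors(j)={b,c,d} -> 2/4
        net = network_from_edges(
            list("ijabcd"),
            [("i", "a"), ("i", "b"), ("i", "c"), ("j", "b"), ("j", "c"), ("j", "d")],
        )
        K = jaccard_kernel(net)
        i, j = net.nodes.index("i"), net.nodes.index("j")
        assert K.values[i, j] == pytest.approx(0.5)

    def test_identical_neighborhoods(self):
        net = network_from_edges("abcd", [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")])
        K = jaccard_kernel(net)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_neighborhoods(self):
        net = network_from_edges("abcd", [("a", "b"), ("c", "d")])
        K = jaccard_kernel(net)
        assert K.values[0, 2] == 0.0

    def test_diagonal_convention(self):
        net = network_from_edges("abc", [("a", "b")])
        K = jaccard_kernel(net)
        assert K.values[0, 0] == 1.0  # has a neighbour
        assert K.values[2, 2] == 0.0  # isolated

    def test_symmetric(self, synthetic_net):
        K = jaccard_kernel(synthetic_net).values
        assert np.abs(K - K.T).max() == 0.0


class TestSharedNeighbors:
    def test_degree_sum_ordering(self):
        # degrees: a=1, b=2, c=2, d=1 on the path a-b-c-d
        net = network_from_edges("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        K = shared_neighbors_kernel(net).values
        # raw degree sums: (b,c)=4 is the max -> 1 after min-max scaling
        assert K[1, 2] == pytest.approx(1.0)
        assert K[0, 3] < K[0, 1] < K[1, 2]

    def test_max_entry_is_one_after_normalization(self, synthetic_net):
        K = shared_neighbors_kernel(synthetic_net).values
        assert K.max() == pytest.approx(1.0)

    def test_all_isolated_gives_zeros(self):
        net = network_from_edges("ab", [])
        assert np.array_equal(shared_neighbors_kernel(net).values, np.zeros((2, 2)))


class TestNormalize:
    def test_affine_map(self):
        v = np.array([[2.0, 4.0], [4.0, 6.0]])
        K = normalize_kernel(FeatureKernel(v, ("a", "b"), "K"))
        assert np.allclose(K.values, (v - 2.0) / 4.0)

    def test_already_unit_range_unchanged(self):
        v = np.array([[0.0, 1.0], [1.0, 0.5]])
        K = normalize_kernel(FeatureKernel(v, ("a", "b"), "K"))
        assert np.array_equal(K.values, v)

    def test_constant_matrix_maps_to_zeros(self):
        K = normalize_kernel(FeatureKernel(np.full((3, 3), 7.0), ("a", "b", "c"), "K"))
        assert np.array_equal(K.values, np.zeros((3, 3)))

    def test_non_finite_rejected(self):
        v = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            normalize_kernel(FeatureKernel(v, ("a", "b"), "K"))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        K = random_kernel(int(np.random.default_rng(seed).integers(2, 10)), seed)
        once = normalize_kernel(K)
        twice = normalize_kernel(once)
        assert np.allclose(once.values, twice.values)


class TestLoadSave:
    def test_round_trip(self, tmp_path):
        K = random_kernel(5, seed=1)
        save_kernel_matrix(K, tmp_path / "k.tsv")
        back = load_kernel_matrix(tmp_path / "k.tsv", K.node_order)
        assert np.allclose(back.values, K.values, atol=1e-9)

    def test_permuted_rows_realigned(self, tmp_path):
        K = random_kernel(4, seed=2)
        perm = [2, 0, 3, 1]
        permuted = FeatureKernel(
            K.values[np.ix_(perm, perm)], tuple(K.node_order[i] for i in perm), "K"
        )
        save_kernel_matrix(permuted, tmp_path / "k.tsv")
        back = load_kernel_matrix(tmp_path / "k.tsv", K.node_order)
        assert np.allclose(back.values, K.values, atol=1e-9)

    def test_unknown_id_named_in_error(self, tmp_path):
        K = random_kernel(3, seed=3)
        save_kernel_matrix(K, tmp_path / "k.tsv")
        with pytest.raises(ValueError, match="n2"):
            load_kernel_matrix(tmp_path / "k.tsv", ("n0", "n1", "nX"))

    def test_gross_asymmetry_rejected(self, tmp_path):
        v = np.array([[0.0, 1.0], [0.5, 0.0]])
        save_kernel_matrix(FeatureKernel(v, ("a", "b"), "K"), tmp_path / "k.tsv")
        with pytest.raises(ValueError, match="asymmetry"):
            load_kernel_matrix(tmp_path / "k.tsv", ("a", "b"))


class TestFusion:
    def test_unit_weight_on_gtn_returns_adjacency(self):
        gtn = random_gtn(6, seed=1)
        ks = [random_kernel(6, seed=2)]
        fused = fuse_kernels(gtn, ks, [1.0, 0.0])
        assert np.array_equal(fused.values, gtn.values)

    def test_two_identical_kernels_halved(self):
        gtn = random_gtn(5, seed=3)
        k = random_kernel(5, seed=4)
        fused = fuse_kernels(gtn, [k, k], [0.0, 0.5, 0.5])
        assert np.allclose(fused.values, k.values)

    def test_equal_weight_mode_is_elementwise_mean(self):
        gtn = random_gtn(5, seed=5)
        ks = [random_kernel(5, seed=6), random_kernel(5, seed=7)]
        fused = fuse_kernels(gtn, ks, "equal")
        mean = (gtn.values + ks[0].values + ks[1].values) / 3.0
        assert np.allclose(fused.values, mean)

    def test_weight_count_mismatch(self):
        gtn = random_gtn(4, seed=8)
        with pytest.raises(ValueError):
            fuse_kernels(gtn, [random_kernel(4, seed=9)], [1.0])

    def test_fusion_linear_in_weights(self):
        gtn = random_gtn(6, seed=10)
        ks = [random_kernel(6, seed=11), random_kernel(6, seed=12)]
        w = np.array([0.2, 0.5, 0.3])
        a = fuse_kernels(gtn, ks, list(3.0 * w))
        b = fuse_kernels(gtn, ks, list(w))
        assert np.allclose(a.values, 3.0 * b.values)


class TestOptimizeWeights:
    def test_planted_mixture_recovered(self):
        gtn = random_gtn(10, seed=20)
        k1, k2 = random_kernel(10, seed=21), random_kernel(10, seed=22)
        target = 0.3 * gtn.values + 0.7 * k1.values + 0.0 * k2.values
        w = optimize_weights(gtn, [k1, k2], target)
        assert w.w0 == pytest.approx(0.3, abs=1e-6)
        assert w.w[0] == pytest.approx(0.7, abs=1e-6)
        assert w.w[1] == pytest.approx(0.0, abs=1e-6)
        assert w.residual < 1e-8

    def test_target_equal_to_gtn(self):
        gtn = random_gtn(8, seed=23)
        ks = [random_kernel(8, seed=24), random_kernel(8, seed=25)]
        w = optimize_weights(gtn, ks, gtn.values)
        assert w.w0 == pytest.approx(1.0, abs=1e-6)
        assert max(w.w) < 1e-6

    def test_residual_matches_grid_search(self):
        """On an unrepresentable target, NNLS residual matches a dense grid
        search over the weight simplex (step 0.01) to 1e-3."""
        m = 6
        gtn = random_gtn(m, seed=26)
        k1 = random_kernel(m, seed=27)
        target = np.random.default_rng(28).random((m, m))
        target = (target + target.T) / 2.0
        w = optimize_weights(gtn, [k1], target)
        grid = np.arange(0.0, 2.0 + 1e-9, 0.01)
        best = min(
            np.sum((w0 * gtn.values + w1 * k1.values - target) ** 2)
            for w0, w1 in itertools.product(grid, grid)
        )
        assert w.residual <= best + 1e-3

    def test_all_zero_kernel_rejected(self):
        gtn = random_gtn(5, seed=29)
        zero = FeatureKernel(np.zeros((5, 5)), gtn.node_order, "zero")
        with pytest.raises(ValueError):
            optimize_weights(gtn, [zero], gtn.values)

    def test_no_kernels_rejected(self):
        gtn = random_gtn(5, seed=30)
        with pytest.raises(ValueError):
            optimize_weights(gtn, [], gtn.values)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_weight_recovery_property(self, seed):
        """Planted nonnegative mixtures are recovered whenever the matrices
        are linearly independent (random kernels almost surely are)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 30))
        n_k = int(rng.integers(1, 5))
        gtn = random_gtn(m, seed=int(rng.integers(2**31)))
        if not np.any(gtn.values):
            gtn = random_gtn(m, seed=0, p=0.5)
        ks = [random_kernel(m, seed=int(rng.integers(2**31)), name=f"K{i}") for i in range(n_k)]
        true = rng.random(n_k + 1)
        target = np.tensordot(true, np.stack([gtn.values] + [k.values for k in ks]), axes=1)
        w = optimize_weights(gtn, ks, target)
        got = np.array([w.w0, *w.w])
        assert np.abs(got - true).max() < 1e-5
        assert w.residual < 1e-8
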