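import numpy as np
import pytest
import scipy.sparse as sp

import rwrmtn as rw
from rwrmtn.networks import HomogeneousNetwork
from rwrmtn.rwr import ConvergenceError


def _iset(pairs):
    return rw.InteractionSet(rw.InteractionRecord(m, g) for m, g in pairs)


def _path_net():
    # mutual path mir-a -- G1 -- mir-b (gene G1 in the middle)
    return rw.build_heterogeneous(_iset([("mir-a", "G1"), ("mir-b", "G1")]), "mutual")


def _edge_net():
    return rw.build_heterogeneous(_iset([("mir-a", "G1")]), "mutual")


def _random_mutual_net(rng, n_mirnas=4, n_genes=5):
    pairs = set()
    while len({m for m, _ in pairs}) < n_mirnas:
        pairs = {
            (f"m{i}", f"G{j}")
            for i in range(n_mirnas)
            for j in range(n_genes)
            if rng.random() < 0.5
        }
    return rw.build_heterogeneous(_iset(pairs), "mutual")


class TestTransitionMatrix:
    def test_equal_split_on_path(self):
        net = _path_net()
        T = rw.transition_matrix(net).toarray()
        mid = net.index("G1")
        a, b = net.index("mir-a"), net.index("mir-b")
        assert T[a, mid] == pytest.approx(0.5)
        assert T[b, mid] == pytest.approx(0.5)
        # columns over nodes with outgoing edges are stochastic
        assert np.allclose(T.sum(axis=0), 1.0)

    def test_weighted_normalization(self):
        # homogeneous triangle-free: a-b weight 1, a-c weight 3 (manual adjacency)
        adj = sp.csr_matrix(np.array([[0, 1, 3], [1, 0, 0], [3, 0, 0]], dtype=float))
        net = HomogeneousNetwork(("a", "b", "c"), adj)
        T = rw.transition_matrix(net).toarray()
        assert T[1, 0] == pytest.approx(0.25)
        assert T[2, 0] == pytest.approx(0.75)

    def test_directed_genes_are_dangling(self):
        net = rw.build_heterogeneous(_iset([("a", "G1"), ("b", "G1")]), "directed")
        T = rw.transition_matrix(net).toarray()
        for g in ("G1",):
            assert T[:, net.index(g)].sum() == 0.0

    def test_edgeless_network_rejected(self):
        empty = HomogeneousNetwork(("a", "b"), sp.csr_matrix((2, 2)))
        with pytest.raises(ValueError, match="no edges"):
            rw.transition_matrix(empty)


class TestSeedVectors:
    def test_uniform_mass(self):
        net = _random_mutual_net(np.random.default_rng(0))
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(net.mirnas)), net)
        assert np.allclose(p0[: net.n_mirnas], 1.0 / net.n_mirnas)
        assert p0.sum() == pytest.approx(1.0)

    def test_absent_seed_renormalized(self):
        net = _path_net()
        p0 = rw.seed_vector_mirna(
            rw.SeedSet(frozenset(["mir-a", "mir-b", "mir-ghost"])), net
        )
        assert p0[net.index("mir-a")] == pytest.approx(0.5)
        assert p0[net.index("mir-b")] == pytest.approx(0.5)
        assert p0.sum() == pytest.approx(1.0)

    def test_single_seed_gets_all_mass(self):
        net = _path_net()
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(["mir-a"])), net)
        assert p0[net.index("mir-a")] == 1.0

    def test_no_present_seed_is_an_error(self):
        net = _path_net()
        with pytest.raises(ValueError, match="empty seed set"):
            rw.seed_vector_mirna(rw.SeedSet(frozenset(["mir-ghost"])), net)

    def test_hetero_split_arithmetic(self):
        net = rw.build_heterogeneous(
            _iset([("m1", "G1"), ("m1", "G2"), ("m2", "G2"), ("m2", "G3")]), "mutual"
        )
        seeds = rw.SeedSet(frozenset(["m1", "m2"]), frozenset(["G1", "G2", "G3"]))
        p0 = rw.seed_vector_hetero(seeds, 0.9, net)
        assert p0[net.index("m1")] == pytest.approx(0.45)
        assert p0[net.index("G1")] == pytest.approx(0.1 / 3)
        assert p0.sum() == pytest.approx(1.0)

    def test_alpha_one_reduces_to_mirna_only(self):
        net = _path_net()
        seeds = rw.SeedSet(frozenset(["mir-a", "mir-b"]))
        hetero = rw.seed_vector_hetero(seeds, 1.0, net)
        mirna_only = rw.seed_vector_mirna(seeds, net)
        assert np.allclose(hetero, mirna_only)

    def test_alpha_zero_puts_all_mass_on_genes(self):
        pairs = [("m1", f"G{j}") for j in range(5)]
        net = rw.build_heterogeneous(_iset(pairs), "mutual")
        p0 = rw.seed_vector_hetero(rw.SeedSet(frozenset(["m1"])), 0.0, net)
        assert np.allclose(p0[net.n_mirnas:], 0.2)
        assert p0[net.index("m1")] == 0.0

    def test_fallback_when_no_seed_gene_present(self):
        net = _path_net()
        seeds = rw.SeedSet(frozenset(["mir-a"]), frozenset(["NOT_A_GENE"]))
        p0 = rw.seed_vector_hetero(seeds, 0.5, net)
        assert p0[net.index("mir-a")] == 1.0  # miRNA-only fallback


class TestRWR:
    def test_gamma_one_returns_seed_vector_in_one_step(self):
        net = _path_net()
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(["mir-a"])), net)
        res = rw.rwr(T, p0, rw.RWRConfig(gamma=1.0))
        assert res.n_iter == 1
        assert np.allclose(res.p, p0)

    @pytest.mark.parametrize("gamma", [0.3, 0.5, 0.7, 0.9])
    def test_two_node_closed_form(self, gamma):
        """Single mutual edge, seed one end: steady seed mass is 1/(2-gamma)."""
        net = _edge_net()
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(["mir-a"])), net)
        res = rw.rwr(T, p0, rw.RWRConfig(gamma=gamma, tol=1e-12))
        assert res.p[net.index("mir-a")] == pytest.approx(1.0 / (2.0 - gamma), abs=1e-9)

    def test_small_gamma_approaches_degree_distribution(self):
        net = _random_mutual_net(np.random.default_rng(3))
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset([net.mirnas[0]])), net)
        # bipartite walks are 2-periodic, so convergence at small gamma is slow
        res = rw.rwr(T, p0, rw.RWRConfig(gamma=1e-3, tol=1e-10, max_iter=60_000))
        deg = np.asarray(net.adjacency.sum(axis=1)).ravel()
        assert np.allclose(res.p, deg / deg.sum(), atol=5e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_matches_direct_linear_solve(self, seed):
        """p_inf agrees with gamma (I - (1-gamma) W')^-1 p0 on <=10-node graphs."""
        rng = np.random.default_rng(seed)
        net = _random_mutual_net(rng)
        assert net.n_nodes <= 10
        gamma, tol = 0.4, 1e-10
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(net.mirnas[:2])), net)
        res = rw.rwr(T, p0, rw.RWRConfig(gamma=gamma, tol=tol))
        exact = gamma * np.linalg.solve(
            np.eye(net.n_nodes) - (1 - gamma) * T.toarray(), p0
        )
        assert np.abs(res.p - exact).max() < 10 * tol

    def test_mass_conserved_every_iteration_on_mutual_network(self):
        net = _random_mutual_net(np.random.default_rng(7))
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset([net.mirnas[0]])), net)
        p = p0.copy()
        for _ in range(60):
            p = 0.5 * (T @ p) + 0.5 * p0
            assert abs(p.sum() - 1.0) < 1e-12

    def test_seed_score_monotone_in_gamma(self):
        for seed in range(4):
            net = _random_mutual_net(np.random.default_rng(seed + 20))
            T = rw.transition_matrix(net)
            p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset([net.mirnas[0]])), net)
            i = net.index(net.mirnas[0])
            prev = -1.0
            for gamma in (0.1, 0.3, 0.5, 0.7, 0.9):
                res = rw.rwr(T, p0, rw.RWRConfig(gamma=gamma, tol=1e-10))
                assert res.p[i] >= prev - 1e-9
                prev = res.p[i]

    def test_relabeling_invariance(self):
        net = _random_mutual_net(np.random.default_rng(11))
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(net.mirnas[:2])), net)
        cfg = rw.RWRConfig(gamma=0.6, tol=1e-12)
        res = rw.rwr(T, p0, cfg)
        perm = np.random.default_rng(1).permutation(net.n_nodes)
        P = sp.csr_matrix((np.ones(len(perm)), (perm, np.arange(len(perm)))))
        res_p = rw.rwr(P @ T @ P.T, np.asarray(P @ p0), cfg)
        assert np.allclose(res_p.p, np.asarray(P @ res.p), atol=1e-9)

    def test_directed_network_traps_walker(self):
        """Directed miRNA->gene edges: non-seed miRNAs stay at zero and mass leaks."""
        iset = _iset([("m1", "G1"), ("m2", "G1"), ("m3", "G2")])
        net = rw.build_heterogeneous(iset, "directed")
        T = rw.transition_matrix(net)
        seeds = rw.SeedSet(frozenset(["m1"]), frozenset(["G1"]))
        p0 = rw.seed_vector_hetero(seeds, 0.9, net)
        res = rw.rwr(T, p0, rw.RWRConfig(gamma=0.7))
        assert res.mass_deficient
        for m in ("m2", "m3"):
            assert res.p[net.index(m)] == 0.0

    def test_non_convergence_is_an_error_with_residual(self):
        net = _path_net()
        T = rw.transition_matrix(net)
        p0 = rw.seed_vector_mirna(rw.SeedSet(frozenset(["mir-a"])), net)
        with pytest.raises(ConvergenceError) as exc:
            rw.rwr(T, p0, rw.RWRConfig(gamma=0.1, tol=1e-12, max_iter=2))
        assert exc.value.residual > 0

    def test_unnormalized_initial_vector_rejected(self):
        net = _path_net()
        T = rw.transition_matrix(net)
        with pytest.raises(ValueError, match="sums to"):
            rw.rwr(T, np.ones(net.n_nodes), rw.RWRConfig())


class TestRankMirnas:
    def test_genes_filtered_and_descending(self):
        net = _path_net()
        p = np.zeros(net.n_nodes)
        p[net.index("mir-a")] = 0.3
        p[net.index("mir-b")] = 0.1
        p[net.index("G1")] = 0.6
        assert rw.rank_mirnas(p, net) == [("mir-a", 0.3), ("mir-b", 0.1)]

    def test_exclusion(self):
        net = _path_net()
        p = np.full(net.n_nodes, 0.25)
        assert rw.rank_mirnas(p, net, exclude={"mir-a"}) == [("mir-b", 0.25)]

    def test_ties_break_lexicographically(self):
        net = rw.build_heterogeneous(
            _iset([("m-z", "G1"), ("m-a", "G1"), ("m-k", "G1")]), "mutual"
        )
        p = np.full(net.n_nodes, 1.0 / net.n_nodes)
        assert [m for m, _ in rw.rank_mirnas(p, net)] == ["m-a", "m-k", "m-z"]
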