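"""Network construction arithmetic, modularity against brute-force double
sums, optimizer vs exhaustive enumeration, z-Rand pair-counting, consensus
and submodule recovery, gamma sweeps, and cross-dataset comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirstage import network as net


def brute_force_modularity(A, labels, gamma):
    n = A.shape[0]
    two_m = A.sum()
    k = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def all_partitions(n):
    """Every set partition of n nodes as a label array (restricted growth)."""
    def rec(prefix, m):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for c in range(m + 1):
            yield from rec(prefix + [c], max(m, c + 1))
    yield from rec([0], 1)


def random_weighted_graph(rng, n, density=0.6):
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    A[A < 1 - density] = 0.0
    np.fill_diagonal(A, 0.0)
    if A.sum() == 0:
        A[0, 1] = A[1, 0] = 1.0
    return A


def pair_count_zrand_oracle(a, b):
    """z-Rand from direct enumeration of all node pairs plus closed moments."""
    nodes = list(a.index)
    n = len(nodes)
    w = sum(1 for i, j in itertools.combinations(nodes, 2)
            if a[i] == a[j] and b[i] == b[j])
    M = n * (n - 1) / 2
    sa = a.value_counts().to_numpy().astype(float)
    sb = b.value_counts().to_numpy().astype(float)
    M1 = (sa * (sa - 1) / 2).sum()
    M2 = (sb * (sb - 1) / 2).sum()
    mu = M1 * M2 / M
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * (sa**3).sum()
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M2 + 4 * (sb**3).sum()
    var = (M / 16 - (4 * M1 - 2 * M) ** 2 * (4 * M2 - 2 * M) ** 2 / (256 * M**2)
           + c1 * c2 / (16 * n * (n - 1) * (n - 2))
           + ((4 * M1 - 2 * M) ** 2 - 4 * c1 - 4 * M)
           * ((4 * M2 - 2 * M) ** 2 - 4 * c2 - 4 * M)
           / (64 * n * (n - 1) * (n - 2) * (n - 3)))
    return (w - mu) / np.sqrt(var)


class TestCorrelationNetwork:
    def test_identical_rows_full_weight(self):
        expr = pd.DataFrame([[1, 2, 3.0], [2, 4, 6.0]], index=["a", "b"])
        cn = net.correlation_network(expr)
        assert cn.adj[0, 1] == pytest.approx(1.0)
        assert cn.adj[0, 0] == 0.0

    def test_anticorrelated_rows_zero_weight(self):
        expr = pd.DataFrame([[1, 2, 3.0], [3, 2, 1.0]], index=["a", "b"])
        assert net.correlation_network(expr).adj[0, 1] == 0.0

    def test_three_node_hand_case(self):
        expr = pd.DataFrame([[0, 1, 2, 3.0], [0, 1, 2, 4.0], [3, 1, 2, 0.0]],
                            index=["a", "b", "c"])
        cn = net.correlation_network(expr)
        expected = np.corrcoef(expr.to_numpy())
        expected = np.maximum(expected, 0)
        np.fill_diagonal(expected, 0)
        assert np.allclose(cn.adj, expected, atol=1e-12)

    def test_constant_row_dropped(self):
        expr = pd.DataFrame([[1, 2, 3.0], [5, 5, 5.0]], index=["a", "b"])
        with pytest.warns(UserWarning):
            cn = net.correlation_network(expr)
        assert cn.nodes == ["a"]


class TestModularity:
    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            A = random_weighted_graph(rng, n)
            labels = rng.integers(0, 3, n)
            gamma = float(rng.uniform(0.2, 2.5))
            assert net.modularity(A, labels, gamma) == pytest.approx(
                brute_force_modularity(A, labels, gamma), abs=1e-12)

    def test_single_community_is_exactly_zero_at_gamma_one(self, rng):
        # sum_ij k_i k_j = (2m)^2, so the null term cancels the edge term
        A = random_weighted_graph(rng, 6)
        assert net.modularity(A, np.zeros(6), 1.0) == pytest.approx(
            brute_force_modularity(A, np.zeros(6), 1.0), abs=1e-12)
        assert net.modularity(A, np.zeros(6), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_closed_form(self, rng):
        A = random_weighted_graph(rng, 6)
        k = A.sum(axis=1)
        expected = -(k**2).sum() / A.sum() ** 2
        assert net.modularity(A, np.arange(6), 1.0) == pytest.approx(expected)

    def test_gamma_zero_one_community_is_unity(self, rng):
        A = random_weighted_graph(rng, 5)
        assert net.modularity(A, np.zeros(5), gamma=0.0) == pytest.approx(1.0)


class TestDetectCommunities:
    def test_two_cliques_split(self):
        A = np.zeros((8, 8))
        for blk in (range(4), range(4, 8)):
            for i in blk:
                for j in blk:
                    if i != j:
                        A[i, j] = 1.0
        A[3, 4] = A[4, 3] = 1.0
        part = net.detect_communities(A, gamma=1.0, seed=0)
        assert part.n_communities == 2
        best = max(net.modularity(A, lab, 1.0) for lab in all_partitions(8))
        assert part.Q == pytest.approx(best, abs=1e-9)

    def test_triangle_single_community(self):
        A = np.ones((3, 3)) - np.eye(3)
        part = net.detect_communities(A, gamma=1.0, seed=0)
        assert part.n_communities == 1
        best = max(net.modularity(A, lab, 1.0) for lab in all_partitions(3))
        assert part.Q == pytest.approx(best, abs=1e-12)

    def test_beats_trivial_baselines(self, rng):
        for seed in range(5):
            A = random_weighted_graph(rng, 15)
            part = net.detect_communities(A, gamma=1.0, seed=seed)
            assert part.Q >= net.modularity(A, np.zeros(15), 1.0) - 1e-12
            assert part.Q >= net.modularity(A, np.arange(15), 1.0) - 1e-12

    def test_deterministic_given_seed(self, rng):
        A = random_weighted_graph(rng, 20)
        p1 = net.detect_communities(A, seed=3)
        p2 = net.detect_communities(A, seed=3)
        assert p1.assignment.equals(p2.assignment) and p1.Q == p2.Q

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            net.detect_communities(np.zeros((0, 0)))


class TestZrand:
    def test_matches_pair_count_oracle(self, rng):
        idx = pd.Index([f"n{i}" for i in range(40)])
        for _ in range(20):
            a = pd.Series(rng.integers(0, 5, 40), index=idx)
            b = pd.Series(rng.integers(0, 3, 40), index=idx)
            got = net.zrand(a, b)
            assert got == pytest.approx(pair_count_zrand_oracle(a, b), abs=1e-10)

    def test_identical_nontrivial_partitions_positive(self):
        idx = pd.Index(range(20))
        a = pd.Series([0] * 10 + [1] * 10, index=idx)
        assert net.zrand(a, a) > 0
        assert net.zrand(a, a) == pytest.approx(pair_count_zrand_oracle(a, a))

    def test_label_invariance(self, rng):
        idx = pd.Index(range(30))
        a = pd.Series(rng.integers(0, 4, 30), index=idx)
        b = pd.Series(rng.integers(0, 4, 30), index=idx)
        remap = a.map({0: 7, 1: 5, 2: 9, 3: 0})
        assert net.zrand(a, b) == pytest.approx(net.zrand(remap, b))

    def test_mismatched_node_sets_rejected(self):
        a = pd.Series([0, 1], index=["x", "y"])
        b = pd.Series([0, 1], index=["x", "z"])
        with pytest.raises(ValueError):
            net.zrand(a, b)

    def test_null_mean_near_zero(self, rng):
        zs = []
        idx = pd.Index(range(60))
        for _ in range(1000):
            a = pd.Series(rng.integers(0, 4, 60), index=idx)
            b = pd.Series(rng.integers(0, 4, 60), index=idx)
            zs.append(net.zrand(a, b))
        assert abs(np.mean(zs)) < 0.1


def planted_block_adjacency(sizes, p_in=0.95, p_out=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    A = np.where(labels[:, None] == labels[None, :], p_in, p_out)
    A = A * rng.uniform(0.8, 1.2, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A, labels


class TestConsensus:
    def test_strong_structure_all_runs_agree(self):
        A, truth = planted_block_adjacency([8, 8], p_in=1.0, p_out=0.01)
        cons = net.consensus_partition(A, n_runs=6, seed=0)
        first = cons.runs[0].assignment
        assert all(r.assignment.equals(first) for r in cons.runs)
        assert np.allclose(cons.mean_z, cons.mean_z[0])

    def test_planted_three_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        A, truth = planted_block_adjacency([12, 10, 8], seed=4)
        cons = net.consensus_partition(A, n_runs=10, seed=1)
        ari = adjusted_rand_score(truth, cons.representative.assignment)
        assert ari >= 0.9

    def test_two_runs_tie_breaks_by_q(self):
        A, _ = planted_block_adjacency([6, 6], seed=2)
        cons = net.consensus_partition(A, n_runs=2, seed=5)
        qs = [r.Q for r in cons.runs]
        assert cons.representative.Q == max(qs)

    def test_single_run_rejected(self):
        A, _ = planted_block_adjacency([4, 4])
        with pytest.raises(ValueError):
            net.consensus_partition(A, n_runs=1)


class TestSubmodules:
    def _expr_two_programs(self):
        rng = np.random.default_rng(8)
        t = np.arange(10, dtype=float)
        rows, names = [], []
        for i in range(6):
            rows.append(t + rng.normal(0, 0.1, 10))
            names.append(f"up{i}")
        for i in range(6):
            rows.append(np.concatenate([t[:5][::-1], t[:5]]) + rng.normal(0, 0.1, 10))
            names.append(f"vee{i}")
        return pd.DataFrame(rows, index=names,
                            columns=[f"s{j}" for j in range(10)])

    def test_two_programs_give_two_lettered_submodules(self):
        expr = self._expr_two_programs()
        cons, labels = net.submodules(expr, expr.index, gamma=1.0, seed=0,
                                      parent_label="2")
        assert set(labels.unique()) == {"2A", "2B"}
        by_prog = labels.groupby(expr.index.str[:2]).nunique()
        assert (by_prog == 1).all()

    def test_tiny_module_single_submodule(self):
        expr = pd.DataFrame(np.tile([1.0, 2, 3, 4], (2, 1)), index=["a", "b"])
        with pytest.warns(UserWarning):
            _, labels = net.submodules(expr, ["a", "b"], parent_label="1")
        assert set(labels) == {"1A"}

    def test_submodules_partition_the_module(self):
        expr = self._expr_two_programs()
        _, labels = net.submodules(expr, expr.index, seed=1)
        assert set(labels.index) == set(expr.index)


class TestGammaSweep:
    def _hierarchy(self):
        n = 24
        A = np.zeros((n, n))
        blocks = [range(0, 6), range(6, 12), range(12, 18), range(18, 24)]
        for b in blocks:
            for i in b:
                for j in b:
                    if i != j:
                        A[i, j] = 1.0
        for x, y in [(0, 1), (2, 3)]:
            for i in blocks[x]:
                for j in blocks[y]:
                    A[i, j] = A[j, i] = 0.55
        for x, y in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            for i in blocks[x]:
                for j in blocks[y]:
                    A[i, j] = A[j, i] = 0.05
        return net.CorrelationNetwork(nodes=list(range(n)), corr=A, adj=A)

    def test_hierarchy_splits_at_high_gamma(self):
        results, report = net.gamma_sweep(self._hierarchy(), gammas=(1.0, 2.5),
                                          n_runs=8, seed=0)
        assert results[0].representative.n_communities == 2
        assert results[1].representative.n_communities == 4
        assert (report["fate"] == "splits").all()

    def test_single_gamma_no_report(self):
        results, report = net.gamma_sweep(self._hierarchy(), gammas=(1.0,),
                                          n_runs=4, seed=0)
        assert len(results) == 1 and report.empty

    def test_increasing_gamma_never_merges_two_cliques(self):
        A = np.zeros((8, 8))
        for blk in (range(4), range(4, 8)):
            for i in blk:
                for j in blk:
                    if i != j:
                        A[i, j] = 1.0
        A[0, 4] = A[4, 0] = 0.5
        k1 = net.detect_communities(A, gamma=1.0, seed=0).n_communities
        k2 = net.detect_communities(A, gamma=2.0, seed=0).n_communities
        assert k2 >= k1 == 2


class TestCompareDatasets:
    def test_identical_partitions_diagonal(self):
        idx = pd.Index([f"n{i}" for i in range(12)])
        p = pd.Series([0] * 6 + [1] * 6, index=idx)
        df, tables = net.compare_datasets({"KR": p, "FDR1": p})
        ct = tables[("KR", "FDR1")]
        assert (ct.to_numpy() * (1 - np.eye(2)) == 0).all()
        assert df["zrand"].iloc[0] > 0

    def test_disjoint_nodes_rejected(self):
        a = pd.Series([0], index=["x"])
        b = pd.Series([0], index=["y"])
        with pytest.raises(ValueError):
            net.compare_datasets({"a": a, "b": b})

    def test_refinement_maps_cleanly(self):
        idx = pd.Index([f"n{i}" for i in range(12)])
        coarse = pd.Series([0] * 6 + [1] * 6, index=idx)
        fine = pd.Series([0] * 3 + [1] * 3 + [2] * 3 + [3] * 3, index=idx)
        _, tables = net.compare_datasets({"coarse": coarse, "fine": fine})
        ct = tables[("coarse", "fine")]
        # each coarse module's shared nodes land wholly inside fine modules
        assert ((ct > 0).sum(axis=0) == 1).all()
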