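"""Unordered-graph clustering: graph construction, merging, combination,
K-selection DP and end-to-end behaviour."""

import itertools
import math

import numpy as np
import pytest

from tecgraph import simulate
from tecgraph.core import (
    EncodingTree,
    EntropyParams,
    WeightedGraph,
    node_entropy,
    node_stats,
    tree_entropy,
    validate_tree,
)
from tecgraph.metrics import adjusted_rand_index
from tecgraph.tec_u import (
    MergeState,
    backtrace_k,
    build_dense_graph,
    build_knn_graph,
    cluster,
    combination_phase,
    contract_graph,
    delta_combine,
    delta_merge,
    init_tree,
    inner_iteration,
    k_selection_dp,
    merging_phase,
)

from conftest import random_symmetric


class TestDenseGraph:
    def test_identical_points_have_weight_one(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        g = build_dense_graph(X, sigma=1.0)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_distance_sigma_sqrt2_gives_inverse_e(self):
        sigma = 0.7
        X = np.array([[0.0], [sigma * math.sqrt(2)]])
        g = build_dense_graph(X, sigma=sigma)
        assert g.weights[0, 1] == pytest.approx(math.exp(-1.0))

    def test_three_point_kernel_oracle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        g = build_dense_graph(X, sigma=1.0)
        for u in range(3):
            for v in range(3):
                d2 = np.sum((X[u] - X[v]) ** 2)
                want = 0.0 if u == v else math.exp(-d2 / 2.0)
                assert g.weights[u, v] == pytest.approx(want)

    def test_default_sigma_is_entrywise_std(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        g = build_dense_graph(X)
        d2 = np.sum((X[0] - X[1]) ** 2)
        want = math.exp(-d2 / (2 * np.std(X) ** 2))
        assert g.weights[0, 1] == pytest.approx(want)

    def test_constant_embedding_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            build_dense_graph(np.ones((5, 2)))


class TestKnnGraph:
    def test_full_k_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        g = build_dense_graph(rng.normal(size=(6, 2)))
        s = build_knn_graph(g, 5)
        assert np.array_equal(s.weights,
                              np.ones((6, 6)) - np.eye(6))

    def test_chain_of_three_k1(self):
        X = np.array([[0.0], [1.0], [2.0]])
        s = build_knn_graph(build_dense_graph(X, sigma=1.0), 1)
        want = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        assert np.array_equal(s.weights, want)

    def test_union_symmetry_binary(self):
        rng = np.random.default_rng(2)
        g = build_dense_graph(rng.normal(size=(15, 2)))
        s = build_knn_graph(g, 3)
        assert np.array_equal(s.weights, s.weights.T)
        assert set(np.unique(s.weights)) <= {0.0, 1.0}
        assert np.all(np.diag(s.weights) == 0)

    def test_k_out_of_range(self):
        g = build_dense_graph(np.array([[0.0], [1.0]]), sigma=1.0)
        with pytest.raises(ValueError):
            build_knn_graph(g, 2)


class TestInitTree:
    def test_singleton_leaves(self, barbell):
        tree = init_tree(barbell)
        assert len(tree.nodes) == 7
        assert validate_tree(tree) == []
        assert tree_entropy(tree, barbell) == 0.0


def state_tree_entropy(state, params):
    """Oracle: rebuild the flat tree and recompute entropy on the working
    graph from scratch."""
    parts = [set(p) for p in state.partition()]
    tree = EncodingTree.from_partition(state.n_vertices, parts)
    return tree_entropy(tree, state.graph, params)


class TestDeltaMerge:
    @pytest.mark.parametrize("seed", range(8))
    def test_incremental_equals_full_recompute(self, seed, params):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        W = (random_symmetric(rng, n) > 0.5).astype(float)
        state = MergeState(WeightedGraph(W))
        for _ in range(12):
            u = int(rng.integers(n))
            cands = [lf for lf in state.cut[u]
                     if lf != state.leaf_of[u] and lf in state.leaf_s
                     and state.cut[u][lf] > 0]
            if not cands:
                continue
            target = cands[int(rng.integers(len(cands)))]
            before = state_tree_entropy(state, params)
            delta = delta_merge(state, u, target, params)
            state.execute_move(u, target)
            after = state_tree_entropy(state, params)
            assert delta == pytest.approx(after - before, abs=1e-10)

    def test_non_neighbor_target_signalled(self, barbell, params):
        state = MergeState(barbell)
        with pytest.raises(ValueError, match="candidate"):
            delta_merge(state, 0, 5, params)

    def test_barbell_singleton_merge_matches_oracle(self, barbell, params):
        state = MergeState(barbell)
        before = state_tree_entropy(state, params)
        delta = delta_merge(state, 2, 0, params)
        state.execute_move(2, 0)
        assert delta == pytest.approx(
            state_tree_entropy(state, params) - before)


class TestInnerIteration:
    def test_no_edges_leaves_state_unchanged(self, params):
        state = MergeState(WeightedGraph(np.zeros((4, 4))))
        inner_iteration(state, params)
        assert len(state.members) == 4

    def test_two_triangles_become_two_leaves(self, params):
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            W[a, b] = W[b, a] = 1.0
        state = MergeState(WeightedGraph(W))
        inner_iteration(state, params)
        assert state.partition() == [{0, 1, 2}, {3, 4, 5}]
        # no further single-vertex move lowers entropy (exhaustive check)
        for u in range(6):
            for lf in list(state.cut[u]):
                if lf == state.leaf_of[u] or lf not in state.leaf_s:
                    continue
                assert delta_merge(state, u, lf, params) >= -1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_final_state_has_no_negative_candidate(self, seed, params):
        rng = np.random.default_rng(seed)
        W = (random_symmetric(rng, 10) > 0.6).astype(float)
        state = MergeState(WeightedGraph(W))
        inner_iteration(state, params)
        for u in range(10):
            for lf in list(state.cut[u]):
                if lf == state.leaf_of[u] or lf not in state.leaf_s:
                    continue
                if state.cut[u][lf] > 0:
                    assert delta_merge(state, u, lf, params) >= -1e-12


class TestContractGraph:
    def test_singleton_partition_is_identity(self, barbell):
        g = contract_graph(barbell, [{u} for u in range(6)])
        assert np.array_equal(g.weights, barbell.weights)

    def test_whole_graph_single_vertex_conserves_volume(self, barbell):
        g = contract_graph(barbell, [set(range(6))])
        assert g.weights.shape == (1, 1)
        assert g.total_volume == pytest.approx(barbell.total_volume)

    def test_barbell_by_triangles(self, barbell):
        g = contract_graph(barbell, [{0, 1, 2}, {3, 4, 5}])
        assert g.weights[0, 0] == 6.0 and g.weights[1, 1] == 6.0
        assert g.weights[0, 1] == g.weights[1, 0] == 1.0
        assert g.degrees[0] == 7.0  # per-group volume conserved

    def test_incomplete_partition_rejected(self, barbell):
        with pytest.raises(ValueError):
            contract_graph(barbell, [{0, 1}])


class TestMergingPhase:
    def test_two_blobs_merge_into_pure_leaves(self, params):
        """Merged leaves never mix the two well-separated blobs and are
        substantially coarser than singletons."""
        ds = simulate.simulate_blobs(k=2, per_cluster=15, sd=0.4, seed=1)
        dense = build_dense_graph(ds.data)
        sparse = build_knn_graph(dense, 5)
        tree, ent, multis = merging_phase(sparse, params)
        leaves = [tree.nodes[c].vertex_set for c in tree.root.children]
        assert 2 <= len(leaves) <= 6
        for leaf in leaves:
            assert len({ds.labels[v] for v in leaf}) == 1

    def test_returned_entropy_matches_recompute(self, rng, params):
        W = (random_symmetric(rng, 12) > 0.6).astype(float)
        g = WeightedGraph(W)
        tree, ent, multis = merging_phase(g, params)
        assert ent == pytest.approx(tree_entropy(tree, g, params))

    def test_infinite_threshold_behaves_like_single_round(self, params):
        rng = np.random.default_rng(3)
        W = (random_symmetric(rng, 10) > 0.5).astype(float)
        g = WeightedGraph(W)
        from tecgraph.tec_u import _merge_run
        single = _merge_run(g, params, multis=False, delta_threshold=1e-7)
        multi = _merge_run(g, params, multis=True, delta_threshold=np.inf)
        assert single.partition() == multi.partition()


class TestDeltaCombine:
    def test_two_leaves_covering_v_give_zero(self, barbell, params):
        tree = EncodingTree.from_partition(6, [{0, 1, 2}, {3, 4, 5}])
        c1, c2 = tree.root.children
        assert delta_combine(tree, c1, c2, barbell,
                             params) == pytest.approx(0.0)

    def test_equals_full_recompute_difference(self, rng, params):
        W = random_symmetric(rng, 9)
        g = WeightedGraph(W)
        tree = EncodingTree.from_partition(
            9, [{0, 1}, {2, 3, 4}, {5, 6}, {7, 8}])
        mu, nu = tree.root.children[0], tree.root.children[2]
        before = tree_entropy(tree, g, params)
        delta = delta_combine(tree, mu, nu, g, params)
        # full recompute: same leaves plus parent over mu, nu
        omega = tree.add_child(tree.root_id,
                               tree.nodes[mu].vertex_set
                               | tree.nodes[nu].vertex_set)
        tree.root.children.remove(mu)
        tree.root.children.remove(nu)
        tree.nodes[mu].parent = tree.nodes[nu].parent = omega
        tree.nodes[omega].children = [mu, nu]
        after = tree_entropy(tree, g, params)
        assert delta == pytest.approx(after - before)

    def test_non_root_children_rejected(self, barbell, params):
        tree = EncodingTree.from_partition(6, [{0, 1, 2}, {3, 4, 5}])
        with pytest.raises(ValueError):
            delta_combine(tree, tree.root.children[0],
                          tree.root.children[0], barbell, params)


class TestCombinationPhase:
    def test_two_leaves_give_three_nodes(self, barbell, params):
        tree = EncodingTree.from_partition(6, [{0, 1, 2}, {3, 4, 5}])
        d = combination_phase(tree, barbell, params)
        assert len(d.nodes) == 3 and d.n_leaves == 2

    @pytest.mark.parametrize("l", [1, 2, 3, 5, 8])
    def test_node_count_is_2l_minus_1(self, l, params):
        rng = np.random.default_rng(l)
        n = 2 * l
        W = (random_symmetric(rng, n) > 0.3).astype(float)
        g = WeightedGraph(W)
        parts = [{2 * i, 2 * i + 1} for i in range(l)]
        tree = EncodingTree.from_partition(n, parts)
        d = combination_phase(tree, g, params)
        assert len(d.nodes) == 2 * l - 1
        assert d.nodes[d.root_id].vertex_set == frozenset(range(n))

    def test_dumbbell_pairs_join_first(self, params):
        # two dumbbells: tight pairs (0,1)+(2,3) and (4,5)+(6,7), with the
        # intra-dumbbell bridges much heavier than any cross weight
        W = np.zeros((8, 8))
        for a, b in [(0, 1), (2, 3), (4, 5), (6, 7)]:
            W[a, b] = W[b, a] = 5.0
        W[1, 2] = W[2, 1] = 3.0
        W[5, 6] = W[6, 5] = 3.0
        W[3, 4] = W[4, 3] = 0.1
        g = WeightedGraph(W)
        tree = EncodingTree.from_partition(
            8, [{0, 1}, {2, 3}, {4, 5}, {6, 7}])
        d = combination_phase(tree, g, params)
        internal = [nd for nd in d.nodes if nd.children is not None]
        first_two = {frozenset(nd.vertex_set) for nd in internal[:2]}
        assert first_two == {frozenset({0, 1, 2, 3}),
                             frozenset({4, 5, 6, 7})}


def frontier_oracle(dendro, dense, params, K):
    """Exhaustive minimum over all K-node frontiers (antichains covering
    the root's vertex set) of summed dense-graph node entropies."""
    vol_g = dense.total_volume

    def frontiers(nid):
        nd = dendro.nodes[nid]
        yield (nid,)
        if nd.children is not None:
            a, b = nd.children
            for fa in frontiers(a):
                for fb in frontiers(b):
                    yield fa + fb

    best = None
    for fr in frontiers(dendro.root_id):
        if len(fr) != K:
            continue
        tot = 0.0
        for nid in fr:
            if nid == dendro.root_id:
                continue  # root entropy is 0 by definition
            st = node_stats(dense, dendro.nodes[nid].vertex_set)
            tot += node_entropy(st, vol_g, params)
        if best is None or tot < best[0] - 1e-12:
            best = (tot, fr)
    return best


def random_instance(seed, l):
    rng = np.random.default_rng(seed)
    n = 3 * l
    dense_w = random_symmetric(rng, n)
    dense = WeightedGraph(dense_w)
    sparse = WeightedGraph((dense_w > 0.4).astype(float))
    parts = [set(range(3 * i, 3 * i + 3)) for i in range(l)]
    tree = EncodingTree.from_partition(n, parts)
    dendro = combination_phase(tree, sparse, EntropyParams())
    return dendro, dense


class TestKSelection:
    def test_root_k1_is_zero(self, params):
        dendro, dense = random_instance(0, 4)
        tables = k_selection_dp(dendro, dense, params, k_max=4)
        assert tables.J[dendro.root_id][1] == 0.0

    def test_single_leaf_dendrogram(self, params):
        dendro, dense = random_instance(1, 1)
        tables = k_selection_dp(dendro, dense, params, k_max=1)
        K, parts = backtrace_k(tables, dendro, mode="fixed", K_fixed=1)
        assert K == 1 and parts[0] == frozenset(range(3))

    @pytest.mark.parametrize("seed,l", [(0, 3), (1, 4), (2, 5), (3, 6)])
    def test_matches_frontier_enumeration(self, seed, l, params):
        dendro, dense = random_instance(seed, l)
        tables = k_selection_dp(dendro, dense, params, k_max=l)
        for K in range(1, l + 1):
            oracle = frontier_oracle(dendro, dense, params, K)
            assert tables.J[dendro.root_id][K] == pytest.approx(oracle[0])
            _, parts = backtrace_k(tables, dendro, mode="fixed", K_fixed=K)
            got = sum(
                node_entropy(node_stats(dense, p), dense.total_volume,
                             params)
                for p in parts) if K > 1 else 0.0
            assert got == pytest.approx(oracle[0])

    @pytest.mark.parametrize("seed,l", [(5, 4), (6, 5)])
    def test_auto_mode_matches_oracle(self, seed, l, params):
        dendro, dense = random_instance(seed, l)
        tables = k_selection_dp(dendro, dense, params, k_max=l)
        K, parts = backtrace_k(tables, dendro, mode="auto")
        best = min(range(1, l + 1),
                   key=lambda k: (round(frontier_oracle(
                       dendro, dense, params, k)[0], 12), k))
        assert K == best

    def test_fixed_extremes(self, params):
        dendro, dense = random_instance(7, 4)
        tables = k_selection_dp(dendro, dense, params, k_max=4)
        _, one = backtrace_k(tables, dendro, mode="fixed", K_fixed=1)
        assert one == [frozenset(range(12))]
        _, all_leaves = backtrace_k(tables, dendro, mode="fixed", K_fixed=4)
        assert sorted(all_leaves, key=min) == [
            frozenset({0, 1, 2}), frozenset({3, 4, 5}),
            frozenset({6, 7, 8}), frozenset({9, 10, 11})]

    def test_unreachable_fixed_k(self, params):
        dendro, dense = random_instance(8, 3)
        tables = k_selection_dp(dendro, dense, params, k_max=10)
        with pytest.raises(ValueError):
            backtrace_k(tables, dendro, mode="fixed", K_fixed=7)


class TestClusterEndToEnd:
    def test_auto_k_two_separated_blobs(self, params):
        ds = simulate.simulate_blobs(k=2, per_cluster=25, sd=0.5, seed=0)
        res = cluster(ds.data, mode="auto", knn_k=8)
        assert res.k == 2
        assert adjusted_rand_index(res.labels, ds.labels) == 1.0

    def test_duplicate_samples_get_identical_labels(self, params):
        ds = simulate.simulate_blobs(k=2, per_cluster=10, sd=0.3, seed=2)
        X = np.vstack([ds.data, ds.data])
        res = cluster(X, mode="fixed", K=2, knn_k=6)
        n = ds.data.shape[0]
        assert np.array_equal(res.labels[:n], res.labels[n:])

    def test_determinism(self):
        ds = simulate.simulate_blobs(k=3, per_cluster=20, sd=0.6, seed=4)
        r1 = cluster(ds.data, mode="auto", knn_k=8, seed=11)
        r2 = cluster(ds.data, mode="auto", knn_k=8, seed=11)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.k == r2.k and r1.entropy == r2.entropy

    def test_label_count_invariant(self):
        ds = simulate.simulate_blobs(k=4, per_cluster=15, sd=0.5, seed=5)
        res = cluster(ds.data, mode="fixed", K=4, knn_k=8)
        assert res.labels.shape == (60,)
        assert len(set(res.labels.tolist())) == res.k == 4
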