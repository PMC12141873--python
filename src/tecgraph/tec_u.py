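"""Agglomerative topology-entropy clustering of unordered graphs (TEC-U).

Samples (rows of a dimension-reduced embedding) are turned into two graphs:
a *dense* graph with Gaussian-kernel weights and a *sparse* binary kNN
graph (edge iff either endpoint is among the other's top-k neighbors).
Clustering proceeds in four steps:

1. initialization — an encoding tree with one singleton leaf per vertex;
2. merging phase — repeatedly relocate the vertex whose move between
   leaves lowers the tree's topology entropy on the sparse graph the most,
   optionally (``multis``) contracting leaves into super-vertices and
   repeating; both variants are run and the lower-entropy one kept;
3. combination phase — greedily pair root children of minimal combination
   delta (connected pairs first) into a full binary dendrogram;
4. K selection — dynamic programming over the dendrogram minimizes the
   summed *dense-graph* node entropy of a K-node frontier, either for a
   user-fixed K or over all K up to ``k_max`` (auto-K).

All tie-breaks use smallest vertex/node ids, so results are deterministic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import EncodingTree, EntropyParams, WeightedGraph

__all__ = [
    "MergeState",
    "Dendrogram",
    "DendrogramNode",
    "KSelectTables",
    "ClusteringResult",
    "build_dense_graph",
    "build_knn_graph",
    "init_tree",
    "delta_merge",
    "inner_iteration",
    "contract_graph",
    "merging_phase",
    "delta_combine",
    "combination_phase",
    "k_selection_dp",
    "backtrace_k",
    "cluster",
]


def _h(s: float, vol: float, vol_g: float, params: EntropyParams) -> float:
    """Topology entropy of one node; 0 at s = 0 or vol = 0."""
    if s <= 0 or vol <= 0:
        return 0.0
    ps = s / vol_g
    pv = vol / vol_g
    val = -(ps ** (params.alpha1 - 1.0)) * (
        math.log(ps) - (1.0 + params.alpha2) * math.log(pv))
    if params.log_base != math.e:
        val /= math.log(params.log_base)
    return val


def build_dense_graph(X: np.ndarray, sigma: float | None = None) -> WeightedGraph:
    """Gaussian-kernel similarity graph over samples.

    ``e(u, v) = exp(-||x_u - x_v||^2 / (2 sigma^2))`` with zero diagonal.
    ``sigma`` defaults to the standard deviation of all entries of X.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("embedding contains non-finite values")
    if sigma is None:
        sigma = float(np.std(X))
    if sigma <= 0:
        raise ValueError(
            "sigma must be positive; a constant embedding has zero spread — "
            "pass an explicit sigma or check the input"
        )
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    W = np.exp(-d2 / (2.0 * sigma ** 2))
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(W)


def build_knn_graph(dense: WeightedGraph, k: int) -> WeightedGraph:
    """Binary kNN graph from the dense similarities, symmetrized by union.

    An edge (u, v) exists iff u is among v's k most similar neighbors or
    vice versa.  Ties at the k-th neighbor are broken toward the smaller
    vertex id.  No self-edges.
    """
    n = dense.n_vertices
    if not (1 <= k < n):
        raise ValueError(f"k must be in [1, {n - 1}]")
    W = dense.weights.copy()
    np.fill_diagonal(W, -np.inf)
    # sort by (descending weight, ascending id): lexsort on (id, -w)
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), -W), axis=1)
    topk = order[:, :k]
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    A[rows, topk.ravel()] = 1.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return WeightedGraph(A)


def init_tree(Gs: WeightedGraph) -> EncodingTree:
    """Root plus one singleton leaf per vertex."""
    return EncodingTree.from_partition(
        Gs.n_vertices, [{u} for u in range(Gs.n_vertices)])


def contract_graph(graph: WeightedGraph, leaf_partition) -> WeightedGraph:
    """Contract each group of the partition into a super-vertex.

    Inter-group weights are summed; intra-group (ordered-pair) weight
    becomes the super-vertex self-loop, so every group's volume and the
    total volume are conserved exactly.
    """
    parts = [sorted(p) for p in leaf_partition]
    n = graph.n_vertices
    seen: set = set()
    for p in parts:
        seen.update(p)
    if len(seen) != n or seen != set(range(n)):
        raise ValueError("partition must cover all vertices disjointly")
    B = np.zeros((n, len(parts)))
    for j, p in enumerate(parts):
        B[p, j] = 1.0
    return WeightedGraph(B.T @ graph.weights @ B)


class MergeState:
    """Mutable state of the merging phase on a (possibly contracted) graph.

    Tracks the current leaf of every vertex, cached (s, vol) per leaf, and
    for every vertex its cut weight to each adjacent leaf, so merge deltas
    are O(1) and the affected set after a move is known exactly.
    ``vertex_map`` maps each working vertex to the original sample ids it
    represents.
    """

    def __init__(self, graph: WeightedGraph, multis: bool = False,
                 delta_threshold: float = 1e-7,
                 vertex_map: list[frozenset] | None = None):
        self.graph = graph
        self.multis = multis
        self.delta_threshold = delta_threshold
        n = graph.n_vertices
        W = graph.weights
        self.vertex_map = (vertex_map if vertex_map is not None
                           else [frozenset([u]) for u in range(n)])
        if len(self.vertex_map) != n:
            raise ValueError("vertex_map must cover all working vertices")
        self.self_w = np.diag(W).copy()
        self.deg = W.sum(axis=1)
        self.vol_g = float(self.deg.sum())
        self.adj: list[tuple[np.ndarray, np.ndarray]] = []
        for u in range(n):
            nb = np.flatnonzero(W[u])
            nb = nb[nb != u]
            self.adj.append((nb, W[u, nb]))
        # one leaf per vertex initially; leaf ids coincide with vertex ids
        self.leaf_of = np.arange(n)
        self.leaf_s = {u: float(self.self_w[u]) for u in range(n)}
        self.leaf_vol = {u: float(self.deg[u]) for u in range(n)}
        self.members: dict[int, set] = {u: {u} for u in range(n)}
        # cut[x][leaf] = weight from x to members of leaf (excluding x)
        self.cut: list[dict] = [dict() for _ in range(n)]
        self.adjacent: dict[int, set] = {u: set() for u in range(n)}
        for u in range(n):
            for v, w in zip(*self.adj[u]):
                lf = int(self.leaf_of[v])
                self.cut[u][lf] = self.cut[u].get(lf, 0.0) + w
                self.adjacent[lf].add(u)

    @property
    def n_vertices(self) -> int:
        return self.graph.n_vertices

    def leaf_entropy(self, leaf: int, params: EntropyParams) -> float:
        return _h(self.leaf_s[leaf], self.leaf_vol[leaf], self.vol_g, params)

    def total_entropy(self, params: EntropyParams) -> float:
        return sum(self.leaf_entropy(lf, params) for lf in self.leaf_s)

    def move_delta(self, u: int, target: int, params: EntropyParams) -> float:
        """Entropy change of relocating vertex u to leaf ``target``."""
        mu = int(self.leaf_of[u])
        if target == mu:
            raise ValueError("vertex already in the target leaf")
        if self.cut[u].get(target, 0.0) <= 0:
            raise ValueError(
                f"leaf {target} holds no neighbor of vertex {u}; "
                "not a merge candidate"
            )
        w_mu = self.cut[u].get(mu, 0.0)
        w_nu = self.cut[u][target]
        s_mu, v_mu = self.leaf_s[mu], self.leaf_vol[mu]
        s_nu, v_nu = self.leaf_s[target], self.leaf_vol[target]
        sw, d = float(self.self_w[u]), float(self.deg[u])
        old = (_h(s_mu, v_mu, self.vol_g, params)
               + _h(s_nu, v_nu, self.vol_g, params))
        new = (_h(s_mu - 2 * w_mu - sw, v_mu - d, self.vol_g, params)
               + _h(s_nu + 2 * w_nu + sw, v_nu + d, self.vol_g, params))
        return new - old

    def best_move(self, u: int, params: EntropyParams):
        """(delta, target) minimizing the move delta for u; None when u
        has no candidate leaf.  Ties go to the smaller leaf id."""
        mu = int(self.leaf_of[u])
        best = None
        for lf in sorted(self.cut[u]):
            if lf == mu or lf not in self.leaf_s:
                continue
            if self.cut[u][lf] <= 0:
                continue
            d = self.move_delta(u, lf, params)
            if best is None or d < best[0]:
                best = (d, lf)
        return best

    def execute_move(self, u: int, target: int) -> set:
        """Relocate u; returns the set of vertices whose best move may
        have changed."""
        mu = int(self.leaf_of[u])
        affected = set(self.members[mu]) | set(self.members[target])
        affected |= self.adjacent[mu] | self.adjacent[target]
        w_mu = self.cut[u].get(mu, 0.0)
        w_nu = self.cut[u][target]
        sw, d = float(self.self_w[u]), float(self.deg[u])
        self.leaf_s[mu] -= 2 * w_mu + sw
        self.leaf_vol[mu] -= d
        self.leaf_s[target] += 2 * w_nu + sw
        self.leaf_vol[target] += d
        self.members[mu].discard(u)
        self.members[target].add(u)
        self.leaf_of[u] = target
        if not self.members[mu]:
            del self.members[mu], self.leaf_s[mu], self.leaf_vol[mu]
            for x in self.adjacent.pop(mu):
                self.cut[x].pop(mu, None)
        for v, w in zip(*self.adj[u]):
            v = int(v)
            if mu in self.leaf_s:
                left = self.cut[v].get(mu, 0.0) - w
                if left <= 1e-12:
                    self.cut[v].pop(mu, None)
                    self.adjacent[mu].discard(v)
                else:
                    self.cut[v][mu] = left
            self.cut[v][target] = self.cut[v].get(target, 0.0) + w
            self.adjacent[target].add(v)
            affected.add(v)
        affected.add(u)
        return affected

    def partition(self) -> list[set]:
        """Current leaf partition as working-vertex sets, ordered by their
        smallest member."""
        return [self.members[lf] for lf in
                sorted(self.members, key=lambda lf: min(self.members[lf]))]

    def to_tree(self) -> EncodingTree:
        """Encoding tree over the original samples (root + merged leaves)."""
        n_orig = sum(len(s) for s in self.vertex_map)
        parts = []
        for grp in self.partition():
            ids: set = set()
            for v in grp:
                ids |= self.vertex_map[v]
            parts.append(ids)
        return EncodingTree.from_partition(n_orig, parts)


def delta_merge(state: MergeState, u: int, target_leaf: int,
                params: EntropyParams = EntropyParams()) -> float:
    """Entropy change of moving vertex u into ``target_leaf`` (must hold a
    sparse-graph neighbor of u)."""
    return state.move_delta(u, target_leaf, params)


def inner_iteration(state: MergeState,
                    params: EntropyParams = EntropyParams()) -> MergeState:
    """Execute globally best negative-delta moves until none remains.

    Each step evaluates, over all vertices, the candidate relocation with
    the smallest entropy delta and executes it when strictly negative.
    Terminates because every executed move strictly lowers the (bounded)
    total entropy.  Empty leaves disappear as a side effect of the moves.
    """
    n = state.n_vertices
    stamp = np.zeros(n, dtype=np.int64)
    heap: list = []
    for u in range(n):
        best = state.best_move(u, params)
        if best is not None:
            heapq.heappush(heap, (best[0], u, best[1], 0))
    while heap:
        delta, u, target, st = heapq.heappop(heap)
        if st != stamp[u]:
            continue
        if delta >= 0:
            break
        if target not in state.leaf_s or state.cut[u].get(target, 0.0) <= 0:
            # stale in content though not in stamp; recompute defensively
            stamp[u] += 1
            best = state.best_move(u, params)
            if best is not None:
                heapq.heappush(heap, (best[0], u, best[1], int(stamp[u])))
            continue
        affected = state.execute_move(u, target)
        for x in affected:
            stamp[x] += 1
            best = state.best_move(x, params)
            if best is not None:
                heapq.heappush(heap, (best[0], x, best[1], int(stamp[x])))
    return state


def _merge_run(Gs: WeightedGraph, params: EntropyParams, multis: bool,
               delta_threshold: float):
    """One merging-phase run for a fixed ``multis`` value."""
    state = MergeState(Gs, multis=multis, delta_threshold=delta_threshold)
    if not multis:
        inner_iteration(state, params)
        return state
    prev = state.total_entropy(params)
    while True:
        inner_iteration(state, params)
        cur = state.total_entropy(params)
        if abs(cur - prev) < delta_threshold:
            return state
        # contract leaves into super-vertices and start a new round
        parts = state.partition()
        if len(parts) == state.n_vertices:
            return state
        new_map = []
        for grp in parts:
            ids: set = set()
            for v in grp:
                ids |= state.vertex_map[v]
            new_map.append(frozenset(ids))
        g2 = contract_graph(state.graph, parts)
        state = MergeState(g2, multis=True, delta_threshold=delta_threshold,
                           vertex_map=new_map)
        prev = cur


def merging_phase(Gs: WeightedGraph,
                  params: EntropyParams = EntropyParams(),
                  delta_threshold: float = 1e-7):
    """Run the merging phase with multis False and True; keep the better.

    Returns ``(tree, total_entropy, multis_used)`` where the tree is a
    flat encoding tree over the original samples and the entropy is the
    topology entropy of that partition on the sparse graph.  Ties prefer
    multis=False.
    """
    best = None
    for multis in (False, True):
        state = _merge_run(Gs, params, multis, delta_threshold)
        ent = state.total_entropy(params)
        if best is None or ent < best[1] - 1e-15:
            best = (state.to_tree(), ent, multis)
    return best


def delta_combine(tree: EncodingTree, mu: int, nu: int, Gs: WeightedGraph,
                  params: EntropyParams = EntropyParams()) -> float:
    """Entropy change of inserting a parent over two root children.

    Computed in full generality as D(omega) + D(mu') + D(nu') - D(mu) -
    D(nu); under this node entropy the children's terms cancel and the
    value reduces to the entropy of the new parent omega.
    """
    root = tree.root
    if mu not in root.children or nu not in root.children or mu == nu:
        raise ValueError("mu and nu must be distinct children of the root")
    from .core import node_entropy, node_stats
    vol_g = Gs.total_volume
    set_mu = tree.nodes[mu].vertex_set
    set_nu = tree.nodes[nu].vertex_set
    h_mu = node_entropy(node_stats(Gs, set_mu), vol_g, params)
    h_nu = node_entropy(node_stats(Gs, set_nu), vol_g, params)
    h_om = node_entropy(node_stats(Gs, set_mu | set_nu), vol_g, params)
    return h_om + h_mu + h_nu - h_mu - h_nu


@dataclass
class DendrogramNode:
    node_id: int
    children: tuple[int, int] | None
    vertex_set: frozenset


@dataclass
class Dendrogram:
    """Full binary tree over the l merged leaves (2l - 1 nodes)."""

    nodes: list[DendrogramNode]
    root_id: int
    n_leaves: int

    def leaves(self) -> list[DendrogramNode]:
        return [nd for nd in self.nodes if nd.children is None]


def combination_phase(tree: EncodingTree, Gs: WeightedGraph,
                      params: EntropyParams = EntropyParams()) -> Dendrogram:
    """Greedily combine root children into a full binary dendrogram.

    At each step the connected pair (sharing at least one sparse-graph
    edge) with the smallest combination delta is joined; when no connected
    pair remains the connectivity constraint is relaxed.  Ties break on
    the smaller node-id pair.
    """
    leaf_sets = sorted(
        (tree.nodes[c].vertex_set for c in tree.root.children),
        key=lambda s: min(s) if s else -1,
    )
    l = len(leaf_sets)
    nodes = [DendrogramNode(i, None, frozenset(s))
             for i, s in enumerate(leaf_sets)]
    if l == 1:
        return Dendrogram(nodes=nodes, root_id=0, n_leaves=1)

    # contracted sparse matrix over current groups
    parts = [sorted(s) for s in leaf_sets]
    n = Gs.n_vertices
    B = np.zeros((n, l))
    for j, p in enumerate(parts):
        B[p, j] = 1.0
    M = B.T @ Gs.weights @ B
    s_arr = np.diag(M).copy()
    vol_arr = M.sum(axis=1)
    vol_g = Gs.total_volume
    active = list(range(l))

    while len(active) > 1:
        ids = np.array(active)
        Ms = M[np.ix_(ids, ids)]
        sp = s_arr[ids][:, None] + s_arr[ids][None, :] + 2 * Ms
        vp = vol_arr[ids][:, None] + vol_arr[ids][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ps = sp / vol_g
            pv = vp / vol_g
            h = -(ps ** (params.alpha1 - 1.0)) * (
                np.log(ps) - (1.0 + params.alpha2) * np.log(pv))
        h[(sp <= 0) | (vp <= 0)] = 0.0
        if params.log_base != math.e:
            h /= math.log(params.log_base)
        m = len(ids)
        iu = np.triu_indices(m, k=1)
        deltas = h[iu]
        connected = (Ms[iu] > 0)
        pool = np.flatnonzero(connected)
        if pool.size == 0:
            pool = np.arange(deltas.size)
        pick = pool[int(np.argmin(deltas[pool]))]
        i_loc, j_loc = iu[0][pick], iu[1][pick]
        a, b = int(ids[i_loc]), int(ids[j_loc])

        new_id = len(nodes)
        nodes.append(DendrogramNode(
            new_id, (a, b), nodes[a].vertex_set | nodes[b].vertex_set))
        # grow M/s/vol for the new super-node
        row = M[a] + M[b]
        M = np.pad(M, ((0, 1), (0, 1)))
        M[new_id, :new_id] = row
        M[:new_id, new_id] = row
        M[new_id, new_id] = s_arr[a] + s_arr[b] + 2 * M[a, b]
        s_arr = np.append(s_arr, M[new_id, new_id])
        vol_arr = np.append(vol_arr, vol_arr[a] + vol_arr[b])
        active = [x for x in active if x not in (a, b)] + [new_id]

    return Dendrogram(nodes=nodes, root_id=active[0], n_leaves=l)


@dataclass
class KSelectTables:
    """DP tables over the dendrogram: J[node][K] = minimal summed
    dense-graph entropy of a K-node frontier below the node; Kc stores the
    chosen split, I the child pair."""

    J: dict[int, np.ndarray]
    Kc: dict[int, np.ndarray]
    I: dict[int, tuple[int, int] | None]
    k_max: int
    node_entropy: dict[int, float] = field(default_factory=dict)


def k_selection_dp(dendrogram: Dendrogram, dense: WeightedGraph,
                   params: EntropyParams = EntropyParams(),
                   k_max: int = 50) -> KSelectTables:
    """Fill the K-selection DP tables on the dense graph.

    ``J(node, 1)`` is the node's own dense-graph entropy (0 for the root,
    whose entropy is 0 by definition); for K >= 2 the node's subtree is
    split into K' and K - K' frontiers over its two children.  Leaves
    admit only K = 1.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, dendrogram.n_leaves)
    vol_g = dense.total_volume
    degs = dense.degrees

    ent: dict[int, float] = {}
    for nd in dendrogram.nodes:
        idx = np.fromiter(nd.vertex_set, dtype=np.int64)
        s = float(dense.weights[np.ix_(idx, idx)].sum())
        vol = float(degs[idx].sum())
        ent[nd.node_id] = _h(s, vol, vol_g, params)
    ent[dendrogram.root_id] = 0.0

    J: dict[int, np.ndarray] = {}
    Kc: dict[int, np.ndarray] = {}
    I: dict[int, tuple[int, int] | None] = {}

    def fill(nid: int):
        nd = dendrogram.nodes[nid]
        arr = np.full(k_max + 1, np.inf)
        cut = np.zeros(k_max + 1, dtype=np.int64)
        arr[1] = ent[nid]
        cut[1] = 1
        I[nid] = nd.children
        if nd.children is not None:
            a, b = nd.children
            fill(a)
            fill(b)
            for K in range(2, k_max + 1):
                best, best_kp = np.inf, 0
                for kp in range(1, K):
                    if kp > k_max or K - kp > k_max:
                        continue
                    v = J[a][kp] + J[b][K - kp]
                    if v < best:
                        best, best_kp = v, kp
                arr[K] = best
                cut[K] = best_kp
        J[nid] = arr
        Kc[nid] = cut

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * len(dendrogram.nodes) + 100))
    try:
        fill(dendrogram.root_id)
    finally:
        sys.setrecursionlimit(old)
    return KSelectTables(J=J, Kc=Kc, I=I, k_max=k_max, node_entropy=ent)


def backtrace_k(tables: KSelectTables, dendrogram: Dendrogram,
                mode: str = "auto", K_fixed: int | None = None):
    """Select K and recover the corresponding frontier partition.

    Auto mode minimizes J(root, K) over K = 1..k_max (ties to the smallest
    K); fixed mode starts from J(root, K_fixed).  The descent follows the
    stored child pairs and split values, stopping at nodes assigned K = 1,
    whose vertex sets are the clusters.
    """
    root = dendrogram.root_id
    if mode == "auto":
        vals = tables.J[root][1:]
        K = int(np.argmin(vals)) + 1
    elif mode == "fixed":
        if K_fixed is None or not (1 <= K_fixed <= tables.k_max):
            raise ValueError(f"fixed K must be in [1, {tables.k_max}]")
        if not np.isfinite(tables.J[root][K_fixed]):
            raise ValueError(f"K={K_fixed} is unreachable on this dendrogram")
        K = int(K_fixed)
    else:
        raise ValueError("mode must be 'auto' or 'fixed'")

    clusters: list[frozenset] = []

    def descend(nid: int, k: int):
        if k == 1:
            clusters.append(dendrogram.nodes[nid].vertex_set)
            return
        a, b = tables.I[nid]
        kp = int(tables.Kc[nid][k])
        descend(a, kp)
        descend(b, k - kp)

    descend(root, K)
    clusters.sort(key=min)
    return K, clusters


@dataclass
class ClusteringResult:
    """TEC-U output: labels per sample, selected K, dense-graph topology
    entropy of the selected frontier, dendrogram, mode and multis used."""

    labels: np.ndarray
    k: int
    entropy: float
    clusters: list[frozenset]
    dendrogram: Dendrogram
    mode: str
    multis: bool
    merge_entropy: float


def cluster(X: np.ndarray, mode: str = "auto", K: int | None = None,
            params: EntropyParams = EntropyParams(), knn_k: int = 15,
            k_max: int = 50, sigma: float | None = None,
            delta_threshold: float = 1e-7, seed: int = 0) -> ClusteringResult:
    """End-to-end TEC-U clustering of an embedding matrix.

    The pipeline is deterministic given its inputs (``seed`` is accepted
    for interface uniformity; no stage draws random numbers).
    """
    X = np.asarray(X, dtype=float)
    dense = build_dense_graph(X, sigma=sigma)
    knn_k = min(knn_k, dense.n_vertices - 1)
    sparse = build_knn_graph(dense, knn_k)
    tree, merge_ent, multis = merging_phase(sparse, params, delta_threshold)
    dendro = combination_phase(tree, sparse, params)
    tables = k_selection_dp(dendro, dense, params, k_max=k_max)
    k_sel, clusters = backtrace_k(tables, dendro, mode=mode, K_fixed=K)
    labels = np.empty(X.shape[0], dtype=np.int64)
    for lab, cl in enumerate(clusters):
        labels[np.fromiter(cl, dtype=np.int64)] = lab
    return ClusteringResult(
        labels=labels, k=k_sel,
        entropy=float(tables.J[dendro.root_id][k_sel]),
        clusters=clusters, dendrogram=dendro, mode=mode, multis=multis,
        merge_entropy=merge_ent,
    )
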