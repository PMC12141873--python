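# Methods

## The topology-entropy objective

Let `G = (V, E, w)` be an undirected graph with non-negative weights.  For
a vertex subset `U` define, over *ordered* vertex pairs,

* `s(U) = Σ_{u,v ∈ U} w(u,v)` — internal weight (each undirected edge
  counted twice, a self-loop once),
* `vol(U) = Σ_{u ∈ U} deg(u)` — volume,
* `g(U) = vol(U) − s(U)` — boundary weight,

and write `p = s/vol(G)`, `q = vol/vol(G)`.  Under the configuration-model
null a random edge has both endpoints in `U` with probability `q²`, so
`p/q²` measures how much denser than chance the set is — the quantity
behind modularity and behind the KL divergence between the edge-joint
distribution of a partition and its degree-product null.

An *encoding tree* is a rooted tree whose root encodes `V`, whose
children partition their parent's set, and whose leaves disjointly cover
`V`.  Each non-root node `μ` contributes the tempered negative-divergence
term

```
H(μ) = −p^(α1−1) · [ log p − (1+α2) · log q ]
     = −p^(α1−1) · log( p / q^(1+α2) )
```

and the topology entropy of the tree is the sum of `H` over its non-root
nodes (the root scores 0).  Every algorithm in the package **minimizes**
this sum.  A set denser than the tempered null (`p > q^(1+α2)`)
contributes a negative reward; a sparser-than-chance set a positive
penalty; the trivial one-cluster tree and an all-singleton tree on a
loop-free graph both score 0, so the minimizer is pushed toward genuine
block structure and nothing else.

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `alpha1` | 2.0 | weight exponent: each node is weighted by `p^(α1−1)`; 2.0 is the plain KL weight `p`.  Must exceed 1 so the `s → 0` limit of `H` is 0. |
| `alpha2` | 0.85 | null tempering: the null exponent is `1 + α2`; 1.0 recovers the pure degree-product null `q²`.  Values slightly below 1 damp the resolution bias of the untempered null and were the most noise-robust setting in the simulation sweeps below. |
| `log_base` | e | rescales all entropies by `1/log(base)`; never changes an argmin, which the test suite asserts. |

The ordered-pair convention makes `vol = g + s` exact and survives
super-vertex contraction: contracting a vertex group into one vertex with
a self-loop carrying its internal weight preserves `s`, `vol` and
`vol(G)` for every union of groups, which both algorithms rely on.

## TEC-O: exact segmentation of ordered graphs

A Hi-C contact map is an ordered graph; admissible domains are runs of
consecutive bins.  With 2-D prefix sums every segment's `(s, vol)` is an
O(1) query, and the optimal division of the first `i` bins into `k`
segments satisfies

```
D(i, k) = min_{i' < i} [ D(i', k−1) + H(i'+1 : i) ],   D(i, 1) = H(1 : i)
```

The table is filled for all `k` (vectorized over split positions), the
domain count is chosen as `k* = argmin_{2 ≤ k ≤ n−1} D(n, k)` — `k = 1`
and `k = n` mean "no partitioning" and are excluded — and the segmentation
is recovered by backtracing.  Ties are broken toward the smallest split
index and then the smallest `k`, with a relative tolerance of 1e-9 so that
uniformly rescaling the matrix (which leaves all `p`, `q` unchanged)
cannot flip a tie through float rounding; the output is fully
deterministic and scale-invariant.

Sub-TADs are called by recursing on the raw sub-matrix of each domain
with at least `min_size` bins (default 5 — domains of "a few bins" are
left alone) up to `max_levels` (default 2).  The matrix diagonal is kept
as self-loop weight by default (`--zero-diagonal` removes it).

Complexity is O(n²) per `k`; a 100-bin matrix with the full `k` range
takes milliseconds.

## TEC-U: agglomerative clustering of unordered graphs

Input is a samples × dimensions embedding `X` (dimensionality reduction
is the caller's responsibility; UMAP/PCA output is the expected input).
Two graphs are built:

* **dense**: Gaussian kernel `e(u,v) = exp(−‖x_u − x_v‖² / 2σ²)`, zero
  diagonal, with `σ` defaulting to the standard deviation of all entries
  of `X` (entry-wise; an explicit `sigma` overrides it).  The entry-wise
  default is a global bandwidth: on embeddings whose cluster spread is
  much smaller than the overall spread it leaves distant clusters with
  substantial kernel weight, which biases auto-K downward.  Fixed-K is
  insensitive to this (the dendrogram's fine structure comes from the
  sparse graph), but for auto-K on such data pass a `sigma` near the
  typical within-cluster scale;
* **sparse**: binary kNN graph (default `knn_k` 15), edge iff either
  endpoint is among the other's `k` most similar neighbors, ties at the
  k-th neighbor to the smaller vertex id.

**Merging phase** (on the sparse graph).  Starting from singleton leaves,
the globally best single-vertex relocation (vertex `u` into a leaf
holding at least one of its sparse neighbors) is executed while its
entropy delta is negative.  Deltas are computed incrementally from cached
per-leaf `(s, vol)` and per-vertex cut weights; after a move only the
members and sparse-adjacent vertices of the two touched leaves are
re-evaluated, through a lazy priority queue, so the phase runs in roughly
O(E) per sweep.  With `multis` enabled, converged leaves are contracted
into super-vertices (self-loops preserve all volumes) and the phase
repeats until the round-over-round entropy change drops below
`delta_threshold` (default 1e-7).  Both `multis` settings are run and the
lower-entropy result kept.  The merging optimum is deliberately
finer-grained than the final clustering: locally dense halves of one
cluster may stay separate leaves — the next two steps coarsen.

**Combination phase** (on the sparse graph).  Root children are greedily
paired — connected pairs first, the connectivity constraint is relaxed
only when none remains — by smallest combination delta, which under this
node entropy equals the entropy of the new parent.  The result is a full
binary dendrogram with `2l − 1` nodes over the `l` merged leaves.

**K selection** (on the dense graph).  For each dendrogram node `ω` and
cluster count `K`, `J(ω, K)` is the minimal summed dense-graph node
entropy of a `K`-node frontier of the subtree under `ω`:
`J(ω, 1)` is `ω`'s own entropy (0 for the root) and
`J(ω, K) = min_{K'} J(μ, K') + J(ν, K−K')` over its children.  Fixed mode
backtracks from `J(root, K)`; auto mode first selects
`K̂ = argmin_K J(root, K)` for `K ≤ k_max` (default `min(l, 50)`; reduce
for very large inputs).  The returned clusters are dendrogram nodes that
need not sit at one depth, but their vertex sets tile `V`.  The whole
pipeline is deterministic; the `seed` argument exists for interface
uniformity only.

## Simulators

* `simulate_ordered` — binary symmetric adjacency, zero diagonal: TAD
  count uniform in 8–10, sizes uniform in `tad_size ± deviation`
  (default 10 ± 0), within-TAD edges Bernoulli(`p_intra` = 0.7),
  between-TAD edges Bernoulli(`noise_ratio · p_intra`).  The uniform size
  law is the simplest bounded choice for an unspecified "deviation in TAD
  sizes".
* `simulate_two_level` — nested structure with a geometrically split
  contrast: edge probabilities `p_intra` inside sub-TADs,
  `√noise_ratio · p_intra` between sub-TADs of one TAD, and
  `noise_ratio · p_intra` between TADs; layers are combined by
  elementwise maximum.  This keeps the overall inter-TAD : sub-interior
  ratio equal to `noise_ratio` while giving both levels the same relative
  contrast — sampling both layers at full `p_intra` and max-combining
  would leave sub-TADs a 0.91-vs-0.7 contrast that no segmentation
  objective can separate.  TADs under 4 bins are left unsplit; sub-TAD
  counts are 2–4 with parts of at least 3 bins where possible.
* `simulate_blobs` — isotropic 2-D Gaussian blobs (default 14 clusters ×
  150 members, sd 1.2) via `sklearn.datasets.make_blobs` with centers
  uniform in (−15, 15): at that spread the clusters are mostly separated
  with occasional touching pairs; the sklearn default box (−10, 10)
  yields heavily overlapping blobs on which no method can score well.
* `simulate_markers` — baseline expression Uniform(0,1) over 500 genes,
  16 clusters of 40–60 cells, 20 disjoint marker genes per cluster with
  member values Uniform(0.5, 1.2) (mean shift +0.35, individual values
  may dip below baseline).

What the generators do *not* emulate: genomic distance decay and
coverage biases of real Hi-C, count noise/dropout of real single-cell
data, unbalanced or hierarchical cluster abundances.  Recovery results
on them certify the optimization and its noise robustness, not
performance on real tissues.

## Evaluation statistics

* **Overlapping ratio**: Jaccard index of the two segmentations' sets of
  intra-domain bin pairs; 1 iff identical, 0 when no pair is shared.  The
  0/0 case (two all-singleton segmentations) is 1 by the identity rule.
* **Weighted similarity**: `½[S(a→b) + S(b→a)]` with
  `S(a→b) = Σ_d (|d|/n) · max_{d'} |d∩d'|/|d∪d'|`.
* **ARI / NMI** delegate to scikit-learn (NMI with arithmetic-mean
  normalization); multi-level trees are compared level by level and
  averaged.
* **Boundary fold change**: peak density at boundary windows (boundary
  bin ± 1 bin) over density in 100-kb flanks 400 kb away, minus 1.
  Counts are normalized per kilobase because windows and flanks differ in
  width; zero flank coverage yields an infinite/NaN sentinel with a
  warning rather than an exception.
* **Histone LR test**: the region is tiled at 10% of the mean TAD
  length; per tile `LR = log10((n_k27 + 1)/(n_k36 + 1))` (pseudocount 1
  avoids log 0); a TAD's statistic is its mean tile LR; the null permutes
  the tile LR vector genome-wide (1000 shuffles); two-sided empirical p
  with the add-one convention `p = (1 + #{|null| ≥ |obs|})/(N + 1)`;
  Benjamini–Hochberg adjustment; calls at FDR ≤ 0.1 signed by the
  observed mean.  TADs with fewer than two tiles are flagged untestable.

## Numerical and design notes

* `0 · log 0 := 0` everywhere (analytic limit, requires `alpha1 > 1`).
* All tie-breaks (DP splits, k choice, merge/combination candidates,
  K' splits) go to the smallest index/id, making every output
  reproducible bit-for-bit.
* The merging phase evaluates candidates only among leaves containing a
  sparse-graph neighbor — the natural reading of "connected".
* `J(leaf, K ≥ 2) = +∞`: the dendrogram carries no structure below
  merged leaves, so a requested `K` larger than `l` is an input error.
* Problem sizes in the test suite (80–100-bin matrices, 100 replicates;
  2100-sample blob sets; brute-force oracles at n ≤ 10 and l ≤ 6) were
  chosen so every brute-force oracle is exhaustive yet the whole suite
  runs in well under a minute apart from the end-to-end clustering
  checks.

## Known limitations

* The DP is exact per level, but multi-level calling is greedy across
  levels: level-2 boundaries are conditioned on level-1 output.
* The merging phase is a local search; it guarantees termination and a
  negative-gradient path, not a global optimum (the combination +
  K-selection stages are exact given the dendrogram).
* Peak-based enrichment only; signal tracks (bigWig) are out of scope.
* No normalization (KR/ICE) is applied to contact matrices; feed
  normalized matrices if normalization matters for your data.
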