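# tecgraph

Entropy-guided graph partitioning for two problems that share one
objective:

* **TEC-O** — calling topologically associating domains (TADs) on Hi-C
  contact matrices.  A contact map is an *ordered* graph (bins have a
  fixed linear order, domains are runs of consecutive bins), so the
  globally optimal partition is found exactly by dynamic programming,
  optionally recursing into domains to call sub-TADs.
* **TEC-U** — clustering samples (cells) from a low-dimensional
  embedding, an *unordered* graph problem, by agglomerative search plus
  an exact dynamic program over the resulting dendrogram that selects the
  number of clusters K automatically (`auto` mode) or honors a given K
  (`fixed` mode).

Both minimize the **topology entropy** of an encoding tree.  For a vertex
subset with internal-weight fraction `p = s/vol(G)` and volume fraction
`q = vol/vol(G)`, each tree node contributes

```
H = −p^(α1−1) · log( p / q^(1+α2) )        (defaults α1 = 2, α2 = 0.85)
```

a tempered negative KL divergence between the observed edge distribution
and the configuration-model null: denser-than-chance sets are rewarded,
sparser ones penalized, and the trivial partitions score zero.  See
`docs/methods.md` for the full model, parameter semantics, simulators and
evaluation statistics.

Intended users: computational biologists analyzing chromatin conformation
(TAD calling, boundary enrichment) or single-cell data (clustering with
automatic K), and method developers who want a reproducible, exactly
optimizable entropy objective to compare against.

## Worked example: TAD calling

Simulate a contact map with known TADs, call domains, evaluate:

```sh
$ tec simulate-hic --noise 0.2 --seed 42 --out-matrix sim.tsv --out-truth truth.bed
INFO wrote 80-bin matrix (8 TADs) to sim.tsv
$ tec call-tads sim.tsv --out tads.bed --levels 1
INFO called 8 level-1 TADs on 80 bins
$ head -3 tads.bed
.	0	10	TAD_1	1
.	10	20	TAD_2	1
.	20	30	TAD_3	1
$ tec evaluate tads.bed truth.bed --n-bins 80
overlapping_ratio	1.000000
weighted_similarity	1.000000
```

The simulator planted 8 domains of ~10 bins with intra-edge probability
0.7 and 20% relative inter-domain noise; the caller recovered every
boundary (both agreement scores are 1, their maximum).  With real data,
pass `--chrom/--start/--binsize` to get genomic BED coordinates, e.g. a
25-kb matrix starting at chr19:7,500,000.

## Worked example: clustering with automatic K

```python
from tecgraph import simulate, cluster, adjusted_rand_index

ds = simulate.simulate_blobs(k=5, per_cluster=100, sd=0.5, seed=0)
res = cluster(ds.data, mode="auto", sigma=2.0)
print("auto-K:", res.k)                                    # auto-K: 5
print("ARI:", adjusted_rand_index(res.labels, ds.labels))  # ARI: 1.0
print("entropy:", round(res.entropy, 4))                   # entropy: -1.2073
```

Five Gaussian blobs are recovered exactly: the selected K minimizes the
dense-graph topology entropy over all dendrogram frontiers, and the
reported entropy is that minimal value (more negative = stronger cluster
structure).  `mode="fixed", K=...` skips the K search.  Embeddings are
expected to be dimension-reduced upstream (UMAP, PCA); `tec cluster
embedding.csv --out labels.csv` does the same from the shell.

## Layout

| path | contents |
|---|---|
| `src/tecgraph/core.py` | weighted graph, encoding tree, topology entropy |
| `src/tecgraph/tec_o.py` | prefix tables, segmentation DP, hierarchical TAD calling |
| `src/tecgraph/tec_u.py` | dense/kNN graph construction, merging, combination, K-selection DP |
| `src/tecgraph/simulate.py` | block-model contact maps (1 and 2 levels), blobs, marker genes |
| `src/tecgraph/metrics.py` | overlapping ratio, weighted similarity, ARI/NMI, contact density, boundary fold change, histone LR permutation test |
| `src/tecgraph/io.py`, `cli.py` | readers/writers and the `tec` command |
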