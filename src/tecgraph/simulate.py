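"""Synthetic data generators with ground-truth structure.

Ordered graphs: block-structured binary adjacency matrices emulating Hi-C
contact maps — consecutive bins grouped into TADs, intra-TAD edges drawn
with probability ``p_intra`` and inter-TAD (noise) edges with probability
``noise_ratio * p_intra``.  Two-level matrices nest sub-TADs inside each
TAD and combine the two layers by elementwise maximum.

Unordered data: isotropic Gaussian blobs in 2-D, and marker-gene expression
matrices where each cluster is distinguished by a disjoint set of marker
genes whose member values are drawn from a shifted uniform range.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.datasets import make_blobs

from .tec_o import Segmentation

__all__ = [
    "OrderedSimConfig",
    "LabeledMatrix",
    "LabeledDataset",
    "simulate_ordered",
    "simulate_two_level",
    "simulate_blobs",
    "simulate_markers",
]


@dataclass(frozen=True)
class OrderedSimConfig:
    """Protocol for simulated ordered (contact-map-like) graphs.

    ``noise_ratio`` is the inter-TAD edge probability relative to the
    intra-TAD probability, so inter edges are Bernoulli(noise_ratio *
    p_intra).  TAD sizes are drawn uniformly from
    [tad_size - deviation, tad_size + deviation].
    """

    n_tads_min: int = 8
    n_tads_max: int = 10
    tad_size: int = 10
    deviation: int = 0
    p_intra: float = 0.7
    noise_ratio: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_intra <= 1):
            raise ValueError("p_intra must be in (0, 1]")
        if not (0 <= self.noise_ratio * self.p_intra <= 1):
            raise ValueError("noise_ratio * p_intra must be in [0, 1]")
        if self.tad_size - self.deviation < 2:
            raise ValueError("tad_size - deviation must be >= 2")
        if self.n_tads_min < 1 or self.n_tads_max < self.n_tads_min:
            raise ValueError("invalid TAD count range")


@dataclass
class LabeledMatrix:
    """Binary symmetric adjacency with its generating segmentation(s)."""

    matrix: np.ndarray
    truth: Segmentation
    sub_truth: Segmentation | None = None


@dataclass
class LabeledDataset:
    data: np.ndarray
    labels: np.ndarray


def _draw_sizes(rng: np.random.Generator, cfg: OrderedSimConfig) -> list[int]:
    n_tads = int(rng.integers(cfg.n_tads_min, cfg.n_tads_max + 1))
    lo, hi = cfg.tad_size - cfg.deviation, cfg.tad_size + cfg.deviation
    return [int(rng.integers(lo, hi + 1)) for _ in range(n_tads)]


def _sizes_to_segmentation(sizes: list[int]) -> Segmentation:
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    ivs = [(a, b - 1) for a, b in zip(bounds, bounds[1:])]
    return Segmentation(ivs, int(bounds[-1]))


def _block_bernoulli(rng: np.random.Generator, labels: np.ndarray,
                     p_intra: float, p_inter: float,
                     active: np.ndarray | None = None) -> np.ndarray:
    """Symmetric binary matrix, zero diagonal; edge probability p_intra for
    same-label pairs and p_inter otherwise.  ``active`` masks pairs to
    which no edge may be assigned at all."""
    n = labels.size
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, p_intra, p_inter)
    if active is not None:
        prob = np.where(active, prob, 0.0)
    upper = rng.random((n, n)) < prob
    upper = np.triu(upper, k=1)
    return (upper | upper.T).astype(float)


def simulate_ordered(cfg: OrderedSimConfig) -> LabeledMatrix:
    """Single-level block-model adjacency matrix with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    truth = _sizes_to_segmentation(_draw_sizes(rng, cfg))
    labels = truth.labels()
    mat = _block_bernoulli(rng, labels, cfg.p_intra,
                           cfg.noise_ratio * cfg.p_intra)
    return LabeledMatrix(matrix=mat, truth=truth)


def _split_tad(rng: np.random.Generator, size: int) -> list[int] | None:
    """Random composition of ``size`` into 2-4 sub-TADs of >= 3 bins each
    (>= 2 for the smallest splittable TADs); None when the TAD is too
    small to split (< 4 bins)."""
    if size < 4:
        return None
    min_part = 3 if size >= 6 else 2
    k_hi = min(4, size // min_part)
    k = int(rng.integers(2, k_hi + 1)) if k_hi > 2 else 2
    # k-1 split points over the bins left after the per-part minimum
    free = size - min_part * k
    cuts = np.sort(rng.integers(0, free + 1, size=k - 1))
    parts = np.diff(np.concatenate([[0], cuts, [free]])) + min_part
    return [int(p) for p in parts]


def simulate_two_level(cfg: OrderedSimConfig) -> LabeledMatrix:
    """Two-level matrix: sub-TADs nested inside TADs, layers combined by
    elementwise maximum.

    The construction is hierarchically self-similar: the overall
    inter-TAD : sub-TAD-interior probability ratio equals ``noise_ratio``,
    split geometrically across the two levels (each level's local
    contrast is ``sqrt(noise_ratio)``).  Edge probabilities are
    ``p_intra`` inside sub-TADs, ``sqrt(noise_ratio) * p_intra`` between
    sub-TADs of the same TAD, and ``noise_ratio * p_intra`` between TADs,
    so sub-TADs stand out against the TAD background exactly as strongly
    as TADs stand out against the inter-TAD background.
    """
    rng = np.random.default_rng(cfg.seed)
    mid = float(np.sqrt(cfg.noise_ratio))
    sizes = _draw_sizes(rng, cfg)
    truth = _sizes_to_segmentation(sizes)
    labels = truth.labels()
    level1 = _block_bernoulli(rng, labels, mid * cfg.p_intra,
                              cfg.noise_ratio * cfg.p_intra)

    sub_ivs: list[tuple[int, int]] = []
    sub_labels = np.zeros(truth.n, dtype=np.int64)
    next_lab = 0
    for a, b in truth:
        parts = _split_tad(rng, b - a + 1)
        if parts is None:
            sub_ivs.append((a, b))
            sub_labels[a: b + 1] = next_lab
            next_lab += 1
            continue
        pos = a
        for p in parts:
            sub_ivs.append((pos, pos + p - 1))
            sub_labels[pos: pos + p] = next_lab
            next_lab += 1
            pos += p
    sub_truth = Segmentation(sub_ivs, truth.n)

    within_tad = labels[:, None] == labels[None, :]
    level2 = _block_bernoulli(rng, sub_labels, cfg.p_intra,
                              mid * cfg.p_intra,
                              active=within_tad)
    combined = np.maximum(level1, level2)
    return LabeledMatrix(matrix=combined, truth=truth, sub_truth=sub_truth)


def simulate_blobs(k: int = 14, per_cluster: int = 150, sd: float = 1.2,
                   seed: int = 0,
                   center_box: tuple[float, float] = (-15.0, 15.0)
                   ) -> LabeledDataset:
    """Isotropic 2-D Gaussian blobs with ground-truth cluster labels.

    Cluster centers are drawn uniformly in ``center_box``; the default
    (-15, 15) keeps 14 blobs of spread 1.2 mostly separated with
    occasional touching pairs, matching the visual difficulty of typical
    2-D clustering benchmarks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, y = make_blobs(n_samples=k * per_cluster, centers=k, n_features=2,
                      cluster_std=sd, center_box=center_box,
                      random_state=seed)
    return LabeledDataset(data=X, labels=y)


def simulate_markers(k: int = 16, size_range: tuple[int, int] = (40, 60),
                     n_genes: int = 500, markers_per_cluster: int = 20,
                     marker_range: tuple[float, float] = (0.5, 1.2),
                     seed: int = 0) -> LabeledDataset:
    """Marker-gene expression matrix emulating single-cell profiles.

    Baseline entries are Uniform(0, 1); each cluster owns a disjoint set of
    marker genes whose values for member cells are redrawn from
    Uniform(marker_range).  The default range (0.5, 1.2) makes markers
    moderately elevated on average while still allowing individual values
    below baseline.
    """
    if markers_per_cluster * k > n_genes:
        raise ValueError("marker demand exceeds the number of genes")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=k)
    n = int(sizes.sum())
    labels = np.repeat(np.arange(k), sizes)
    X = rng.random((n, n_genes))
    lo, hi = marker_range
    for c in range(k):
        genes = np.arange(c * markers_per_cluster,
                          (c + 1) * markers_per_cluster)
        members = np.flatnonzero(labels == c)
        X[np.ix_(members, genes)] = rng.uniform(lo, hi,
                                                (members.size, genes.size))
    return LabeledDataset(data=X, labels=labels)
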