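"""Evaluation statistics: partition agreement, TAD quality and
epigenetic-enrichment procedures.

Partition agreement between segmentations uses two scores in [0, 1]:

* overlapping ratio — Jaccard index of the sets of intra-domain bin pairs,
  1 for identical segmentations and 0 for structures sharing no pair;
* weighted similarity — symmetrized, size-weighted best-match Jaccard
  between domains, ``0.5 * [S(a->b) + S(b->a)]`` with
  ``S(a->b) = sum_d (|d|/n) * max_d' |d ∩ d'| / |d ∪ d'|``.

Cluster-label agreement (ARI, NMI) is delegated to scikit-learn.
Enrichment procedures operate on BED-style peak intervals: fold change of
peak density at TAD boundaries versus distal flanks, and a permutation
test on the per-interval log10 ratio of two histone marks (H3K27me3 vs
H3K36me3) with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from statsmodels.stats.multitest import multipletests

from .tec_o import BinInfo, ContactMap, Segmentation, TADTree

__all__ = [
    "PeakSet",
    "EnrichmentResult",
    "overlapping_ratio",
    "weighted_similarity",
    "tree_agreement",
    "adjusted_rand_index",
    "normalized_mutual_info",
    "contact_density",
    "boundary_fold_change",
    "histone_lr_test",
]


def _check_same_n(a: Segmentation, b: Segmentation):
    if a.n != b.n:
        raise ValueError(f"segmentations cover different bin counts "
                         f"({a.n} vs {b.n})")


def _pair_counts(a: Segmentation, b: Segmentation):
    """(|Pa ∩ Pb|, |Pa|, |Pb|) where P = intra-domain unordered bin pairs,
    via the contingency table of the two bin labelings."""
    la, lb = a.labels(), b.labels()
    ct = pd.crosstab(la, lb).to_numpy()
    inter = (ct * (ct - 1) // 2).sum()
    pa = sum(m * (m - 1) // 2 for m in np.bincount(la))
    pb = sum(m * (m - 1) // 2 for m in np.bincount(lb))
    return int(inter), int(pa), int(pb)


def overlapping_ratio(a: Segmentation, b: Segmentation) -> float:
    """Jaccard index of intra-domain bin-pair sets; 1 iff identical."""
    _check_same_n(a, b)
    inter, pa, pb = _pair_counts(a, b)
    union = pa + pb - inter
    if union == 0:
        # both all-singletons: identical by construction
        return 1.0
    return inter / union


def weighted_similarity(a: Segmentation, b: Segmentation) -> float:
    """Symmetrized size-weighted best-match Jaccard between domains."""
    _check_same_n(a, b)

    def directed(x: Segmentation, y: Segmentation) -> float:
        total = 0.0
        for xa, xb in x:
            size = xb - xa + 1
            best = 0.0
            for ya, yb in y:
                ov = min(xb, yb) - max(xa, ya) + 1
                if ov <= 0:
                    continue
                un = max(xb, yb) - min(xa, ya) + 1
                best = max(best, ov / un)
            total += size / x.n * best
        return total

    return 0.5 * (directed(a, b) + directed(b, a))


def tree_agreement(a: TADTree, b: TADTree, metric=overlapping_ratio) -> float:
    """Compare multi-level TAD trees level by level and average the
    per-level agreement scores."""
    levels = max(a.max_level(), b.max_level())
    scores = [metric(a.level_segmentation(lv), b.level_segmentation(lv))
              for lv in range(1, levels + 1)]
    return float(np.mean(scores))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def normalized_mutual_info(labels_a, labels_b) -> float:
    """NMI with arithmetic-mean normalization."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))


def contact_density(cm: ContactMap, seg: Segmentation) -> pd.DataFrame:
    """Per-TAD contact density: ordered-pair intra-weight sum divided by
    the TAD length in bins; lengths are reported alongside."""
    if seg.n != cm.n_bins:
        raise ValueError("segmentation does not match the contact map")
    rows = []
    for a, b in seg:
        length = b - a + 1
        s = float(cm.matrix[a: b + 1, a: b + 1].sum())
        rows.append({"start_bin": a, "end_bin": b, "length": length,
                     "density": s / length})
    return pd.DataFrame(rows)


class PeakSet:
    """Genomic peak intervals (chrom, start, end), 0-based half-open."""

    def __init__(self, intervals):
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        if (df["start"] >= df["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")
        self.df = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    @classmethod
    def from_bed(cls, path) -> "PeakSet":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: BED line has < 3 columns")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(rows)

    def __len__(self):
        return len(self.df)

    def count_overlaps(self, chrom: str, start: int, end: int) -> int:
        """Number of peaks overlapping [start, end)."""
        sub = self.df[self.df["chrom"] == chrom]
        return int(((sub["start"] < end) & (sub["end"] > start)).sum())


def _boundary_positions(seg: Segmentation, bins: BinInfo) -> list[int]:
    """Genomic coordinates of internal domain boundaries (the point between
    consecutive TADs)."""
    return [bins.start + (b + 1) * bins.binsize for _, b in seg.intervals[:-1]]


def boundary_fold_change(seg: Segmentation, peaks: PeakSet, bins: BinInfo,
                         flank_distance: int = 400_000,
                         flank_width: int = 100_000,
                         boundary_halo: int = 1) -> float:
    """Peak enrichment at TAD boundaries relative to distal flanks.

    Boundary windows span the boundary bin +/- ``boundary_halo`` bins;
    flanks are ``flank_width`` segments located ``flank_distance`` away on
    each side of every boundary.  Peak counts are normalized per kilobase
    of window before forming the ratio (windows and flanks differ in
    width), and the result is ratio - 1: zero means no enrichment, 1 means
    twice the flank density at boundaries.
    """
    if bins is None:
        raise ValueError("genomic bin metadata is required")
    b_count = f_count = 0
    b_len = f_len = 0
    for pos in _boundary_positions(seg, bins):
        w0 = pos - (boundary_halo + 1) * bins.binsize
        w1 = pos + boundary_halo * bins.binsize
        b_count += peaks.count_overlaps(bins.chrom, w0, w1)
        b_len += w1 - w0
        for f0 in (pos - flank_distance - flank_width, pos + flank_distance):
            f_count += peaks.count_overlaps(bins.chrom, f0, f0 + flank_width)
            f_len += flank_width
    if f_count == 0 or f_len == 0:
        warnings.warn("no peaks in flanking regions; fold change undefined")
        return float("inf") if b_count > 0 else float("nan")
    b_density = b_count / (b_len / 1000.0)
    f_density = f_count / (f_len / 1000.0)
    return b_density / f_density - 1.0


@dataclass
class EnrichmentResult:
    """Per-TAD two-mark enrichment calls from the LR permutation test."""

    table: pd.DataFrame = field(repr=False)
    prop_mark_a: float = 0.0
    prop_mark_b: float = 0.0
    prop_none: float = 0.0


def histone_lr_test(seg: Segmentation, peaks_a: PeakSet, peaks_b: PeakSet,
                    bins: BinInfo, n_shuffles: int = 1000,
                    fdr_cut: float = 0.1, seed: int = 0) -> EnrichmentResult:
    """Permutation test for per-TAD enrichment of one of two marks.

    The analyzed region is tiled into intervals of 10% of the mean TAD
    length; each interval's statistic is LR = log10((count_a + 1) /
    (count_b + 1)) (pseudocount 1 avoids log of zero).  A TAD's observed
    statistic is the mean LR over its intervals; the null permutes the
    interval LR vector genome-wide ``n_shuffles`` times and recomputes the
    per-TAD means.  Two-sided empirical p-values use the add-one
    convention p = (1 + #{|null| >= |obs|}) / (n_shuffles + 1); the sign of
    the observed mean assigns the enriched mark; BH-adjusted p-values above
    ``fdr_cut`` mean no significant enrichment.  TADs with fewer than two
    intervals are flagged untestable.
    """
    if bins is None:
        raise ValueError("genomic bin metadata is required")
    rng = np.random.default_rng(seed)
    region_len = seg.n * bins.binsize
    mean_tad_bp = region_len / len(seg)
    width = max(int(round(0.10 * mean_tad_bp)), 1)

    starts = np.arange(bins.start, bins.start + region_len, width)
    lr = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        ca = peaks_a.count_overlaps(bins.chrom, s0, s0 + width)
        cb = peaks_b.count_overlaps(bins.chrom, s0, s0 + width)
        lr[i] = np.log10((ca + 1) / (cb + 1))

    centers = starts + width / 2.0
    tad_of_interval = np.full(starts.size, -1, dtype=np.int64)
    for t, (a, b) in enumerate(seg):
        lo = bins.start + a * bins.binsize
        hi = bins.start + (b + 1) * bins.binsize
        tad_of_interval[(centers >= lo) & (centers < hi)] = t

    n_tads = len(seg)
    counts = np.bincount(tad_of_interval[tad_of_interval >= 0],
                         minlength=n_tads).astype(float)
    testable = counts >= 2

    def tad_means(vec: np.ndarray) -> np.ndarray:
        sums = np.bincount(tad_of_interval[tad_of_interval >= 0],
                           weights=vec[tad_of_interval >= 0],
                           minlength=n_tads)
        with np.errstate(invalid="ignore"):
            return sums / counts

    obs = tad_means(lr)
    null = np.empty((n_shuffles, n_tads))
    for j in range(n_shuffles):
        null[j] = tad_means(rng.permutation(lr))

    with np.errstate(invalid="ignore"):
        exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (n_shuffles + 1.0)
    pvals = np.where(testable, pvals, np.nan)

    fdr = np.full(n_tads, np.nan)
    if testable.any():
        fdr[testable] = multipletests(pvals[testable], method="fdr_bh")[1]

    call = np.where(
        testable & (fdr <= fdr_cut),
        np.where(obs > 0, "mark_a", "mark_b"),
        "none",
    )
    call = np.where(testable, call, "untestable")
    table = pd.DataFrame({
        "tad": np.arange(n_tads),
        "n_intervals": counts.astype(int),
        "observed_lr": obs,
        "p_value": pvals,
        "fdr": fdr,
        "call": call,
    })
    n_called = int(testable.sum())
    if n_called:
        pa = float((call == "mark_a").sum()) / n_called
        pb = float((call == "mark_b").sum()) / n_called
        pn = float(((call == "none") & testable).sum()) / n_called
    else:
        pa = pb = pn = 0.0
    return EnrichmentResult(table=table, prop_mark_a=pa, prop_mark_b=pb,
                            prop_none=pn)
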