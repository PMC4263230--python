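"""Union regions, occupancy matrix, promoter/enhancer split, pairwise overlap
significance with a randomisation null, clustering, and k-way Venn partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    count_overlapping,
    merge_intervals,
)
from .model import Compendium, GenomeAnnotation, PeakSet


@dataclass
class UnionRegionSet:
    """Atomic merged regions and the binary region x sample occupancy matrix."""

    regions: list[GenomicInterval]
    occupancy: np.ndarray  # bool, regions x samples
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != (len(self.regions), len(self.sample_ids)):
            raise ValueError("occupancy shape mismatch")

    def column(self, sample_id: str) -> np.ndarray:
        return self.occupancy[:, self.sample_ids.index(sample_id)]

    def subset_regions(self, mask: np.ndarray) -> "UnionRegionSet":
        mask = np.asarray(mask, dtype=bool)
        return UnionRegionSet(
            [r for r, m in zip(self.regions, mask) if m],
            self.occupancy[mask],
            list(self.sample_ids),
        )


def build_union_regions(compendium: Compendium) -> UnionRegionSet:
    """Merge all sample peaks into atomic regions and mark which samples
    touch each region by >= 1 bp."""
    if not compendium:
        raise ValueError("empty compendium")
    sample_ids = list(compendium)
    all_peaks = [p for ps in compendium.values() for p in ps.peaks]
    regions = merge_intervals(all_peaks)
    occ = np.zeros((len(regions), len(sample_ids)), dtype=bool)
    # merged regions are disjoint and sorted: locate by searchsorted per chrom
    region_ids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, ids in by_chrom.items():
        starts = np.array([regions[i].start for i in ids], dtype=np.int64)
        ends = np.array([regions[i].end for i in ids], dtype=np.int64)
        region_ids[chrom] = (starts, ends, np.array(ids))
    for s, sid in enumerate(sample_ids):
        for p in compendium[sid].peaks:
            if p.chrom not in region_ids:
                continue
            starts, ends, ids = region_ids[p.chrom]
            lo = np.searchsorted(ends, p.start, side="right")
            hi = np.searchsorted(starts, p.end, side="left")
            occ[ids[lo:hi], s] = True
    keep = occ.any(axis=1)
    return UnionRegionSet(
        [r for r, k in zip(regions, keep) if k], occ[keep], sample_ids
    )


def promoter_windows(annotation: GenomeAnnotation, window_bp: int = 1000
                     ) -> list[GenomicInterval]:
    out = []
    for g in annotation.genes:
        start = max(0, g.tss - window_bp)
        end = min(annotation.chrom_sizes[g.chrom], g.tss + window_bp)
        if end > start:
            out.append(GenomicInterval(g.chrom, start, end))
    return out


def split_promoter_enhancer(
    intervals: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    window_bp: int = 1000,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition intervals into promoter (overlapping any TSS +-window by
    >= 1 bp) and enhancer (all others) subsets."""
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    mask = promoter_mask(intervals, annotation, window_bp)
    prom = [iv for iv, m in zip(intervals, mask) if m]
    enh = [iv for iv, m in zip(intervals, mask) if not m]
    return prom, enh


def promoter_mask(intervals, annotation, window_bp: int = 1000) -> np.ndarray:
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    index = IntervalIndex(promoter_windows(annotation, window_bp))
    return index.interval_overlap_flags(list(intervals))


def split_compendium(
    compendium: Compendium, annotation: GenomeAnnotation, window_bp: int = 1000
) -> tuple[Compendium, Compendium]:
    """Per-sample promoter/enhancer partition of a whole compendium."""
    prom: Compendium = {}
    enh: Compendium = {}
    for sid, ps in compendium.items():
        p, e = split_promoter_enhancer(ps.peaks, annotation, window_bp)
        prom[sid] = PeakSet(sid, ps.factor, ps.cell_type, p)
        enh[sid] = PeakSet(sid, ps.factor, ps.cell_type, e)
    return prom, enh


@dataclass
class OverlapSignificance:
    """Pairwise peak-overlap statistics against the shuffle null.

    ``observed[i, j]`` counts peaks of sample i overlapping >= 1 peak of
    sample j; z and the empirical p matrices come from re-shuffling sample
    i's peaks ``n_randomizations`` times.  ``correlation`` is the Pearson
    correlation of binary occupancy columns over union regions.
    """

    sample_ids: list[str]
    observed: np.ndarray
    z: np.ndarray
    p_over: np.ndarray
    p_under: np.ndarray
    correlation: np.ndarray
    n_randomizations: int
    missing: list[str] = field(default_factory=list)

    def frame(self, which: str) -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.sample_ids,
                            columns=self.sample_ids)


def occupancy_correlation(union: UnionRegionSet) -> np.ndarray:
    """Pearson correlation between binary occupancy columns (unit diagonal)."""
    occ = union.occupancy.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(occ.T)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def overlap_significance(
    compendium: Compendium,
    chrom_sizes: dict[str, int],
    n_rand: int = 1000,
    seed: int = 0,
    union: UnionRegionSet | None = None,
) -> OverlapSignificance:
    """Observed pairwise peak overlaps vs the within-chromosome shuffle null.

    For every ordered pair (i, j), sample i's peaks are relocated ``n_rand``
    times and the overlap count with sample j's real peaks recomputed;
    p_over = (#null >= observed + 1) / (n_rand + 1) and symmetrically for
    p_under.  Samples with zero peaks are flagged missing (NaN rows/columns).
    """
    if n_rand < 10:
        raise ValueError("n_rand must be >= 10")
    sample_ids = list(compendium)
    k = len(sample_ids)
    observed = np.full((k, k), np.nan)
    z = np.full((k, k), np.nan)
    p_over = np.full((k, k), np.nan)
    p_under = np.full((k, k), np.nan)
    missing = [sid for sid in sample_ids if len(compendium[sid]) == 0]

    merged_by_sample = {
        sid: merge_intervals(compendium[sid].peaks) if len(compendium[sid]) else []
        for sid in sample_ids
    }
    ss = np.random.SeedSequence(seed)
    shuffle_seeds = ss.generate_state(k * n_rand).reshape(k, n_rand)
    null_cache: dict[tuple[int, int], PeakSet] = {}
    for i, si in enumerate(sample_ids):
        if si in missing:
            continue
        for j, sj in enumerate(sample_ids):
            if sj in missing:
                continue
            obs = count_overlapping(compendium[si].peaks, merged_by_sample[sj])
            null = np.empty(n_rand)
            for r in range(n_rand):
                key = (i, r)
                if key not in null_cache:
                    null_cache[key] = compendium[si].shuffled(
                        chrom_sizes, int(shuffle_seeds[i, r])
                    )
                null[r] = count_overlapping(
                    null_cache[key].peaks, merged_by_sample[sj]
                )
            mu, sd = null.mean(), null.std(ddof=1)
            observed[i, j] = obs
            z[i, j] = 0.0 if sd == 0 else (obs - mu) / sd
            p_over[i, j] = ((null >= obs).sum() + 1) / (n_rand + 1)
            p_under[i, j] = ((null <= obs).sum() + 1) / (n_rand + 1)
        null_cache = {key: v for key, v in null_cache.items() if key[0] != i}

    if union is None:
        present = {sid: compendium[sid] for sid in sample_ids if sid not in missing}
        corr = np.full((k, k), np.nan)
        if present:
            sub = build_union_regions(present)
            subcorr = occupancy_correlation(sub)
            idx = [sample_ids.index(s) for s in sub.sample_ids]
            corr[np.ix_(idx, idx)] = subcorr
    else:
        corr = occupancy_correlation(union)
    return OverlapSignificance(
        sample_ids=sample_ids, observed=observed, z=z,
        p_over=p_over, p_under=p_under, correlation=corr,
        n_randomizations=n_rand, missing=missing,
    )


@dataclass
class ClusterResult:
    leaf_order: list[str]
    linkage: np.ndarray
    sample_ids: list[str]

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.sample_ids, columns=self.sample_ids)

    def nearest_neighbors(self) -> dict[str, list[str]]:
        """Per leaf, the other leaves at minimal cophenetic distance."""
        d = self.cophenetic().to_numpy()
        np.fill_diagonal(d, np.inf)
        out = {}
        for i, sid in enumerate(self.sample_ids):
            row = d[i]
            out[sid] = [self.sample_ids[j] for j in np.nonzero(row == row.min())[0]]
        return out


def hierarchical_cluster(
    correlation: np.ndarray | pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
) -> ClusterResult:
    """Average-linkage agglomerative clustering on distance 1 - r.

    scipy's linkage is deterministic for a fixed input; equal-distance merges
    resolve to the smallest cluster indices, so the leaf order is stable.
    """
    if isinstance(correlation, pd.DataFrame):
        sample_ids = list(correlation.index)
        correlation = correlation.to_numpy()
    correlation = np.asarray(correlation, dtype=float)
    if correlation.ndim != 2 or correlation.shape[0] != correlation.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(correlation, correlation.T, atol=1e-8, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(correlation.shape[0])]
    sample_ids = list(sample_ids)
    if len(sample_ids) == 1:
        return ClusterResult(sample_ids, np.empty((0, 4)), sample_ids)
    dist = 1.0 - correlation
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    return ClusterResult([sample_ids[i] for i in order], link, sample_ids)


def venn_partition(
    sample_ids: Sequence[str], union: UnionRegionSet
) -> tuple[dict[int, int], float]:
    """Region counts per membership cell of a k-way Venn diagram (2 <= k <= 6).

    Cell keys are bitmasks over ``sample_ids`` (bit i set = region occupied by
    sample i).  Returns the counts over the 2^k - 1 non-empty cells and the
    fraction of regions in the all-samples cell.
    """
    k = len(sample_ids)
    if not (2 <= k <= 6):
        raise ValueError(f"k must be in [2, 6], got {k}")
    cols = np.stack([union.column(sid) for sid in sample_ids], axis=1)
    masks = cols @ (1 << np.arange(k))
    counts = {cell: 0 for cell in range(1, 2 ** k)}
    vals, ns = np.unique(masks[masks > 0], return_counts=True)
    for v, n in zip(vals, ns):
        counts[int(v)] = int(n)
    total = sum(counts.values())
    full = counts[2 ** k - 1]
    shared_fraction = full / total if total else float("nan")
    return counts, shared_fraction
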