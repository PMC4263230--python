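"""Nearest-gene mapping, peaks-per-gene statistics, gene-length-corrected
TF-locus enrichment, and the promoter/enhancer co-occurrence check."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .model import Compendium, GenomeAnnotation


def assign_nearest_gene(
    peaks: Sequence[GenomicInterval], annotation: GenomeAnnotation
) -> list[tuple[str, float]]:
    """Map each peak to the gene with the nearest TSS (midpoint anchor).

    Distance is |peak midpoint - TSS| minimised over all genes genome-wide
    (chromosome mismatches are effectively infinite).  The signed distance is
    negative upstream of the TSS in the gene's reading direction.  Midpoint
    ties go to the lexicographically smallest gene_id.
    """
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    ids, tss, chroms, sign = annotation.tss_table()
    chrom_arr = np.array(chroms)
    out: list[tuple[str, float]] = []
    for p in peaks:
        mid = p.midpoint
        dist = np.abs(mid - tss).astype(float)
        dist[chrom_arr != p.chrom] = np.inf
        i = int(np.argmin(dist))  # first minimum = smallest gene_id
        signed = (mid - tss[i]) * sign[i]
        out.append((ids[i], float(signed)))
    return out


@dataclass
class GenePeakTable:
    table: pd.DataFrame  # index gene_id; columns: length, is_tf, per-sample, total
    mean_peaks_per_bound_gene: float
    n_genes_gt5: int
    n_genes_gt50: int


def peaks_per_gene(
    compendium: Compendium,
    annotation: GenomeAnnotation,
    all_genes_denominator: bool = False,
) -> GenePeakTable:
    """Per-gene peak counts (per sample and totalled across the compendium).

    The headline mean is computed over genes with >= 1 assigned peak unless
    ``all_genes_denominator`` is set.  Threshold counts use strict
    inequalities ("more than 5", "more than 50" peaks).
    """
    genes = sorted(annotation.genes, key=lambda g: g.gene_id)
    idx = [g.gene_id for g in genes]
    table = pd.DataFrame(
        {
            "length": [g.length for g in genes],
            "is_tf": [g.gene_id in annotation.tf_gene_ids for g in genes],
        },
        index=pd.Index(idx, name="gene_id"),
    )
    for sid, ps in compendium.items():
        counts = pd.Series(0, index=table.index, dtype=int)
        if len(ps):
            assigned = [g for g, _ in assign_nearest_gene(ps.peaks, annotation)]
            vc = pd.Series(assigned).value_counts()
            counts.loc[vc.index] = vc.to_numpy()
        table[sid] = counts
    sample_cols = list(compendium)
    table["total"] = table[sample_cols].sum(axis=1) if sample_cols else 0
    totals = table["total"]
    denom = totals if all_genes_denominator else totals[totals > 0]
    mean = float(denom.mean()) if len(denom) else float("nan")
    return GenePeakTable(
        table=table,
        mean_peaks_per_bound_gene=mean,
        n_genes_gt5=int((totals > 5).sum()),
        n_genes_gt50=int((totals > 50).sum()),
    )


@dataclass
class TfLocusEnrichment:
    observed_tf_mean: float
    null_mean: float
    p_value: float
    n_resample: int


def tf_locus_enrichment(
    gene_table: pd.DataFrame,
    n_resample: int = 10_000,
    n_length_bins: int = 20,
    seed: int = 0,
    count_column: str = "total",
) -> TfLocusEnrichment:
    """Are TF gene loci covered by more peaks than length-matched genes?

    Genes are stratified into gene-length quantile bins; each resample draws,
    within every bin, as many non-TF genes as that bin holds TF genes, and the
    statistic is the mean peak count of the drawn genes.  The add-one
    empirical p compares the observed TF mean against this length-matched
    null, which corrects for longer genes simply having more room for peaks.
    """
    tf = gene_table["is_tf"].to_numpy(dtype=bool)
    if tf.sum() < 10 or (~tf).sum() < 10:
        raise ValueError("need >= 10 TF and >= 10 non-TF genes")
    counts = gene_table[count_column].to_numpy(dtype=float)
    bins = pd.qcut(gene_table["length"], q=n_length_bins, duplicates="drop",
                   labels=False).to_numpy()
    rng = np.random.default_rng(seed)
    observed = float(counts[tf].mean())
    n_tf_total = int(tf.sum())

    per_bin: list[tuple[np.ndarray, int]] = []
    for b in np.unique(bins):
        in_bin = bins == b
        n_tf_bin = int((tf & in_bin).sum())
        if n_tf_bin == 0:
            continue
        pool = counts[in_bin & ~tf]
        if pool.size == 0:
            raise ValueError(
                f"length bin {b} has TF genes but no non-TF genes; "
                "use fewer length bins"
            )
        per_bin.append((pool, n_tf_bin))
    null_sums = np.zeros(n_resample)
    for pool, n_draw in per_bin:
        draws = rng.choice(pool, size=(n_resample, n_draw), replace=True)
        null_sums += draws.sum(axis=1)
    null_means = null_sums / n_tf_total
    p = float(((null_means >= observed).sum() + 1) / (n_resample + 1))
    return TfLocusEnrichment(observed, float(null_means.mean()), p, n_resample)


@dataclass
class PromoterEnhancerDependence:
    mean_enhancer_with_promoter: float
    mean_enhancer_without_promoter: float
    rate_ratio: float  # inf when the without-promoter stratum mean is zero
    p_value: float     # NaN when a stratum is empty
    n_with: int
    n_without: int


def promoter_enhancer_dependence(
    promoter_counts: pd.Series,
    enhancer_counts: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PromoterEnhancerDependence:
    """Does a promoter peak at a gene predict more enhancer peaks at it?

    Genes are split by promoter-peak presence; the difference in mean
    enhancer-peak counts is tested by label permutation (two-sided add-one
    empirical p).
    """
    has_prom = (promoter_counts > 0).to_numpy()
    enh = enhancer_counts.reindex(promoter_counts.index).fillna(0).to_numpy(float)
    n_with, n_without = int(has_prom.sum()), int((~has_prom).sum())
    if n_with == 0 or n_without == 0:
        return PromoterEnhancerDependence(
            float("nan"), float("nan"), float("nan"), float("nan"),
            n_with, n_without,
        )
    m1, m0 = float(enh[has_prom].mean()), float(enh[~has_prom].mean())
    ratio = float("inf") if m0 == 0 and m1 > 0 else (
        float("nan") if m0 == 0 else m1 / m0
    )
    obs = abs(m1 - m0)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(has_prom)
        exceed += abs(enh[perm].mean() - enh[~perm].mean()) >= obs
    p = (exceed + 1) / (n_perm + 1)
    return PromoterEnhancerDependence(m1, m0, ratio, float(p), n_with, n_without)
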