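"""Genomic-context annotation: nine categories (promoter, UTRs, exon, intron,
intergenic, LINE/SINE/LTR) with shuffle-based enrichment, plus the CpG-island
preference test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, false_discovery_control

from .intervals import GenomicInterval, IntervalIndex
from .model import GenomeAnnotation, PeakSet

CATEGORIES = (
    "Promoter", "5UTR", "3UTR", "Exon", "Intron",
    "LTR", "SINE", "LINE", "Intergenic",
)
# midpoint membership is tested in this order; the first match wins
_PRECEDENCE = ("Promoter", "5UTR", "3UTR", "Exon", "Intron", "LTR", "SINE", "LINE")


def _utr_intervals(annotation: GenomeAnnotation, utr_bp: int = 200
                   ) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """5'/3' UTR stand-ins: the first/last ``utr_bp`` of the terminal exons
    (reading direction aware).  Used because the gene table carries no CDS."""
    utr5, utr3 = [], []
    for g in annotation.genes:
        exons = sorted(g.exons, key=lambda e: e.start)
        if not exons:
            continue
        first, last = exons[0], exons[-1]
        if g.strand == "+":
            utr5.append(GenomicInterval(g.chrom, first.start,
                                        min(first.end, first.start + utr_bp)))
            utr3.append(GenomicInterval(g.chrom, max(last.start, last.end - utr_bp),
                                        last.end))
        else:
            utr5.append(GenomicInterval(g.chrom, max(last.start, last.end - utr_bp),
                                        last.end))
            utr3.append(GenomicInterval(g.chrom, first.start,
                                        min(first.end, first.start + utr_bp)))
    return utr5, utr3


class CategoryAnnotator:
    """Assigns each peak exactly one of the nine categories by its midpoint."""

    def __init__(self, annotation: GenomeAnnotation, promoter_window: int = 1000,
                 utr_bp: int = 200):
        if not annotation.genes:
            raise ValueError("annotation has no genes")
        from .occupancy import promoter_windows

        utr5, utr3 = _utr_intervals(annotation, utr_bp)
        self._indexes = {
            "Promoter": IntervalIndex(promoter_windows(annotation, promoter_window)),
            "5UTR": IntervalIndex(utr5),
            "3UTR": IntervalIndex(utr3),
            "Exon": IntervalIndex([e for g in annotation.genes for e in g.exons]),
            "Intron": IntervalIndex(
                [GenomicInterval(g.chrom, g.start, g.end) for g in annotation.genes]
            ),
            "LTR": IntervalIndex(annotation.repeats_of_class("LTR")),
            "SINE": IntervalIndex(annotation.repeats_of_class("SINE")),
            "LINE": IntervalIndex(annotation.repeats_of_class("LINE")),
        }

    def annotate(self, peaks) -> list[str]:
        labels = np.array(["Intergenic"] * len(peaks), dtype=object)
        undecided = np.ones(len(peaks), dtype=bool)
        chroms = np.array([p.chrom for p in peaks])
        mids = np.array([p.midpoint for p in peaks])
        for cat in _PRECEDENCE:
            idx = self._indexes[cat]
            for chrom in np.unique(chroms[undecided]):
                sel = undecided & (chroms == chrom)
                hit = idx.contains_point(chrom, mids[sel])
                where = np.nonzero(sel)[0][hit]
                labels[where] = cat
                undecided[where] = False
        return list(labels)

    def counts(self, peaks) -> pd.Series:
        labels = self.annotate(peaks)
        return pd.Series(labels).value_counts().reindex(CATEGORIES, fill_value=0)


def annotate_category(peak: GenomicInterval, annotator: CategoryAnnotator) -> str:
    return annotator.annotate([peak])[0]


@dataclass
class CategoryProfile:
    table: pd.DataFrame  # index CATEGORIES; observed, expected_fraction, fold, p, q
    n_peaks: int


def category_enrichment(
    sample: PeakSet,
    annotation: GenomeAnnotation,
    annotator: CategoryAnnotator | None = None,
    n_rand: int = 100,
    seed: int = 0,
) -> CategoryProfile:
    """Category enrichment of one sample against the shuffle null.

    Expected category fractions are the mean over ``n_rand`` length-
    preserving within-chromosome shuffles of the sample's own peaks; the
    two-sided binomial test uses the expected fraction as the success
    probability and BH corrects across the nine categories.  Expected
    fractions of exactly zero with observed hits are floored (flagged fold
    ``inf``).
    """
    if len(sample) < 10:
        raise ValueError("need >= 10 peaks")
    ann = annotator or CategoryAnnotator(annotation)
    observed = ann.counts(sample.peaks)
    n = len(sample)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_rand)
    null_fracs = np.zeros((n_rand, len(CATEGORIES)))
    for r in range(n_rand):
        shuf = sample.shuffled(annotation.chrom_sizes, int(seeds[r]))
        null_fracs[r] = ann.counts(shuf.peaks).to_numpy() / n
    expected = null_fracs.mean(axis=0)
    p_vals, folds = [], []
    for i, cat in enumerate(CATEGORIES):
        exp = expected[i]
        obs = int(observed.iloc[i])
        if exp == 0:
            folds.append(float("inf") if obs else 1.0)
            p_vals.append(1.0 / (n_rand * n + 1) if obs else 1.0)
            continue
        folds.append(obs / (exp * n))
        p_vals.append(binomtest(obs, n, exp).pvalue)
    q = false_discovery_control(p_vals, method="bh")
    table = pd.DataFrame(
        {
            "observed": observed.to_numpy(),
            "expected_fraction": expected,
            "fold": folds,
            "p_value": p_vals,
            "q_value": q,
        },
        index=pd.Index(CATEGORIES, name="category"),
    )
    return CategoryProfile(table, n)


@dataclass
class CpGEnrichment:
    observed_fraction: float
    expected_fraction: float
    fold: float
    p_value: float
    label: str  # Prefer / Avoid / Neutral / not available


def cpg_enrichment(
    sample: PeakSet,
    annotation: GenomeAnnotation,
    n_rand: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> CpGEnrichment:
    """CpG-island preference of one sample against the shuffle null.

    The statistic is the fraction of peaks overlapping an island by >= 1 bp;
    the empirical two-sided p doubles the smaller tail.  Labels mirror the
    Prefer/Avoid/Neutral convention of per-sample CpG reports.
    """
    if not annotation.cpg_islands:
        return CpGEnrichment(float("nan"), float("nan"), float("nan"),
                             float("nan"), "not available")
    idx = IntervalIndex(annotation.cpg_islands)
    obs = float(idx.interval_overlap_flags(sample.peaks).mean())
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_rand)
    null = np.empty(n_rand)
    for r in range(n_rand):
        shuf = sample.shuffled(annotation.chrom_sizes, int(seeds[r]))
        null[r] = idx.interval_overlap_flags(shuf.peaks).mean()
    exp = float(null.mean())
    p_over = ((null >= obs).sum() + 1) / (n_rand + 1)
    p_under = ((null <= obs).sum() + 1) / (n_rand + 1)
    p = min(1.0, 2 * min(p_over, p_under))
    if obs > exp and p <= alpha:
        label = "Prefer"
    elif obs < exp and p <= alpha:
        label = "Avoid"
    else:
        label = "Neutral"
    fold = float("inf") if exp == 0 and obs > 0 else (
        1.0 if exp == 0 else obs / exp
    )
    return CpGEnrichment(obs, exp, fold, float(p), label)
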