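"""Nine-category genomic-context assignment and CpG preference tests."""

import numpy as np
import pytest

from chipcompendium.context import (
    CATEGORIES,
    CategoryAnnotator,
    annotate_category,
    category_enrichment,
    cpg_enrichment,
)
from chipcompendium.intervals import GenomicInterval
from chipcompendium.model import Gene, GenomeAnnotation, PeakSet

from conftest import random_intervals


def rich_annotation():
    genes = [
        Gene("gA", "chr1", "+", 10_000, 20_000, exons=[
            GenomicInterval("chr1", 10_000, 10_500),
            GenomicInterval("chr1", 14_000, 14_600),
            GenomicInterval("chr1", 19_500, 20_000),
        ]),
        Gene("gB", "chr1", "-", 40_000, 48_000, exons=[
            GenomicInterval("chr1", 40_000, 40_400),
            GenomicInterval("chr1", 47_600, 48_000),
        ]),
    ]
    repeats = [
        (GenomicInterval("chr1", 60_000, 60_500), "LTR"),
        (GenomicInterval("chr1", 62_000, 62_500), "SINE"),
        (GenomicInterval("chr1", 64_000, 64_500), "LINE"),
    ]
    cpg = [GenomicInterval("chr1", 9_800, 10_300)]
    return GenomeAnnotation({"chr1": 100_000}, genes=genes, repeats=repeats,
                            cpg_islands=cpg)


@pytest.fixture(scope="module")
def annotator():
    return CategoryAnnotator(rich_annotation())


class TestAnnotateCategory:
    @pytest.mark.parametrize("interval,expected", [
        # promoter window beats everything, even inside the first exon
        (GenomicInterval("chr1", 10_100, 10_200), "Promoter"),
        # inside gA's middle exon, outside promoter/UTR windows
        (GenomicInterval("chr1", 14_200, 14_300), "Exon"),
        # intronic: inside gA's span, no exon
        (GenomicInterval("chr1", 12_000, 12_100), "Intron"),
        # 3'UTR: last 200 bp of gA's terminal exon
        (GenomicInterval("chr1", 19_850, 19_950), "3UTR"),
        # 5'UTR of the minus-strand gene gB sits at its right end, but the
        # promoter window around TSS=48000 wins; step outside it:
        (GenomicInterval("chr1", 64_100, 64_200), "LINE"),
        (GenomicInterval("chr1", 60_100, 60_200), "LTR"),
        (GenomicInterval("chr1", 62_100, 62_200), "SINE"),
        (GenomicInterval("chr1", 80_000, 80_100), "Intergenic"),
    ])
    def test_fixed_precedence(self, annotator, interval, expected):
        assert annotate_category(interval, annotator) == expected

    def test_matches_brute_force_membership_oracle(self):
        ann = rich_annotation()
        annotator = CategoryAnnotator(ann)
        rng = np.random.default_rng(61)
        peaks = random_intervals(rng, 1000, chroms=("chr1",), max_pos=99_000)
        got = annotator.annotate(peaks)

        def inside(mid, ivs):
            return any(iv.start <= mid < iv.end for iv in ivs)

        from chipcompendium.context import _utr_intervals
        from chipcompendium.occupancy import promoter_windows

        utr5, utr3 = _utr_intervals(ann)
        tracks = [
            ("Promoter", promoter_windows(ann)),
            ("5UTR", utr5),
            ("3UTR", utr3),
            ("Exon", [e for g in ann.genes for e in g.exons]),
            ("Intron", [GenomicInterval(g.chrom, g.start, g.end) for g in ann.genes]),
            ("LTR", ann.repeats_of_class("LTR")),
            ("SINE", ann.repeats_of_class("SINE")),
            ("LINE", ann.repeats_of_class("LINE")),
        ]
        for p, label in zip(peaks, got):
            expect = "Intergenic"
            for name, ivs in tracks:
                if inside(p.midpoint, ivs):
                    expect = name
                    break
            assert label == expect

    def test_category_counts_partition_peaks(self):
        ann = rich_annotation()
        annotator = CategoryAnnotator(ann)
        rng = np.random.default_rng(67)
        peaks = random_intervals(rng, 500, chroms=("chr1",), max_pos=99_000)
        counts = annotator.counts(peaks)
        assert counts.sum() == len(peaks)
        assert set(counts.index) == set(CATEGORIES)

    def test_removing_unrelated_track_preserves_labels(self):
        ann = rich_annotation()
        without_ltr = GenomeAnnotation(
            ann.chrom_sizes, genes=ann.genes,
            repeats=[(iv, c) for iv, c in ann.repeats if c != "LTR"],
            cpg_islands=ann.cpg_islands,
        )
        rng = np.random.default_rng(71)
        peaks = [p for p in random_intervals(rng, 300, chroms=("chr1",),
                                             max_pos=99_000)
                 if not (60_000 - 200 <= p.midpoint < 60_500 + 200)]
        a1 = CategoryAnnotator(ann).annotate(peaks)
        a2 = CategoryAnnotator(without_ltr).annotate(peaks)
        assert a1 == a2


class TestCategoryEnrichment:
    def test_planted_ltr_peaks_are_enriched(self):
        ann = rich_annotation()
        rng = np.random.default_rng(73)
        starts = rng.integers(60_000, 60_400, size=30)
        peaks = [GenomicInterval("chr1", int(s), int(s) + 100) for s in starts]
        profile = category_enrichment(PeakSet("s", "f", "c", peaks), ann,
                                      n_rand=50, seed=0)
        row = profile.table.loc["LTR"]
        assert row["fold"] > 10
        assert row["q_value"] <= 0.05

    def test_expected_fractions_sum_to_one(self):
        ann = rich_annotation()
        rng = np.random.default_rng(79)
        peaks = random_intervals(rng, 50, chroms=("chr1",), max_pos=99_000)
        profile = category_enrichment(PeakSet("s", "f", "c", peaks), ann,
                                      n_rand=30, seed=1)
        assert profile.table["expected_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert profile.table["observed"].sum() == len(peaks)


class TestCpG:
    def test_peaks_equal_to_islands_prefer(self):
        ann = rich_annotation()
        peaks = list(ann.cpg_islands) * 20  # deduplicated to 1 by PeakSet
        ps = PeakSet("s", "f", "c", [
            GenomicInterval("chr1", 9_800 + i, 10_300 + i) for i in range(20)
        ])
        res = cpg_enrichment(ps, ann, n_rand=50, seed=0)
        assert res.label == "Prefer"
        assert res.p_value == pytest.approx(2 / 51)

    def test_empty_track_reports_not_available(self):
        ann = rich_annotation()
        ann = GenomeAnnotation(ann.chrom_sizes, genes=ann.genes,
                               repeats=ann.repeats)
        ps = PeakSet("s", "f", "c", [GenomicInterval("chr1", 0, 100)])
        res = cpg_enrichment(ps, ann)
        assert res.label == "not available"

    def test_null_peaks_are_mostly_neutral(self):
        """Shuffle-generated peaks should be labeled Neutral in >=90% of runs."""
        ann = rich_annotation()
        labels = []
        master = np.random.default_rng(83)
        for run in range(60):
            rng = np.random.default_rng(master.integers(2**31))
            peaks = [GenomicInterval("chr1", s, s + 150)
                     for s in rng.integers(0, 99_000, 40)]
            res = cpg_enrichment(PeakSet("s", "f", "c", peaks), ann,
                                 n_rand=60, seed=int(master.integers(2**31)))
            labels.append(res.label)
        assert labels.count("Neutral") / len(labels) >= 0.9
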