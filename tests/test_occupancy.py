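"""Union regions, promoter/enhancer split, overlap significance, clustering,
and Venn partitions."""

import numpy as np
import pytest

from chipcompendium.intervals import GenomicInterval
from chipcompendium.model import PeakSet
from chipcompendium.occupancy import (
    build_union_regions,
    hierarchical_cluster,
    overlap_significance,
    split_promoter_enhancer,
    venn_partition,
)

from conftest import random_intervals, toy_annotation

SIZES = {"chr1": 100_000, "chr2": 100_000}


def make_compendium(rng, n_samples=5, n_peaks=60):
    comp = {}
    for s in range(n_samples):
        peaks = random_intervals(rng, n_peaks, max_pos=90_000, max_len=200)
        comp[f"s{s}"] = PeakSet(f"s{s}", f"f{s % 2}", f"c{s % 3}", peaks)
    return comp


class TestUnionRegions:
    def test_single_sample_occupancy_all_ones(self):
        ps = PeakSet("a", "f", "c", [GenomicInterval("chr1", 0, 10),
                                     GenomicInterval("chr1", 50, 60)])
        union = build_union_regions({"a": ps})
        assert union.occupancy.shape == (2, 1)
        assert union.occupancy.all()

    def test_disjoint_samples_have_exclusive_regions(self):
        a = PeakSet("a", "f", "c", [GenomicInterval("chr1", 0, 10)])
        b = PeakSet("b", "f", "c", [GenomicInterval("chr1", 100, 110)])
        union = build_union_regions({"a": a, "b": b})
        assert union.occupancy.sum() == 2
        assert (union.occupancy.sum(axis=1) == 1).all()

    def test_empty_compendium_rejected(self):
        with pytest.raises(ValueError):
            build_union_regions({})

    def test_occupancy_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(4)
        comp = make_compendium(rng, n_samples=5, n_peaks=80)
        union = build_union_regions(comp)
        for s, sid in enumerate(union.sample_ids):
            for r, region in enumerate(union.regions):
                expect = any(region.overlaps(p) for p in comp[sid].peaks)
                assert union.occupancy[r, s] == expect
        # every region occupied by >= 1 sample
        assert union.occupancy.any(axis=1).all()


class TestPromoterEnhancerSplit:
    def test_peak_800bp_upstream_of_tss_is_promoter(self):
        ann = toy_annotation()  # gA TSS = 5000
        prom, enh = split_promoter_enhancer(
            [GenomicInterval("chr1", 4200, 4400)], ann
        )
        assert len(prom) == 1 and not enh

    def test_distal_peak_is_enhancer(self):
        ann = toy_annotation()
        prom, enh = split_promoter_enhancer(
            [GenomicInterval("chr1", 7000, 7100)], ann
        )
        assert len(enh) == 1 and not prom

    def test_no_genes_rejected(self):
        ann = toy_annotation(genes=[])
        with pytest.raises(ValueError):
            split_promoter_enhancer([GenomicInterval("chr1", 0, 10)], ann)

    def test_partition_matches_exhaustive_tss_scan(self):
        rng = np.random.default_rng(6)
        ann = toy_annotation()
        peaks = random_intervals(rng, 1000, max_pos=90_000, max_len=300)
        prom, enh = split_promoter_enhancer(peaks, ann, window_bp=1000)
        assert len(prom) + len(enh) == len(peaks)
        prom_set = {(p.chrom, p.start, p.end) for p in prom}
        for p in peaks:
            near = any(
                g.chrom == p.chrom
                and min(p.end, g.tss + 1000) - max(p.start, g.tss - 1000) >= 1
                for g in ann.genes
            )
            assert ((p.chrom, p.start, p.end) in prom_set) == near


class TestOverlapSignificance:
    def test_self_pair_observed_equals_peak_count(self):
        rng = np.random.default_rng(8)
        ps = PeakSet("a", "f", "c",
                     random_intervals(rng, 40, max_pos=90_000, max_len=150))
        sig = overlap_significance({"a": ps}, SIZES, n_rand=20, seed=0)
        assert sig.observed[0, 0] == len(ps)
        # the shuffled null essentially never reproduces perfect self-overlap
        assert sig.p_over[0, 0] == pytest.approx(1 / 21)

    def test_samples_on_different_chromosomes(self):
        a = PeakSet("a", "f", "c", [GenomicInterval("chr1", i * 500, i * 500 + 100)
                                    for i in range(20)])
        b = PeakSet("b", "f", "c", [GenomicInterval("chr2", i * 500, i * 500 + 100)
                                    for i in range(20)])
        sig = overlap_significance({"a": a, "b": b}, SIZES, n_rand=20, seed=0)
        assert sig.observed[0, 1] == 0
        assert sig.z[0, 1] <= 0

    def test_empty_sample_flagged_missing(self):
        rng = np.random.default_rng(8)
        a = PeakSet("a", "f", "c",
                    random_intervals(rng, 30, max_pos=90_000, max_len=150))
        b = PeakSet("b", "f", "c", [])
        sig = overlap_significance({"a": a, "b": b}, SIZES, n_rand=10, seed=0)
        assert sig.missing == ["b"]
        assert np.isnan(sig.observed[0, 1]) and np.isnan(sig.observed[1, 1])

    def test_correlation_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(12)
        comp = make_compendium(rng, n_samples=4)
        sig = overlap_significance(comp, SIZES, n_rand=10, seed=0)
        np.testing.assert_allclose(sig.correlation, sig.correlation.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sig.correlation), 1.0)


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero_distance(self):
        corr = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        res = hierarchical_cluster(corr, ["a", "b", "c"])
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_single_sample_tree(self):
        res = hierarchical_cluster(np.array([[1.0]]), ["only"])
        assert res.leaf_order == ["only"]
        assert res.linkage.shape == (0, 4)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[1.0, 0.5], [0.1, 1.0]]))

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(3)
        x = rng.random((6, 40))
        corr = np.corrcoef(x)
        ids = [f"s{i}" for i in range(6)]
        res = hierarchical_cluster(corr, ids)
        perm = rng.permutation(6)
        res2 = hierarchical_cluster(corr[np.ix_(perm, perm)],
                                    [ids[i] for i in perm])
        # same tree up to relabeling: identical cophenetic distances
        d1 = res.cophenetic()
        d2 = res2.cophenetic().loc[d1.index, d1.columns]
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-10)


class TestVennPartition:
    def test_five_way_has_31_cells(self):
        rng = np.random.default_rng(10)
        comp = make_compendium(rng, n_samples=5)
        union = build_union_regions(comp)
        counts, _ = venn_partition(list(comp), union)
        assert len(counts) == 31

    def test_identical_samples_all_shared(self):
        peaks = [GenomicInterval("chr1", i * 300, i * 300 + 100) for i in range(10)]
        comp = {s: PeakSet(s, "f", "c", peaks) for s in ("a", "b")}
        union = build_union_regions(comp)
        counts, shared = venn_partition(["a", "b"], union)
        assert shared == 1.0
        assert counts[3] == 10 and counts[1] == 0 and counts[2] == 0

    def test_counts_match_membership_oracle_and_sum(self):
        rng = np.random.default_rng(13)
        comp = make_compendium(rng, n_samples=3, n_peaks=50)
        union = build_union_regions(comp)
        ids = list(comp)
        counts, _ = venn_partition(ids, union)
        oracle = {}
        for r, region in enumerate(union.regions):
            mask = sum(
                (1 << i) for i, sid in enumerate(ids)
                if union.occupancy[r, union.sample_ids.index(sid)]
            )
            if mask:
                oracle[mask] = oracle.get(mask, 0) + 1
        for cell in counts:
            assert counts[cell] == oracle.get(cell, 0)
        n_any = int(union.occupancy[:, [union.sample_ids.index(s) for s in ids]]
                    .any(axis=1).sum())
        assert sum(counts.values()) == n_any

    def test_k_out_of_range(self):
        rng = np.random.default_rng(1)
        comp = make_compendium(rng, n_samples=2)
        union = build_union_regions(comp)
        with pytest.raises(ValueError):
            venn_partition(["s0"], union)
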