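"""The synthetic compendium generator: determinism, planted structure, and
the statistical features the analyses assume."""

import numpy as np
import pytest

from chipcompendium.intervals import IntervalIndex
from chipcompendium.occupancy import build_union_regions, split_compendium
from chipcompendium.simulate import (
    SimulationConfig,
    build_genome,
    default_config,
    simulate_compendium,
    write_bundle,
)


def generate(cfg):
    rng = np.random.default_rng(cfg.seed)
    seqs, ann = build_genome(cfg, rng)
    comp, truth, ann = simulate_compendium(cfg, ann, seqs, rng)
    return seqs, comp, truth, ann


class TestBuildGenome:
    def test_same_seed_identical_bytes(self, tmp_path):
        a = write_bundle(default_config(seed=5), tmp_path / "a")
        b = write_bundle(default_config(seed=5), tmp_path / "b")
        for name in ("genome.fa", "chrom.sizes", "genes.tsv", "ground_truth.json",
                     "peaks/Pu1_prog.bed"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_zero_genes_still_builds(self):
        cfg = SimulationConfig(n_genes=0, n_latent_regions=0, seed=0,
                               cpg_island_fraction=0.0, tf_gene_fraction=0.0)
        _, ann = build_genome(cfg)
        assert ann.genes == []
        assert len(ann.chrom_sizes) == cfg.n_chroms

    def test_cpg_blocks_are_gc_rich(self):
        cfg = default_config(seed=3)
        seqs, ann = build_genome(cfg, np.random.default_rng(cfg.seed))
        assert ann.cpg_islands
        gc = at = 0
        for iv in ann.cpg_islands:
            block = bytes(seqs[iv.chrom][iv.start:iv.end])
            gc += block.count(b"G") + block.count(b"C")
            at += block.count(b"A") + block.count(b"T")
        assert gc / (gc + at) >= 0.60  # configured 0.65 minus sampling noise

    def test_genes_do_not_overlap(self):
        _, ann = build_genome(default_config(seed=4))
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start


class TestSimulateCompendium:
    def test_same_seed_identical_peaks(self):
        _, c1, t1, _ = generate(default_config(seed=9))
        _, c2, t2, _ = generate(default_config(seed=9))
        for sid in c1:
            assert c1[sid].peaks == c2[sid].peaks
        assert t1.bound == t2.bound

    def test_exclusive_cell_type_binding_when_offtype_zero(self):
        cfg = SimulationConfig(
            p_bind_offtype=0.0, p_bind_celltype_enhancer=1.0,
            p_bind_shared_promoter=0.0, pu1_like_factor=False, seed=2,
        )
        _, comp, truth, _ = generate(cfg)
        owners = {r.region_id: r.owner for r in truth.regions}
        cells = cfg.cell_type_names()
        s1 = f"tf1_{cells[0]}"
        s2 = f"tf1_{cells[1]}"
        assert not set(truth.bound[s1]) & set(truth.bound[s2])
        assert all(owners[r] == cells[0] for r in truth.bound[s1])

    def test_ground_truth_peak_count_matches_emitted_peaks(self):
        _, comp, truth, _ = generate(default_config(seed=11))
        assert truth.n_peaks() == sum(len(ps) for ps in comp.values())
        for sid, ps in comp.items():
            assert len(truth.peak_regions[sid]) == len(ps)

    def test_peak_region_ids_align_with_sorted_peaks(self):
        _, comp, truth, _ = generate(default_config(seed=12))
        regions = {r.region_id: r.interval for r in truth.regions}
        for sid, ps in comp.items():
            for peak, rid in zip(ps.peaks, truth.peak_regions[sid]):
                assert peak.overlaps(regions[rid])

    def test_unknown_sample_in_planted_spacing_rejected(self):
        cfg = default_config(seed=1)
        cfg.planted_spacings[0].samples = ["nonexistent_sample"]
        rng = np.random.default_rng(cfg.seed)
        seqs, ann = build_genome(cfg, rng)
        with pytest.raises(ValueError, match="unknown samples"):
            simulate_compendium(cfg, ann, seqs, rng)

    def test_within_cell_type_enhancer_correlation_exceeds_between(
            self, default_study):
        cfg, comp, truth, ann, _ = default_study
        _, enh = split_compendium(comp, ann)
        union = build_union_regions(enh)
        occ = union.occupancy.astype(float)
        corr = np.corrcoef(occ.T)
        ids = union.sample_ids
        cell = {sid: comp[sid].cell_type for sid in ids}
        factor = {sid: comp[sid].factor for sid in ids}
        within, between = [], []
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if j <= i or "Pu1" in (factor[a], factor[b]):
                    continue
                (within if cell[a] == cell[b] else between).append(corr[i, j])
        assert np.mean(within) > np.mean(between)

    def test_pu1_samples_share_enhancers_across_cell_types(self, default_study):
        cfg, comp, truth, ann, _ = default_study
        _, enh = split_compendium(comp, ann)

        def jaccard(a, b):
            sa = {(p.chrom, p.start) for p in enh[a].peaks}
            sb = {(p.chrom, p.start) for p in enh[b].peaks}
            # peaks at the same latent region share centers but not exact
            # coordinates, so compare bound-region sets from the truth
            ra, rb = set(truth.bound[a]), set(truth.bound[b])
            return len(ra & rb) / len(ra | rb)

        pu1 = [s for s in comp if comp[s].factor == "Pu1"]
        pu1_pairs = [jaccard(a, b) for i, a in enumerate(pu1)
                     for b in pu1[i + 1:]]
        cross = []
        for a in pu1:
            for b in comp:
                if b not in pu1 and comp[b].cell_type == comp[a].cell_type:
                    cross.append(jaccard(a, b))
        assert min(pu1_pairs) > max(cross)

    def test_conserved_fraction_nondecreasing_in_multiplicity(self, default_study):
        cfg, comp, truth, ann, _ = default_study
        conserved = set(truth.conserved_region_ids)
        fractions = []
        for m in sorted(set(truth.multiplicity.values()) - {0}):
            rids = [r for r, mm in truth.multiplicity.items() if mm == m]
            if len(rids) < 20:
                continue
            fractions.append(np.mean([r in conserved for r in rids]))
        assert len(fractions) >= 3
        # allow binomial noise: each step may dip by at most a small margin
        for a, b in zip(fractions, fractions[1:]):
            assert b >= a - 0.08

    def test_composites_planted_into_co_bound_regions(self, default_study):
        cfg, comp, truth, ann, seqs = default_study
        (sp,) = cfg.planted_spacings
        co_bound = set(truth.bound[sp.samples[0]]) & set(truth.bound[sp.samples[1]])
        for ins in truth.composite_insertions:
            assert ins["region_id"] in co_bound
            chrom_seq = bytes(seqs[ins["chrom"]]).decode()
            anchor_seq = sp.anchor.max_score_sequence()
            start = ins["start"]
            got = chrom_seq[start:start + len(anchor_seq)]
            assert got == anchor_seq
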