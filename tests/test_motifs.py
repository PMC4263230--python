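"""PWM scanning against a brute-force scorer and matched-random-set
enrichment behaviour."""

import numpy as np
import pytest

from chipcompendium.model import (
    MotifModel,
    consensus_motif,
    pfm_from_consensus,
    reverse_complement,
)
from chipcompendium.motifs import (
    GenomeSampler,
    MotifEnrichment,
    enrichment_heatmap,
    log_odds_matrix,
    motif_enrichment,
    promoter_enhancer_specific_motifs,
    scan_pwm,
)

BG = [0.25, 0.25, 0.25, 0.25]


def brute_force_hits(seq, motif, background=BG):
    """Score every offset on both strands with plain Python loops."""
    lo = log_odds_matrix(motif, background)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    thr = motif.threshold_fraction * lo[:4].max(axis=0).sum()
    L = motif.length
    hits = []
    for strand in "+-":
        target = seq if strand == "+" else reverse_complement(seq)
        for off in range(len(seq) - L + 1):
            window = target[off:off + L]
            score = sum(
                lo[base_idx.get(b, 4), j] for j, b in enumerate(window)
            )
            if score >= thr:
                pos = off if strand == "+" else len(seq) - off - L
                hits.append((pos, strand, round(score, 9)))
    return sorted(hits)


class TestScanPwm:
    def test_gata_consensus_single_plus_hit(self):
        m = pfm_from_consensus("GATA", "gata")
        m.threshold_fraction = 1.0
        hits = scan_pwm("TTGATATT", m, BG)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (2, "+")

    def test_motif_longer_than_sequence_is_empty(self):
        m = pfm_from_consensus("GATAGATA", "m")
        assert scan_pwm("ACG", m, BG) == []

    def test_matches_brute_force_scorer_on_random_pairs(self):
        rng = np.random.default_rng(31)
        for k in range(100):
            L = int(rng.integers(4, 9))
            mat = rng.integers(0, 20, size=(4, L)) + 1
            m = MotifModel(f"m{k}", matrix=mat,
                           threshold_fraction=float(rng.uniform(0.6, 0.95)))
            seq = "".join(np.array(list("ACGTN"))[
                rng.choice(5, size=60, p=[0.24, 0.24, 0.24, 0.24, 0.04])])
            got = sorted((h.start, h.strand, round(h.score, 9))
                         for h in scan_pwm(seq, m, BG))
            assert got == brute_force_hits(seq, m)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(41)
        m = MotifModel("m", matrix=rng.integers(1, 15, size=(4, 6)),
                       threshold_fraction=0.8)
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
            fwd = {(h.start, h.strand) for h in scan_pwm(seq, m, BG)}
            rc = {(len(seq) - h.end, "+-"["+-".index(h.strand) ^ 1])
                  for h in scan_pwm(reverse_complement(seq), m, BG)}
            assert fwd == rc

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(43)
        mat = rng.integers(1, 15, size=(4, 6))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        prev = None
        for thr in (0.6, 0.7, 0.8, 0.9, 1.0):
            m = MotifModel("m", matrix=mat, threshold_fraction=thr)
            n = len(scan_pwm(seq, m, BG))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_n_bases_score_as_background(self):
        m = pfm_from_consensus("GATA", "m")
        m.threshold_fraction = 1.0
        # an N in the window contributes zero log-odds, so it cannot reach
        # the full maximum score of a sharply peaked matrix
        assert scan_pwm("TTGANATT", m, BG) == []

    def test_consensus_iupac_matching_both_strands(self):
        m = consensus_motif("CANNTG")  # E-box
        hits = scan_pwm("AACAGGTGAA", m)
        assert {(h.start, h.strand) for h in hits} == {(2, "+"), (2, "-")}


class TestMotifEnrichment:
    @pytest.fixture()
    def sampler(self, uniform_genome):
        fasta, sizes, _ = uniform_genome
        return GenomeSampler(sizes, fasta)

    def _random_seqs(self, rng, n=40, length=150):
        return ["".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
                for _ in range(n)]

    def test_planted_motif_detected_and_absent_motif_null(self, sampler):
        rng = np.random.default_rng(47)
        seqs = self._random_seqs(rng)
        planted = pfm_from_consensus("AGATAAGA", "planted")
        # never-matching motif: requires a 12-mer of alternating GC absent by chance
        for i in range(20):
            s = seqs[i]
            pos = int(rng.integers(0, len(s) - 8))
            seqs[i] = s[:pos] + "AGATAAGA" + s[pos + 8:]
        decoy = pfm_from_consensus("GCGCGCGCGCGC", "decoy")
        res = motif_enrichment(seqs, [planted, decoy], sampler,
                               n_sets=100, seed=3)
        by_id = {r.motif_id: r for r in res}
        assert by_id["planted"].enriched
        assert by_id["planted"].p_value == pytest.approx(1 / 101)
        assert not by_id["decoy"].enriched

    def test_zero_hit_motif_reports_fold_zero_p_one(self, sampler):
        rng = np.random.default_rng(53)
        seqs = self._random_seqs(rng, n=15)
        never = pfm_from_consensus("GCGCGCGCGCGCGC", "never")
        (res,) = motif_enrichment(seqs, [never], sampler, n_sets=20, seed=0)
        assert res.observed == 0 and res.fold == 0.0 and res.p_value == 1.0

    def test_minimum_peak_count_enforced(self, sampler):
        with pytest.raises(ValueError):
            motif_enrichment(["ACGT" * 10] * 5, [], sampler)


class TestHeatmap:
    def _enr(self, motif_id, enriched):
        return MotifEnrichment(motif_id, 10, 5.0, 1.0, 2.0, 0.01, 0.01, enriched)

    def test_columns_restricted_to_enriched_motifs(self):
        per_sample = {
            "s1": [self._enr("m1", True), self._enr("m2", False)],
            "s2": [self._enr("m1", False), self._enr("m2", False)],
        }
        binary, fold = enrichment_heatmap(per_sample)
        assert list(binary.columns) == ["m1"]
        assert binary.loc["s1", "m1"] == 1 and binary.loc["s2", "m1"] == 0

    def test_no_enrichment_gives_empty_columns(self):
        per_sample = {"s1": [self._enr("m1", False)]}
        binary, _ = enrichment_heatmap(per_sample)
        assert binary.shape == (1, 0)

    def test_universally_planted_motif_fills_column(self):
        per_sample = {f"s{i}": [self._enr("m1", True)] for i in range(4)}
        binary, _ = enrichment_heatmap(per_sample)
        assert (binary["m1"] == 1).all()


class TestClassSpecificMotifs:
    def test_promoter_only_plant_is_promoter_specific(self, uniform_genome):
        fasta, sizes, _ = uniform_genome
        sampler = GenomeSampler(sizes, fasta)
        rng = np.random.default_rng(59)
        mk = lambda: ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
                      for _ in range(30)]
        prom, enh = mk(), mk()
        motif = pfm_from_consensus("TTGCGCAAT", "m")
        prom = [s[:60] + "TTGCGCAAT" + s[69:] if i < 20 else s
                for i, s in enumerate(prom)]
        calls = promoter_enhancer_specific_motifs(
            prom, enh, [motif], sampler, n_sets=50, seed=0)
        assert calls[0].label == "promoter-specific"

    def test_class_below_minimum_size_rejected(self, uniform_genome):
        fasta, sizes, _ = uniform_genome
        sampler = GenomeSampler(sizes, fasta)
        with pytest.raises(ValueError):
            promoter_enhancer_specific_motifs(
                ["ACGT" * 20] * 3, ["ACGT" * 20] * 30, [], sampler)
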