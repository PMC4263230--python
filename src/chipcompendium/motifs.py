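"""PWM / consensus scanning and motif over-representation analysis.

Scanning scores log-odds of a position frequency matrix (pseudocount added
per cell) against a background mononucleotide composition; a window is a hit
when its score reaches ``threshold_fraction`` of the maximum achievable
score.  ``N`` bases contribute zero log-odds.  Over-representation follows a
matched-random-set design: the fraction of peaks containing a hit is
compared against random genomic sequence sets of identical number and
lengths, with an empirical add-one p-value and Benjamini-Hochberg control
across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import false_discovery_control

from .intervals import GenomicInterval
from .model import IUPAC, MotifModel, reverse_complement

_ENC = np.full(256, 4, dtype=np.int8)  # everything unknown -> N slot
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_IUPAC_MASK = {code: sum(1 << "ACGT".index(b) for b in bases)
               for code, bases in IUPAC.items()}
_BASE_MASK = np.zeros(5, dtype=np.int8)
_BASE_MASK[:4] = [1, 2, 4, 8]
_BASE_MASK[4] = 15  # N matches any code
_BASE_MASK_EXT = np.zeros(6, dtype=np.int8)
_BASE_MASK_EXT[:5] = _BASE_MASK  # code 5 = boundary, matches nothing


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, other=4 (N)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    """One scored motif match inside a scanned sequence.

    ``start`` is the 0-based offset of the match on the + strand coordinate
    system of the scanned sequence, regardless of the hit strand.
    """

    motif_id: str
    start: int
    end: int
    strand: str
    score: float


def log_odds_matrix(motif: MotifModel, background: Sequence[float] | None = None
                    ) -> np.ndarray:
    """6 x L log-odds matrix (rows A,C,G,T,N,block); the N row is all zeros.

    The sixth row is a large negative sentinel used to block windows from
    crossing sequence boundaries in batched scans.
    """
    if motif.matrix is None:
        raise ValueError("consensus motifs have no log-odds matrix")
    bg = np.asarray(background if background is not None else [0.25] * 4, float)
    bg = bg / bg.sum()
    counts = motif.matrix + motif.pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    lo = np.zeros((6, motif.length))
    lo[:4] = np.log2(probs / bg[:, None])
    lo[5] = -1e9
    return lo


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    L = lo.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    out = lo[:, 0][codes[:n]].copy()
    for j in range(1, L):  # shifted gathers beat a windows matrix here
        out += lo[:, j][codes[j:j + n]]
    return out


def scan_pwm(
    sequence: str,
    motif: MotifModel,
    background: Sequence[float] | None = None,
) -> list[MotifHit]:
    """All hits of ``motif`` in ``sequence`` on both strands, sorted by offset.

    Consensus motifs are matched exactly against their IUPAC codes (score 1.0,
    threshold implicit); PFM motifs are scored by log-odds with the hit
    threshold at ``threshold_fraction`` of the best achievable score.
    """
    codes = encode(sequence)
    L = motif.length
    if codes.size < L:
        return []
    hits: list[MotifHit] = []
    if motif.matrix is not None:
        lo = log_odds_matrix(motif, background)
        threshold = motif.threshold_fraction * lo[:4].max(axis=0).sum()
        for strand, mat in (("+", lo), ("-", lo[[3, 2, 1, 0, 4, 5]][:, ::-1])):
            scores = _window_scores(codes, mat)
            for off in np.nonzero(scores >= threshold)[0]:
                hits.append(MotifHit(motif.motif_id, int(off), int(off) + L,
                                     strand, float(scores[off])))
    else:
        masks = np.array([_IUPAC_MASK[c] for c in motif.consensus], dtype=np.int8)
        seq_masks = _BASE_MASK[codes]
        windows = np.lib.stride_tricks.sliding_window_view(seq_masks, L)
        fwd = np.all(windows & masks, axis=1)
        rc = np.array([_IUPAC_MASK[c] for c in reverse_complement(motif.consensus)],
                      dtype=np.int8)
        rev = np.all(windows & rc, axis=1)
        for off in np.nonzero(fwd)[0]:
            hits.append(MotifHit(motif.motif_id, int(off), int(off) + L, "+", 1.0))
        for off in np.nonzero(rev)[0]:
            hits.append(MotifHit(motif.motif_id, int(off), int(off) + L, "-", 1.0))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def has_hit(sequence: str, motif: MotifModel,
            background: Sequence[float] | None = None) -> bool:
    return bool(scan_pwm(sequence, motif, background))


def best_hit(sequence: str, motif: MotifModel,
             background: Sequence[float] | None = None) -> MotifHit | None:
    """Highest-scoring hit; ties broken by leftmost start, then + strand."""
    hits = scan_pwm(sequence, motif, background)
    if not hits:
        return None
    return max(hits, key=lambda h: (h.score, -h.start, h.strand == "+"))


class SequenceBatch:
    """Concatenated encoding of a sequence collection for fast batch scans.

    Sequences are joined with a blocking sentinel so no scan window can span
    two sequences; hit positions map back to sequence indices by offset.
    """

    def __init__(self, sequences: Sequence[str]):
        self.n = len(sequences)
        parts, starts, pos = [], [], 0
        sep = np.array([5], dtype=np.int8)
        for seq in sequences:
            codes = encode(seq)
            starts.append(pos)
            parts.append(codes)
            parts.append(sep)
            pos += codes.size + 1
        self.codes = (np.concatenate(parts) if parts
                      else np.empty(0, dtype=np.int8))
        self.starts = np.array(starts, dtype=np.int64)

    def _hit_positions_pwm(self, motif: MotifModel, background) -> np.ndarray:
        lo = log_odds_matrix(motif, background)
        thr = motif.threshold_fraction * lo[:4].max(axis=0).sum()
        hits = []
        for mat in (lo, lo[[3, 2, 1, 0, 4, 5]][:, ::-1]):
            scores = _window_scores(self.codes, mat)
            hits.append(np.nonzero(scores >= thr)[0])
        return np.concatenate(hits) if hits else np.empty(0, dtype=np.int64)

    def _hit_positions_consensus(self, motif: MotifModel) -> np.ndarray:
        L = motif.length
        if self.codes.size < L:
            return np.empty(0, dtype=np.int64)
        seq_masks = _BASE_MASK_EXT[self.codes]
        windows = np.lib.stride_tricks.sliding_window_view(seq_masks, L)
        hits = []
        for pattern in (motif.consensus, reverse_complement(motif.consensus)):
            masks = np.array([_IUPAC_MASK[c] for c in pattern], dtype=np.int8)
            hits.append(np.nonzero(np.all(windows & masks, axis=1))[0])
        return np.concatenate(hits)

    def sequences_with_hit(self, motif: MotifModel, background=None) -> np.ndarray:
        """Boolean per-sequence flag: does the motif hit it on either strand?"""
        out = np.zeros(self.n, dtype=bool)
        if self.n == 0:
            return out
        pos = (self._hit_positions_consensus(motif) if motif.matrix is None
               else self._hit_positions_pwm(motif, background))
        if pos.size:
            idx = np.searchsorted(self.starts, pos, side="right") - 1
            out[np.unique(idx)] = True
        return out


def genome_background(sequences: Sequence[str]) -> np.ndarray:
    """Mononucleotide composition over a sequence collection (ACGT, sums to 1)."""
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


@dataclass
class MotifEnrichment:
    motif_id: str
    observed: int
    null_mean: float
    null_sd: float
    fold: float
    p_value: float
    q_value: float = np.nan
    enriched: bool = False
    # null tail counts backing the add-one p; n_ge counts sets with
    # statistic >= observed, n_gt strictly greater (for tie-randomised
    # calibration diagnostics on an inherently discrete statistic)
    n_sets: int = 0
    n_ge: int = 0
    n_gt: int = 0


class GenomeSampler:
    """Draws length-matched random genomic intervals, uniform over positions."""

    def __init__(self, chrom_sizes: dict[str, int], fasta):
        self.chroms = list(chrom_sizes)
        self.sizes = np.array([chrom_sizes[c] for c in self.chroms], dtype=np.int64)
        self.fasta = fasta

    def sample_set(self, lengths: Sequence[int], rng: np.random.Generator
                   ) -> list[str]:
        from .io import extract_sequences

        intervals = []
        for L in lengths:
            room = self.sizes - L + 1
            ok = room > 0
            if not ok.any():
                raise ValueError(f"no chromosome can host a {L} bp interval")
            w = np.where(ok, room, 0).astype(float)
            ci = rng.choice(len(self.chroms), p=w / w.sum())
            start = int(rng.integers(0, room[ci]))
            intervals.append(GenomicInterval(self.chroms[ci], start, start + L))
        return extract_sequences(intervals, self.fasta)


def count_peaks_with_hit(sequences: Sequence[str] | SequenceBatch,
                         motif: MotifModel, background) -> int:
    batch = sequences if isinstance(sequences, SequenceBatch) else SequenceBatch(sequences)
    return int(batch.sequences_with_hit(motif, background).sum())


def motif_enrichment(
    peak_sequences: Sequence[str],
    motif_list: Sequence[MotifModel],
    sampler: GenomeSampler,
    n_sets: int = 100,
    seed: int = 0,
    background: Sequence[float] | None = None,
    min_fold: float = 1.5,
    q_max: float = 0.05,
) -> list[MotifEnrichment]:
    """Per-motif over-representation vs length-matched random sequence sets.

    The statistic is the number of peaks containing at least one hit.  The
    null is ``n_sets`` random genomic sets of identical count and lengths;
    p = (#sets with statistic >= observed + 1) / (n_sets + 1).  A motif is
    flagged enriched when its BH q-value is <= ``q_max`` and its fold change
    over the null mean is >= ``min_fold``.
    """
    if len(peak_sequences) < 10:
        raise ValueError("need at least 10 peak sequences")
    rng = np.random.default_rng(seed)
    lengths = [len(s) for s in peak_sequences]
    if background is None:
        background = genome_background(peak_sequences)
    obs_batch = SequenceBatch(peak_sequences)
    observed = np.array(
        [count_peaks_with_hit(obs_batch, m, background) for m in motif_list]
    )
    null = np.zeros((n_sets, len(motif_list)))
    for k in range(n_sets):
        rand_batch = SequenceBatch(sampler.sample_set(lengths, rng))
        null[k] = [count_peaks_with_hit(rand_batch, m, background)
                   for m in motif_list]
    n_ge = (null >= observed).sum(axis=0)
    n_gt = (null > observed).sum(axis=0)
    p = (n_ge + 1) / (n_sets + 1)
    q = false_discovery_control(p, method="bh")
    means, sds = null.mean(axis=0), null.std(axis=0, ddof=1)
    out = []
    for i, m in enumerate(motif_list):
        fold = 0.0 if observed[i] == 0 else (
            float("inf") if means[i] == 0 else observed[i] / means[i]
        )
        out.append(
            MotifEnrichment(
                motif_id=m.motif_id,
                observed=int(observed[i]),
                null_mean=float(means[i]),
                null_sd=float(sds[i]),
                fold=fold,
                p_value=float(p[i]),
                q_value=float(q[i]),
                enriched=bool(q[i] <= q_max and fold >= min_fold),
                n_sets=n_sets,
                n_ge=int(n_ge[i]),
                n_gt=int(n_gt[i]),
            )
        )
    return out


def enrichment_heatmap(
    per_sample: dict[str, list[MotifEnrichment]],
):
    """Binary and fold matrices (samples x motifs), columns restricted to
    motifs enriched in at least one sample; deterministic ordering."""
    import pandas as pd

    samples = list(per_sample)
    motif_ids = sorted({e.motif_id for res in per_sample.values() for e in res})
    binary = pd.DataFrame(0, index=samples, columns=motif_ids, dtype=int)
    fold = pd.DataFrame(np.nan, index=samples, columns=motif_ids)
    for s, res in per_sample.items():
        for e in res:
            binary.loc[s, e.motif_id] = int(e.enriched)
            fold.loc[s, e.motif_id] = e.fold
    keep = [m for m in motif_ids if binary[m].any()]
    return binary[keep], fold[keep]


@dataclass
class MotifClassCall:
    motif_id: str
    promoter_enriched: bool
    enhancer_enriched: bool

    @property
    def label(self) -> str:
        if self.promoter_enriched and self.enhancer_enriched:
            return "both"
        if self.promoter_enriched:
            return "promoter-specific"
        if self.enhancer_enriched:
            return "enhancer-specific"
        return "neither"


def promoter_enhancer_specific_motifs(
    promoter_sequences: Sequence[str],
    enhancer_sequences: Sequence[str],
    motif_list: Sequence[MotifModel],
    sampler: GenomeSampler,
    n_sets: int = 100,
    seed: int = 0,
    min_class_size: int = 10,
    **kwargs,
) -> list[MotifClassCall]:
    """Classify motifs as promoter-specific / enhancer-specific / both / neither
    by running the matched-random-set enrichment separately per peak class."""
    if len(promoter_sequences) < min_class_size or len(enhancer_sequences) < min_class_size:
        raise ValueError(
            f"both classes need >= {min_class_size} sequences "
            f"(got {len(promoter_sequences)} promoter, {len(enhancer_sequences)} enhancer)"
        )
    prom = motif_enrichment(promoter_sequences, motif_list, sampler,
                            n_sets=n_sets, seed=seed, **kwargs)
    enh = motif_enrichment(enhancer_sequences, motif_list, sampler,
                           n_sets=n_sets, seed=seed + 1, **kwargs)
    return [
        MotifClassCall(m.motif_id, m.enriched, e.enriched)
        for m, e in zip(prom, enh)
    ]
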