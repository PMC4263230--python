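"""Domain containers: peak sets, genome annotation, motif models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .intervals import GenomicInterval, sort_intervals

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PeakSet:
    """One ChIP-seq sample: the called peaks of one factor in one cell type."""

    sample_id: str
    factor: str
    cell_type: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.peaks = sort_intervals(dict.fromkeys(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def shuffled(self, chrom_sizes: dict[str, int], seed: int) -> "PeakSet":
        """Length-preserving within-chromosome uniform random relocation.

        This is the randomisation null used throughout: each peak keeps its
        chromosome and length and receives a uniform start on
        ``[0, chrom_len - length]``.  Output peaks may overlap each other.
        """
        rng = np.random.default_rng(seed)
        moved: list[GenomicInterval] = []
        for iv in self.peaks:
            clen = chrom_sizes[iv.chrom]
            if iv.length > clen:
                raise ValueError(
                    f"peak length {iv.length} exceeds {iv.chrom} length {clen}"
                )
            s = int(rng.integers(0, clen - iv.length + 1))
            moved.append(GenomicInterval(iv.chrom, s, s + iv.length, iv.strand))
        return PeakSet(self.sample_id, self.factor, self.cell_type, moved)


def shuffle_peaks(peaks: PeakSet, chrom_sizes: dict[str, int], seed: int) -> PeakSet:
    """Functional alias for :meth:`PeakSet.shuffled`."""
    return peaks.shuffled(chrom_sizes, seed)


Compendium = dict[str, PeakSet]  # sample_id -> PeakSet, insertion-ordered


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # leftmost transcribed position (bp)
    end: int    # rightmost transcribed position (exclusive)
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start site: gene start on +, gene end on - strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


REPEAT_CLASSES = ("LINE", "SINE", "LTR")


@dataclass
class GenomeAnnotation:
    """Everything the analyses need to know about the genome besides sequence."""

    chrom_sizes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    repeats: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    conserved_regions: list[GenomicInterval] = field(default_factory=list)
    validated_enhancers: list[GenomicInterval] = field(default_factory=list)
    tf_gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for iv, cls in self.repeats:
            if cls not in REPEAT_CLASSES:
                raise ValueError(f"unknown repeat class {cls!r}")
        for iv in self._all_intervals():
            clen = self.chrom_sizes.get(iv.chrom)
            if clen is None:
                raise ValueError(f"interval on unknown chromosome {iv.chrom}")
            if iv.end > clen:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} beyond length {clen}"
                )

    def _all_intervals(self) -> Iterable[GenomicInterval]:
        yield from self.cpg_islands
        yield from (iv for iv, _ in self.repeats)
        yield from self.conserved_regions
        yield from self.validated_enhancers
        for g in self.genes:
            yield GenomicInterval(g.chrom, g.start, g.end, g.strand)

    def repeats_of_class(self, cls: str) -> list[GenomicInterval]:
        return [iv for iv, c in self.repeats if c == cls]

    def tss_table(self) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
        """(gene_ids, tss, chroms, strand_sign) sorted by gene_id.

        Lexicographic gene_id order makes argmin tie-breaking deterministic:
        the first minimum is the lexicographically smallest gene.
        """
        genes = sorted(self.genes, key=lambda g: g.gene_id)
        ids = [g.gene_id for g in genes]
        tss = np.array([g.tss for g in genes], dtype=np.int64)
        chroms = [g.chrom for g in genes]
        sign = np.array([1 if g.strand == "+" else -1 for g in genes], dtype=np.int64)
        return ids, tss, chroms, sign


@dataclass
class MotifModel:
    """A TF binding-sequence model: a 4xL count matrix or an IUPAC consensus.

    ``matrix`` rows are A, C, G, T.  PWM scanning adds ``pseudocount`` to every
    cell, converts to log-odds against a background composition, and calls a
    hit wherever the window score reaches ``threshold_fraction`` of the best
    achievable score.  Consensus models are matched exactly (every position
    must be compatible with the IUPAC code).
    """

    motif_id: str
    name: str = ""
    matrix: np.ndarray | None = None
    consensus: str | None = None
    pseudocount: float = 0.25
    threshold_fraction: float = 0.85

    def __post_init__(self) -> None:
        if (self.matrix is None) == (self.consensus is None):
            raise ValueError("provide exactly one of matrix / consensus")
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 3:
                raise ValueError("matrix must be 4 x L with L >= 3")
            if np.any(self.matrix < 0):
                raise ValueError("matrix counts must be nonnegative")
            if np.any(self.matrix.sum(axis=0) <= 0):
                raise ValueError("matrix column sums must be strictly positive")
        else:
            self.consensus = self.consensus.upper()
            if len(self.consensus) < 3:
                raise ValueError("consensus must have length >= 3")
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC codes in consensus: {sorted(bad)}")
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def length(self) -> int:
        return self.matrix.shape[1] if self.matrix is not None else len(self.consensus)

    def max_score_sequence(self) -> str:
        """The best-scoring sequence (first base on count ties)."""
        if self.matrix is not None:
            return "".join(BASES[i] for i in np.argmax(self.matrix, axis=0))
        return "".join(IUPAC[c][0] for c in self.consensus)


def consensus_motif(pattern: str, motif_id: str | None = None) -> MotifModel:
    return MotifModel(motif_id=motif_id or pattern, name=pattern, consensus=pattern)


def pfm_from_consensus(pattern: str, motif_id: str, counts: int = 100) -> MotifModel:
    """A sharply peaked PFM whose columns follow an IUPAC consensus."""
    pattern = pattern.upper()
    mat = np.zeros((4, len(pattern)))
    for j, code in enumerate(pattern):
        allowed = IUPAC[code]
        for b in allowed:
            mat[BASES.index(b), j] = counts / len(allowed)
    return MotifModel(motif_id=motif_id, name=pattern, matrix=mat)
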