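"""Readers and writers for every on-disk format the pipeline touches.

Formats: BED3+ for peaks and interval tracks (repeat files carry the repeat
class in column 4), a RefSeq-style tab-separated gene table, two-column
chrom.sizes, FASTA (via pyfaidx), JASPAR PFM text (via Bio.motifs), one-id-
per-line TF lists, and GMT-style gene sets.
"""

from __future__ import annotations

import logging
import textwrap
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

from .intervals import GenomicInterval
from .model import Gene, GenomeAnnotation, MotifModel, PeakSet

log = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    pass


def _bed_records(path: str | Path, min_cols: int = 3):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            yield lineno, fields[0], start, end, fields[3:]


def read_bed(
    path: str | Path,
    sample_id: str = "",
    factor: str = "",
    cell_type: str = "",
) -> PeakSet:
    """Read a BED3+ peak file into a sorted, deduplicated :class:`PeakSet`."""
    peaks = [
        GenomicInterval(chrom, start, end)
        for _, chrom, start, end, _ in _bed_records(path)
    ]
    return PeakSet(sample_id or Path(path).stem, factor, cell_type, peaks)


def read_interval_bed(path: str | Path) -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, start, end)
        for _, chrom, start, end, _ in _bed_records(path)
    ]


def read_repeat_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED with the repeat class (LINE/SINE/LTR) in column 4."""
    out = []
    for lineno, chrom, start, end, rest in _bed_records(path, min_cols=4):
        out.append((GenomicInterval(chrom, start, end), rest[0]))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              extra: Sequence[Sequence] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra is not None:
                cols.extend(str(x) for x in extra[i])
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


GENE_TABLE_COLUMNS = (
    "gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends"
)


def read_gene_table(path: str | Path) -> list[Gene]:
    """Tab-separated gene table with the RefSeq-style comma-list exon columns."""
    genes: list[Gene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in GENE_TABLE_COLUMNS[:5]}
        has_exons = "exon_starts" in header and "exon_ends" in header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[idx["tx_start"]]), int(f[idx["tx_end"]])
            chrom, strand = f[idx["chrom"]], f[idx["strand"]]
            exons: list[GenomicInterval] = []
            if has_exons:
                es = f[header.index("exon_starts")].strip(",")
                ee = f[header.index("exon_ends")].strip(",")
                if es and ee:
                    exons = [
                        GenomicInterval(chrom, int(a), int(b), strand)
                        for a, b in zip(es.split(","), ee.split(","))
                    ]
            genes.append(Gene(f[idx["gene_id"]], chrom, strand, start, end, exons))
    return genes


def write_gene_table(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            es = ",".join(str(e.start) for e in g.exons)
            ee = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{es}\t{ee}\n"
            )


def read_tf_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_annotation(
    gene_table: str | Path,
    chrom_sizes: str | Path,
    cpg_bed: str | Path | None = None,
    repeat_bed: str | Path | None = None,
    conserved_bed: str | Path | None = None,
    validated_bed: str | Path | None = None,
    tf_list: str | Path | None = None,
) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from its constituent files.

    Optional files that are missing or ``None`` yield empty tracks with a
    logged warning; downstream analyses then report those results as
    unavailable rather than computing them from nothing.
    """

    def _optional(path, reader, what):
        if path is None or not Path(path).exists():
            log.warning("%s file not provided; %s analyses will be unavailable",
                        what, what)
            return []
        return reader(path)

    return GenomeAnnotation(
        chrom_sizes=read_chrom_sizes(chrom_sizes),
        genes=read_gene_table(gene_table),
        cpg_islands=_optional(cpg_bed, read_interval_bed, "CpG island"),
        repeats=_optional(repeat_bed, read_repeat_bed, "repeat"),
        conserved_regions=_optional(conserved_bed, read_interval_bed, "conserved region"),
        validated_enhancers=_optional(validated_bed, read_interval_bed,
                                      "validated enhancer"),
        tf_gene_ids=set(_optional(tf_list, read_tf_list, "TF gene list")),
    )


def read_jaspar(path: str | Path, pseudocount: float = 0.25,
                threshold_fraction: float = 0.85) -> list[MotifModel]:
    """Read JASPAR-format PFMs (``>id name`` then four A/C/G/T count rows)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(
            MotifModel(
                motif_id=m.matrix_id or m.name,
                name=m.name or m.matrix_id,
                matrix=mat,
                pseudocount=pseudocount,
                threshold_fraction=threshold_fraction,
            )
        )
    return out


def write_jaspar(motif_list: Sequence[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motif_list:
            if m.matrix is None:
                raise ValueError(f"{m.motif_id}: consensus motifs have no PFM")
            fh.write(f">{m.motif_id} {m.name}\n")
            for base, row in zip("ACGT", m.matrix):
                cells = " ".join(f"{int(v)}" if float(v).is_integer() else f"{v:.2f}"
                                 for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-style gene sets: name <tab> description <tab> gene ids..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3 and f[0]:
                sets[f[0]] = {g for g in f[2:] if g}
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")


def extract_sequences(
    intervals: Sequence[GenomicInterval], fasta: str | Path | Fasta
) -> list[str]:
    """Uppercase plus-strand sequences for the given intervals."""
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    out: list[str] = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise KeyError(f"chromosome {iv.chrom} absent from FASTA")
        out.append(str(fa[iv.chrom][iv.start:iv.end]).upper())
    return out
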