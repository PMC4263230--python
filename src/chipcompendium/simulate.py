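"""Synthetic genome + multi-sample peak compendium with known ground truth.

The generator emulates the statistical structures a multi-factor ChIP-seq
compendium analysis assumes:

* latent regulatory regions split into promoters (near TSSs, bound by nearly
  every sample) and enhancers (distal, owned by one cell type and bound
  mostly by that cell type's samples);
* one optional "Pu.1-like" factor whose enhancer repertoire follows the
  factor rather than the cell type, so its samples cluster together;
* sequence motifs planted into bound regions (optionally restricted to an
  owner cell type or to regions bound by particular samples);
* composite motif pairs planted at a fixed gap into regions co-bound by a
  given set of samples;
* conservation and in-vivo validation probabilities that increase with the
  number of distinct factors bound;
* elevated enhancer density around transcription-factor gene loci.

All randomness flows from a single seeded generator, and sample order is
fixed, so a given config reproduces its bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as cio
from .intervals import GenomicInterval
from .model import (
    Compendium,
    Gene,
    GenomeAnnotation,
    MotifModel,
    PeakSet,
    pfm_from_consensus,
    reverse_complement,
)

PU1_OWNER = "PU1"


@dataclass
class PlantedMotif:
    """Plant ``motif`` into eligible bound latent regions with ``probability``.

    Eligibility: region owner in ``owners`` (enhancer owner cell type,
    ``"PU1"``, or ``"promoter"``), and/or region bound by one of ``samples``.
    ``None`` means unrestricted.
    """

    motif: MotifModel
    probability: float
    owners: list[str] | None = None
    samples: list[str] | None = None


@dataclass
class PlantedSpacing:
    """Plant anchor+partner at a fixed signed gap into co-bound regions.

    ``gap`` counts bases strictly between the anchor end and partner start;
    negative values overlap the partner into the anchor's 3' end.  The
    composite is inserted, both parts on the + strand, into a ``fraction`` of
    the latent regions bound by every sample in ``samples``.
    """

    anchor: MotifModel
    partner: MotifModel | str  # MotifModel or plain k-mer string
    gap: int
    fraction: float
    samples: list[str]

    @property
    def partner_seq(self) -> str:
        if isinstance(self.partner, str):
            return self.partner.upper()
        return self.partner.max_score_sequence()

    @property
    def partner_id(self) -> str:
        return self.partner if isinstance(self.partner, str) else self.partner.motif_id


@dataclass
class SimulationConfig:
    n_chroms: int = 3
    chrom_length: int = 300_000
    n_genes: int = 60
    n_cell_types: int = 3
    factors_per_cell_type: int = 4
    n_latent_regions: int = 420
    promoter_fraction: float = 0.3
    p_bind_shared_promoter: float = 0.8
    p_bind_celltype_enhancer: float = 0.7
    p_bind_offtype: float = 0.05
    pu1_like_factor: bool = True
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    planted_spacings: list[PlantedSpacing] = field(default_factory=list)
    conservation_by_multiplicity: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.15, 3: 0.30, 4: 0.50}
    )
    validated_scale: float = 0.5
    tf_locus_rate_multiplier: float = 3.0
    tf_gene_fraction: float = 0.2
    peak_length_mean: float = 200.0
    peak_length_sd: float = 40.0
    peak_length_min: int = 50
    region_width: int = 200
    cpg_island_fraction: float = 0.6
    cpg_gc: float = 0.65
    n_repeats_per_chrom: int = 24
    repeat_length: int = 300
    cell_types: list[str] | None = None
    factors: list[str] | None = None
    union_repertoires: dict[str, list[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_fraction", "p_bind_shared_promoter",
                     "p_bind_celltype_enhancer", "p_bind_offtype",
                     "cpg_island_fraction", "cpg_gc", "tf_gene_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_latent_regions < self.n_genes:
            raise ValueError("n_latent_regions must be >= n_genes")
        if self.tf_locus_rate_multiplier < 1:
            raise ValueError("tf_locus_rate_multiplier must be >= 1")
        for sp in self.planted_spacings:
            if not (-len(sp.partner_seq) <= sp.gap <= 50):
                raise ValueError(f"gap {sp.gap} outside [-partner length, 50]")

    def cell_type_names(self) -> list[str]:
        if self.cell_types is not None:
            return list(self.cell_types)
        return [f"ct{i + 1}" for i in range(self.n_cell_types)]

    def factor_names(self) -> list[str]:
        if self.factors is not None:
            return list(self.factors)
        names = [f"tf{i + 1}" for i in range(self.factors_per_cell_type)]
        if self.pu1_like_factor:
            names[0] = "Pu1"
        return names

    def sample_grid(self) -> list[tuple[str, str, str]]:
        """(sample_id, factor, cell_type) for every sample, fixed order."""
        return [
            (f"{f}_{c}", f, c)
            for c in self.cell_type_names()
            for f in self.factor_names()
        ]


@dataclass
class LatentRegion:
    region_id: int
    kind: str                 # "promoter" | "enhancer"
    owner: str | None         # cell type, "PU1", or None for promoters
    interval: GenomicInterval
    host_gene: str


@dataclass
class GroundTruth:
    regions: list[LatentRegion]
    bound: dict[str, list[int]]                 # sample_id -> region ids
    peak_regions: dict[str, list[int]]          # sample_id -> region id per peak
    motif_insertions: list[dict]                # motif_id, chrom, start, strand, region_id
    composite_insertions: list[dict]            # anchor/partner ids, gap, chrom, start, region_id
    multiplicity: dict[int, int]                # region_id -> distinct factors bound
    conserved_region_ids: list[int]
    validated_region_ids: list[int]

    def n_peaks(self) -> int:
        return sum(len(v) for v in self.peak_regions.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": [
                {
                    "region_id": r.region_id,
                    "kind": r.kind,
                    "owner": r.owner,
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "host_gene": r.host_gene,
                }
                for r in self.regions
            ],
            "bound": self.bound,
            "peak_regions": self.peak_regions,
            "motif_insertions": self.motif_insertions,
            "composite_insertions": self.composite_insertions,
            "multiplicity": {str(k): v for k, v in self.multiplicity.items()},
            "conserved_region_ids": self.conserved_region_ids,
            "validated_region_ids": self.validated_region_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int, p=None) -> np.ndarray:
    return _BASE_ARR[rng.choice(4, size=n, p=p)]


def build_genome(config: SimulationConfig, rng: np.random.Generator | None = None
                 ) -> tuple[dict[str, bytearray], GenomeAnnotation]:
    """Background genome sequence plus gene/CpG/repeat/TF annotation.

    Sequence is i.i.d. uniform except CpG islands, which are G+C-rich blocks
    around a configurable fraction of TSSs.  Genes are non-overlapping with
    three exons each; repeats are labeled blocks of the three major classes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chroms}
    sequences = {
        c: bytearray(_random_dna(rng, config.chrom_length).tobytes()) for c in chroms
    }

    genes: list[Gene] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        spans = rng.integers(3000, 8001, size=n_here)
        # spread genes over the whole chromosome: minimum 2 kb gaps plus a
        # Dirichlet split of the slack across the n+1 intergenic stretches,
        # so no gene owns an outsized nearest-gene territory at either end
        slack = config.chrom_length - int(spans.sum()) - 2000 * (n_here + 1)
        if slack < 0:
            raise ValueError(
                "requested genes exceed genome space; increase chrom_length"
            )
        extra = np.floor(rng.dirichlet(np.ones(n_here + 1)) * slack).astype(int)
        cursor = 0
        for k in range(n_here):
            span = int(spans[k])
            start = cursor + 2000 + int(extra[k])
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [
                GenomicInterval(chrom, start, start + 300, strand),
                GenomicInterval(chrom, (start + end) // 2 - 200,
                                (start + end) // 2 + 200, strand),
                GenomicInterval(chrom, end - 300, end, strand),
            ]
            genes.append(Gene(f"g{len(genes):04d}", chrom, strand, start, end, exons))
            cursor = end
    n_tf = int(round(config.tf_gene_fraction * len(genes)))
    tf_ids = set(
        rng.choice([g.gene_id for g in genes], size=n_tf, replace=False)
    ) if n_tf else set()

    cpg_islands: list[GenomicInterval] = []
    if genes:
        n_cpg = int(round(config.cpg_island_fraction * len(genes)))
        for g in sorted(rng.choice(len(genes), size=n_cpg, replace=False)):
            gene = genes[int(g)]
            s = max(0, gene.tss - 250)
            e = min(config.chrom_length, gene.tss + 250)
            cpg_islands.append(GenomicInterval(gene.chrom, s, e))
            gc = config.cpg_gc
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            sequences[gene.chrom][s:e] = _random_dna(rng, e - s, p).tobytes()

    repeats: list[tuple[GenomicInterval, str]] = []
    classes = ("LINE", "SINE", "LTR")
    for chrom in chroms:
        for k in range(config.n_repeats_per_chrom):
            start = int(rng.integers(0, config.chrom_length - config.repeat_length))
            repeats.append(
                (GenomicInterval(chrom, start, start + config.repeat_length),
                 classes[k % 3])
            )

    annotation = GenomeAnnotation(
        chrom_sizes=sizes,
        genes=genes,
        cpg_islands=sorted(cpg_islands, key=lambda iv: (iv.chrom, iv.start)),
        repeats=sorted(repeats, key=lambda r: (r[0].chrom, r[0].start)),
        tf_gene_ids=tf_ids,
    )
    return sequences, annotation


def _place_latent_regions(
    config: SimulationConfig, annotation: GenomeAnnotation, rng: np.random.Generator
) -> list[LatentRegion]:
    genes = annotation.genes
    w = config.region_width
    n_prom = int(round(config.promoter_fraction * config.n_latent_regions))
    n_enh = config.n_latent_regions - n_prom

    regions: list[LatentRegion] = []
    placed: dict[str, list[tuple[int, int]]] = {}

    def _collides(chrom: str, start: int, end: int, margin: int = 30) -> bool:
        return any(start < e + margin and s - margin < end
                   for s, e in placed.get(chrom, ()))

    def _add(kind, owner, chrom, start, host):
        placed.setdefault(chrom, []).append((start, start + w))
        regions.append(
            LatentRegion(len(regions), kind, owner,
                         GenomicInterval(chrom, start, start + w), host)
        )

    # promoter regions: slotted around the TSS so several can share a gene
    # without overlapping, all inside the +-1 kb promoter window
    order = rng.permutation(len(genes))
    for i in range(n_prom):
        g = genes[int(order[i % len(genes)])]
        slot = i // len(genes)
        center = g.tss - 450 + 260 * slot + int(rng.integers(-10, 11))
        start = max(0, center - w // 2)
        if _collides(g.chrom, start, start + w):
            raise ValueError("promoter slots exhausted; reduce promoter count")
        _add("promoter", None, g.chrom, start, g.gene_id)

    owners = config.cell_type_names() + (
        [PU1_OWNER] if config.pu1_like_factor else []
    )
    # promoter exclusion zone: +-1600 bp of any TSS keeps enhancer peaks
    # clear of the +-1 kb promoter window even after peak-length extension
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    # enhancers: uniform positions away from promoter zones, thinned so the
    # density near TF gene loci is tf_locus_rate_multiplier-fold.  Host gene
    # is the nearest gene by TSS (the assignment rule downstream analyses
    # use), so the planted density multiplier is exact under that rule.
    chroms = list(annotation.chrom_sizes)
    gene_sorted = sorted(genes, key=lambda g: g.gene_id)
    mult = config.tf_locus_rate_multiplier
    for _ in range(n_enh):
        for _attempt in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, annotation.chrom_sizes[chrom] - w))
            center = start + w // 2
            tss = tss_by_chrom.get(chrom, np.empty(0))
            if tss.size and np.min(np.abs(tss - center)) < 1600 + w:
                continue
            if _collides(chrom, start, start + w):
                continue
            host = min(
                (g for g in gene_sorted if g.chrom == chrom),
                key=lambda g: (abs(center - g.tss), g.gene_id),
                default=None,
            )
            if host is None:
                continue
            accept = (mult if host.gene_id in annotation.tf_gene_ids else 1.0
                      ) / mult
            if rng.random() >= accept:
                continue
            owner = owners[int(rng.integers(len(owners)))]
            _add("enhancer", owner, chrom, start, host.gene_id)
            break
        else:
            raise ValueError("could not place enhancer away from promoters; "
                             "reduce n_latent_regions or gene density")
    return regions


def _sample_peak(
    region: LatentRegion, config: SimulationConfig,
    chrom_len: int, rng: np.random.Generator
) -> GenomicInterval:
    length = max(
        config.peak_length_min,
        int(round(rng.normal(config.peak_length_mean, config.peak_length_sd))),
    )
    center = (region.interval.start + region.interval.end) // 2 + int(
        rng.integers(-30, 31)
    )
    start = max(0, min(center - length // 2, chrom_len - length))
    return GenomicInterval(region.interval.chrom, start, start + length)


def simulate_compendium(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    sequences: dict[str, bytearray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Compendium, GroundTruth, GenomeAnnotation]:
    """Simulate per-sample binding over latent regions; plant motifs/composites.

    Returns the compendium, the ground truth, and a new annotation carrying
    the simulated conserved-region and validated-enhancer tracks.  When
    ``sequences`` is given, planted motifs and composites are written into it
    in place.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    regions = _place_latent_regions(config, annotation, rng)
    grid = config.sample_grid()
    known = {sid for sid, _, _ in grid}
    for sp in config.planted_spacings:
        missing = set(sp.samples) - known
        if missing:
            raise ValueError(f"planted spacing references unknown samples {missing}")

    repertoire = {}
    for sid, factor, cell in grid:
        if config.pu1_like_factor and factor == config.factor_names()[0]:
            repertoire[sid] = PU1_OWNER
        else:
            repertoire[sid] = cell
    unions = config.union_repertoires or {}

    bound: dict[str, list[int]] = {}
    for sid, factor, cell in grid:
        mine: list[int] = []
        own_labels = set(unions.get(cell, [repertoire[sid]]))
        if config.pu1_like_factor and repertoire[sid] == PU1_OWNER:
            own_labels = {PU1_OWNER}
        for r in regions:
            if r.kind == "promoter":
                p = config.p_bind_shared_promoter
            elif r.owner in own_labels:
                p = config.p_bind_celltype_enhancer
            else:
                p = config.p_bind_offtype
            if rng.random() < p:
                mine.append(r.region_id)
        bound[sid] = mine

    compendium: Compendium = {}
    peak_regions: dict[str, list[int]] = {}
    for sid, factor, cell in grid:
        pairs = []
        for rid in bound[sid]:
            r = regions[rid]
            pairs.append((
                _sample_peak(r, config, annotation.chrom_sizes[r.interval.chrom], rng),
                rid,
            ))
        # keep region ids aligned with the PeakSet's sorted peak order
        pairs.sort(key=lambda pr: (pr[0].chrom, pr[0].start, pr[0].end))
        compendium[sid] = PeakSet(sid, factor, cell, [p for p, _ in pairs])
        peak_regions[sid] = [rid for _, rid in pairs]

    factor_of = {sid: f for sid, f, _ in grid}
    bound_samples: dict[int, set[str]] = {r.region_id: set() for r in regions}
    for sid, rids in bound.items():
        for rid in rids:
            bound_samples[rid].add(sid)
    multiplicity = {
        rid: len({factor_of[s] for s in smp}) for rid, smp in bound_samples.items()
    }

    motif_insertions: list[dict] = []
    for rule in config.planted_motifs:
        for r in regions:
            if rule.owners is not None:
                label = "promoter" if r.kind == "promoter" else r.owner
                if label not in rule.owners:
                    continue
            if rule.samples is not None and not (
                set(rule.samples) & bound_samples[r.region_id]
            ):
                continue
            if not bound_samples[r.region_id]:
                continue
            if rng.random() >= rule.probability:
                continue
            inst = _sample_motif_instance(rule.motif, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            written = inst if strand == "+" else reverse_complement(inst)
            off = int(rng.integers(0, r.interval.length - len(inst) + 1))
            start = r.interval.start + off
            if sequences is not None:
                sequences[r.interval.chrom][start:start + len(inst)] = written.encode()
            motif_insertions.append(
                {"motif_id": rule.motif.motif_id, "chrom": r.interval.chrom,
                 "start": start, "strand": strand, "region_id": r.region_id}
            )

    composite_insertions: list[dict] = []
    for sp in config.planted_spacings:
        targets = [r for r in regions
                   if set(sp.samples) <= bound_samples[r.region_id]]
        anchor_seq = sp.anchor.max_score_sequence()
        partner_seq = sp.partner_seq
        total = len(anchor_seq) + sp.gap + len(partner_seq)
        for r in targets:
            if rng.random() >= sp.fraction:
                continue
            off = int(rng.integers(0, r.interval.length - max(total, len(anchor_seq)) + 1))
            start = r.interval.start + off
            if sequences is not None:
                seq = sequences[r.interval.chrom]
                seq[start:start + len(anchor_seq)] = anchor_seq.encode()
                pstart = start + len(anchor_seq) + sp.gap
                seq[pstart:pstart + len(partner_seq)] = partner_seq.encode()
            composite_insertions.append(
                {"anchor_id": sp.anchor.motif_id, "partner_id": sp.partner_id,
                 "gap": sp.gap, "chrom": r.interval.chrom, "start": start,
                 "region_id": r.region_id}
            )

    sched = config.conservation_by_multiplicity
    cap = max(sched) if sched else 0
    conserved_ids, validated_ids = [], []
    conserved, validated = [], []
    for r in regions:
        m = multiplicity[r.region_id]
        if m == 0:
            continue
        p = sched.get(min(m, cap), 0.0)
        iv = GenomicInterval(
            r.interval.chrom,
            max(0, r.interval.start - 20),
            min(annotation.chrom_sizes[r.interval.chrom], r.interval.end + 20),
        )
        if rng.random() < p:
            conserved_ids.append(r.region_id)
            conserved.append(iv)
        if rng.random() < p * config.validated_scale:
            validated_ids.append(r.region_id)
            validated.append(iv)

    new_annotation = dataclasses.replace(
        annotation,
        conserved_regions=sorted(conserved, key=lambda iv: (iv.chrom, iv.start)),
        validated_enhancers=sorted(validated, key=lambda iv: (iv.chrom, iv.start)),
    )
    truth = GroundTruth(
        regions=regions,
        bound=bound,
        peak_regions=peak_regions,
        motif_insertions=motif_insertions,
        composite_insertions=composite_insertions,
        multiplicity=multiplicity,
        conserved_region_ids=conserved_ids,
        validated_region_ids=validated_ids,
    )
    return compendium, truth, new_annotation


def _sample_motif_instance(motif: MotifModel, rng: np.random.Generator) -> str:
    """Draw one site from the motif's column distributions (consensus as-is)."""
    if motif.matrix is None:
        return motif.max_score_sequence()
    probs = motif.matrix / motif.matrix.sum(axis=0, keepdims=True)
    return "".join("ACGT"[rng.choice(4, p=probs[:, j])]
                   for j in range(motif.length))


# --- default study conditions -------------------------------------------------

def default_motif_library() -> list[MotifModel]:
    """A compact JASPAR-style library: planted factor motifs plus decoys."""
    return [
        pfm_from_consensus("GGGGAAGT", "M_ETS"),      # Pu.1-like ETS site
        pfm_from_consensus("AGATAAGA", "M_GATA"),     # GATA site
        pfm_from_consensus("CAGCTGTT", "M_EBOX"),     # E-box
        pfm_from_consensus("TTGCGCAA", "M_CEBP"),     # CEBP-like palindrome
        pfm_from_consensus("CCGGAAGC", "M_DECOY1"),   # never planted
        pfm_from_consensus("TGACGTCA", "M_DECOY2"),   # never planted
    ]


def default_config(seed: int = 0) -> SimulationConfig:
    """The default synthetic study: 3 cell types x 4 factors, one Pu.1-like.

    Cell-type-owned enhancers carry a cell-type motif; the Pu.1-like
    repertoire carries the ETS motif; a GATA/E-box composite at a 9 bp gap is
    planted into regions co-bound by the two GATA-factor samples.
    """
    lib = {m.motif_id: m for m in default_motif_library()}
    cells = ["prog", "ery", "bcell"]
    factors = ["Pu1", "Gata1", "Scl", "Cebpa"]
    return SimulationConfig(
        cell_types=cells,
        factors=factors,
        planted_motifs=[
            PlantedMotif(lib["M_ETS"], 0.6, owners=[PU1_OWNER]),
            PlantedMotif(lib["M_GATA"], 0.6, owners=["ery"]),
            PlantedMotif(lib["M_EBOX"], 0.6, owners=["prog"]),
            PlantedMotif(lib["M_CEBP"], 0.6, owners=["bcell"]),
        ],
        planted_spacings=[
            PlantedSpacing(lib["M_GATA"], lib["M_EBOX"], gap=9, fraction=0.4,
                           samples=["Gata1_ery", "Scl_ery"]),
        ],
        seed=seed,
    )


def write_bundle(config: SimulationConfig, outdir: str | Path,
                 motif_library: Sequence[MotifModel] | None = None) -> Path:
    """Generate and write the full pipeline input bundle plus ground truth.

    Layout: genome.fa, chrom.sizes, genes.tsv, cpg_islands.bed, repeats.bed,
    conserved.bed, validated.bed, tf_genes.txt, motifs.jaspar,
    gene_sets.gmt, peaks/<sample>.bed, sample_sheet.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sequences, annotation = build_genome(config, rng)
    compendium, truth, annotation = simulate_compendium(
        config, annotation, sequences, rng
    )

    cio.write_fasta({c: bytes(s).decode() for c, s in sequences.items()},
                    outdir / "genome.fa")
    cio.write_chrom_sizes(annotation.chrom_sizes, outdir / "chrom.sizes")
    cio.write_gene_table(annotation.genes, outdir / "genes.tsv")
    cio.write_bed(annotation.cpg_islands, outdir / "cpg_islands.bed")
    cio.write_bed([iv for iv, _ in annotation.repeats], outdir / "repeats.bed",
                  extra=[[cls] for _, cls in annotation.repeats])
    cio.write_bed(annotation.conserved_regions, outdir / "conserved.bed")
    cio.write_bed(annotation.validated_enhancers, outdir / "validated.bed")
    (outdir / "tf_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(annotation.tf_gene_ids))
    )
    lib = list(motif_library) if motif_library is not None else (
        default_motif_library()
        if not config.planted_motifs
        else _library_from_config(config)
    )
    cio.write_jaspar(lib, outdir / "motifs.jaspar")

    marker_sets = {}
    for cell in config.cell_type_names() + (
        [PU1_OWNER] if config.pu1_like_factor else []
    ):
        genes = sorted({r.host_gene for r in truth.regions if r.owner == cell})
        if genes:
            marker_sets[f"markers_{cell}"] = genes
    tf_set = sorted(annotation.tf_gene_ids)
    if tf_set:
        marker_sets["transcription_factors"] = tf_set
    cio.write_gmt(marker_sets, outdir / "gene_sets.gmt")

    primary = _primary_motifs(config, lib)
    with open(outdir / "sample_sheet.tsv", "w") as fh:
        fh.write("sample_id\tfactor\tcell_type\tpeaks\tprimary_motif\n")
        for sid, factor, cell in config.sample_grid():
            cio.write_bed(compendium[sid].peaks, outdir / "peaks" / f"{sid}.bed")
            fh.write(f"{sid}\t{factor}\t{cell}\tpeaks/{sid}.bed\t"
                     f"{primary.get(factor, '')}\n")
    truth.to_json(outdir / "ground_truth.json")
    return outdir


def _library_from_config(config: SimulationConfig) -> list[MotifModel]:
    lib: dict[str, MotifModel] = {}
    for rule in config.planted_motifs:
        lib[rule.motif.motif_id] = rule.motif
    for sp in config.planted_spacings:
        lib[sp.anchor.motif_id] = sp.anchor
        if isinstance(sp.partner, MotifModel):
            lib[sp.partner.motif_id] = sp.partner
    for m in default_motif_library():
        lib.setdefault(m.motif_id, m)
    return list(lib.values())


def _primary_motifs(config: SimulationConfig, lib: Sequence[MotifModel]
                    ) -> dict[str, str]:
    """Heuristic factor -> motif_id map for the sample sheet (by name match)."""
    ids = {m.motif_id for m in lib}
    out: dict[str, str] = {}
    defaults = {"Pu1": "M_ETS", "Gata1": "M_GATA", "Scl": "M_EBOX",
                "Cebpa": "M_CEBP"}
    for factor in config.factor_names():
        mid = defaults.get(factor)
        if mid in ids:
            out[factor] = mid
    return out
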