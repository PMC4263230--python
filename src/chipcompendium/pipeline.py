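"""End-to-end pipeline orchestration over a peak-compendium input bundle.

A run config (YAML or constructed in code) names every input file and the
per-stage parameters; ``run_pipeline`` executes the stages in order and
writes TSV reports plus a manifest recording the seed, parameters and
input/output checksums, so identical config + seed reproduces identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from . import io as cio
from .context import CategoryAnnotator, category_enrichment, cpg_enrichment
from .genes import peaks_per_gene, promoter_enhancer_dependence, tf_locus_enrichment
from .genesets import hypergeometric_enrichment
from .model import Compendium, GenomeAnnotation
from .motifs import GenomeSampler, enrichment_heatmap, genome_background, motif_enrichment
from .multiplicity import (
    multi_factor_fraction,
    multiplicity_trend_test,
    region_multiplicity,
    stratified_overlap_fraction,
)
from .occupancy import (
    build_union_regions,
    hierarchical_cluster,
    overlap_significance,
    split_compendium,
)
from .spacing import detect_preferred_gaps, motif_pair_spacing, replication_filter

log = logging.getLogger(__name__)

STAGES = ("classify", "occupancy", "genes", "multiplicity", "motifs",
          "context", "spacing", "genesets")


class ConfigError(ValueError):
    pass


@dataclass
class SampleSheetRow:
    sample_id: str
    factor: str
    cell_type: str
    peaks: str
    primary_motif: str = ""


@dataclass
class RunConfig:
    genome_fasta: str
    chrom_sizes: str
    gene_table: str
    samples: list[SampleSheetRow]
    out_dir: str
    seed: int
    cpg_islands: str | None = None
    repeats: str | None = None
    conserved: str | None = None
    validated: str | None = None
    tf_list: str | None = None
    motifs: str | None = None
    gene_sets: str | None = None
    promoter_window: int = 1000
    n_rand_pairwise: int = 100
    n_rand_context: int = 100
    n_motif_sets: int = 100
    n_resample_genes: int = 2000
    n_null_spacing: int = 2000
    max_gap: int = 50
    multiplicity_cap: int = 8
    stages: tuple[str, ...] = STAGES
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.setdefault("base_dir", str(Path(path).parent))
        samples = [SampleSheetRow(**row) for row in raw.pop("samples")]
        cfg = cls(samples=samples, **raw)
        cfg.validate()
        return cfg

    def path(self, name: str) -> Path | None:
        value = getattr(self, name)
        if value is None:
            return None
        return Path(self.base_dir) / value

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("genome_fasta", "chrom_sizes", "gene_table"):
            p = self.path(name)
            if not p.exists():
                raise ConfigError(f"{name} file not found: {p}")
        for row in self.samples:
            p = Path(self.base_dir) / row.peaks
            if not p.exists():
                raise ConfigError(
                    f"peak file missing for sample {row.sample_id}: {p}"
                )


def config_from_bundle(bundle_dir: str | Path, out_dir: str | Path,
                       seed: int, **overrides) -> RunConfig:
    """Build a RunConfig pointing at a directory written by ``write_bundle``."""
    bundle_dir = Path(bundle_dir)
    rows = []
    sheet = pd.read_csv(bundle_dir / "sample_sheet.tsv", sep="\t",
                        keep_default_na=False)
    for _, r in sheet.iterrows():
        rows.append(SampleSheetRow(r.sample_id, r.factor, r.cell_type,
                                   r.peaks, r.primary_motif))
    cfg = RunConfig(
        genome_fasta="genome.fa",
        chrom_sizes="chrom.sizes",
        gene_table="genes.tsv",
        cpg_islands="cpg_islands.bed",
        repeats="repeats.bed",
        conserved="conserved.bed",
        validated="validated.bed",
        tf_list="tf_genes.txt",
        motifs="motifs.jaspar",
        gene_sets="gene_sets.gmt",
        samples=rows,
        out_dir=str(out_dir),
        seed=seed,
        base_dir=str(bundle_dir),
        **overrides,
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **params) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
                     + "\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")
    log.info("wrote %s", path)


def load_inputs(config: RunConfig) -> tuple[Compendium, GenomeAnnotation]:
    annotation = cio.read_annotation(
        gene_table=config.path("gene_table"),
        chrom_sizes=config.path("chrom_sizes"),
        cpg_bed=config.path("cpg_islands"),
        repeat_bed=config.path("repeats"),
        conserved_bed=config.path("conserved"),
        validated_bed=config.path("validated"),
        tf_list=config.path("tf_list"),
    )
    compendium: Compendium = {}
    for row in config.samples:
        compendium[row.sample_id] = cio.read_bed(
            Path(config.base_dir) / row.peaks,
            sample_id=row.sample_id, factor=row.factor, cell_type=row.cell_type,
        )
    return compendium, annotation


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages and write TSV reports plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    compendium, annotation = load_inputs(config)
    fasta = Fasta(str(config.path("genome_fasta")))
    seed = int(config.seed)

    prom, enh = split_compendium(compendium, annotation, config.promoter_window)
    union = build_union_regions(compendium)

    if "classify" in config.stages:
        rows = []
        for sid, ps in compendium.items():
            n_p, n_e = len(prom[sid]), len(enh[sid])
            rows.append((sid, len(ps), n_p, n_e,
                         n_p / len(ps) if len(ps) else np.nan))
        _write_tsv(
            pd.DataFrame(rows, columns=["sample_id", "n_peaks", "n_promoter",
                                        "n_enhancer", "promoter_fraction"]
                         ).set_index("sample_id"),
            out / "classify" / "promoter_enhancer.tsv",
            window_bp=config.promoter_window,
        )

    if "occupancy" in config.stages:
        for label, comp in (("promoter", prom), ("enhancer", enh)):
            present = {s: p for s, p in comp.items() if len(p)}
            if len(present) < 2:
                continue
            sig = overlap_significance(
                present, annotation.chrom_sizes,
                n_rand=config.n_rand_pairwise, seed=seed,
            )
            for which in ("observed", "z", "p_over", "p_under", "correlation"):
                _write_tsv(sig.frame(which),
                           out / "occupancy" / f"{label}_{which}.tsv",
                           n_rand=config.n_rand_pairwise, seed=seed)
            clust = hierarchical_cluster(sig.correlation, sig.sample_ids)
            _write_tsv(
                pd.DataFrame({"leaf_order": clust.leaf_order}),
                out / "occupancy" / f"{label}_leaf_order.tsv",
            )

    if "genes" in config.stages:
        gpt = peaks_per_gene(compendium, annotation)
        _write_tsv(gpt.table, out / "genes" / "gene_peak_table.tsv")
        summary = {
            "mean_peaks_per_bound_gene": gpt.mean_peaks_per_bound_gene,
            "n_genes_gt5": gpt.n_genes_gt5,
            "n_genes_gt50": gpt.n_genes_gt50,
        }
        if annotation.tf_gene_ids and gpt.table["is_tf"].sum() >= 10:
            tfres = tf_locus_enrichment(
                gpt.table, n_resample=config.n_resample_genes, seed=seed,
            )
            summary.update(
                tf_observed_mean=tfres.observed_tf_mean,
                tf_null_mean=tfres.null_mean,
                tf_p_value=tfres.p_value,
            )
        prom_gpt = peaks_per_gene(prom, annotation)
        enh_gpt = peaks_per_gene(enh, annotation)
        dep = promoter_enhancer_dependence(
            prom_gpt.table["total"], enh_gpt.table["total"],
            n_perm=config.n_resample_genes, seed=seed,
        )
        summary.update(
            dep_mean_with_promoter=dep.mean_enhancer_with_promoter,
            dep_mean_without_promoter=dep.mean_enhancer_without_promoter,
            dep_rate_ratio=dep.rate_ratio,
            dep_p_value=dep.p_value,
        )
        _write_tsv(pd.DataFrame([summary]).T.rename(columns={0: "value"}),
                   out / "genes" / "summary.tsv", seed=seed)

    if "multiplicity" in config.stages:
        mult = region_multiplicity(union, compendium)
        report = {"multi_factor_fraction": multi_factor_fraction(mult)}
        for label, feats in (("conserved", annotation.conserved_regions),
                             ("validated", annotation.validated_enhancers)):
            strata = stratified_overlap_fraction(
                union, mult, feats, cap=config.multiplicity_cap,
            )
            _write_tsv(strata.table, out / "multiplicity" / f"{label}_strata.tsv")
            if feats and (strata.table["n"] > 0).sum() >= 3:
                trend = multiplicity_trend_test(strata, seed=seed)
                report.update({
                    f"{label}_stratum_rho": trend.stratum_rho,
                    f"{label}_region_rho": trend.region_rho,
                    f"{label}_trend_p": trend.p_value,
                })
        _write_tsv(pd.DataFrame([report]).T.rename(columns={0: "value"}),
                   out / "multiplicity" / "trend.tsv", seed=seed)

    if "motifs" in config.stages and config.path("motifs") is not None:
        library = cio.read_jaspar(config.path("motifs"))
        sampler = GenomeSampler(annotation.chrom_sizes, fasta)
        bg = genome_background(
            cio.extract_sequences(
                [p for ps in compendium.values() for p in ps.peaks[:50]], fasta
            )
        )
        per_sample = {}
        rows = []
        for i, (sid, ps) in enumerate(compendium.items()):
            if len(ps) < 10:
                continue
            seqs = cio.extract_sequences(ps.peaks, fasta)
            res = motif_enrichment(
                seqs, library, sampler, n_sets=config.n_motif_sets,
                seed=seed + i, background=bg,
            )
            per_sample[sid] = res
            rows.extend(
                dict(sample_id=sid, motif_id=e.motif_id, observed=e.observed,
                     null_mean=e.null_mean, fold=e.fold, p_value=e.p_value,
                     q_value=e.q_value, enriched=int(e.enriched))
                for e in res
            )
        _write_tsv(pd.DataFrame(rows).set_index("sample_id"),
                   out / "motifs" / "enrichment.tsv",
                   n_sets=config.n_motif_sets, seed=seed)
        binary, fold = enrichment_heatmap(per_sample)
        _write_tsv(binary, out / "motifs" / "heatmap_binary.tsv")
        _write_tsv(fold, out / "motifs" / "heatmap_fold.tsv")

    if "context" in config.stages:
        annotator = CategoryAnnotator(annotation, config.promoter_window)
        cat_rows, cpg_rows = [], []
        for i, (sid, ps) in enumerate(compendium.items()):
            if len(ps) < 10:
                continue
            profile = category_enrichment(
                ps, annotation, annotator,
                n_rand=config.n_rand_context, seed=seed + i,
            )
            for cat, row in profile.table.iterrows():
                cat_rows.append(dict(sample_id=sid, category=cat, **row))
            cpg = cpg_enrichment(ps, annotation,
                                 n_rand=config.n_rand_context, seed=seed + i)
            cpg_rows.append(dict(sample_id=sid, label=cpg.label,
                                 observed=cpg.observed_fraction,
                                 expected=cpg.expected_fraction,
                                 fold=cpg.fold, p_value=cpg.p_value))
        _write_tsv(pd.DataFrame(cat_rows).set_index("sample_id"),
                   out / "context" / "categories.tsv",
                   n_rand=config.n_rand_context, seed=seed)
        _write_tsv(pd.DataFrame(cpg_rows).set_index("sample_id"),
                   out / "context" / "cpg.tsv",
                   n_rand=config.n_rand_context, seed=seed)

    if "spacing" in config.stages and config.path("motifs") is not None:
        library = {m.motif_id: m for m in cio.read_jaspar(config.path("motifs"))}
        primary = {r.sample_id: r.primary_motif for r in config.samples
                   if r.primary_motif}
        profiles = []
        sids = list(compendium)
        for i, si in enumerate(sids):
            if si not in primary or primary[si] not in library:
                continue
            anchor = library[primary[si]]
            for j, sj in enumerate(sids):
                if j == i or sj not in primary or primary[sj] not in library:
                    continue
                partner = library[primary[sj]]
                if partner.motif_id == anchor.motif_id:
                    continue
                co_mask = union.column(si) & union.column(sj)
                if co_mask.sum() < 10:
                    continue
                seqs = cio.extract_sequences(
                    [r for r, m in zip(union.regions, co_mask) if m], fasta
                )
                prof = motif_pair_spacing(seqs, anchor, partner, sample_id=si,
                                          max_gap=config.max_gap)
                detect_preferred_gaps(prof, n_null=config.n_null_spacing,
                                      seed=seed + 101 * i + j)
                profiles.append(prof)
        rows = [
            dict(sample_id=p.sample_id, anchor=p.anchor_id, partner=p.partner_id,
                 gap=g, count=p.histogram()[g],
                 expected=p.null_expectation.get(g, np.nan),
                 p_value=p.p_values.get(g, np.nan),
                 q_value=p.q_values.get(g, np.nan))
            for p in profiles for g in p.enriched_gaps
        ]
        _write_tsv(
            pd.DataFrame(rows, columns=["sample_id", "anchor", "partner", "gap",
                                        "count", "expected", "p_value", "q_value"]
                         ).set_index("sample_id") if rows else
            pd.DataFrame(columns=["sample_id", "anchor", "partner", "gap",
                                  "count", "expected", "p_value", "q_value"]
                         ).set_index("sample_id"),
            out / "spacing" / "enriched_gaps.tsv",
            n_null=config.n_null_spacing, seed=seed,
        )
        reps = replication_filter(profiles)
        _write_tsv(
            pd.DataFrame(
                [dict(anchor=r.anchor_id, partner=r.partner_id, gap=r.gap,
                      samples=",".join(r.samples)) for r in reps],
                columns=["anchor", "partner", "gap", "samples"],
            ),
            out / "spacing" / "replicated.tsv",
        )

    if "genesets" in config.stages and config.path("gene_sets") is not None:
        gene_sets = cio.read_gmt(config.path("gene_sets"))
        universe = [g.gene_id for g in annotation.genes]
        gpt = peaks_per_gene(compendium, annotation)
        top = gpt.table[gpt.table["total"] > 5].index.tolist()
        rows = []
        if top and gene_sets:
            for r in hypergeometric_enrichment(top, gene_sets, universe):
                rows.append(dataclasses.asdict(r))
        _write_tsv(pd.DataFrame(rows, columns=[
            "set_name", "universe_size", "list_size", "set_size", "overlap",
            "p_value", "q_value"]).set_index("set_name"),
            out / "genesets" / "dense_gene_enrichment.tsv")

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": list(config.stages),
        "parameters": {
            k: getattr(config, k) for k in (
                "promoter_window", "n_rand_pairwise", "n_rand_context",
                "n_motif_sets", "n_resample_genes", "n_null_spacing",
                "max_gap", "multiplicity_cap",
            )
        },
        "inputs": {
            name: _sha256(config.path(name))
            for name in ("genome_fasta", "chrom_sizes", "gene_table",
                         "cpg_islands", "repeats", "conserved", "validated",
                         "tf_list", "motifs", "gene_sets")
            if config.path(name) is not None and config.path(name).exists()
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
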