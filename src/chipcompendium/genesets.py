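"""Hypergeometric gene-set enrichment and the lineage-priming analysis.

Functional enrichment uses a plain upper-tail hypergeometric test on
GMT-style gene sets with BH correction — a transparent, offline replacement
for web-service annotation tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import false_discovery_control, hypergeom

from .genes import assign_nearest_gene
from .model import Compendium, GenomeAnnotation
from .occupancy import build_union_regions, promoter_mask, venn_partition

log = logging.getLogger(__name__)


@dataclass
class GeneSetResult:
    set_name: str
    universe_size: int
    list_size: int
    set_size: int
    overlap: int
    p_value: float
    q_value: float = float("nan")


def hypergeometric_enrichment(
    gene_list: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    universe: Sequence[str],
) -> list[GeneSetResult]:
    """Upper-tail hypergeometric enrichment of each set in ``gene_list``.

    Genes outside the universe are dropped with a warning; sets are
    intersected with the universe before testing.
    """
    uni = set(universe)
    glist = set(gene_list)
    if not glist:
        raise ValueError("empty gene list")
    outside = glist - uni
    if outside:
        log.warning("%d genes outside the universe dropped", len(outside))
        glist &= uni
    if not glist:
        raise ValueError("no genes left after restricting to the universe")
    M, n = len(uni), len(glist)
    results = []
    for name, members in gene_sets.items():
        K = len(members & uni)
        if K == 0:
            continue
        k = len(members & glist)
        p = float(hypergeom.sf(k - 1, M, K, n))
        results.append(GeneSetResult(name, M, n, K, k, p))
    if results:
        q = false_discovery_control([r.p_value for r in results], method="bh")
        for r, qq in zip(results, q):
            r.q_value = float(qq)
    return results


@dataclass
class LineagePrimingResult:
    """Per-Venn-cell gene lists and their enrichment, per peak class."""

    sample_ids: list[str]
    cells: dict[str, dict[int, list[str]]]          # class -> bitmask -> genes
    enrichment: dict[str, dict[int, list[GeneSetResult]]]
    counts: dict[str, dict[int, int]]               # class -> bitmask -> regions


def lineage_priming_analysis(
    compendium: Compendium,
    sample_ids: Sequence[str],
    annotation: GenomeAnnotation,
    gene_sets: Mapping[str, set[str]] | None = None,
    promoter_window: int = 1000,
    universe: Sequence[str] | None = None,
) -> LineagePrimingResult:
    """Membership-cell gene lists for one factor assayed across >= 3 cell
    types, split into promoter and enhancer regions, with per-cell gene-set
    enrichment.

    Regions bound by any selected sample are partitioned into Venn membership
    cells; each cell's regions map to their nearest genes; enrichment is run
    per cell (skipped when ``gene_sets`` is empty).  Cells expected to show
    lineage priming are those shared between a progenitor and one mature
    lineage but not the other.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 3:
        raise ValueError("need >= 3 samples of the factor")
    factors = {compendium[s].factor for s in sample_ids}
    if len(factors) != 1:
        raise ValueError(f"samples span multiple factors: {sorted(factors)}")
    selected = {s: compendium[s] for s in sample_ids}
    union = build_union_regions(selected)
    prom_flags = promoter_mask(union.regions, annotation, promoter_window)
    universe = list(universe) if universe is not None else [
        g.gene_id for g in annotation.genes
    ]

    cells: dict[str, dict[int, list[str]]] = {}
    enrich: dict[str, dict[int, list[GeneSetResult]]] = {}
    counts: dict[str, dict[int, int]] = {}
    for label, mask in (("promoter", prom_flags), ("enhancer", ~prom_flags)):
        sub = union.subset_regions(mask)
        cells[label], enrich[label], counts[label] = {}, {}, {}
        if not sub.regions:
            continue
        cell_counts, _ = venn_partition(sample_ids, sub)
        cols = np.stack([sub.column(s) for s in sample_ids], axis=1)
        masks = cols @ (1 << np.arange(len(sample_ids)))
        assigned = assign_nearest_gene(sub.regions, annotation)
        for cell in sorted(c for c, n in cell_counts.items() if n > 0):
            sel = masks == cell
            genes = sorted({assigned[i][0] for i in np.nonzero(sel)[0]})
            cells[label][cell] = genes
            counts[label][cell] = int(sel.sum())
            if gene_sets and genes:
                enrich[label][cell] = hypergeometric_enrichment(
                    genes, gene_sets, universe
                )
    return LineagePrimingResult(sample_ids, cells, enrich, counts)
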