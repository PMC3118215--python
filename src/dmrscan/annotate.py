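"""Genomic location categories for DMRs and CpG-island shore density.

Each DMR is assigned exactly one category, in strict priority order:

1. CpGi promoter      — inside a promoter (TSS +/- 1 kb, strand-aware) and
                        within 500 bp of a CpG island;
2. non-CpGi promoter  — inside a promoter, no CpG island within 500 bp;
3. intragenic CpGi    — within 500 bp of a CpG island that lies in a gene
                        body (gene span excluding the promoter window);
4. intergenic CpGi    — within 500 bp of a CpG island that is more than
                        2 kb from every annotated gene span;
5. non-CpGi intragenic / 6. non-CpGi intergenic — fallthrough by gene-span
   overlap. On the promoter+CpGi array design these two arise only inside
   the contiguous tiling regions; in strict mode they are flagged when a DMR
   outside a declared tiling region lands there.

All proximity is edge-to-edge distance; "within N bp" means distance <= N.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .classify import DMRRecord
from .genome import CpGIsland, GeneModel, PipelineConfig
from .intervals import GenomicInterval, IntervalIndex, distance, subtract, total_length, union

__all__ = [
    "LocationCategory",
    "CORE_CATEGORIES",
    "TILING_CATEGORIES",
    "AnnotationIndex",
    "assign_location",
    "annotate_records",
    "shore_density",
]


class LocationCategory(enum.Enum):
    CPGI_PROMOTER = "CpGi_promoter"
    NONCPGI_PROMOTER = "nonCpGi_promoter"
    INTRAGENIC_CPGI = "intragenic_CpGi"
    INTERGENIC_CPGI = "intergenic_CpGi"
    NONCPGI_INTRAGENIC = "nonCpGi_intragenic"
    NONCPGI_INTERGENIC = "nonCpGi_intergenic"


CORE_CATEGORIES = (
    LocationCategory.CPGI_PROMOTER,
    LocationCategory.NONCPGI_PROMOTER,
    LocationCategory.INTRAGENIC_CPGI,
    LocationCategory.INTERGENIC_CPGI,
)
TILING_CATEGORIES = (
    LocationCategory.NONCPGI_INTRAGENIC,
    LocationCategory.NONCPGI_INTERGENIC,
)


@dataclass
class LocationAssignment:
    category: LocationCategory
    gene_ids: tuple[str, ...]
    cpgi_ids: tuple[str, ...]
    in_tiling_region: bool
    outside_design: bool  # strict mode: tiling-only category outside tiling


class AnnotationIndex:
    """Precomputed promoter/gene-body/CpG-island lookups for assignment.

    Per CpG island two flags are cached: whether it overlaps a gene body
    (gene span minus that gene's promoter window — overlap, not containment)
    and whether it is intergenic (> ``intergenic_min_bp`` from every gene
    span). Assignment is then pure interval queries, independent of record
    order.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        cpgis: Sequence[CpGIsland],
        config: PipelineConfig | None = None,
    ):
        self.cfg = config or PipelineConfig()
        self.genes = list(genes)
        self.cpgis = list(cpgis)
        self.promoters = [g.promoter(self.cfg.promoter_flank_bp) for g in self.genes]
        self.spans = [g.span for g in self.genes]
        self.promoter_idx = IntervalIndex(self.promoters)
        self.span_idx = IntervalIndex(self.spans)
        self.cpgi_idx = IntervalIndex([c.interval for c in self.cpgis])

        # Gene bodies: span minus the gene's own promoter window.
        bodies: list[GenomicInterval] = []
        for g, prom in zip(self.genes, self.promoters):
            bodies.extend(subtract(g.span, [prom]))
        self.body_idx = IntervalIndex(bodies)

        self.cpgi_in_body: list[bool] = []
        self.cpgi_intergenic: list[bool] = []
        for c in self.cpgis:
            self.cpgi_in_body.append(bool(self.body_idx.overlapping(c.interval)))
            near_gene = self.span_idx.within(c.interval, self.cfg.intergenic_min_bp)
            self.cpgi_intergenic.append(not near_gene)

        self.tiling = self.cfg.tiling_intervals()

    def in_tiling(self, iv: GenomicInterval) -> bool:
        return any(iv.overlaps(t) for t in self.tiling)


def assign_location(
    dmr: GenomicInterval,
    index: AnnotationIndex,
    config: PipelineConfig | None = None,
) -> LocationAssignment:
    """Assign the single location category for one DMR (priority order above)."""
    cfg = config or index.cfg
    prox = cfg.cpgi_proximity_bp

    prom_hits = index.promoter_idx.overlapping(dmr)
    cpgi_hits = index.cpgi_idx.within(dmr, prox)
    gene_ids = tuple(sorted(index.genes[i].gene_id for i in prom_hits))
    cpgi_ids = tuple(sorted(index.cpgis[i].id for i in cpgi_hits))
    tiling = index.in_tiling(dmr)

    if prom_hits and cpgi_hits:
        cat = LocationCategory.CPGI_PROMOTER
    elif prom_hits:
        cat = LocationCategory.NONCPGI_PROMOTER
    elif any(index.cpgi_in_body[i] for i in cpgi_hits):
        cat = LocationCategory.INTRAGENIC_CPGI
    elif any(index.cpgi_intergenic[i] for i in cpgi_hits):
        cat = LocationCategory.INTERGENIC_CPGI
    elif index.span_idx.overlapping(dmr):
        cat = LocationCategory.NONCPGI_INTRAGENIC
    else:
        cat = LocationCategory.NONCPGI_INTERGENIC

    outside = (
        cfg.strict_paper_mode and cat in TILING_CATEGORIES and not tiling
    )
    if cat in (LocationCategory.NONCPGI_INTRAGENIC,):
        gene_ids = tuple(
            sorted(index.genes[i].gene_id for i in index.span_idx.overlapping(dmr))
        )
    return LocationAssignment(
        category=cat,
        gene_ids=gene_ids,
        cpgi_ids=cpgi_ids,
        in_tiling_region=tiling,
        outside_design=outside,
    )


def annotate_records(
    records: Iterable[DMRRecord],
    index: AnnotationIndex,
    config: PipelineConfig | None = None,
) -> list[DMRRecord]:
    """Fill location_category and associations on a list of DMR records."""
    out = []
    for rec in records:
        a = assign_location(rec.interval, index, config)
        out.append(
            replace(
                rec,
                location_category=a.category,
                associated_gene_ids=a.gene_ids,
                associated_cpgi_ids=a.cpgi_ids,
                in_tiling_region=a.in_tiling_region,
            )
        )
    return out


def shore_density(
    dmrs: Sequence[GenomicInterval],
    cpgis: Sequence[CpGIsland],
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """DMR density inside CpG islands vs their 2-kb shores.

    Shores are the ``shore_bp`` flanks on each side of every island, minus
    any island bp (union semantics): the two compartments are disjoint.
    Returns per-bp densities (DMR bp overlapping the compartment / compartment
    bp) and per-count densities (number of DMRs overlapping / compartment bp).
    Empty compartments yield NaN.
    """
    cfg = config or PipelineConfig()
    islands = union([c.interval for c in cpgis])
    flanks = union([c.interval.expanded(cfg.shore_bp) for c in cpgis])
    shores: list[GenomicInterval] = []
    for f in flanks:
        shores.extend(subtract(f, islands))
    shores = union(shores)

    dmr_union = union(dmrs)

    def overlap_bp(compartment: list[GenomicInterval]) -> int:
        idx = IntervalIndex(compartment)
        bp = 0
        for d in dmr_union:
            for i in idx.overlapping(d):
                c = compartment[i]
                bp += min(d.end, c.end) - max(d.start, c.start)
        return bp

    def overlap_count(compartment: list[GenomicInterval]) -> int:
        idx = IntervalIndex(compartment)
        return sum(1 for d in dmrs if idx.overlapping(d))

    cpgi_bp = total_length(islands)
    shore_bp_total = total_length(shores)
    nan = float("nan")
    return {
        "cpgi_bp": float(cpgi_bp),
        "shore_bp": float(shore_bp_total),
        "density_in_cpgi": overlap_bp(islands) / cpgi_bp if cpgi_bp else nan,
        "density_in_shores": overlap_bp(shores) / shore_bp_total
        if shore_bp_total
        else nan,
        "count_density_in_cpgi": overlap_count(islands) / cpgi_bp if cpgi_bp else nan,
        "count_density_in_shores": overlap_count(shores) / shore_bp_total
        if shore_bp_total
        else nan,
    }
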