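"""Cross-sample set algebra on consensus peaks and DMR classification.

The genome is partitioned at every consensus-peak boundary into atomic
intervals so that one part of an overlapping peak can be a common region and
another part a sample-unique region. Each atom gets a three-valued presence
call per sample:

* present   — covered by that sample's replicate-consensus;
* absent    — overlaps no raw peak of either replicate of that sample;
* ambiguous — overlaps a raw peak but not the consensus (one replicate only,
  or replicate peaks whose intersection misses the atom).

Ambiguous membership quarantines a region from headline counts rather than
letting a single-replicate peak veto or support a differential call — the
same conservative direction as requiring peaks in both replicates.

T-DMRs are regions methylated in >= 1 of the four adult tissues and
unmethylated in >= 1; DS-DMRs are regions methylated in >= 1 of the stages
{E15, NB, AD} within a tissue and unmethylated in >= 1. DS-DMRs split into
UnMe-AD (unmethylated in adult: demethylation during development) and Me-AD
(methylated in adult: de novo methylation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .genome import PipelineConfig, ProbeLayout
from .intervals import GenomicInterval, IntervalIndex
from .peaks import ConsensusPeak, RawPeak

__all__ = [
    "TISSUES",
    "STAGES",
    "PresencePattern",
    "DMRRecord",
    "SummaryTable",
    "AdjustmentModel",
    "CrossTissueReport",
    "pattern_name",
    "partition_regions",
    "classify_tdmr",
    "classify_dsdmr",
    "cross_tissue_overlap",
    "adjust_counts",
    "tabulate",
]

TISSUES = ("brain", "heart", "liver", "testis")
STAGES = ("E15", "NB", "AD")


@dataclass(frozen=True)
class PresencePattern:
    """Partition of the sample universe into present/absent/ambiguous."""

    universe: tuple[str, ...]
    present: frozenset[str]
    absent: frozenset[str]
    ambiguous: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        u = set(self.universe)
        parts = [self.present, self.absent, self.ambiguous]
        if set().union(*parts) != u or sum(len(p) for p in parts) != len(u):
            raise ValueError("present/absent/ambiguous must partition the universe")

    @property
    def is_common(self) -> bool:
        return not self.absent and not self.ambiguous

    @property
    def flagged(self) -> bool:
        return bool(self.ambiguous)


def pattern_name(present: Iterable[str], universe: Sequence[str], style: str) -> str:
    """Canonical row label for a presence pattern.

    style='tissue': "Brain unique", "B + H", "Common".
    style='stage':  "E15_uniq", "E15+NB", "Common".
    """
    ordered = [u for u in universe if u in set(present)]
    if len(ordered) == len(universe):
        return "Common"
    if style == "tissue":
        if len(ordered) == 1:
            return f"{ordered[0].capitalize()} unique"
        return " + ".join(t[0].upper() for t in ordered)
    if len(ordered) == 1:
        return f"{ordered[0]}_uniq"
    return "+".join(ordered)


@dataclass
class DMRRecord:
    """Atomic region with its cross-sample presence pattern and classification."""

    interval: GenomicInterval
    pattern: PresencePattern
    n_probes: int
    dmr_class: str | None = None  # common | unique | multi
    stage_group: str | None = None  # UnMe-AD | Me-AD | common (DS mode)
    location_category: object | None = None  # annotate.LocationCategory
    associated_gene_ids: tuple[str, ...] = ()
    associated_cpgi_ids: tuple[str, ...] = ()
    in_tiling_region: bool = False

    @property
    def flagged(self) -> bool:
        return self.pattern.flagged

    @property
    def name(self) -> str:
        style = "stage" if set(self.pattern.universe) == set(STAGES) else "tissue"
        return pattern_name(self.pattern.present, self.pattern.universe, style)


def partition_regions(
    consensus_by_sample: Mapping[str, Sequence[ConsensusPeak]],
    raw_by_replicate: Mapping[str, Sequence[Sequence[RawPeak]]],
    layout: ProbeLayout,
    config: PipelineConfig | None = None,
    universe: Sequence[str] | None = None,
) -> list[DMRRecord]:
    """Partition consensus peaks across samples into presence-pattern atoms.

    ``consensus_by_sample`` maps each sample label (tissue, or stage within a
    tissue) to its consensus peaks; ``raw_by_replicate`` maps the same labels
    to the per-replicate raw-peak lists used for the absent/ambiguous call.
    Adjacent atoms with identical patterns are merged; atoms holding fewer
    than ``min_subpeak_probes`` probes, or present in no sample, are dropped.
    """
    cfg = config or PipelineConfig()
    labels = tuple(universe) if universe is not None else tuple(consensus_by_sample)
    if set(labels) != set(consensus_by_sample):
        raise ValueError("universe does not match consensus_by_sample keys")
    if set(raw_by_replicate) != set(labels):
        raise ValueError("raw_by_replicate keys do not match the sample universe")

    cons_idx = {
        lab: IntervalIndex([p.interval for p in consensus_by_sample[lab]])
        for lab in labels
    }
    raw_idx = {
        lab: IntervalIndex(
            [p.interval for reps in raw_by_replicate[lab] for p in reps]
        )
        for lab in labels
    }

    # Atom boundaries: all consensus edges, per chromosome.
    bounds: dict[str, set[int]] = {}
    for lab in labels:
        for pk in consensus_by_sample[lab]:
            bounds.setdefault(pk.interval.chrom, set()).update(
                (pk.interval.start, pk.interval.end)
            )

    records: list[DMRRecord] = []
    for chrom in sorted(bounds):
        edges = sorted(bounds[chrom])
        prev: DMRRecord | None = None
        for lo, hi in zip(edges[:-1], edges[1:]):
            atom = GenomicInterval(chrom, lo, hi)
            present, absent, ambiguous = set(), set(), set()
            for lab in labels:
                if cons_idx[lab].overlapping(atom):
                    present.add(lab)
                elif raw_idx[lab].overlapping(atom):
                    ambiguous.add(lab)
                else:
                    absent.add(lab)
            if not present:
                prev = _emit(prev, None, records, layout, cfg)
                continue
            pattern = PresencePattern(
                labels, frozenset(present), frozenset(absent), frozenset(ambiguous)
            )
            rec = DMRRecord(interval=atom, pattern=pattern, n_probes=0)
            if (
                prev is not None
                and prev.pattern == pattern
                and prev.interval.chrom == chrom
                and prev.interval.end == lo
            ):
                prev = replace(
                    prev,
                    interval=GenomicInterval(chrom, prev.interval.start, hi),
                )
            else:
                prev = _emit(prev, rec, records, layout, cfg)
        _emit(prev, None, records, layout, cfg)
    return records


def _emit(prev, nxt, records, layout, cfg):
    if prev is not None:
        n = layout.count_in(prev.interval)
        if n >= cfg.min_subpeak_probes:
            records.append(replace(prev, n_probes=n))
    return nxt


def classify_tdmr(
    records: Iterable[DMRRecord], universe: Sequence[str] = TISSUES
) -> list[DMRRecord]:
    """Assign common / tissue-unique / multi-tissue classes over adult tissues."""
    out = []
    for rec in records:
        if set(rec.pattern.universe) != set(universe):
            raise ValueError("record universe does not match the tissue universe")
        if rec.pattern.is_common:
            cls = "common"
        elif len(rec.pattern.present) == 1:
            cls = "unique"
        else:
            cls = "multi"
        out.append(replace(rec, dmr_class=cls))
    return out


def classify_dsdmr(
    records: Iterable[DMRRecord], universe: Sequence[str] = STAGES
) -> list[DMRRecord]:
    """Assign stage classes and the UnMe-AD / Me-AD developmental grouping."""
    out = []
    for rec in records:
        if set(rec.pattern.universe) != set(universe):
            raise ValueError("record universe does not match the stage universe")
        if rec.pattern.is_common:
            cls, group = "common", "common"
        else:
            cls = "unique" if len(rec.pattern.present) == 1 else "multi"
            group = "Me-AD" if "AD" in rec.pattern.present else "UnMe-AD"
        out.append(replace(rec, dmr_class=cls, stage_group=group))
    return out


# ---------------------------------------------------------------------------
# Cross-tissue overlap of DS-DMRs
# ---------------------------------------------------------------------------


@dataclass
class CrossTissueReport:
    """Overlap accounting across tissues, with and without multiplicity."""

    per_tissue_total: dict[str, int]
    per_tissue_unique: dict[str, int]
    per_tissue_multi: dict[str, int]
    total_with_multiplicity: int
    multi_with_multiplicity: int
    n_unique: int
    n_multi_clusters: int

    @property
    def dedup_total(self) -> int:
        return self.n_unique + self.n_multi_clusters

    @property
    def unique_fraction(self) -> float:
        return self.n_unique / self.dedup_total if self.dedup_total else float("nan")


def cross_tissue_overlap(
    dsdmr_sets: Mapping[str, Sequence[GenomicInterval]]
) -> CrossTissueReport:
    """Overlap DS-DMR interval sets across tissues.

    A region is tissue-unique if it overlaps no region of any other tissue.
    Overlapping regions are clustered by transitive (single-linkage) overlap;
    totals are reported both with multiplicity (each tissue's copy counted)
    and de-duplicated (one count per overlap cluster).
    """
    if len(dsdmr_sets) < 2:
        raise ValueError("cross_tissue_overlap needs >= 2 tissues")
    tagged = sorted(
        ((iv, tissue) for tissue, ivs in dsdmr_sets.items() for iv in ivs),
        key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]),
    )
    per_total = {t: len(ivs) for t, ivs in dsdmr_sets.items()}
    per_unique = {t: 0 for t in dsdmr_sets}
    per_multi = {t: 0 for t in dsdmr_sets}
    n_unique = 0
    n_multi_clusters = 0
    multi_mult = 0

    # Sweep: strict-overlap connected components within each chromosome.
    cluster: list[tuple[GenomicInterval, str]] = []
    max_end = -1
    chrom = None

    def close(cluster):
        nonlocal n_unique, n_multi_clusters, multi_mult
        if not cluster:
            return
        tissues = {t for _, t in cluster}
        if len(tissues) == 1:
            # no cross-tissue overlap: every member is tissue-unique
            n_unique += len(cluster)
            per_unique[next(iter(tissues))] += len(cluster)
        else:
            n_multi_clusters += 1
            multi_mult += len(cluster)
            for _, t in cluster:
                per_multi[t] += 1

    for iv, tissue in tagged:
        if chrom == iv.chrom and iv.start < max_end:
            cluster.append((iv, tissue))
            max_end = max(max_end, iv.end)
        else:
            close(cluster)
            cluster = [(iv, tissue)]
            chrom, max_end = iv.chrom, iv.end
    close(cluster)

    return CrossTissueReport(
        per_tissue_total=per_total,
        per_tissue_unique=per_unique,
        per_tissue_multi=per_multi,
        total_with_multiplicity=sum(per_total.values()),
        multi_with_multiplicity=multi_mult,
        n_unique=n_unique,
        n_multi_clusters=n_multi_clusters,
    )


# ---------------------------------------------------------------------------
# Replicate-quality count adjustment
# ---------------------------------------------------------------------------


@dataclass
class AdjustmentModel:
    """Per-stage count inflation from replicate Pearson concordance.

    Samples with lower replicate concordance under-call peaks; counts are
    rescaled as if every stage in a tissue had the concordance of that
    tissue's best stage. The default rule is a linear r-ratio: factor
    ``f_s = r_best / r_s`` per stage, a geometric mean of member factors for
    multi-stage patterns. The published analysis does not document its exact
    rule; this one is a declared, config-visible choice.
    """

    r_pscore: Mapping[str, Mapping[str, float]]  # tissue -> stage -> r

    def factor(self, tissue: str, stage: str) -> float:
        rs = self.r_pscore[tissue]
        if any(r <= 0 for r in rs.values()):
            raise ValueError(f"non-positive concordance for tissue {tissue}")
        return max(rs.values()) / rs[stage]

    def combined_factor(self, tissue: str, stages: Iterable[str]) -> float:
        fs = [self.factor(tissue, s) for s in stages]
        if not fs:
            raise ValueError("empty stage set")
        return math.exp(sum(math.log(f) for f in fs) / len(fs))


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

# Canonical row orders mirroring the published table layouts.
_TDMR_PATTERNS = (
    ("brain",), ("heart",), ("liver",), ("testis",),
    ("brain", "heart"), ("brain", "liver"), ("brain", "testis"),
    ("heart", "liver"), ("heart", "testis"), ("liver", "testis"),
    ("brain", "heart", "liver"), ("brain", "heart", "testis"),
    ("brain", "liver", "testis"), ("heart", "liver", "testis"),
)
_DSDMR_PATTERNS = (
    ("E15",), ("E15", "NB"), ("NB",), ("AD",), ("NB", "AD"), ("E15", "AD"),
)


@dataclass
class SummaryTable:
    """Counts per presence pattern x location category, mirroring the
    published table layouts (differential patterns, totals, and the common
    row reported separately)."""

    mode: str  # 'tdmr' | 'dsdmr'
    counts: dict[frozenset, dict]  # present-set -> {category-or-'total': n}
    categories: tuple
    universe: tuple[str, ...]
    tissue: str | None = None
    adjusted: dict[frozenset, int] | None = None

    def pattern_sets(self) -> list[frozenset]:
        pats = _TDMR_PATTERNS if self.mode == "tdmr" else _DSDMR_PATTERNS
        return [frozenset(p) for p in pats]

    def row(self, present: frozenset) -> dict:
        return self.counts.get(
            present, {"total": 0, **{c: 0 for c in self.categories}}
        )

    def total(self, which: str = "all") -> int:
        """Grand totals. which: all | unique | multi | common | UnMe-AD | Me-AD."""
        pats = self.pattern_sets()
        if which == "common":
            return self.row(frozenset(self.universe))["total"]
        if which == "unique":
            sel = [p for p in pats if len(p) == 1]
        elif which == "multi":
            sel = [p for p in pats if len(p) > 1]
        elif which == "UnMe-AD":
            sel = [p for p in pats if "AD" not in p]
        elif which == "Me-AD":
            sel = [p for p in pats if "AD" in p]
        else:
            sel = pats
        return sum(self.row(p)["total"] for p in sel)

    def category_total(self, category, which: str = "all") -> int:
        pats = self.pattern_sets()
        if which == "common":
            return self.row(frozenset(self.universe)).get(category, 0)
        if which == "unique":
            pats = [p for p in pats if len(p) == 1]
        elif which == "multi":
            pats = [p for p in pats if len(p) > 1]
        elif which == "UnMe-AD":
            pats = [p for p in pats if "AD" not in p]
        elif which == "Me-AD":
            pats = [p for p in pats if "AD" in p]
        return sum(self.row(p).get(category, 0) for p in pats)

    def to_frame(self):
        """Render to a DataFrame in the printed layout (one-decimal pcts)."""
        import pandas as pd

        style = "tissue" if self.mode == "tdmr" else "stage"
        rows = []

        def fmt_row(label, present, totals_of=None):
            if present is not None:
                r = self.row(present)
                total = r["total"]
                cats = {c: r.get(c, 0) for c in self.categories}
                adj = self.adjusted.get(present) if self.adjusted else None
            else:
                total = self.total(totals_of)
                cats = {
                    c: self.category_total(c, totals_of) for c in self.categories
                }
                adj = (
                    sum(
                        self.adjusted.get(p, self.row(p)["total"])
                        for p in self.pattern_sets()
                        if totals_of == "all"
                        or (totals_of == "unique" and len(p) == 1)
                        or (totals_of == "multi" and len(p) > 1)
                        or (totals_of == "UnMe-AD" and "AD" not in p)
                        or (totals_of == "Me-AD" and "AD" in p)
                    )
                    if self.adjusted and totals_of != "common"
                    else None
                )
            row = {"row": label, "total": total}
            if self.adjusted is not None:
                row["adjusted"] = adj
            for c in self.categories:
                n = cats[c]
                row[getattr(c, "value", str(c))] = n
                row[f"{getattr(c, 'value', str(c))}_pct"] = (
                    round(100.0 * n / total, 1) if total else 0.0
                )
            return row

        rows.append(fmt_row("Common", frozenset(self.universe)))
        if self.mode == "tdmr":
            for p in self.pattern_sets():
                if len(p) == 1:
                    rows.append(fmt_row(pattern_name(p, self.universe, style), p))
            rows.append(fmt_row("Total unique", None, "unique"))
            for p in self.pattern_sets():
                if len(p) > 1:
                    rows.append(fmt_row(pattern_name(p, self.universe, style), p))
            rows.append(fmt_row("Total multi", None, "multi"))
            rows.append(fmt_row("Total T-DMRs", None, "all"))
        else:
            for p in self.pattern_sets():
                rows.append(fmt_row(pattern_name(p, self.universe, style), p))
            rows.append(fmt_row("Total", None, "all"))
            rows.append(fmt_row("UnMe-AD", None, "UnMe-AD"))
            rows.append(fmt_row("Me-AD", None, "Me-AD"))
        return pd.DataFrame(rows).set_index("row")


def tabulate(
    records: Iterable[DMRRecord],
    mode: str,
    tissue: str | None = None,
    categories: Sequence | None = None,
) -> SummaryTable:
    """Count classified, location-annotated records per pattern x category.

    Ambiguous-flagged records are quarantined (excluded from all counts).
    """
    from .annotate import CORE_CATEGORIES

    if mode not in ("tdmr", "dsdmr"):
        raise ValueError("mode must be 'tdmr' or 'dsdmr'")
    universe = TISSUES if mode == "tdmr" else STAGES
    cats = tuple(categories) if categories is not None else CORE_CATEGORIES
    counts: dict[frozenset, dict] = {}
    for rec in records:
        if rec.flagged:
            continue
        key = frozenset(rec.pattern.present)
        row = counts.setdefault(key, {"total": 0, **{c: 0 for c in cats}})
        row["total"] += 1
        if rec.location_category in cats:
            row[rec.location_category] += 1
    return SummaryTable(
        mode=mode, counts=counts, categories=cats, universe=tuple(universe),
        tissue=tissue,
    )


def adjust_counts(table: SummaryTable, model: AdjustmentModel) -> SummaryTable:
    """Add the concordance-adjusted column to a DS-DMR summary table."""
    if table.mode != "dsdmr" or table.tissue is None:
        raise ValueError("adjustment applies to per-tissue DS-DMR tables")
    adjusted = {}
    for present in table.pattern_sets():
        f = model.combined_factor(table.tissue, present)
        adjusted[present] = round(table.row(present)["total"] * f)
    return replace(table, adjusted=adjusted)
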