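"""Synthetic MeDIP-chip experiments with known ground truth.

Emulates the promoter + CpG-island array design: non-overlapping genes on a
small genome, a configurable fraction of promoters carrying a CpG island,
probes tiling promoters (TSS +/- 1 kb), islands (+/- 500 bp) and any declared
contiguous tiling regions at ~100-bp spacing, with uncovered gaps elsewhere.

Ground-truth methylated regions are snapped to probe boundaries and carry a
(tissue, stage) presence pattern. Probe log2 ratios decompose into a shared
biological component plus independent per-replicate noise:

    value = mu(probe, sample) + N(0, sigma_shared) + N(0, sigma_rep)

with mu = mu_me inside a truth region present in that sample, else 0. The
shared/replicate variance split is derived analytically from the target
replicate Pearson correlation, including the variance contributed by the
mean-shift mixture itself, so the realized correlation matches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import DMRRecord, PresencePattern, STAGES, TISSUES
from .genome import CpGIsland, GeneModel, PipelineConfig, Probe, ProbeLayout
from .intervals import GenomicInterval, union

__all__ = [
    "SimulationConfig",
    "TruthRegion",
    "TruthSet",
    "generate_annotation",
    "generate_truth",
    "simulate_tracks",
    "generate_experiment",
    "fixture_from_counts",
]

# Default (tissue-set, stage-set) mixture: most regions are tissue-specific,
# with a realistic spread of stage patterns including pure demethylation
# (E15/NB-only) and adult de novo methylation (AD-containing) patterns.
DEFAULT_TISSUE_PATTERNS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("brain",), 0.13), (("heart",), 0.13), (("liver",), 0.12), (("testis",), 0.12),
    (("brain", "heart"), 0.10), (("liver", "testis"), 0.10),
    (("brain", "heart", "liver"), 0.10),
    (("brain", "heart", "liver", "testis"), 0.20),
)
DEFAULT_STAGE_PATTERNS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("E15", "NB", "AD"), 0.40),
    (("E15", "NB"), 0.15), (("E15",), 0.08), (("NB",), 0.08),
    (("AD",), 0.17), (("NB", "AD"), 0.06), (("E15", "AD"), 0.06),
)


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic experiment."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 150
    cpgi_promoter_fraction: float = 0.685  # share of promoters with a CpGi
    intragenic_cpgi_fraction: float = 0.15
    intergenic_cpgi_per_chrom: int = 3
    probe_spacing: int = 100
    probe_length: int = 50
    tiling_regions: tuple[str, ...] = ()
    tissues: tuple[str, ...] = TISSUES
    stages: tuple[str, ...] = STAGES
    n_replicates: int = 2
    n_truth_regions: int = 100
    truth_probes_min: int = 6
    truth_probes_max: int = 12
    truth_min_separation_bp: int = 1500
    tissue_pattern_dist: tuple = DEFAULT_TISSUE_PATTERNS
    stage_pattern_dist: tuple = DEFAULT_STAGE_PATTERNS
    mu_me: float = 1.5  # mean log2-ratio shift inside methylated regions
    sigma: float = 0.4  # total per-probe noise s.d.
    replicate_corr_target: float = 0.85

    def __post_init__(self) -> None:
        for dist in (self.tissue_pattern_dist, self.stage_pattern_dist):
            s = sum(w for _, w in dist)
            if abs(s - 1.0) > 1e-9:
                raise ValueError("pattern distribution weights must sum to 1")
        if self.mu_me < 0 or self.sigma <= 0:
            raise ValueError("mu_me must be >= 0 and sigma > 0")
        if not 0 < self.replicate_corr_target <= 1:
            raise ValueError("replicate_corr_target must be in (0, 1]")

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [(t, s) for t in self.tissues for s in self.stages]


@dataclass(frozen=True)
class TruthRegion:
    interval: GenomicInterval
    present: frozenset  # of (tissue, stage) pairs
    n_probes: int


@dataclass
class TruthSet:
    regions: list[TruthRegion]

    def present_in(self, tissue: str, stage: str) -> list[GenomicInterval]:
        return [
            r.interval for r in self.regions if (tissue, stage) in r.present
        ]


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[CpGIsland], ProbeLayout]:
    """Generate genes, CpG islands, and the probe layout they imply."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    cpgis: list[CpGIsland] = []
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if c < config.n_genes % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    gi = 0
    ci = 0
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        # room per gene: span + intergenic gap; fail early if too dense
        slot = config.chrom_length // max(n_here, 1)
        if slot < 12_000:
            raise ValueError("infeasible gene density for chrom_length")
        pos = 3000
        for _ in range(n_here):
            span = int(rng.integers(5000, min(20_000, slot - 7000)))
            gap = int(rng.integers(5000, 7000))
            start = pos
            end = start + span
            if end + 2000 > (config.chrom_length):
                raise ValueError("genes exceed chromosome length")
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"G{gi:04d}"
            genes.append(
                GeneModel(
                    gene_id=gid, name=gid, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=end,
                )
            )
            gene = genes[-1]
            if rng.random() < config.cpgi_promoter_fraction:
                # CpGi straddling the TSS
                w = int(rng.integers(300, 800))
                lo = max(0, gene.tss - w // 2)
                cpgis.append(
                    CpGIsland(f"CpG{ci:04d}", GenomicInterval(chrom, lo, lo + w))
                )
                ci += 1
            if rng.random() < config.intragenic_cpgi_fraction and span > 9000:
                # deep in the gene body, clear of the promoter window + proximity
                if strand == "+":
                    lo = start + 4000
                else:
                    lo = end - 4500
                w = int(rng.integers(300, 500))
                cpgis.append(
                    CpGIsland(f"CpG{ci:04d}", GenomicInterval(chrom, lo, lo + w))
                )
                ci += 1
            pos = end + gap
        # intergenic CpGis: past the last gene, > 2 kb from every span
        tail = pos + 4000
        for _ in range(config.intergenic_cpgi_per_chrom):
            w = int(rng.integers(300, 600))
            if tail + w + 1000 > config.chrom_length:
                break
            cpgis.append(
                CpGIsland(f"CpG{ci:04d}", GenomicInterval(chrom, tail, tail + w))
            )
            ci += 1
            tail += w + 6000

    cpgis.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    probes = _tile_probes(genes, cpgis, config)
    return genes, cpgis, probes


def _tile_probes(
    genes: Sequence[GeneModel], cpgis: Sequence[CpGIsland], config: SimulationConfig
) -> ProbeLayout:
    cfg = PipelineConfig(tiling_regions=config.tiling_regions)
    covered: list[GenomicInterval] = []
    for g in genes:
        covered.append(g.promoter(1000))
    for c in cpgis:
        covered.append(c.interval.expanded(500))
    covered.extend(cfg.tiling_intervals())
    probes: list[Probe] = []
    k = 0
    for iv in union(covered):
        x = iv.start
        while x + config.probe_length <= iv.end:
            probes.append(
                Probe(f"P{k:06d}", GenomicInterval(iv.chrom, x, x + config.probe_length))
            )
            k += 1
            x += config.probe_spacing
    return ProbeLayout(probes)


def _draw_pattern(dist, rng: np.random.Generator):
    weights = np.array([w for _, w in dist])
    i = int(rng.choice(len(dist), p=weights / weights.sum()))
    return dist[i][0]


def generate_truth(
    layout: ProbeLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Place disjoint truth regions snapped to probe boundaries.

    Each region spans a run of consecutive probes on one chromosome (random
    length between truth_probes_min and truth_probes_max) and is assigned a
    presence pattern = tissue-set x stage-set drawn from the configured
    mixtures. Regions keep >= truth_min_separation_bp apart so that peak
    merging cannot bridge two regions with different patterns.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)

    # Contiguous covered runs: consecutive same-chromosome probes whose gap
    # stays within 2x the design spacing.
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(layout) + 1):
        if i == len(layout):
            runs.append((start, i))
            break
        a, b = layout.probes[i - 1], layout.probes[i]
        if (
            b.interval.chrom != a.interval.chrom
            or b.interval.start - a.interval.end > 2 * config.probe_spacing
        ):
            runs.append((start, i))
            start = i

    sep_probes = max(1, -(-config.truth_min_separation_bp // config.probe_spacing))
    candidates: list[tuple[int, int]] = []  # (first probe idx, k)
    for lo, hi in runs:
        cursor = lo + int(rng.integers(0, 3))
        while True:
            k = int(rng.integers(config.truth_probes_min, config.truth_probes_max + 1))
            if cursor + k > hi:
                break
            candidates.append((cursor, k))
            cursor += k + sep_probes + int(rng.integers(0, 3))
    if len(candidates) < config.n_truth_regions:
        raise ValueError(
            f"could not place {config.n_truth_regions} truth regions "
            f"(capacity {len(candidates)}); layout too small"
        )
    chosen = sorted(
        rng.choice(len(candidates), size=config.n_truth_regions, replace=False)
    )
    regions: list[TruthRegion] = []
    for ci in chosen:
        i, k = candidates[ci]
        first, last = layout.probes[i], layout.probes[i + k - 1]
        tset = _draw_pattern(config.tissue_pattern_dist, rng)
        sset = _draw_pattern(config.stage_pattern_dist, rng)
        present = frozenset((t, s) for t in tset for s in sset)
        regions.append(
            TruthRegion(
                interval=GenomicInterval(
                    first.interval.chrom, first.interval.start, last.interval.end
                ),
                present=present,
                n_probes=k,
            )
        )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return TruthSet(regions=regions)


def _noise_split(config: SimulationConfig, meth_fraction: float) -> tuple[float, float]:
    """(sigma_shared, sigma_rep) hitting the replicate-correlation target.

    Total per-probe variance T = sigma^2 + v with v = f(1-f) mu^2 the
    mean-shift mixture variance; shared variance S = sigma_shared^2 + v.
    Solving S / T = rho gives sigma_shared^2 = rho*T - v, clamped to
    [0, sigma^2].
    """
    v = meth_fraction * (1.0 - meth_fraction) * config.mu_me**2
    total = config.sigma**2 + v
    sh2 = min(max(config.replicate_corr_target * total - v, 0.0), config.sigma**2)
    return math.sqrt(sh2), math.sqrt(config.sigma**2 - sh2)


def simulate_tracks(
    truth: TruthSet,
    layout: ProbeLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str, int], "pd.Series"]:
    """Simulate raw per-replicate log2-ratio vectors for every sample.

    Returns a dict keyed by (tissue, stage, replicate_index) of probe_id ->
    log2 ratio Series (unscaled; feed through scale_track as in a real run).
    """
    from .scoring import SignalTrack  # noqa: F401 (documented return usage)

    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    centers = np.array([p.center for p in layout.probes])
    chroms = np.array([p.interval.chrom for p in layout.probes])
    out: dict[tuple[str, str, int], pd.Series] = {}
    for tissue, stage in config.samples:
        mu = np.zeros(len(layout))
        for r in truth.regions:
            if (tissue, stage) not in r.present:
                continue
            mask = (chroms == r.interval.chrom) & (
                (centers >= r.interval.start) & (centers < r.interval.end)
            )
            mu[mask] = config.mu_me
        f = float((mu > 0).mean())
        s_sh, s_rep = _noise_split(config, f)
        shared = mu + rng.normal(0.0, s_sh, size=len(layout))
        for rep in range(1, config.n_replicates + 1):
            vals = shared + rng.normal(0.0, s_rep, size=len(layout))
            out[(tissue, stage, rep)] = pd.Series(vals, index=layout.probe_ids)
    return out


def generate_experiment(config: SimulationConfig):
    """Annotation + truth + tracks in one call (deterministic under seed)."""
    rng = np.random.default_rng(config.seed)
    genes, cpgis, layout = generate_annotation(config, rng)
    truth = generate_truth(layout, config, rng)
    tracks = simulate_tracks(truth, layout, config, rng)
    return genes, cpgis, layout, truth, tracks


def recovery_metrics(
    truth: TruthSet,
    consensus_by_sample: Mapping[tuple[str, str], Sequence],
    min_reciprocal: float = 0.5,
) -> dict[str, float]:
    """Region-level recall/precision and exact pattern recovery vs truth.

    A (region, sample) truth entry is recovered when some consensus peak of
    that sample overlaps the region reciprocally (overlap >= min_reciprocal
    of both lengths). Precision is the fraction of consensus peaks matching
    a truth region present in their sample. Pattern recovery is the fraction
    of detected truth regions whose detected sample set equals the truth
    presence set exactly.
    """

    def _iv(p):
        return getattr(p, "interval", p)

    def recip(a, b) -> bool:
        if a.chrom != b.chrom:
            return False
        ov = min(a.end, b.end) - max(a.start, b.start)
        return ov >= min_reciprocal * a.length and ov >= min_reciprocal * b.length

    tp = fn = 0
    pat_ok = detected = 0
    for r in truth.regions:
        det = {
            key
            for key, peaks in consensus_by_sample.items()
            if any(recip(r.interval, _iv(p)) for p in peaks)
        }
        for key in r.present:
            if key in det:
                tp += 1
            else:
                fn += 1
        if det:
            detected += 1
            if det == r.present:
                pat_ok += 1
    fp = n_peaks = 0
    for key, peaks in consensus_by_sample.items():
        present = [r.interval for r in truth.regions if key in r.present]
        for p in peaks:
            n_peaks += 1
            if not any(recip(_iv(p), iv) for iv in present):
                fp += 1
    nan = float("nan")
    return {
        "recall": tp / (tp + fn) if tp + fn else nan,
        "precision": 1.0 - fp / n_peaks if n_peaks else nan,
        "pattern_recovery": pat_ok / detected if detected else nan,
        "n_truth_sample_pairs": tp + fn,
        "n_consensus_peaks": n_peaks,
    }


def fixture_from_counts(
    count_spec: Mapping,
    universe: Sequence[str],
    region_bp: int = 500,
    spacing_bp: int = 1000,
    chrom: str = "chrF",
) -> list[DMRRecord]:
    """Emit disjoint dummy DMR records realizing exact per-pattern counts.

    ``count_spec`` maps a presence set (any iterable of labels from
    ``universe``) either to an integer count or to a mapping
    ``location_category -> count``. Regions are laid out end to end on a
    synthetic chromosome; presence complements are all 'absent' (no
    ambiguity), so every record enters headline counts.
    """
    uni = tuple(universe)
    records: list[DMRRecord] = []
    pos = 0
    for present_key in count_spec:
        present = frozenset(
            [present_key] if isinstance(present_key, str) else present_key
        )
        if not present or not present <= set(uni):
            raise ValueError(f"bad pattern {present_key!r} for universe {uni}")
        val = count_spec[present_key]
        per_cat = val if isinstance(val, Mapping) else {None: int(val)}
        for category, n in per_cat.items():
            if n < 0:
                raise ValueError("counts must be non-negative")
            for _ in range(int(n)):
                iv = GenomicInterval(chrom, pos, pos + region_bp)
                pos += region_bp + spacing_bp
                records.append(
                    DMRRecord(
                        interval=iv,
                        pattern=PresencePattern(
                            uni, present, frozenset(set(uni) - present)
                        ),
                        n_probes=2,
                        location_category=category,
                    )
                )
    return records
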