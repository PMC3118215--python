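"""Methylation peak calling from P-score tracks.

A raw peak is a maximal run of >= 2 consecutive probes (array order within a
chromosome) with P score >= 2; its interval spans the first to last
qualifying probe. Raw peaks within 500 bp (edge-to-edge, inclusive) are
merged. The sample-level consensus is the intersection of the two biological
replicates' raw peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .genome import PipelineConfig, ProbeLayout
from .intervals import GenomicInterval, intersect, union
from .scoring import PScoreTrack

__all__ = ["RawPeak", "ConsensusPeak", "call_peaks", "merge_peaks", "consensus_peaks"]


@dataclass
class RawPeak:
    interval: GenomicInterval
    sample_id: Hashable
    n_probes: int
    max_pscore: float
    mean_pscore: float
    # layout indices of the qualifying probes; used to recompute stats on merge
    probe_idx: tuple[int, ...] = field(default_factory=tuple, repr=False)


@dataclass
class ConsensusPeak:
    """Replicate-intersected methylated region for one (tissue, stage) sample."""

    interval: GenomicInterval
    tissue: str
    stage: str
    n_probes: int
    source_raw_ids: tuple[int, ...] = ()


def call_peaks(
    pscores: PScoreTrack, layout: ProbeLayout, config: PipelineConfig | None = None
) -> list[RawPeak]:
    """Call raw peaks: threshold runs, then nearby-peak merging."""
    cfg = config or PipelineConfig()
    p = layout.values_in_order(pscores.pscores)
    peaks: list[RawPeak] = []
    for chrom in layout.chroms:
        a, b = layout.chrom_slice(chrom)
        run: list[int] = []
        for i in range(a, b):
            qualifies = p[i] >= cfg.pscore_threshold
            if qualifies and run and cfg.max_probe_gap_bp is not None:
                gap = layout.probes[i].interval.start - layout.probes[run[-1]].interval.end
                if gap > cfg.max_probe_gap_bp:
                    _flush_run(run, p, pscores.sample_id, layout, cfg, peaks)
                    run = []
            if qualifies:
                run.append(i)
            else:
                _flush_run(run, p, pscores.sample_id, layout, cfg, peaks)
                run = []
        _flush_run(run, p, pscores.sample_id, layout, cfg, peaks)
    return merge_peaks(peaks, cfg.merge_bp)


def _flush_run(
    run: list[int],
    p: np.ndarray,
    sample_id: Hashable,
    layout: ProbeLayout,
    cfg: PipelineConfig,
    out: list[RawPeak],
) -> None:
    if len(run) < cfg.min_consecutive_probes:
        return
    first, last = layout.probes[run[0]], layout.probes[run[-1]]
    scores = p[run]
    out.append(
        RawPeak(
            interval=GenomicInterval(
                first.interval.chrom, first.interval.start, last.interval.end
            ),
            sample_id=sample_id,
            n_probes=len(run),
            max_pscore=float(scores.max()),
            mean_pscore=float(scores.mean()),
            probe_idx=tuple(run),
        )
    )


def merge_peaks(peaks: Sequence[RawPeak], merge_bp: int) -> list[RawPeak]:
    """Merge peaks with edge distance <= merge_bp (inclusive) to a fixpoint.

    The merged interval is the convex hull; probe statistics are recomputed
    over the union of the qualifying probes. A single sorted sweep reaches
    the fixpoint because merging only ever extends the right edge.
    """
    ordered = sorted(peaks, key=lambda pk: (pk.interval.chrom, pk.interval.start))
    out: list[RawPeak] = []
    for pk in ordered:
        if (
            out
            and out[-1].interval.chrom == pk.interval.chrom
            and pk.interval.start - out[-1].interval.end <= merge_bp
        ):
            prev = out[-1]
            idx = tuple(sorted(set(prev.probe_idx) | set(pk.probe_idx)))
            hull = GenomicInterval(
                pk.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, pk.interval.end),
            )
            scores = [prev.max_pscore, pk.max_pscore]
            if idx:
                mean = (
                    prev.mean_pscore * prev.n_probes + pk.mean_pscore * pk.n_probes
                ) / max(prev.n_probes + pk.n_probes, 1)
            else:
                mean = max(prev.mean_pscore, pk.mean_pscore)
            out[-1] = RawPeak(
                interval=hull,
                sample_id=pk.sample_id,
                n_probes=len(idx) if idx else prev.n_probes + pk.n_probes,
                max_pscore=max(scores),
                mean_pscore=mean,
                probe_idx=idx,
            )
        else:
            out.append(pk)
    return out


def consensus_peaks(
    rep1: Sequence[RawPeak],
    rep2: Sequence[RawPeak],
    layout: ProbeLayout,
    config: PipelineConfig | None = None,
    tissue: str = "",
    stage: str = "",
) -> list[ConsensusPeak]:
    """Regions shared between the two biological replicates of one sample.

    Pairwise intersections of overlapping raw peaks; intersections holding
    fewer than ``min_subpeak_probes`` probes (by center) are dropped; the
    remainder is unioned into disjoint consensus peaks.
    """
    cfg = config or PipelineConfig()
    pieces: list[GenomicInterval] = []
    for p1 in rep1:
        for p2 in rep2:
            ov = intersect(p1.interval, p2.interval)
            if ov is not None and layout.count_in(ov) >= cfg.min_subpeak_probes:
                pieces.append(ov)
    merged = union(pieces)
    return [
        ConsensusPeak(
            interval=iv, tissue=tissue, stage=stage, n_probes=layout.count_in(iv)
        )
        for iv in merged
        if layout.count_in(iv) >= cfg.min_subpeak_probes
    ]
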