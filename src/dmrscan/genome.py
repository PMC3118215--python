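"""Array/genome domain types and readers/writers for the standard formats.

Internal coordinates are uniformly 0-based half-open. Readers convert at the
boundary: BED, refFlat and cpgIslandExt are already 0-based half-open; the
NimbleGen GFF dialect is 1-based inclusive and is shifted on read/write.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "Probe",
    "GeneModel",
    "CpGIsland",
    "PipelineConfig",
    "ProbeLayout",
    "ParseError",
    "read_genes",
    "read_cpg_islands",
    "read_annotation",
    "read_probes",
    "write_probes",
    "read_bed",
    "write_bed",
    "read_signal_tsv",
    "write_signal_tsv",
    "read_nimblegen_gff",
    "write_pscore_gff",
]


class ParseError(ValueError):
    """Raised for malformed annotation/signal input, naming the line."""


@dataclass(frozen=True)
class Probe:
    """One array feature."""

    probe_id: str
    interval: GenomicInterval

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"empty gene span for {self.gene_id}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (a single base position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)

    def promoter(self, flank_bp: int) -> GenomicInterval:
        """Promoter window: TSS +/- flank_bp, clipped at 0."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - flank_bp), self.tss + flank_bp
        )


@dataclass(frozen=True)
class CpGIsland:
    id: str
    interval: GenomicInterval


@dataclass
class PipelineConfig:
    """Every numeric constant of the analysis, in bp or score units.

    Defaults are the published NimbleGen/MeDIP settings: 750-bp scoring
    window, P score >= 2, >= 2 consecutive probes per peak, 500-bp peak
    merging, TSS +/- 1 kb promoters, 500-bp CpG-island proximity, 2-kb
    intergenic cutoff, and 2-kb CpG-island shores.
    """

    window_bp: int = 750
    pscore_threshold: float = 2.0
    min_consecutive_probes: int = 2
    merge_bp: int = 500
    promoter_flank_bp: int = 1000
    cpgi_proximity_bp: int = 500
    intergenic_min_bp: int = 2000
    shore_bp: int = 2000
    min_window_probes: int = 2
    min_subpeak_probes: int = 2
    ks_pvalue_floor: float = 1e-300
    # NimbleScan's exact biweight constants are unpublished; exposed here.
    biweight_c: float = 5.0
    # Background for the KS test: rest of the array (False) or whole array.
    background_includes_window: bool = False
    # Optional: break probe runs across uncovered gaps larger than this.
    max_probe_gap_bp: int | None = None
    strict_paper_mode: bool = False
    tiling_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "window_bp",
            "merge_bp",
            "promoter_flank_bp",
            "cpgi_proximity_bp",
            "intergenic_min_bp",
            "shore_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.pscore_threshold <= 0:
            raise ValueError("pscore_threshold must be > 0")
        if self.min_consecutive_probes < 1 or self.min_subpeak_probes < 1:
            raise ValueError("probe floors must be >= 1")

    def tiling_intervals(self) -> list[GenomicInterval]:
        """Parse ``chrom:start-end`` tiling-region strings (0-based half-open)."""
        out = []
        for s in self.tiling_regions:
            chrom, _, rng = s.replace(",", "").partition(":")
            lo, _, hi = rng.partition("-")
            out.append(GenomicInterval(chrom, int(lo), int(hi)))
        return out

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


class ProbeLayout:
    """Sorted probe set with fast per-chromosome center lookups.

    Probe membership in an interval is decided by the probe *center*
    throughout the package (window membership, peak/atom probe counts).
    """

    def __init__(self, probes: Iterable[Probe]):
        plist = sorted(probes, key=lambda p: (p.interval.chrom, p.interval.start))
        ids = [p.probe_id for p in plist]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe_id in layout")
        self.probes: list[Probe] = plist
        self.probe_ids: list[str] = ids
        self._index = {pid: i for i, pid in enumerate(ids)}
        self.chroms: list[str] = []
        self._ranges: dict[str, tuple[int, int]] = {}
        self._centers: dict[str, np.ndarray] = {}
        start = 0
        for i, p in enumerate(plist + [None]):  # type: ignore[list-item]
            if p is None or (i > 0 and p.interval.chrom != plist[i - 1].interval.chrom):
                chrom = plist[i - 1].interval.chrom
                self.chroms.append(chrom)
                self._ranges[chrom] = (start, i)
                self._centers[chrom] = np.array(
                    [q.center for q in plist[start:i]], dtype=np.int64
                )
                start = i
            if p is None:
                break

    def __len__(self) -> int:
        return len(self.probes)

    def index_of(self, probe_id: str) -> int:
        return self._index[probe_id]

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        return self._ranges[chrom]

    def centers(self, chrom: str) -> np.ndarray:
        return self._centers[chrom]

    def probes_in(self, interval: GenomicInterval) -> list[Probe]:
        """Probes whose center lies inside the interval."""
        if interval.chrom not in self._ranges:
            return []
        lo, _ = self._ranges[interval.chrom]
        c = self._centers[interval.chrom]
        i = int(np.searchsorted(c, interval.start, side="left"))
        j = int(np.searchsorted(c, interval.end - 1, side="right"))
        return self.probes[lo + i : lo + j]

    def count_in(self, interval: GenomicInterval) -> int:
        if interval.chrom not in self._ranges:
            return 0
        c = self._centers[interval.chrom]
        i = np.searchsorted(c, interval.start, side="left")
        j = np.searchsorted(c, interval.end - 1, side="right")
        return int(j - i)

    def values_in_order(self, values: dict[str, float] | pd.Series) -> np.ndarray:
        """Align a probe_id -> value mapping to layout order."""
        s = pd.Series(values)
        missing = [pid for pid in self.probe_ids if pid not in s.index]
        if missing:
            raise ValueError(f"values missing for {len(missing)} probes, e.g. {missing[0]}")
        return s.reindex(self.probe_ids).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, n_min_cols: int, what: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            parts = line.split("\t")
            if len(parts) < n_min_cols:
                raise ParseError(
                    f"{path}:{lineno}: malformed {what} line "
                    f"({len(parts)} fields, expected >= {n_min_cols})"
                )
            rows.append(parts)
    return rows


def read_genes(path: str | Path, fmt: str = "auto") -> list[GeneModel]:
    """Read gene models from refFlat-style TSV or BED12.

    refFlat: geneName, name, chrom, strand, txStart, txEnd, ... (0-based
    half-open). BED12: chrom, start, end, name, score, strand, ... Both are
    returned sorted by (chrom, tx_start); thickStart/exon fields are ignored.
    """
    rows = _read_table(path, 6, "gene")
    genes: list[GeneModel] = []
    for i, parts in enumerate(rows, start=1):
        if fmt == "auto":
            # refFlat has strand in column 4; BED12 has it in column 6.
            this_fmt = "refflat" if parts[3] in ("+", "-") else "bed12"
        else:
            this_fmt = fmt
        try:
            if this_fmt == "refflat":
                gene = GeneModel(
                    gene_id=parts[1],
                    name=parts[0],
                    chrom=parts[2],
                    strand=parts[3],
                    tx_start=int(parts[4]),
                    tx_end=int(parts[5]),
                )
            else:
                gene = GeneModel(
                    gene_id=parts[3],
                    name=parts[3],
                    chrom=parts[0],
                    strand=parts[5],
                    tx_start=int(parts[1]),
                    tx_end=int(parts[2]),
                )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: gene record {i}: {exc}") from exc
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def read_cpg_islands(path: str | Path, fmt: str = "auto") -> list[CpGIsland]:
    """Read CpG islands from BED or UCSC cpgIslandExt TSV.

    cpgIslandExt rows may carry a leading integer ``bin`` column; both layouts
    are 0-based half-open already.
    """
    rows = _read_table(path, 3, "CpG island")
    out: list[CpGIsland] = []
    for i, parts in enumerate(rows, start=1):
        this_fmt = fmt
        if fmt == "auto":
            # cpgIslandExt: [bin,] chrom, chromStart, chromEnd, name, length, ...
            if parts[0].lstrip("-").isdigit():
                this_fmt = "cpgislandext_bin"
            else:
                this_fmt = "bed"
        try:
            if this_fmt == "cpgislandext_bin":
                chrom, start, end = parts[1], int(parts[2]), int(parts[3])
                name = parts[4] if len(parts) > 4 else f"CpG_{i}"
            else:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"CpG_{i}"
        except ValueError as exc:
            raise ParseError(f"{path}: CpG island record {i}: {exc}") from exc
        out.append(CpGIsland(id=name, interval=GenomicInterval(chrom, start, end)))
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return out


def read_annotation(
    gene_path: str | Path, cpgi_path: str | Path
) -> tuple[list[GeneModel], list[CpGIsland]]:
    """Load gene models and CpG islands together, sorted by (chrom, start)."""
    return read_genes(gene_path), read_cpg_islands(cpgi_path)


def read_probes(path: str | Path) -> ProbeLayout:
    """Read an array layout TSV: chrom, start, end, probe_id."""
    rows = _read_table(path, 4, "probe")
    probes = []
    for i, parts in enumerate(rows, start=1):
        try:
            probes.append(
                Probe(
                    probe_id=parts[3],
                    interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: probe record {i}: {exc}") from exc
    return ProbeLayout(probes)


def write_probes(layout: ProbeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in layout.probes:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.probe_id}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    rows = _read_table(path, 3, "BED")
    out = []
    for i, parts in enumerate(rows, start=1):
        try:
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ParseError(f"{path}: BED record {i}: {exc}") from exc
    return out


def write_bed(
    records: Sequence[tuple[GenomicInterval, str, float]] | Sequence[GenomicInterval],
    path: str | Path,
) -> None:
    """Write BED3 (bare intervals) or BED6 ((interval, name, score) tuples)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
            else:
                iv, name, score = rec
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\n"
                )


def read_signal_tsv(path: str | Path) -> pd.Series:
    """Per-replicate signal TSV: probe_id <tab> value. Returns probe_id-indexed Series."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["probe_id", "value"], comment="#"
    )
    if df["value"].isna().any() or not np.isfinite(df["value"]).all():
        raise ParseError(f"{path}: non-finite signal values")
    return df.set_index("probe_id")["value"]


def write_signal_tsv(values: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, v in values.items():
            fh.write(f"{pid}\t{v:.6g}\n")


def read_nimblegen_gff(path: str | Path) -> pd.DataFrame:
    """Read a NimbleGen-dialect GFF of per-probe scores.

    Columns: seqid, source, feature, start (1-based incl.), end, score,
    strand, frame, attributes. The probe id is taken from the attributes
    field. Returns a DataFrame (probe_id, chrom, start, end, score) with
    coordinates converted to 0-based half-open.
    """
    rows = _read_table(path, 9, "GFF")
    recs = []
    for i, parts in enumerate(rows, start=1):
        try:
            attrs = parts[8]
            pid = attrs.split("=")[-1].split(";")[0].strip().strip('"')
            recs.append(
                {
                    "probe_id": pid,
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "score": float(parts[5]),
                }
            )
        except ValueError as exc:
            raise ParseError(f"{path}: GFF record {i}: {exc}") from exc
    return pd.DataFrame(recs)


def write_pscore_gff(
    layout: ProbeLayout, pscores: dict[str, float] | pd.Series, path: str | Path,
    source: str = "dmrscan",
) -> None:
    """Write per-probe P scores in the NimbleGen GFF dialect (1-based incl.)."""
    s = pd.Series(pscores)
    with open(path, "w") as fh:
        for p in layout.probes:
            fh.write(
                f"{p.interval.chrom}\t{source}\tprobe\t{p.interval.start + 1}"
                f"\t{p.interval.end}\t{s[p.probe_id]:.4f}\t.\t.\tID={p.probe_id}\n"
            )
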