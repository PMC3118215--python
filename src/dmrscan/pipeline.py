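"""End-to-end orchestration: scale -> score -> call -> consensus ->
partition -> classify -> annotate -> tabulate.

Runs either on files (per-replicate signal TSVs + annotation) or on a
self-contained synthetic experiment, writes every intermediate, and records
a manifest (config hash, inputs, seed, per-stage counts) so identical
manifests imply identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    CORE_CATEGORIES,
    TILING_CATEGORIES,
    AnnotationIndex,
    annotate_records,
    shore_density,
)
from .classify import (
    AdjustmentModel,
    adjust_counts,
    classify_dsdmr,
    classify_tdmr,
    cross_tissue_overlap,
    partition_regions,
    tabulate,
)
from .genome import (
    PipelineConfig,
    ProbeLayout,
    read_annotation,
    read_probes,
    read_signal_tsv,
    write_bed,
    write_probes,
    write_signal_tsv,
)
from .peaks import call_peaks, consensus_peaks
from .scoring import (
    PScoreTrack,
    SignalTrack,
    concordance_report,
    scale_track,
    windowed_ks_pscore,
)
from .simulate import SimulationConfig, generate_experiment

log = logging.getLogger("dmrscan")

__all__ = ["ConfigError", "InputError", "RunManifest", "PipelineResult", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class InputError(ValueError):
    """Missing or unreadable inputs (CLI exit code 3)."""


@dataclass
class RunManifest:
    config_hash: str
    inputs: list[str]
    seed: int | None
    stage_counts: dict[str, int]
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    out_dir: Path
    layout: ProbeLayout
    tdmr_records: list
    tdmr_table: object
    dsdmr_records: dict  # tissue -> records
    dsdmr_tables: dict  # tissue -> SummaryTable
    cross_tissue: object | None
    concordance: list
    manifest: RunManifest
    consensus: dict = field(default_factory=dict)  # (tissue, stage) -> peaks
    truth: object | None = None


def _config_hash(payload) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        p = Path(config)
        if not p.exists():
            raise InputError(f"config file not found: {p}")
        try:
            cfg = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"bad YAML in {p}: {exc}") from exc
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
    return cfg


def _build_params(cfg: dict) -> PipelineConfig:
    try:
        return PipelineConfig(**cfg.get("params", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad params: {exc}") from exc


def run_pipeline(config, out_dir=None, seed=None) -> PipelineResult:
    """Run the full analysis per a YAML/dict run configuration.

    See README for the config schema. ``out_dir``/``seed`` override the
    config's values. Returns a PipelineResult; all tables and BED files are
    written under the output directory.
    """
    cfg = _load_config(config)
    params = _build_params(cfg)
    seed = seed if seed is not None else cfg.get("seed", 0)
    out = Path(out_dir if out_dir is not None else cfg.get("output_dir", "dmrscan_out"))
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if "simulate" in cfg:
        try:
            sim = SimulationConfig(seed=seed, **(cfg["simulate"] or {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad simulate block: {exc}") from exc
        genes, cpgis, layout, truth, raw_values = generate_experiment(sim)
        tissues, stages = list(sim.tissues), list(sim.stages)
        inputs = [f"simulated(seed={seed})"]
        write_probes(layout, out / "probes.tsv")
        with open(out / "genes.refflat", "w") as fh:
            for g in genes:
                fh.write(
                    f"{g.name}\t{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}"
                    f"\t{g.tx_end}\t{g.tx_start}\t{g.tx_end}\t0\t\t\n"
                )
        write_bed([(c.interval, c.id, 0.0) for c in cpgis], out / "cpgi.bed")
        write_bed(
            [
                (r.interval, "|".join(sorted(f"{t}.{s}" for t, s in r.present)), 0.0)
                for r in truth.regions
            ],
            out / "truth.bed",
        )
    else:
        inp = cfg["inputs"]
        for k in ("probes", "genes", "cpgi", "samples"):
            if k not in inp:
                raise ConfigError(f"inputs block missing '{k}'")
        for k in ("probes", "genes", "cpgi"):
            if not Path(inp[k]).exists():
                raise InputError(f"input file not found: {inp[k]}")
        layout = read_probes(inp["probes"])
        genes, cpgis = read_annotation(inp["genes"], inp["cpgi"])
        raw_values = {}
        for s in inp["samples"]:
            p = Path(s["path"])
            if not p.exists():
                raise InputError(f"signal file not found: {p}")
            raw_values[(s["tissue"], s["stage"], int(s["replicate"]))] = read_signal_tsv(p)
        tissues = sorted({k[0] for k in raw_values})
        stages = sorted({k[1] for k in raw_values})
        stages = [s for s in ("E15", "NB", "AD") if s in stages] or stages
        inputs = [str(inp[k]) for k in ("probes", "genes", "cpgi")] + [
            str(s["path"]) for s in inp["samples"]
        ]

    # Every sample needs exactly two replicates (consensus is defined on two).
    for t in tissues:
        for s in stages:
            reps = sorted(r for (tt, ss, r) in raw_values if (tt, ss) == (t, s))
            if reps != [1, 2]:
                raise InputError(
                    f"sample ({t}, {s}) needs replicates 1 and 2, found {reps}"
                )

    counts: dict[str, int] = {"probes": len(layout), "genes": len(genes), "cpgi": len(cpgis)}

    # scale -> score -> call, per replicate
    pscores: dict[tuple, PScoreTrack] = {}
    scaled: dict[tuple, SignalTrack] = {}
    raws: dict[tuple, list] = {}
    for key in sorted(raw_values):
        tr = scale_track(SignalTrack(sample_id=key, values=raw_values[key]), params)
        scaled[key] = tr
        ps = windowed_ks_pscore(tr, layout, params)
        pscores[key] = ps
        pk = call_peaks(ps, layout, params)
        raws[key] = pk
        t, s, r = key
        write_signal_tsv(tr.values, out / f"scaled_{t}_{s}_r{r}.tsv")
        write_signal_tsv(ps.pscores, out / f"pscores_{t}_{s}_r{r}.tsv")
        write_bed(
            [
                (p.interval, f"{t}.{s}.r{r}", round(10 * p.max_pscore))
                for p in pk
            ],
            out / f"rawpeaks_{t}_{s}_r{r}.bed",
        )
    counts["raw_peaks"] = sum(len(v) for v in raws.values())
    log.info("raw peaks: %d across %d replicate tracks", counts["raw_peaks"], len(raws))

    # P-score matrix export (plain-matrix stand-in for heat-map rendering)
    mat = pd.DataFrame(
        {f"{t}.{s}.r{r}": pscores[(t, s, r)].pscores for (t, s, r) in sorted(pscores)}
    )
    mat.index.name = "probe_id"
    mat.round(4).to_csv(out / "pscore_matrix.tsv", sep="\t")

    # consensus per (tissue, stage)
    consensus: dict[tuple, list] = {}
    reports = []
    for t in tissues:
        for s in stages:
            cons = consensus_peaks(
                raws[(t, s, 1)], raws[(t, s, 2)], layout, params, tissue=t, stage=s
            )
            consensus[(t, s)] = cons
            reports.append(
                concordance_report(
                    t, s, (scaled[(t, s, 1)], scaled[(t, s, 2)]),
                    (pscores[(t, s, 1)], pscores[(t, s, 2)]),
                )
            )
            write_bed(
                [(p.interval, f"{t}.{s}", p.n_probes) for p in cons],
                out / f"consensus_{t}_{s}.bed",
            )
    counts["consensus_peaks"] = sum(len(v) for v in consensus.values())
    pd.DataFrame(
        [
            {"tissue": r.tissue, "stage": r.stage, "r_log2": round(r.r_log2, 4),
             "r_pscore": round(r.r_pscore, 4)}
            for r in reports
        ]
    ).to_csv(out / "concordance.tsv", sep="\t", index=False)

    ann_index = AnnotationIndex(genes, cpgis, params)
    all_cats = CORE_CATEGORIES + (
        TILING_CATEGORIES if params.tiling_regions else ()
    )

    # T-DMRs across tissues at the adult stage
    tdmr_stage = "AD" if "AD" in stages else stages[-1]
    tdmr_records = partition_regions(
        {t: consensus[(t, tdmr_stage)] for t in tissues},
        {t: (raws[(t, tdmr_stage, 1)], raws[(t, tdmr_stage, 2)]) for t in tissues},
        layout, params, universe=tissues,
    )
    tdmr_records = annotate_records(
        classify_tdmr(tdmr_records, tissues), ann_index, params
    )
    tdmr_table = tabulate(tdmr_records, "tdmr", categories=all_cats)
    _write_dmr_bed(tdmr_records, out / "tdmr.bed")
    tdmr_table.to_frame().to_csv(out / "tdmr_table.tsv", sep="\t")
    counts["tdmr_records"] = len(tdmr_records)

    # DS-DMRs across stages within each tissue
    dsdmr_records: dict[str, list] = {}
    dsdmr_tables: dict[str, object] = {}
    cross = None
    if len(stages) < 2:
        log.warning("fewer than 2 stages: DS-DMR stage skipped")
    else:
        model = AdjustmentModel(
            r_pscore={
                t: {r.stage: r.r_pscore for r in reports if r.tissue == t}
                for t in tissues
            }
        )
        ds_intervals = {}
        for t in tissues:
            recs = partition_regions(
                {s: consensus[(t, s)] for s in stages},
                {s: (raws[(t, s, 1)], raws[(t, s, 2)]) for s in stages},
                layout, params, universe=stages,
            )
            recs = annotate_records(classify_dsdmr(recs, stages), ann_index, params)
            dsdmr_records[t] = recs
            table = tabulate(recs, "dsdmr", tissue=t, categories=all_cats)
            try:
                table = adjust_counts(table, model)
            except ValueError:
                log.warning("concordance non-positive for %s; adjusted column skipped", t)
            dsdmr_tables[t] = table
            _write_dmr_bed(recs, out / f"dsdmr_{t}.bed")
            table.to_frame().to_csv(out / f"dsdmr_table_{t}.tsv", sep="\t")
            ds_intervals[t] = [
                r.interval for r in recs
                if r.dmr_class in ("unique", "multi") and not r.flagged
            ]
        counts["dsdmr_records"] = sum(len(v) for v in dsdmr_records.values())
        if len(tissues) >= 2:
            cross = cross_tissue_overlap(ds_intervals)
            pd.DataFrame(
                [
                    {
                        "tissue": t,
                        "all_dsdmrs": cross.per_tissue_total[t],
                        "tissue_unique": cross.per_tissue_unique[t],
                        "multiple_tissues": cross.per_tissue_multi[t],
                    }
                    for t in tissues
                ]
            ).to_csv(out / "cross_tissue.tsv", sep="\t", index=False)

        sd = shore_density(
            [iv for ivs in ds_intervals.values() for iv in ivs], cpgis, params
        )
        pd.DataFrame([sd]).to_csv(out / "shore_density.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config_hash=_config_hash(
            {"params": dataclasses.asdict(params), "cfg": cfg, "seed": seed}
        ),
        inputs=inputs,
        seed=seed,
        stage_counts=counts,
    )
    manifest.write(out / "manifest.json")
    return PipelineResult(
        out_dir=out, layout=layout, tdmr_records=tdmr_records,
        tdmr_table=tdmr_table, dsdmr_records=dsdmr_records,
        dsdmr_tables=dsdmr_tables, consensus=consensus, cross_tissue=cross,
        concordance=reports, manifest=manifest, truth=truth,
    )


def _write_dmr_bed(records, path: Path) -> None:
    """BED6+ export: name = pattern, extra columns for class/group/category."""
    with open(path, "w") as fh:
        for r in records:
            cat = r.location_category.value if r.location_category else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.name}\t{r.n_probes}\t.\t{r.dmr_class or '.'}"
                f"\t{r.stage_group or '.'}\t{cat}\t{int(r.flagged)}\n"
            )
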