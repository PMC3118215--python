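# dmrscan

Differential-methylation analysis for MeDIP-chip experiments on promoter +
CpG-island tiling arrays.

MeDIP (methylated-DNA immunoprecipitation) enriches 5-methyl-cytosine-bearing
DNA fragments; co-hybridizing IP and input DNA to a tiling array yields a
per-probe log2 IP/input ratio that is high where the genome is methylated.
`dmrscan` implements the downstream analysis for a multi-sample design —
several tissues, each sampled at several developmental stages, with two
biological replicates per sample:

1. **Scaling** — each replicate's log2 ratios are centred by subtracting the
   array-wide Tukey biweight mean.
2. **P scores** — for every probe, a fixed 750-bp window around the probe is
   compared against the rest of the array with a one-sided two-sample
   Kolmogorov–Smirnov test for a *more positive* window distribution:

   `D+ = sup_x [F_bg(x) − F_win(x)]`,  `p = exp(−2 D+² mn / (m+n))`,
   `P = −log10 p`

   with *m* window and *n* background probes.
3. **Peak calling** — runs of ≥ 2 consecutive probes with P ≥ 2 become raw
   methylation peaks; peaks within 500 bp are merged.
4. **Replicate consensus** — a sample's methylated regions are the
   intersections of its two replicates' raw peaks.
5. **DMR classification** — consensus peaks of all samples are partitioned at
   peak boundaries into atomic regions with a per-sample
   present/absent/ambiguous call ("absent" additionally requires no raw-peak
   overlap in either replicate). Regions methylated in ≥ 1 tissue and
   unmethylated in ≥ 1 are tissue-specific DMRs (**T-DMRs**); within one
   tissue, regions differing across stages (embryonic day 15, newborn, adult)
   are stage-specific DMRs (**DS-DMRs**), grouped into UnMe-AD (unmethylated
   in adult — developmental demethylation) and Me-AD (de novo methylation).
6. **Location categories** — each DMR gets exactly one category in priority
   order: CpGi promoter → non-CpGi promoter → intragenic CpGi → intergenic
   CpGi → (tiling regions only) non-CpGi intragenic/intergenic, with
   promoters = TSS ± 1 kb and CpG-island proximity = 500 bp edge-to-edge.
7. **Tabulation** — counts and percentages per presence pattern × location
   category, cross-tissue overlap accounting with and without multiplicity,
   replicate-concordance-adjusted counts, and CpG-island vs 2-kb-shore DMR
   density.

A first-class synthetic-data generator (`dmrscan.simulate`) emulates the
array design and produces ground-truth experiments, so every stage is
testable end to end without array data.

## Worked example

```python
from dmrscan import run_pipeline
from dmrscan.simulate import recovery_metrics

res = run_pipeline({"simulate": {}}, out_dir="out", seed=1)
print(res.tdmr_table.total("all"), res.tdmr_table.total("common"))
m = recovery_metrics(res.truth, res.consensus)
print(round(m["recall"], 3), round(m["precision"], 3))
```

prints

```
47 13
0.995 0.993
```

meaning: on the default synthetic design (150 genes on two 1.2-Mb
chromosomes, 100 ground-truth methylated regions, effect size 1.5 log2
units, noise σ = 0.4, replicate correlation target 0.85) the pipeline calls
47 adult T-DMRs plus 13 regions methylated in all four tissues, and
recovers 99.5% of truth (region, sample) pairs at 99.3% precision.
`out/` then contains per-replicate P-score tracks, raw/consensus peak BEDs,
classified DMR BED6+ files, summary tables mirroring the standard
pattern × category layout, a P-score matrix TSV, and a run manifest.

The `examples/` directory walks through each capability (simulation,
scoring/peak calling, consensus + classification, location annotation, full
pipeline); each script prints the numbers it computes and what they mean.

## Command line

```bash
dmrscan simulate --seed 1 --out sim/
dmrscan run --config run.yaml --seed 1 --out out/
dmrscan score --probes sim/probes.tsv --signal scaled.tsv --out pscores.tsv
```

The `run` config takes either a `simulate:` block (generator parameters) or
an `inputs:` block (`probes`, `genes`, `cpgi`, and a `samples` list of
`{tissue, stage, replicate, path}` signal TSVs — two replicates per sample
are required). All thresholds (`--threshold`, `--window-bp`, `--merge-bp`,
`--strict-paper-mode`) override the config. Exit codes: 0 ok, 2 config
error, 3 input error.

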