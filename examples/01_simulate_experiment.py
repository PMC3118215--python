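"""Generate a synthetic MeDIP-chip experiment and inspect its design.

Builds a promoter + CpG-island array layout over a small two-chromosome
genome, places ground-truth methylated regions with (tissue, stage)
presence patterns, and simulates duplicate log2 IP/input ratio tracks for
the 4-tissue x 3-stage design.
"""

from collections import Counter

from dmrscan import SimulationConfig, generate_experiment

cfg = SimulationConfig(seed=42)
genes, cpgis, layout, truth, tracks = generate_experiment(cfg)

print(f"genes: {len(genes)}   CpG islands: {len(cpgis)}   probes: {len(layout)}")
print(f"truth regions: {len(truth.regions)}   replicate tracks: {len(tracks)}")

sizes = Counter(len(r.present) for r in truth.regions)
print("\nregions by number of (tissue, stage) samples methylated:")
for k in sorted(sizes):
    print(f"  present in {k:2d} samples: {sizes[k]} regions")

r = truth.regions[0]
print(f"\nfirst truth region: {r.interval} ({r.n_probes} probes)")
print("  methylated in:", ", ".join(sorted(f"{t}/{s}" for t, s in r.present)))

# Each printed region is a location the pipeline should later recover as a
# methylation peak in exactly the listed samples.
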