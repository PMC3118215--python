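# Methods

## Signal model and scaling

The unit of observation is a probe-level log2 IP/input ratio from a MeDIP
hybridization on a promoter + CpG-island tiling array. Ratios are centred by
subtracting the array-wide **Tukey biweight mean**: location initialised at
the median, scale fixed at `c · MAD` (MAD about the initial median), weights
`(1 − u²)²` for `|u| < 1` and 0 otherwise, iterated to `|Δ| < 1e-9` (≤ 50
iterations). `c = 5.0` by default and config-exposed, because the vendor's
exact constants for this step are unpublished; with a zero MAD (no spread in
the bulk of the data) the median is returned directly. The MAD is *not*
re-estimated between iterations — the one-step fixed-scale form is standard,
converges in a handful of iterations, and makes the estimate deterministic.

## Windowed one-sided KS P score

For each probe, the window is the set of probes on the same chromosome whose
**centre** lies within `window_bp / 2` (default ±375 bp, i.e. a 750-bp total
span) of the focal probe's centre. The background is every other probe on
the array ("rest of the array"); a config switch
(`background_includes_window`) instead uses the whole array, for
compatibility experiments with processors that do not exclude the window.

The one-sided statistic is `D+ = sup_x [F_bg(x) − F_win(x)]` with
right-continuous empirical CDFs — positive when the window's ratios are
shifted upward. Because `F_bg − F_win` only increases at background points
and drops at window points, the supremum is attained immediately below a
window jump, so it is evaluated with strict counts at the sorted window
values (ties handled by `searchsorted(..., side="left")`). The p-value is
the asymptotic one-sided form `p = exp(−2 D+² mn/(m+n))`, clipped to
`[ks_pvalue_floor, 1]` (floor 1e-300), and `P = −log10 p`. Windows with
fewer than `min_window_probes` (default 2) probes score 0 — a one-probe
"window" is just that probe's own value and carries no distributional
information. scipy's `ks_2samp(..., alternative="greater", method="asymp")`
reproduces the same `D+` exactly but adds a small-sample continuity
correction to the p-value; the uncorrected closed form is used here, the
exact permutation distribution serves as a rank-agreement oracle in the
tests, and only the fixed threshold P ≥ 2 is ever consumed downstream.

## Peak calling, merging, consensus

Raw peaks are maximal runs of consecutive probes (array order within a
chromosome) with `P ≥ pscore_threshold` (2.0) of length
`≥ min_consecutive_probes` (2); the peak interval spans the first to last
qualifying probe. "Consecutive" ignores genomic gaps by default (the array
is locally dense where it covers at all); `max_probe_gap_bp` optionally
breaks runs across large uncovered gaps. Peaks with edge-to-edge distance
`≤ merge_bp` (500, inclusive — "within 500 bp" reads as ≤) are merged to a
convex hull; a single left-to-right sweep reaches the fixpoint.

A sample's **consensus peaks** are the pairwise intersections of its two
replicates' raw peaks, dropped when they hold fewer than
`min_subpeak_probes` (2) probe centres — this floor mirrors the 2-probe peak
floor and prevents 1-bp sliver consensus — then unioned to disjoint
intervals.

Probe membership in any interval (windows, peaks, atoms) is decided by the
probe centre, so counts partition cleanly when intervals abut.

## Partition and three-valued presence

The genome is cut at every consensus-peak boundary of every sample into
atomic intervals; only atoms covered by at least one sample's consensus are
kept. Per atom and sample the call is:

* **present** — covered by that sample's consensus;
* **absent** — overlaps no raw peak of either replicate of the sample;
* **ambiguous** — overlaps a raw peak but not the consensus.

The raw-peak veto for "absent" extends the published uniqueness criterion
(which applies it to unique peaks) to every absent call, and ambiguous
membership quarantines the region from headline counts instead of either
vetoing or supporting the differential call — both choices bias toward
undercounting DMRs, the same conservative direction as requiring peaks in
both replicates. A region overlapping raw peaks of *both* replicates whose
intersection misses the atom is likewise ambiguous (it is not confirmably
absent). Adjacent atoms with identical patterns are re-merged, and atoms
with fewer than `min_subpeak_probes` probes are dropped.

T-DMR classification runs over the four adult tissues: absent ∅ and
ambiguous ∅ → common; one present tissue → tissue-unique; otherwise
multi-tissue. DS-DMR classification runs over the stages {E15, NB, AD}
within one tissue, with the developmental grouping UnMe-AD (AD ∉ present:
demethylated by adulthood) vs Me-AD (AD ∈ present: de novo methylation).

## Cross-tissue overlap and adjusted counts

Cross-tissue overlap treats each tissue's DS-DMR intervals as a set; a
region is tissue-unique when it overlaps no other tissue's region, and
overlapping regions are clustered by transitive (single-linkage) strict
overlap. Totals are reported both with multiplicity (each tissue's copy
counted) and de-duplicated (one per cluster), reproducing the dual
accounting used for such tables.

Replicate-quality adjustment rescales per-pattern counts as if every stage
in a tissue had the replicate Pearson concordance (on P scores) of that
tissue's best stage: factor `f_s = r_best / r_s`, multi-stage patterns use
the geometric mean of member factors, results are rounded. The rule behind
the published "Adjusted" columns is not documented; this linear r-ratio
rule is a declared default, labelled non-canonical, and nothing downstream
depends on it. Non-positive concordance makes the adjustment undefined and
raises.

## Location categories

With promoters = TSS ± `promoter_flank_bp` (1 kb, strand-aware TSS) and all
proximity measured edge-to-edge:

1. **CpGi promoter** — overlaps a promoter and lies within
   `cpgi_proximity_bp` (500) of some CpG island;
2. **non-CpGi promoter** — overlaps a promoter, no island within 500 bp;
3. **intragenic CpGi** — within 500 bp of an island that overlaps a gene
   body (gene span minus that gene's promoter window; overlap, not
   containment, so boundary islands still count);
4. **intergenic CpGi** — within 500 bp of an island more than
   `intergenic_min_bp` (2 kb) from every gene span;
5./6. **non-CpGi intragenic / intergenic** — fallthrough by gene-span
   overlap.

Assignment is strictly first-match, so a DMR gets exactly one category and
record order can never change an assignment. The four main categories are
not exhaustive — e.g. a DMR near an island that is 0–2 kb from a gene but
outside promoter and body matches none of them — and such DMRs fall through
to 5/6 rather than being dropped. On a pure promoter + CpGi design the
fallthrough categories arise essentially only inside contiguous tiling
regions; `strict_paper_mode` flags fallthrough assignments outside the
declared tiling regions (`tiling_regions`, `chrom:start-end` strings).
Bidirectional promoters may claim one DMR for two genes: the category comes
from the highest-priority match and both gene associations are recorded.

CpG-island **shores** are the `shore_bp` (2 kb) flanks of each island minus
any island bp (union semantics), so island and shore compartments are
disjoint; DMR density is reported per-bp (covered bp / compartment bp) and
per-count.

## Synthetic experiments

The generator emulates the array design rather than the genome: genes are
placed without overlap (5–20 kb spans, 5–7 kb gaps), a configurable fraction
of promoters (default 0.685, the array's CpGi-promoter share) get an island
straddling the TSS, some gene bodies and intergenic stretches get additional
islands, and probes (50-mers) tile promoters (TSS ± 1 kb), islands ± 500 bp
and any declared tiling regions at 100-bp spacing, leaving uncovered gaps
elsewhere.

Ground-truth methylated regions are runs of 6–12 consecutive probes snapped
to probe boundaries — window-scale and larger, the size class a 750-bp
windowed test is designed for — kept ≥ 1.5 kb apart so peak merging cannot
bridge two regions. Each region draws a tissue-set and a stage-set from
configurable mixtures (defaults: 20% common to all tissues, 55% one or two
tissues; 40% all-stage, with demethylation-type and de-novo-type stage
patterns both represented); its presence set is the product of the two.

Probe values decompose as `value = μ + shared + replicate noise` with
`μ = mu_me` (1.5) inside regions present in that sample and 0 elsewhere and
total noise s.d. `sigma` (0.4). The shared/replicate variance split is
solved from the target replicate Pearson correlation (0.85) *including* the
variance `f(1−f)μ²` contributed by the methylation mixture itself
(`σ_shared² = ρ(σ² + v) − v`, clamped to `[0, σ²]`), so the realized
correlation matches the target instead of overshooting it. Setting the
target to 1 makes replicates identical; `mu_me = 0` is the null model.

What the generator does **not** emulate: CpG-density-dependent MeDIP
efficiency, fragment-size effects, dye bias or spatial artefacts, repeat
regions (the arrays exclude them), and probe-level variance heterogeneity.
Passing recovery tests therefore demonstrates the correctness of the
scoring/peak/set-algebra machinery under the stated noise model, not
robustness to array artefacts.

## Problem sizes and numerical choices

Default synthetic experiments use two 1.2-Mb chromosomes, 150 genes,
~3,100 probes and 24 replicate tracks (4 tissues × 3 stages × 2), about
1.5 s per full pipeline run; recovery checks average 5 seeds. These sizes
give stable metrics (≈ 400 truth (region, sample) pairs per run) while
keeping the whole suite fast. Recovery is scored at ≥ 50% reciprocal
overlap; expected performance at defaults is recall/precision ≈ 0.96–0.99
and exact-pattern recovery ≈ 0.9–0.99.

Other numerical choices: p-values clipped at 1e-300 before the log; summary
percentages rounded to one decimal from each row's own total; peak merging
is annotation-blind (categories are assigned after region calling, matching
the stage order of the original processing); chromosome names are compared
as exact strings; all coordinates are 0-based half-open internally with
dialect conversion (NimbleGen GFF is 1-based inclusive) only at I/O.

## Known limitations

* The KS p-value is asymptotic; for very small windows the permutation
  p-value differs in level (though not in ranking), and only the fixed
  threshold is used.
* The adjusted-count rule is a declared approximation (see above).
* Ambiguous regions are quarantined, not resolved; with noisy replicates
  this shrinks headline counts rather than inflating them.
* `distance`-based proximity is edge-to-edge; midpoint-based readings of
  "within 500 bp" would classify a small boundary set differently.
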