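# Methods

`azoreg` implements a genome-scale workflow for nominating regulators of a
focal bacterial gene — here an azoreductase (*azoR*-like) gene whose product
reduces azo dyes such as methyl red, bleaching the medium at 450 nm. The
workflow combines five independent lines of evidence: where in condition
space the gene's expression sits across public expression compendia, which
genes repeatedly co-express with it, which transposon disruptions change the
decolorization phenotype, where those transposons landed, and how candidate
genes respond transcriptionally to the dye. This note records the models,
the defaults and why, the numerical choices, and what the synthetic data do
and do not establish.

## Percentile-rank compendium meta-analysis

**Unit of analysis.** Cross-platform expression repositories publish a
gene's expression within a sample as a percentile rank: its average rank
among all measured genes, scaled to 0–100. The package takes that
representation as primary (`to_percentile_ranks` exists to transform raw
synthetic matrices: per column, `average_rank / n_genes * 100`, average
ranks for ties, order-preserving and idempotent up to re-ranking).

**Filtering.** Samples without a focal-gene value are dropped and counted;
an optional strain regex (e.g. `"K-12"`) restricts to a genetic background.
The filter reports per-reason removal counts because the funnel (how many
samples survived each rule) is part of the result.

**Stratification and test.** Each metadata condition partitions its
non-missing samples into categories; numeric fields are binned. Default
bins follow the contrasts the workflow was designed around: OD600 <0.4 /
0.4–0.7 / >0.7; glucose ~0.02% / 0.1–0.4% / ≥0.5%; agitation ≤60 / 61–199 /
200–300 rpm; temperature 25–30 °C vs 37 °C. All bins are configurable.
Each category's values are tested against the *grand median* of all values
for that condition with a two-sided one-sample Wilcoxon signed-rank test
(`zero_method="zsplit"`, so ties at the median are kept rather than
silently shrinking n; a category identical to the grand median returns
p = 1 directly). Categories with fewer than 3 samples are flagged
untestable, not errored. P-values are Benjamini–Hochberg adjusted across
the categories of one condition; `significant` means adjusted p < α
(default 0.05). The choice of a nonparametric one-sample test is this
package's decision — it matches rank-scale data and the
"category vs condition-wide median" comparison — and is deliberately
isolated behind `category_significance` so it can be swapped.

**Missing metadata** are excluded per condition, never imputed: public
compendia are heterogeneous by construction and an imputed growth phase is
worse than an absent one.

## Consensus co-expression

Within one dataset, the focal gene's *profile neighbors* are the top
K = 200 genes by Pearson correlation between percentile-rank profiles
(equivalent to Spearman on the raw scale; Spearman and cosine are available
alternatives — which similarity public repositories use for their neighbor
lists is not documented, so it is configurable rather than resolved).
Genes with zero-variance profiles are excluded (undefined r); ties break
lexicographically so results are deterministic. Datasets with fewer than 3
samples or a flat focal profile are skipped with a logged reason.

A gene's **consensus count** is the number of datasets in which it makes
the neighbor list; each dataset contributes once (duplicate dataset ids are
an error). The candidate cutoff is *half the maximum observed count,
rounded up* (`ceil(max/2)`): with a maximum of 10 that is 5; ceiling keeps
the rule from ever selecting below half for odd maxima. Candidates are
sorted by (count desc, gene id).

**Category tallies.** Functional-category summaries count a multi-category
gene once per category; genes without annotation are tallied as
`unannotated`. Percentages are integer **truncations** of
100·count/n_candidates, applied consistently across the package (the
published tables this mirrors truncate 14/112 to 12%). Fuzzy functional
clustering (kappa-statistic style) is out of scope; only the tallies are
implemented.

## Decolorization screen

Decolorization % = (A₀ − A₁₆)/A₀ × 100 at 450 nm; the quantity is
scale-invariant in absorbance units. Negative values (a well that got
darker) are returned as-is and flagged — they signal growth or turbidity
artefacts and should be inspected, not clamped. Mutants are normalized to
the wild type: mutant% / WT% × 100, by default against *their own plate's*
WT wells (absorbing plate effects); a global-WT mode exists. Hit classes
use inclusive cutoffs: normalized ≤ 65 → reduced, ≥ 110 → increased
(inclusivity chosen because a strain at exactly 65 belongs in the reduced
set). Confirmation retests preliminary hits (default 2 experiments × 3
replicates) and requires both a Welch two-tailed t-test against WT
rejecting at α *and* a mean normalized value still beyond its cutoff. Welch
rather than pooled-variance is this package's choice: mutant and WT well
variances need not match. Strains with fewer than 3 replicates are
reported untestable.

The retest's WT reference is measured in 24 wells by default, against 6 per
candidate. The wild type is the shared denominator of every normalized
value, so its estimation error is systematic across all candidates; with
hundreds of chance preliminary flags, a WT mean a few percent low pushes
every neutral strain toward the ≥110 cutoff. Giving the reference strain a
plate-row's worth of wells is standard practice and keeps the confirmation
false-discovery rate below 0.1 under the generator's noise model.

## Insertion mapping

**Trimming.** Junction reads begin (or, reverse-complemented, end) with the
19-bp Tn5 mosaic end `CTGTCTCTTATACACATCT` (the default; configurable —
any Tn5-derived transposon shares it). The trimmer scans both orientations
allowing ≤2 mismatches (ambiguous bases count as mismatches), removes the
end and everything outward, strips terminal N runs, and discards reads
shorter than 20 bp or with >10% internal Ns. Reads with no detectable end
pass through untrimmed with a warning — single-primer amplification
products can start past the end sequence — but then the junction side is
unknown and the reported coordinate assumes a 5′ junction. Whether
ambiguity cleanup should also remove internal Ns is left as a policy knob
(`max_internal_n_frac`); the default only gates on their fraction.

**Alignment.** Exact affine-gap Smith–Waterman (a numba kernel) on both
strands; the minus strand aligns the reverse-complemented query and maps
coordinates back. Scoring defaults mimic common nucleotide-search defaults
(match +2, mismatch −3, gap open 5, gap extend 2) with Karlin–Altschul
parameters λ = 0.625, K = 0.41 and E = K·m·n·e^(−λS). Exact agreement with
any production search tool's statistics is **not** claimed: those tools use
heuristic seeding, edge corrections and database-scale n. At toy scale the
exact DP is the more defensible stand-in. 'N' never matches anything.
Best-cell ties prefer the smallest reference coordinate, making reports
deterministic.

**Reporting.** The "first hit" is the highest-scoring alignment with
E ≤ 1e−5 (cutoff configurable; no hit → `no_similarity`). The insertion
coordinate is the reference base aligned to the query end that abutted the
trimmed transposon end, strand-aware. Coordinates are 0-based half-open
internally and 1-based inclusive in reports (BED output stays 0-based
half-open). Identity % = trunc(100·identities/alignment_columns) and
gaps are counted over alignment columns (`g/len`), matching the `id/len
(N%)` report style. Gene assignment is by 1-based interval containment
against a non-overlapping annotation table.

## ddCt quantification

ΔCt = mean Ct(target) − mean Ct(reference) per condition; ΔΔCt subtracts
the control condition's ΔCt; fold = 2^(−ΔΔCt), assuming 100% amplification
efficiency (no efficiency correction — that is a different method). Using
replicate means for the point estimate makes the control's own fold exactly
1 and makes every ΔΔCt invariant to global Ct shifts. Dispersion defaults
to the SD over replicate-matched fold estimates; a Ct-SD propagation mode
(delta method) is available because published error bars are computed both
ways and rarely say which.

Group statistics operate on Ct values, not folds: >2 groups → one-way
ANOVA with Tukey-adjusted pairwise comparisons; exactly 2 → paired t-test
on replicate-matched Cts (unequal replicate counts are an error, not
silently truncated). Each group needs ≥3 replicates.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed) — identical configs
give byte-identical outputs.

**Compendium** (default 50 datasets, 4000 genes, 4–20 samples per dataset
adjusted to a 462-sample total, ~89% K-12 strain labels): each dataset
draws a latent standard-normal gene × sample matrix; the focal gene's
latent profile encodes a target percentile 50 + Σ(condition shifts) +
N(0, 8) clamped to [0.5, 99.5]; module genes mix the *standardized* focal
latent as r·z + √(1−r²)·ε (standardization matters: without it the realized
correlation is r scaled by the latent's SD, ~0.8 instead of 0.95); every
column is then converted to percentile ranks, so rank-scale validity holds
by construction. Default condition shifts (±8–12 percentile points) follow
the directions the focal gene is reported to respond to: up in mid-density
cultures, log phase, minimal media, ≥0.5% glucose, ≤60 rpm, 25–30 °C.
Each dataset omits each condition field with probability 0.3 (at least one
always kept) — how complete real compendium metadata are is not documented
anywhere, so the omission rate is a free parameter. One 10-gene module at
r = 0.95 in 10 of 50 datasets is planted by default.

What the generator does **not** model: platform chemistry, batch effects,
correlated background modules, non-exchangeable samples within datasets.
Passing recovery tests therefore shows the *statistics* behave as designed
under the stated noise model — not that real compendia are this clean. In
particular, background consensus counts here are Binomial(50, K/n_genes)
by construction, which is why planted-module counts (not the half-max
cutoff itself) are the recovery criterion.

**Screen** (default 4320 mutants, 96-well plates with 3 WT wells and one
knockout-control well each, WT decolorization 60% ± 4 per well): strain
classes neutral/reduced/increased with multipliers 1.0/0.5/1.3 and
frequencies 99.5%/0.35%/0.15%, chosen so a full screen yields confirmed-hit
counts of the order a real 4320-clone screen reported (~20). Initial
absorbance ~N(1.0, 0.02); the final absorbance encodes the noisy
decolorization. Dye kinetics and growth-curve effects are not modeled.

**qPCR** (6 genes × 3 conditions × 3 replicates): Ct = per-gene baseline −
planted log2 fold + N(0, 0.2) cycles; the reference gene must carry no
planted fold. A single triplicate experiment's ΔΔCt has SD ≈ 0.23 cycles,
so fold estimates from one experiment scatter roughly ×/÷ 1.2; recovery
checks therefore average over 30 seeded experiments.

**Mapping** (50 kb genome, 40 genes of 300–1200 bp placed by partitioning
the free space into gaps, 24 insertions, 400 bp reads): reads are mosaic
end + true flank with Ns injected at the configured rate; only 'N' is used
for ambiguity (IUPAC partial codes are out of scope). Chromatogram-level
quality is not modeled.

## Pipeline

`run_pipeline` derives one sub-seed per stage by hashing the stage name
with the global seed (all below 2³¹), so stages re-run independently and
the whole run is byte-reproducible; the manifest lists every output with a
SHA-256 checksum and no timestamps. The toy genome names its first genes
after the regulator analogs whose disruption the screen detects, and the
qPCR stage quantifies the same genes, so the merged per-gene evidence table
exhibits the intended convergence (a gene backed by screen + mapping +
qPCR). Evidence rows always cite their source stages.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the compendium analysis at
full default scale (50 × 4000 × 462), the screen at 4320 mutants, null
calibrations at 500 replicates, alignment-oracle comparisons at 200 tiny
instances (query ≤ 12 bp against reference ≤ 60 bp, where exact recursive
scoring is feasible), and insertion mapping at the 50 kb / 24-read default.
These sizes were chosen so a complete run takes a few minutes on one CPU
while still exercising every code path at its intended scale.

## Known limitations

- The half-max candidate cutoff is sensitive to a single high-count gene;
  on synthetic data with planted modules the maximum is a module gene and
  the cutoff lands above the background, but on null data it degenerates
  toward 1.
- E-values are not comparable to database-scale search tools (n differs by
  orders of magnitude); only their ordering is used.
- The Wilcoxon-vs-grand-median test treats samples as exchangeable across
  datasets; real compendia have dataset-level correlation the test ignores.
- `confirm_hits` tests decolorization percentages, not normalized values;
  with a per-plate WT design these differ slightly when plates drift.
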