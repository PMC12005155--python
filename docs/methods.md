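# Methods

## Coordinate and preprocessing conventions

All coordinates are 0-based half-open (BED). Dyad annotations supplied as
1-based single positions are converted on input. Fragment midpoints are
`(start + end) // 2`; the floor tie-rule for even lengths is not dictated by
any biological argument, but it is applied uniformly to every sample, so all
relative comparisons (V-plots, ΔZ) are unaffected.

Read preprocessing keeps the two procedural constants of the assay in one
place: reads are capped at 140 bp and reads shorter than 35 bp are
discarded. Adapter trimming itself is upstream of this package; the
operation acts on already-adapter-stripped lengths and is idempotent.
Fragment BED records are treated as true protection lengths.

Depth normalization multiplies every coverage increment by
N = 139,712,364 / (total mapped reads). The numerator is an arbitrary fixed
constant (any constant would do — it only sets the display scale); it is
exposed in `coverage.DEFAULT_NORM_CONSTANT` and as a function argument.

## Coverage, V-plots, metagenes

Overlap coverage adds N to every bp a fragment spans (genome-wide sum
= N × Σ lengths); midpoint coverage adds N at the midpoint bp only
(sum = N × fragment count). Length bins are inclusive on both endpoints, so
the 0–60 bin admits everything the 35 bp read floor lets through.

V-plots count fragment midpoints by (strand-oriented offset from anchor) ×
(fragment length); a fragment is counted once per anchor whose ±`max_offset`
window contains its midpoint (anchor-centric convention, so closely spaced
dyads can each count one fragment). Negating all anchor strands reflects the
offset axis exactly, and the column sums over lengths reproduce the
un-normalized midpoint metagene — both are enforced by tests. Defaults
(`max_offset` 500 bp, profile flank 1000 bp) are config-exposed.

Metagene profiles average normalized coverage *across anchors* (equal gene
weighting) rather than pooling fragments; with the per-library N the two
differ only when anchors are dropped at chromosome edges. Occupancy heatmaps
hold one unsmoothed row per gene (genes aligned at the +1 dyad, ranked by
length descending); difference matrices are elementwise mutant − wild-type.

To compare conditions without fragment-length-composition artifacts,
`match_length_distributions` subsamples every sample to the per-length
minimum count across samples, uniformly without replacement and
seed-deterministically. This is the strongest reproducible reading of
"similar length distributions": output histograms are exactly equal.

## Rotational-position shift statistic

Rotational positions are the 11 offsets {−50, −40, …, +50} bp around each
dyad. A 10 bp step matches the helical periodicity of alternative nucleosome
placements; occupancy at each position is collected with a ±2 bp halfwidth
to tolerate digestion jitter in the midpoints. Per (gene, nucleosome index)
the 11-vector of midpoint coverage (from the length bin of interest, e.g.
142–152 bp) is standardized to Z-scores with the population SD;
zero-variance rows map to zeros. Z-scores are invariant to depth
normalization and to per-locus scaling, which is why they are the right
currency for cross-condition comparison.

ΔZ = Z_mutant − Z_wildtype per gene. Per (nucleosome index, rotational
position), the effect size is the median ΔZ across genes and the p-value a
two-sided Wilcoxon rank-sum comparing mutant vs. wild-type Z values across
genes — a rank-sum between conditions, not a signed-rank on ΔZ, with ΔZ
retained as the effect size. Benjamini–Hochberg correction spans all
(index, position) cells of one mutant-vs-wild-type comparison, with
significance at adjusted p < 0.05 (both α and the per-index gene-count
floor, default 10, are arguments). Genes contribute to a nucleosome index
only if they have a dyad of that index, so long genes dominate high indices
by construction — which is why results are reported per length quartile.
The test can be run pooled or per quartile; both modes are provided.

Stratification ranks genes ascending (Q1 = shortest / least expressed) and
splits into k contiguous equal groups (±1), ties broken by gene id so the
assignment is permutation-invariant. Expression scores sum per-bp
nascent-transcription counts over the strand-oriented window
[TSS+100, TSS+200] inclusive (101 bp).

## Enrichment

log2 enrichment of a gene group in a quartile is
log2((|g∩q|/|g|) / (|q|/|u|)); zero overlap yields a −inf sentinel with the
exact depletion p. Both one-sided hypergeometric tails are always reported
(the choice between one- and two-sided conventions is left to the caller);
`p` is the tail matching the enrichment sign. The universe is the gene set
eligible for both the grouping and the stratification (their intersection),
logged explicitly. A labeling utility groups genes by their pattern of
significant calls across comparisons, pooling patterns with fewer than 20
genes as "other"; producing the calls (differential expression) is out of
scope.

## The synthetic digestion model

The generator defines the study conditions for all statistical checks.

**Genome.** Genes are packed ~50 per chromosome with 300 bp gaps; lengths
are log-normal (median ≈ 1.8 kb, σ_log = 0.65, clipped to 0.5–8 kb) so
length quartiles are non-degenerate; strands are random. Each gene has its
+1 dyad 60 bp downstream of the TSS, further dyads one spacing (default
165 bp) apart up to +10 as gene length allows, a −1 dyad upstream, and an
NDR (default 140 bp) between the −1 and +1 nucleosome edges holding 1–3
short protein footprints (20–50 bp wide, random weights).

**Fragment classes.** Fragments are drawn from a mixture with default
weights nucleosome 0.55, hexasome 0.15, tetrasome 0.08, NDR-short 0.10,
background 0.12 — nucleosome-dominated, with enough short-footprint mass
that the NDR peak stands clearly above background, as in real libraries.
Nucleosome lengths are Normal(147, 3) clipped to [142, 152] at high dose
(Normal(147, 5) clipped to [137, 157] at low dose). Hexasome lengths are
uniform in 102–112 or 83–93 (equal odds), tetrasomes 61–71; their midpoints
are displaced ±(147−len)/2 from the dyad with equal probability of
proximal/distal dimer loss, which reproduces the broader rotational spread
of subnucleosome midpoints. NDR-short fragments (20–60 bp) sit on the
footprints; background fragments (35–170 bp) are uniform genome-wide.

**Rotational positions.** Nucleosome/hexasome/tetrasome midpoints occupy
offsets at 10 bp steps in [−30, +30] with relative weights 2^−|k| for the
k-th step — the number of occupied steps and the decay are not
biologically pinned down, so ±3 steps (keeping all mass inside the ±50 bp
analysis window) with geometric decay is used and exposed as
`rotational_decay`.

**Digestion.** MNase cleaves linker DNA at 25× the per-bp rate of
nucleosome-protected DNA (`linker_rate_ratio`). Cut-position simulation
samples cuts with exactly that rate contrast over cores (dyad ± 73 bp) vs.
everything else, and the estimator recovers the ratio as
(cuts/bp in linker) / (cuts/bp in core). Fragment ends receive a geometric
"nibble" whose mean is 0.02 bp per end inside protected cores at high dose,
×10 at low dose, and ×`linker_rate_ratio` for unprotected background ends.
The in-core mean is deliberately tiny: protected ends sit where the
cleavage rate is 25-fold suppressed, and a sub-0.1 bp mean keeps the
fragment-length mode at the 147 bp the protection defines while still
injecting end heterogeneity. Dose is two discrete levels (32U ↔ low,
128U ↔ high); the contrasts of interest need no continuous dose model.

**Mutant phenotypes.** `ndr_protection_scale` multiplies the emission
probability of NDR-short fragments at high dose; at low dose emission is
`max(scale, 0.9)` — the footprints are fragile, not absent, so gentle
digestion still recovers them. A shift magnitude of m bp at nucleosome
index k moves m/10 of the rotational occupancy one 10 bp step downstream
(strand-aware), scaled by the gene's length-quartile coupling
(Q1 0.3, Q2 0.7, Q3 1.3, Q4 2.0). Presets: `WT` (scale 1, no shifts);
`K192N` (scale 0.05, shifts only at indices ≥ 3, magnitudes 1.0–4.5 bp
growing with index); `141-305` (scale 1, `five_prime_shift_enabled`, shifts
at all indices, magnitudes 1.5–6.0 bp). One seed drives the whole
simulation through a splittable generator with per-class substreams, so
identical inputs give byte-identical output and class counts are
independent of each other's draws.

**What the generator does not emulate.** No sequence (no FASTA/FASTQ, no
aligner, no AT-bias of MNase), no fuzzy inter-gene variation in spacing or
+1 placement, no polynucleosomal/partial-digestion ladder, no fragile −1
nucleosomes beyond the NDR-footprint fragility, and linker cleavage enters
fragment synthesis only through end-nibbling rather than a full
cut-and-ligate model. Passing tests therefore demonstrate that the
statistics recover the phenotypes *encoded in this model* at realistic
depths — not that real libraries are free of the biases listed above.

## Problem sizes and numerical choices

The bundled checks simulate 10⁶ fragments over 240 genes for V-plot and
periodicity recovery, 10⁶ cuts for the cleavage-ratio estimate, 3 × 10⁵
fragments per condition for the NDR dose contrast, and 4 × 10⁵ fragments
per sample over 400 genes for shift-statistic calibration (three
independent null pairs pooled) and power (significant-cell counts
aggregated over five seed pairs) — sizes at which every effect of interest
is comfortably resolved. Peak calling for periodicity uses
`scipy.signal.find_peaks` with a 5%-of-maximum height floor. Degenerate
inputs are handled explicitly: zero-variance occupancy rows → zero Z rows;
dyads within reach of a chromosome edge are dropped and logged; nucleosome
indices below the gene-count floor are skipped with a warning; empty
anchor/gene intersections raise.
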