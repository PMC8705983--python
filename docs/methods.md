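# Methods

This note documents the models, defaults and numerical choices behind
`crossbind`, and what the synthetic validation does and does not
demonstrate.

## Coordinates and data model

All internal coordinates are 0-based, half-open `[start, end)`, the BED
convention; GTF input (1-based, inclusive) is converted on read and back
on write. A peak's representative point is its summit when the input
provides one (narrowPeak column 10), else the floor of its midpoint — a
deterministic stand-in for summit-less peak callers. Gene models are
single-isoform: one body, one TSS (body start on `+`, `end − 1` on `-`),
sorted non-overlapping exons, optional UTR interval lists.

## Location classification and gene association

The promoter window is the strand-aware closed interval
[TSS − 1000, TSS + 10] plus the 5′ UTR; the distal-enhancer class is
[TSS − 2000, TSS − 1000) plus the 3′ UTR plus a 1 kb window past the gene
3′ end (the size of "downstream" is our choice; only its existence is
standard). The −1000 boundary belongs to the promoter, +10 is inclusive.
Intron and exonic ("other") labels apply inside the body; everything else
is intergenic. When several genes' windows cover a point, the label with
the highest priority wins (promoter > distal enhancer > intron > other >
intergenic); among genes tied at that priority, the nearest TSS, then the
lexicographically smallest gene id. These tie-breaks make the
classification a pure function of the input.

Association is deliberately multi-gene: a peak joins every gene whose
flank-extended body (defaults: 2 kb upstream, 1 kb downstream) contains
its point — a regulatory element may serve several genes — and only falls
back to the single nearest TSS within 10 kb when no extended body
contains it. Whether the original analyses used overlap, nearest-TSS or
annotator defaults is not documented; these defaults are an explicit,
configurable stand-in, and every test that depends on association
tolerance goes through them.

## The 2 kb co-binding rule

Distance between cross-tissue peaks is edge-to-edge (overlap = 0);
midpoint distance is available as an option. Pairing is one-to-one.
The default matcher is greedy by increasing distance, which is
deterministic and, at realistic densities (peaks of one gene separated by
> 2 kb), identical to the optimal matching. Exhaustive-oracle testing
shows greedy can miss the maximum-cardinality matching on dense pile-ups
(several peaks of both tissues within a couple of kilobases), so
`method="optimal"` (Hungarian assignment with an infeasible-pair penalty)
is provided; the test suite pins the optimal method to a brute-force
enumeration oracle on instances of up to ~15 peaks.

## Occupancy matrix, correlation, PCA

Read-count differential analysis is out of scope; in its place a binary
(or score-valued) occupancy matrix over consensus regions (the merged
union of all peak sets) supports the qualitative sample-similarity surface:
Pearson correlations (zero-variance columns give NaN, not 0) and a PCA of
samples with sign fixed by making each component's largest-magnitude
loading positive. This is a declared surrogate — adequate for "replicates
cluster, tissues separate", not for affinity-based differential binding
statistics.

## Motif scanning, enrichment, discovery

PWMs are per-position probabilities with an explicit background
(uniform by default). Scanning scores log₂-odds on both strands;
reverse-strand hits are reported in forward coordinates; windows
containing N are skipped.

The default hit threshold is 70% of the PWM's maximum achievable score.
At 60% — the more common folklore default — an 8-column AT-rich motif on
an AT-rich background (the biological regime here: Hox motifs in a
~60% AT genome) produces chance hits in most 150–400 bp regions, which
saturates sequence-level 2×2 tables and destroys the power of
presence/absence enrichment; measured on the generator's background, 70%
brings the chance rate to ~0.15 per region while still detecting ~⅔ of
planted instances. The threshold is exposed as configuration everywhere.

Enrichment uses AME's unit: a sequence either has ≥ 1 hit or not.
Foreground is tested against a dinucleotide-preserving (Altschul–Erickson
Euler-path) shuffle of itself with a one-sided Fisher exact test and
Bonferroni correction across the motif set (Bonferroni rather than FDR,
matching the original analysis' correction). Non-significant motifs are
flagged not-enriched rather than dropped.

Discovery is a declared algorithm of this package, STREME-like in spirit
but not a re-implementation: every canonical k-mer (k = 6…10, collapsed
with its reverse complement) is scored by the hypergeometric tail of its
sequence-level foreground/background occurrence, Bonferroni-adjusted by
the number of candidate seeds; the best seed's foreground occurrences
within one mismatch are aligned into a PWM (pseudocount 0.5), flanking
columns are appended while their information content is ≥ 0.3 bits (up to
4 per side), occurrences are masked with N, and the search repeats until
the requested number of motifs or loss of significance. Foregrounds of
fewer than 10 sequences are refused as underpowered. The algorithm is
fully deterministic; its `seed` parameter exists for interface stability.

Built-in motif stand-ins: the classical Hox-like PWM realizes the
canonical core T(A/T)AT(T/G)(A/G) (consensus TTAATGAA) with sharp core
columns (0.95) and moderately constrained flanks (0.85); a divergent
AT-rich variant (consensus TACTTTGA) models the non-canonical
tissue-specific motif and was checked not to cross-react with the
classical scanner (its planted sequences hit the classical PWM at the
background chance rate). The original study's exact matrices are not
published; user-supplied MEME-minimal files replace the stand-ins for
real analyses, and the MEME reader/writer round-trips through
`Bio.motifs` in the tests.

## Affinity model

Free-energy occupancy models (NRLB-style) are replaced by a PSAM product
model: entries in (0, 1] with column maxima exactly 1, window affinity =
product of entries, so consensus = 1 and the model is monotone in
mismatches. The PSAM is an input (MEME file via column-max normalization,
or 4-column TSV); nothing is fitted. Default aggregation is the best
single window over both strands (`max`); `sum` gives occupancy-style
totals. Rank comparisons use the Wilcoxon rank-sum test: exact
enumeration when the pooled sample is ≤ 20 without ties, midrank /
tie-corrected normal approximation otherwise; all-constant inputs report
p = 1 rather than erroring. Stars follow the p < 0.05 (`*`) and
p < 0.001 (`***`) convention.

## Chromatin-mark classes

"Covered with a mark" is binarized at a coverage fraction of 0.25 of the
peak length — the original criterion (any-overlap vs fraction) is not
documented, so the cutoff is explicit configuration. The four cross-tissue
classes are a pure function of the four (mark, tissue) booleans for a
focal-tissue-specific peak; peaks with both marks (bivalent) or neither in
the focal tissue go to a separate `unclassified` bucket rather than being
double-counted. Tracks are interval BEDs; signal-level (bigWig) analysis
is out of scope.

## Synthetic-data generator

The generator emits a toy genome (4 chromosomes × 22 Mb by default),
2000 non-overlapping multi-exon genes, two tissue peak sets, embedded
motif instances, four mark tracks, and a JSON truth manifest recording
every planted fact. Defaults are the study conditions: gene categories
35% common / 29% tissue-A-specific / 36% tissue-B-specific; 10% of common
genes single-bound (both tissues, promoter peaks) and the rest
multi-bound in enhancer regions; specific genes single-bound with
probability 0.375 (70% promoter / 30% distal); a shared-pair fraction of
0.25 among common-gene enhancer peaks (≈ 75% tissue-specific); classical
motif planted in 70% of B-only and shared peaks, the divergent variant in
70% of A-only peaks; mark classes split 50/50 between active and
repressed with the asymmetric cross-tissue pattern (A-active → shared
acetylation, A-repressed → focal-only methylation, and the inverse for
B); background composition A/C/G/T = 0.3/0.2/0.2/0.3 (AT-rich, to stress
AT-rich motif discovery).

Geometry guarantees coherence of the planted truth: enhancer peaks are
placed into per-gene "slots" (the central 3 kb of introns wide enough to
leave > 1 kb margins, plus one upstream intergenic slot 2.5–5.5 kb from
the TSS), so peaks in different slots are always > 2 kb apart and a
planted shared pair (edge gap < 2 kb inside one slot) is exactly what the
2 kb rule recovers; inter-gene gaps of 13.4–16 kb keep neighboring genes'
windows and slots from interacting. Intron widths (5.8–6.4 kb) are wider
than typical *Drosophila* introns for this reason — the geometry serves
identifiability, not realism. Per-gene peak counts are clamped to slot
capacity *before* shared pairs are drawn so the realized shared fraction
stays at its configured value; the manifest records realized counts, and
all recovery tests compare against the manifest, not the nominal config.
Planted motif instances are drawn from the PWM but resampled until they
score ≥ 60% of the maximum log-odds — a planted site should be a
functional site, not a low-probability outlier. Mark intervals coincide
exactly with their peaks (coverage 1), making mark-class recovery exact
by construction.

What passing the recovery tests shows: the pipeline's interval
arithmetic, categorization, matching, scanning, statistics and
classification are correct and coherent end-to-end against known truth.
What it does not show: robustness to real-data features the generator
omits — replicate noise, signal-shaped peaks with uncertain boundaries,
overlapping transcripts and isoforms, repeat-driven sequence composition,
partial mark coverage, and peak-caller artifacts.

## Problem sizes and determinism

The default study is 2000 genes (~6–7 k peaks per run); the discovery
recovery and null-control experiments use 20 runs of a 260-gene
configuration and 200-sequence null sets respectively, sizes at which the
planted effects are comfortably detectable while a full validation run of
the package stays around a minute. Every stochastic step (genome,
placements, plants, shuffles) flows from a single integer seed through
one `numpy` Generator, and identical (config, seed) pairs produce
byte-identical fixture trees; run configs and reports carry a config hash
for provenance.

## Known limitations

* Single gene model per gene; no isoform-aware promoter/UTR logic.
* Occupancy matrix is binary/score-based; no read-count normalization or
  replicate-aware differential statistics.
* Discovery ranks seeds by sequence-level presence only (no positional or
  site-count statistics) and refines by a single mismatch radius.
* The PSAM model has no chemical potential, cooperativity or multi-site
  saturation; scores are relative affinities, not occupancies.
* Mark classification is interval-based; graded signal is not modeled.
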