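# crossbind

Comparative analysis of one transcription factor's ChIP-seq binding across
two tissues. The motivating biology is Hox-style regulation: a single TF
(e.g. Ultrabithorax in *Drosophila*) binds largely different chromatin
sites in, say, mesodermal and neuronal cells, and the differences show up
at every level — which genes are bound, how many peaks a gene carries,
whether a binding event at a shared gene is tissue-specific or not, which
sequence motifs underlie the peaks, how strong the predicted binding
affinity is, and how the surrounding chromatin (H3K27ac / H3K27me3) is
marked in each tissue. `crossbind` packages that whole comparison as a
tested, reusable pipeline, together with a synthetic-data generator that
plants known structure so every step can be validated against ground
truth.

Intended users: genomicists with two peak sets (BED/narrowPeak), a gene
annotation (GTF), a genome (FASTA) and optionally histone-mark interval
tracks per tissue, who want the cross-tissue occupancy comparison without
assembling a dozen one-off scripts.

## What it computes

**Peak annotation.** Each peak is reduced to a representative point
(summit if present, else midpoint) and classified relative to gene models:
promoter = [TSS − 1000, TSS + 10] ∪ 5′ UTR; distal enhancer =
[TSS − 2000, TSS − 1000) ∪ 3′ UTR ∪ 1 kb downstream; intron; other
(exonic); intergenic. Peaks associate with every gene whose flank-extended
body (2 kb upstream / 1 kb downstream) contains the point, else with the
nearest TSS within 10 kb.

**Cross-tissue categories.** Genes bound in both tissues are *common*;
the rest are tissue-specific. Per gene and tissue, the peak count gives
*singlePeak* vs *multiPeak* classes. Enhancer-class peaks (intron,
intergenic, distal) of common genes are subdivided: cross-tissue peaks
within 2 kb edge-to-edge are matched one-to-one into *shared_2kb*
elements; the remainder are *A_only* / *B_only*. A binary occupancy matrix
over consensus regions supports sample correlation and PCA.

**Motifs.** PWM scanning uses log-odds scores `Σⱼ log₂(p_j(b)/π(b))` on
both strands with a threshold at 70% of the maximum achievable score.
Enrichment is AME-style: per motif, a one-sided Fisher exact test on the
2×2 table of sequences with/without a hit in foreground vs a
dinucleotide-preserving shuffled background, Bonferroni-corrected across
the motif set. De novo discovery is a k-mer-seeded STREME-style algorithm:
exhaustive seed scoring by Fisher p of sequence-level occurrence
(k = 6…10, both strands), PWM refinement from within-1-mismatch
occurrences, flank extension by information content, masking, iteration.

**Affinity.** A position-specific affinity matrix (PSAM; column maxima 1)
scores a window as the product of its per-position relative affinities, so
the consensus scores exactly 1 and substitutions multiply in penalties.
Per-region scores (best window, both strands) are compared between peak
categories with Wilcoxon rank-sum tests (exact for small samples,
tie-corrected normal otherwise; `*` p < 0.05, `***` p < 0.001).

**Chromatin marks.** Per tissue-specific peak, coverage fractions by
H3K27ac and H3K27me3 intervals in both tissues are binarized at 25% and
combined into four classes: `active_shared`, `active_focal_only`,
`repressed_shared`, `repressed_focal_only` (bivalent or unmarked peaks are
reported `unclassified`).

## Worked example

```python
from crossbind.simulate import SimulationConfig, simulate
from crossbind.pipeline import analyze_simulation
from crossbind.compare import category_percentages, tissue_specific_fraction

cfg = SimulationConfig(seed=1, n_genes=400, n_chromosomes=2,
                       chromosome_length=9_000_000)
sim = simulate(cfg)                  # genome + peaks + motifs + marks
result = analyze_simulation(sim)     # annotate, categorize, subdivide

counts = result["categories"]["category"].value_counts().to_dict()
print("bound genes per category:", counts)
print("percentages:", category_percentages(counts))
frac = tissue_specific_fraction(result["subdivision"])
print(f"tissue-specific fraction of common-gene enhancer peaks: {frac:.2f}")
```

prints

```
bound genes per category: {'neuronal_specific': 144, 'common': 130, 'mesoderm_specific': 126}
percentages: {'neuronal_specific': 36, 'common': 33, 'mesoderm_specific': 32}
tissue-specific fraction of common-gene enhancer peaks: 0.73
```

i.e. roughly a third of bound genes are shared between the tissues, and
~75% of the enhancer-class binding events at those shared genes are still
specific to one tissue — binding to the same gene does not mean binding to
the same element. The generator planted exactly this structure
(35/29/36 gene split, shared-pair fraction 0.25), and the manifest in the
fixture directory records every planted fact for comparison.

The same analysis runs from the shell on real files:

```bash
crossbind simulate --seed 1 --out demo/          # or bring your own BED/GTF/FASTA
crossbind run-all --config demo/run_config.yaml  # writes TSV/BED tables + summary.json
```

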