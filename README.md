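# episcan

Detect genomic regions whose chromatin-state behaviour across a collection
of epigenomes tracks a classification of those samples — cancer vs. healthy,
brain vs. other tissues, fetal vs. adult — and interpret them through gene
overlap and GO enrichment.

## Who this is for

Epigenomics consortia (Roadmap, ENCODE, BLUEPRINT) publish ChromHMM-style
chromatin-state segmentations: per sample, every 200 bp of the genome
carries one of 15 discrete states ("TssA", "Tx", "Enh", "Quies", ...).
`episcan` is for anyone holding such multi-sample segmentations plus a
grouping of the samples, who wants the genomic windows where the states
*co-vary with the grouping* — candidate functional regions for the
phenomenon behind the classification.

## The statistic

For each window `i` the per-sample collapsed states form a categorical
profile `S_i` (one entry per epigenome; the state covering ≥ 80% of the
window, else `undefined`). Against the group vector `G` the score is the
mutual information

    MI(G : S_i) = Σ_k Σ_l P(G_k, S_il) · log2( P(G_k, S_il) / (P(G_k) · P(S_il)) )

in bits, with undefined samples removed before any frequency is computed
and zero-probability terms skipped. Significance comes from a
composition-preserving permutation null — the profile vector is shuffled
(default 10,000×) against the fixed classification, and the empirical
p-value is the fraction of shuffles with MI ≥ the observed score — followed
by Benjamini–Hochberg FDR control across all scanned windows. The default
reporting filter keeps windows with MI ≥ 0.3 and adjusted p ≤ 1e-4.

Downstream, each detected window is summarized by its per-group majority
state ("transcription in group A / heterochromatin in group B"), overlapping
genes are retrieved (≥ 1 bp, strand-agnostic), and the gene set is tested
for GO-term over-representation with one-sided Fisher exact tests against
the genome background.

## Worked example

Simulate a small study — 2 × 1 Mb chromosomes, two groups of 10 epigenomes,
10 planted windows where group A is transcribed and group B
heterochromatized — then scan it:

```
episcan simulate --out-dir demo --seed 7 --n-planted 10
episcan scan --states-dir demo/states --classification demo/classification.tsv \
    --chrom-sizes demo/chrom.sizes --vocab 5 --seed 7 --out demo/run
```

```
10:29:16 INFO scanning 2 chromosomes, 20 samples, 10000 permutations/window
10:29:26 INFO 400 windows scanned, 10 significant
```

`demo/run.results.tsv` holds one row per window (MI, raw and BH-adjusted
p-value, defined-sample count, per-sample states); `demo/run.significant.bed`
holds the 10 surviving windows — here exactly the planted ones, each with
MI = 1.0 (a perfect split of two equal groups carries H(G) = 1 bit) and
adjusted p = 0.0. The same library calls are available in Python
(`episcan.scan`, `episcan.filter_significant`, `episcan.truth_eval`).

Continue to patterns, genes and enrichment:

```
episcan patterns --results demo/run.results.tsv \
    --classification demo/classification.tsv --out demo/patterns.tsv
episcan annotate --windows demo/run.significant.bed \
    --genes demo/genes.gff3 --out demo/genes.tsv
episcan enrich --genes demo/genes.tsv --annotation demo/genes.gff3 \
    --gene2term demo/gene2term.tsv --out demo/enrichment.tsv
```

`demo/patterns.tsv` reports a single change pattern —
`transcription  heterochromatin  10  1.0` — and `demo/enrichment.tsv` ranks
the planted "brain development" term first (k = 10 of its 10 genes in the
study set). `episcan downsample-eval` reruns the whole pipeline under
increasing random sample removal and tabulates how the positive-term
enrichment (−log10 p) degrades.

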