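# Methods

## Model and procedure

`episcan` treats a collection of chromatin-state segmentations the way
sequence analysis treats a multiple alignment: samples are rows, genomic
windows are columns, and the question is which columns are differentially
"conserved" with respect to a grouping of the rows. The pipeline:

1. **Windowing.** The genome is tiled with fixed-length windows (default
   5,000 bp, non-overlapping; the step is configurable down to 1 bp for
   sliding scans). Trailing partial windows are dropped so every window has
   the same length and the majority-rule denominator is uniform.
2. **Majority collapse.** Within a window, a sample's state is the one with
   the largest base-pair overlap, accepted only if it reaches
   `min_fraction` (default 0.8) of the covered bases; otherwise the sample
   is `undefined` there. Frequency is base-pair weighted, which reduces to
   segment counting on the 200 bp ChromHMM grid but also handles
   arbitrary-length input segments.
3. **Mutual information.** Undefined samples are removed, all frequencies
   (group marginal, state marginal, joint) are recomputed over the retained
   samples, and MI is evaluated in bits with zero-probability terms
   skipped. MI is 0 when fewer than two samples remain or a marginal is
   degenerate. Because the exclusion happens per window, the group marginal
   is window-specific; with a 5-vs-6 retained split the maximum attainable
   score is H(G) = 0.994 bits, the natural calibration point for a
   perfectly separating window.
4. **Permutation null.** The profile vector — undefined entries included,
   so the vector's composition is exactly preserved — is shuffled against
   the fixed classification (default 10,000 times) and each shuffle's MI is
   recomputed under the same exclusion rule. The empirical p-value is the
   fraction of shuffles with MI greater than or equal to the observed
   score; it can be exactly 0. The conservative (r+1)/(n+1) estimate is
   available via `MIParams(pseudocount=True)`.
5. **FDR.** Benjamini–Hochberg step-up correction is applied once,
   genome-wide, across every scanned window — including windows where all
   samples are undefined (reported with MI 0, raw p 1 and an
   `all_undefined` flag) so the family size equals the window count and
   results are comparable across runs. Reported windows pass both MI ≥ 0.3
   and adjusted p ≤ 1e-4 by default.
6. **Interpretation.** Significant windows are summarized by per-group
   majority states; genes overlapping them by ≥ 1 bp (strand-agnostic,
   half-open arithmetic) are collected along with per-gene window counts;
   the gene set is tested per GO term with a one-sided hypergeometric tail
   (Fisher over-representation) against the full annotation as background,
   BH-corrected within each namespace, after propagating gene–term
   annotations to all is_a ancestors.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window_length` / `step` | 5,000 / 5,000 bp | scan resolution; non-overlapping tiles by default |
| `min_fraction` | 0.8 | majority threshold for the per-sample collapse |
| `n_permutations` | 10,000 | permutation-null depth; the smallest nonzero p is 1/n |
| `mi_threshold` | 0.3 bits | effect-size floor for reporting |
| `fdr_threshold` | 1e-4 | BH-adjusted p ceiling for reporting |
| `seed` | — | master seed; per-window generators derive from (seed, chrom, start) |

Per-window generators make results independent of iteration order and safe
to parallelize; permutations are drawn independently per window.

## Vocabularies and reductions

The 15 Roadmap mnemonics ship with the package, together with editable
15→5 and 15→2 reduction tables (`episcan/data/`). The 5-state grouping
(tss / transcription / enhancer / bivalent / heterochromatin) and the
binary active/inactive split follow the conventional functional reading of
the 15-state model; published analyses that used reduced vocabularies did
not print their exact maps, so these tables are documented approximations
that users can replace with two-column files of their own.

## Synthetic data: what it emulates, what it does not

The generator draws each 200 bp segment independently from a background
state distribution (default for the 5-state vocabulary: 60%
heterochromatin, 10% each of the others) and overwrites planted windows
with group-correlated states: each sample of group *g* receives the group's
target state with probability `strength`, a random other state otherwise,
and with probability `undefined_rate` an alternating two-state fill that is
guaranteed to fail the 80% rule. A matched toy annotation (one gene per
planted window, background genes, one keyword-bearing "positive" GO term
holding exactly the planted genes) makes the annotation/enrichment/
downsampling stages testable end to end.

Real chromatin is strongly autocorrelated along the genome; independent
segments are not. One consequence is that under the default background
most background windows collapse to `undefined` for most samples, whereas
real segmentations yield long coherent quiescent domains. Passing tests on
this generator therefore demonstrate the statistical machinery (majority
rule, MI, null, FDR, truth recovery), not realism of background structure,
spatial correlation of detections, or the behaviour of the scan under
biological confounding (batch, tissue composition).

A statistical property of the scaled-down benchmark worth knowing: with
two groups of 10, a perfectly separating window's profile can be re-created
by chance in 2/C(20,10) ≈ 1.1e-5 of shuffles, so at 10,000 permutations
roughly one planted window in ten collects a single null hit (empirical
p = 1e-4), which genome-wide BH then places above an FDR cutoff of 1e-4.
This is intrinsic to the r/n convention at this group size — with the
group sizes of real consortium datasets (e.g. 10 vs 65) the corresponding
probability is below 1e-11 and perfect windows report p = 0 essentially
surely. Benchmarks demanding exact sensitivity 1.0 at 10-vs-10 should
expect ~0.9 per dataset instead.

## Numerical choices and degenerate inputs

- MI is computed from integer joint-count tables in a single vectorized
  pass over all permutations; tiny negative totals from floating point are
  clipped to 0, and the "null ≥ observed" comparison uses a 1e-12 guard so
  bit-identical arrangements always count.
- Ties: a tied top state in the majority collapse yields `undefined`
  (reachable only when `min_fraction` ≤ 0.5); a tied per-group majority in
  pattern summaries likewise yields `undefined`, and windows with any
  undefined group entry are excluded from the pattern distribution (both
  numerator and denominator).
- Coverage gaps: if intervals cover less than `min_fraction` of a window,
  the sample is `undefined` there; otherwise uncovered bases are excluded
  from the frequency denominator.
- BH is delegated to statsmodels (`fdr_bh`); Fisher tails to
  `scipy.stats.hypergeom.sf`. Empty p-vectors, single-term families and
  p = 0 inputs are handled explicitly.
- Coordinates are 0-based half-open everywhere; GFF3/GTF input is shifted
  from 1-based on read (via pyranges) and shifted back on any GFF output.

## Downsampling evaluation

Samples are removed uniformly at random (not stratified), so extreme
fractions can eliminate an entire group; such replicates are recorded as
"no result" and excluded from means, mirroring how small groups vanish in
practice. Performance per replicate is the mean of −log10 enrichment p over
keyword-matched positive terms (the best single term is also reported;
averaging across matched terms was an open choice and both summaries are
emitted). With no matched term — in particular when no window is
significant and the study set is empty, where every term's p is 1 — the
performance is 0.

## Problem sizes

The bundled benchmark uses 2 chromosomes × 1 Mb at 200 bp segments,
20 samples, 400 windows of 5 kb and 10,000 permutations per window (a scan
takes seconds); the downsampling experiment repeats that pipeline per
fraction × replicate. All sizes are configurable, and runtime scales
linearly in windows × permutations × samples.

## Known limitations

- The analytic (e.g. χ²) approximation to MI significance is deliberately
  absent; only the permutation null is offered.
- topGO-style elim/weight decorrelation of the GO graph is not
  implemented; the per-term independent ("classic") Fisher test is.
- The generator does not model HMM-like state autocorrelation, copy-number
  structure or assembly gaps.
- Window lengths below 200 bp are rejected; sliding steps smaller than the
  window length are supported but multiply the multiple-testing family.
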