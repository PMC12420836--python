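# Methods

This note documents the models, conventions and parameter choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want recorded.

## Coordinates and overlap semantics

All intervals are 0-based, half-open (BED convention); 1-based dialects are
converted at the reader boundary. Two overlap predicates coexist because
the analyses use both:

* **strict overlap** — at least one shared base pair; used when
  intersecting TE copies with DMRs to define targets.
* **maxgap overlap** — `gap = max(0, max(starts) − min(ends)) ≤ maxgap`,
  so overlapping *or touching* intervals have gap 0. The four-way chromatin
  classification defaults to maxgap 0; TF-peak/target summaries (the
  NRF1-style analysis) default to maxgap 750 bp. Both are flags.

The production path is a per-chromosome sorted-array sweep; the test suite
keeps the O(n·m) all-pairs computation as the reference oracle.

## Target definition

A DNMT3C target is a TE copy that (a) overlaps ≥ 1 DMR by ≥ 1 bp and
(b) passes a class-specific length filter: LINE (L1) copies strictly
longer than 5000 bp, LTR copies strictly longer than 500 bp ("longer than"
read as strict inequality; both thresholds configurable). SINE and other
classes are never targets. A copy hit by several DMRs is one target with
its supporting DMRs recorded. The "high-confidence" filter removes TE
copies overlapping annotated genes by any amount; it is applied by default
only at the motif-enrichment stage (where gene-derived sequence would
confound the background) and is available as a flag for classification.

## Chromatin classification

Co-occupancy is judged at the target: a target overlapped by ≥ 1 H3K4me3
peak *and* ≥ 1 H3K27me3 peak is likely bivalent even if the two peaks do
not touch each other. Whole-element overlap is used; an optional 5′-window
restriction exists for promoter-focused analyses. The two peak sets must
come from the same condition unless explicitly overridden. Category
composition tables report percentages per family/class within each
category; within every non-empty category they sum to 100.

## Coverage and profiles

RPGC normalization scales a track so the genome-wide mean per-base coverage
is 1×; for fragment counts the factor is `G / (n·L)` with `G` the effective
genome size, `n` fragments of mean length `L`. Multimapping fragments are
assigned to exactly one uniformly chosen candidate location (seeded), and
duplicates are retained. Profile matrices are centered on the target
midpoint by default (a 5′-anchor mode exists), with bins of `binsize` bp
across ±`flank`; minus-strand rows are reversed by default because TE
promoter orientation matters. Bins beyond chromosome ends are zero-filled
and the row flagged; targets on chromosomes absent from the track are
skipped and counted. Heatmap rows are ordered by descending row mean, and
that choice is recorded in the output metadata.

## TE expression

TPM per sample: `rate_i = count_i / length_i`, `TPM_i = 10^6 rate_i / Σ rates`;
all-zero samples stay all-zero rather than NaN. Logs are base 10 (flag to
change): a zero TPM maps to the sentinel −10, which reads naturally on a
log10 axis and keeps silent loci in plotted distributions. Stage z-scores
standardize per-stage means of log TPM against the mean and *population* SD
of those stage means (an alternative standardizes against all per-sample
values); constant rows score 0 at every stage. Grouping is by family by
default, subfamily optionally. Category-stratified comparisons use Welch's
unequal-variance unpaired t test by default (pooled-variance Student mode
available), with sentinel-floored zeros included since the plotted
distributions include them (a flag excludes them); groups under 2 loci are
skipped with a recorded reason.

## Differential TE enrichment

One in-house test serves both the RNA and the chromatin-profiling
enrichment contrasts; the statistical contract is: negative-binomial model,
TMM normalization, BH correction, calls at adjusted p < 0.01.

* **TMM factors** follow the published weighted trimmed mean of M-values:
  reference column by upper-quartile proximity, rows positive in both
  columns, 30% two-sided trim on M and 5% on A, inverse-delta-method-variance
  weights, factors rescaled to geometric mean exactly 1. The implementation
  reproduces edgeR's `calcNormFactors` to ≤ 1e-8 on a frozen reference
  matrix in the test suite.
* **Dispersion** is a method-of-moments common value on library-size-
  equalized pseudo-counts: per-row `α = (v − m)/m²` from pooled
  within-group moments, averaged over informative rows, clipped at ≥ 0
  (floor 1e-8). A fixed dispersion can be supplied.
* **The exact test** conditions the two group sums of pseudo-counts on
  their total (sums of n replicates are NB with size n/α) and doubles the
  smaller conditional tail. Enumeration covers a ±40 SD window around the
  conditional mode; totals whose window would exceed 1e5 outcomes use a
  Gaussian conditional tail instead, which is indistinguishable at those
  counts. Group sums are rounded consistently so the test is exactly
  symmetric under group swap.
* **Fold changes** use a prior of 0.5 counts per million of library depth
  (so log2FC is invariant under rescaling all counts); logCPM uses a prior
  count of 2, keeping zero rows finite. Each contrast is BH-adjusted over
  all tested subfamilies.

The exact-test variant (rather than a GLM) is a deliberate simplification:
for two-group contrasts it is the canonical small-sample NB test, and on
identical single-row simulations it tracks the reference implementation's
power within Monte-Carlo error. Power statements in the tests are made at
the generator's study conditions, where a subfamily aggregates ~40 member
loci each at mean 200, dispersion 0.1, 3 vs 3 replicates — there a planted
4-fold subfamily is recovered essentially always.

## Methyl-sensitive TF discovery

* **Scrambled baits** preserve length, base composition and the *exact* CpG
  position set while shuffling everything else. Because a pinned CpG's C/G
  can never form a new CpG with a shuffled neighbour, spurious CpGs arise
  only between two adjacent shuffled positions; the scrambler therefore
  shuffles once and repairs each spurious CpG by swapping one member with a
  random shuffled position (composition unchanged), within a bounded
  budget. A pure resample-until-clean scheme is astronomically unlikely to
  terminate on GC-rich promoters (~e^−15 acceptance per attempt at 250 bp),
  which is why local repair is the default; the contract (length,
  composition, CpG positions) is asserted on every call in the tests.
* **In-silico methylation** flips the bait flag and records one methylation
  value per CpG; it is idempotent with a warning.
* **Pulldown enrichment** takes four intensity tables (bait/scrambled ×
  unmethylated/methylated), log2-transforms, and runs Welch t per protein
  on the unmethylated-vs-methylated contrast of bait and scrambled
  separately. "Enriched" means log2FC ≥ 1 and p < 0.05 (both thresholds
  config-exposed and printed in output headers; no canonical values exist).
  `methyl_sensitive` = enriched (positive direction) on the bait contrast;
  `sequence_specific` = methyl-sensitive *and not* enriched on the
  scrambled contrast. Proteins with < 2 finite replicates in any condition
  are skipped with a reason; missing intensities are treated as absent, not
  zero-filled, to avoid fabricating enrichment.
* **Motif enrichment** scans PWMs as log-odds on both strands (background
  from sequence composition by default; threshold 80% of the maximum
  achievable score) and tests, per motif, the 2×2 table of sequences with
  ≥ 1 hit in targets vs background with a one-sided Fisher exact test,
  BH-adjusted across motifs. This replaces a ranked-statistic motif tool
  with the plain hit-count contract ("enriched in targets vs all-TE
  background"); a motif absent everywhere reports NA odds and p = 1.

## The synthetic-data generator

The generator emulates, at desk scale, the inputs of a germline TE study:
a 7 Mb two-chromosome genome; 18 TE subfamilies (six young: L1MdT, L1MdA,
L1MdF, IAPEz-int, IAPLTR1a, MMERVK10C-int; twelve ancient null families
from the L1/ERVL-MaLR/SINE classes) at 20–40 copies each, placed on a
fixed-pitch slot grid so features never collide; 5% consensus divergence;
DMRs over 80% of copies anchored at the 5′ promoter; a fraction of copies
deliberately placed inside genes to exercise the exclusion filter. Planted
chromatin categories are drawn per target from subfamily-specific
probabilities (L1MdT biased bivalent, ERVK biased H3K4me3-marked, ancient
families biased uncategorized); peaks realize them with independent
per-mark dropout and spurious-peak probabilities, which makes the expected
reclassification accuracy analytically computable
(`Π_marks (1−dropout or 1−spurious)` per target, averaged over categories).
Counts are negative binomial with variance `μ + αμ²` (mean 200, α = 0.1
per locus, 3 replicates per condition), with planted knockout log2 fold
changes (ERVK +2, L1MdT +1.5, L1MdA +1), a meiotic-stage boost on L1,
chromatin-category expression multipliers ordered
H3K4me3 (6×) > bivalent (2.5×) > H3K27me3 (0.5×) > uncategorized (0.3×),
a per-locus log-normal baseline (SD 0.3), and a mean-one per-sample ×
subfamily log-normal factor (SD 0.2) representing biological replicate
variability — without it, subfamily aggregation would average dispersion
away and make the differential test unrealistically sensitive to residual
composition bias. The planted motif is the GC-rich palindrome GCGCATGCGC
inserted intact in the promoter window of target copies at a per-subfamily
rate (0.2–0.6) and of non-target copies at a 5% background rate. Pulldown
intensities are log-normal (log2 base N(20, 2), replicate noise SD 0.3)
with planted binders elevated 8-fold on the conditions their class
predicts.

What the generator does *not* emulate: read-level sequencing noise and
mapping ambiguity beyond explicit multi-candidate fragments, realistic TE
sequence evolution (copies are mutated consensus, not phylogenies), peak
width/score heterogeneity, proteome-scale intensity distributions, or
gene-expression programs. Passing tests therefore demonstrate that the
statistical machinery recovers planted truth under the stated noise model,
not that the pipeline is robust to every artifact of real sequencing data.

## Reproducibility

A single seed determines every emitted file byte-for-byte. The pipeline
writes a manifest with the seed, a config hash, per-stage row counts and
SHA-256 of every output; re-running an identical config reproduces
identical hashes. All outputs are plain-text TSV/BED/FASTA/bedGraph.

## Problem sizes

Defaults were chosen so a full synthetic run finishes in seconds on one
core: 700 TE copies, ~160 targets, 18 subfamilies × 12 samples,
2000-row null calibrations and 200-replicate power simulations. All are
config parameters and scale up transparently.

## Known limitations

* The NB exact test uses a common dispersion (optionally fixed); tagwise
  shrinkage is not implemented, so genuinely heteroskedastic subfamily sets
  will be tested at an averaged dispersion.
* TMM residual bias is not zero when a large fraction of subfamilies is
  truly differential (composition bias is only trimmed, not modelled); the
  default scenario keeps a null majority for this reason, as does any real
  genome-wide annotation.
* The scrambler's repair step makes the shuffle conditional-uniform only
  approximately; the preserved-property contract is exact.
* Pulldown classification assumes matched replicate structure across the
  four conditions and log-normal intensities.
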