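# Methods

## Genotype-probability model

Allele read counts `(nRef, nAlt)` at a biallelic SNP are modelled as
independent draws from the true diploid genotype with a symmetric per-base
error rate *e*: a reference homozygote emits a reference base with
probability `1 − e`, a heterozygote emits either allele with probability
0.5 (error is absorbed into the half), and an alternative homozygote
mirrors the reference case. The three likelihoods are scaled to sum to 1;
no allele-frequency prior is applied, so the model is a pure
read-likelihood genotyper. Probabilities are computed in log space and
normalised by max-subtraction, so sites of arbitrary depth cannot
underflow.

*e* defaults to 0.01, a round figure at the conservative end of Illumina
per-base error rates; it enters only through the likelihood ratios, and
calls are insensitive to moderate misspecification. Valid range is
(0, 0.5): at *e* ≥ 0.5 the likelihoods no longer order genotypes
meaningfully.

Calling modes:

* **best-guess** — argmax of the three probabilities; no-call at depth 0
  or on an exact tie of the maxima. Threshold comparisons elsewhere are
  strict (probability must *exceed* 0.90/0.98) so a probability exactly at
  the threshold is a no-call; an argmax tie cannot occur at unequal counts
  for valid *e*, so the tie rule only covers degenerate inputs.
* **p > 0.90 / p > 0.98** — call only when confident. At 1× no genotype
  can pass 0.90 (max probability 0.66), and at 2–3× only heterozygotes
  can, which is why stricter thresholds shrink the called set
  dramatically at low coverage while raising concordance.
* **presence/absence** — heterozygote if both alleles have read support,
  the matching homozygote if only one does. This is exactly best-guess in
  the limit *e* → 0⁺ (verified in the tests at *e* = 1e−9 over all count
  pairs with depth ≤ 12) and is the most hop-sensitive mode, since a
  single hopped read flips a homozygote to a heterozygote.

## Pruning-bias emulator

Local-assembly callers build a read-threading graph per region and prune
paths supported by fewer reads than a threshold (default 2). The reference
haplotype is always present in the graph, so pruning is one-sided: when
the alternative path is pruned, its reads are re-scored against the only
surviving haplotype and counted as reference support. The emulator
reproduces this at the level of counts: if `nAlt < min_pruning`, return
`(nRef + nAlt, 0)`, else return the counts unchanged. Total depth is
preserved, `nRef` never decreases, and the operation is the identity
whenever alternative support meets the threshold.

The strictly-smaller comparison (`nAlt < min_pruning`, not ≤) is the
package's reading of how a threshold of 2 behaves: one supporting read is
pruned, two survive — which is the behaviour that makes a `(2, 1)` site
collapse to `(3, 0)` while `(0, 2)` survives.

At 1× an error-free heterozygote is seen by a single read carrying either
allele with probability ½, so best-guess calls split ~50/50 between the
two homozygotes; with the emulator active, every such site becomes a
reference homozygote. That asymmetric collapse — not extra noise — is the
mechanism by which pruning degrades low-coverage concordance.

## Allele-count extraction

Counts are extracted per site from coordinate-sorted indexed BAMs by
walking the aligned pairs of each overlapping read (pysam). Default
filters: MAPQ ≥ 20, proper pair required, secondary alignments excluded,
duplicate-marked reads excluded, no base-quality floor. Reads showing a
third base, an N, or a deletion at the site contribute nothing; each read
contributes at most one observation per site. Two deliberate choices:

* **Duplicates** are excluded by default. Pipelines that mark duplicates
  intend them to be ignored downstream; the option exists to keep them.
* **Overlapping mates** are both counted by default — the simplest,
  documented contract; `count_fragments=True` collapses to one observation
  per fragment (first mate encountered) for users who prefer
  fragment-level evidence.

Coordinates are 1-based at every interface (VCF convention); the 0-based
arithmetic needed by the BAM layer is internal.

Coverage strata for concordance reporting default to 1×–5× singleton bins
plus a pooled 6–10× bin; depth 0 (necessarily a no-call) and depth > 10
fall outside the strata. At ~2× target coverage essentially no site
exceeds 10×, so the default partition covers the data these tables are
built for.

## Concordance

Genotype concordance is the percentage of called genotypes equal to truth;
allele concordance scores each pair by its shared alleles,
`(2 − |Δdosage|)/2`, so a hom–het mismatch is half right. Pairs where
either side is missing or no-call are excluded from **all** denominators —
both concordances and the confusion columns — which is what lets stricter
calling thresholds raise concordance while shrinking n. The confusion
matrix is column-normalised: entry (called x | true y) is the percentage
of called-x among *called* pairs whose truth is y.

## Index-hopping simulation and estimation

Hopping is injected at the fragment level: each fragment is independently
reassigned with probability *h* to a sample drawn uniformly from the other
n − 1 samples in the multiplex. Fragments hop atomically because both
mates carry the same index pair. Injection conserves the total fragment
count and the per-site read totals across the multiplex.

The estimator emulates the dual-sequencing design: a hop-free
high-coverage read set of the same samples is down-sampled (default
fraction 1/15, i.e. 30× → 2×) **independently for each calibration
level** — so sampling noise is represented in the calibration, not just in
the observed data — then hopping is injected at the grid levels 0, 0.1,
0.5, 1, 2 and 5%. Genotypes are called (presence/absence by default, the
most sensitive mode) and the nine confusion percentages recorded per
level.

Estimation inverts a least-squares fit of response on level at the
observed value. Percentages are fitted with degree 1; ilr transforms with
degree 2, since log-ratios of a composition respond curvilinearly over
this range. Only the six homozygote variables are informative: a hopped
read landing on a heterozygote usually supports an allele already present,
so the heterozygote columns are nearly flat in *h* (fits with R² ≈ 0) and
their inversions are reported but excluded from the headline range. For a
degree-2 inversion the real root inside the calibrated level span is
taken (the smaller if two qualify; the response curves are monotone over
the span, so at most one interior root occurs in practice). Zero or
negative composition parts make the ilr undefined and raise — silently
pseudo-counting would corrupt the calibration; callers who need an escape
hatch can perturb their own inputs explicitly.

The package reports one estimate per variable plus the min–max range over
the homozygote variables rather than a single pooled number: with six to
ten correlated estimates there is no principled pooled variance, and the
range is the honest summary.

## Tailored-reference (alignment bias) assay

The tailored reference substitutes the alternative allele at every site of
a copy of the genome (validated against the declared reference alleles;
duplicate or mismatching sites are rejected; the operation is an exact
involution under ref/alt swap). Reads aligned against both genomes give
two count tables; all tables are kept in **original-reference
orientation** — `nRef` always counts the original genome's reference
allele, also for counts extracted against the tailored genome. This is
the single most error-prone convention in the assay, so count files carry
an explicit orientation header line. Combination modes: REF and ALT pass
one table through; CIS takes each allele's count from the genome carrying
that allele (most favourable alignment); TRANS from the genome carrying
the opposite allele. The bias report compares mean per-allele counts under
the favourable and unfavourable genome, overall and by true genotype, as
`100·(mean_fav − mean_unfav)/mean_fav` — the proportion of an allele's
reads lost when the genome carries the opposite allele. Realignment itself
is delegated to an external aligner; the module's contract starts at the
two BAMs or count tables.

## Synthetic-data generator

The generator provides the statistical structure the analyses assume, and
nothing more:

* genotypes under Hardy–Weinberg from per-site allele frequencies
  (default MAF law: uniform on [0.05, 0.5], mimicking an ascertained
  panel of segregating SNPs);
* per sample–site depth Poisson around the target mean, independent
  across sites — no read-length or mate-overlap structure, since every
  analysis consumes per-site counts; each simulated read covers exactly
  one site;
* symmetric per-base error flipping ref ↔ alt with probability *e*;
* single contig, sites every 100 bp, fixed-layout 41 bp reads, MAPQ 60,
  proper-pair/primary/non-duplicate flags that tests can override.

What it does **not** emulate: alignment failure and mapping-quality
variation, indels, GC and coverage waves, linked sites on one read,
batch effects. Tests passing on this generator therefore demonstrate the
correctness of the counting, calling and estimation machinery under the
stated model — not robustness to real-data artefacts upstream of the
count tables.

Determinism: every simulation entry point takes a seed and uses one
generator per call; the truth seed is recorded on the object so fixture
regeneration is byte-identical.

## Problem sizes and numerical choices

The end-to-end hop-recovery check uses 20 samples × 20,000 sites at 30×
(~12 M fragments), down-sampled at 1/15 per scenario, true *h* = 1.5%,
10 seeds — chosen as the smallest multiplex at which per-variable
inversion noise stays well inside ±0.5 percentage points. Probability
normalisation is tested to 1e−12; regression needs at least degree + 2
distinct levels so R² is meaningful; rank-deficient designs and duplicate
levels are rejected rather than silently fitted.

## Known limitations

* The genotyper has no allele-frequency prior and no per-read base
  qualities in the likelihood; both are deliberate, matching the
  count-based model it implements.
* The pruning emulator operates on counts, not on the caller's actual
  graph; it reproduces the documented low-coverage mechanism, not every
  caller edge case.
* Hop injection reassigns uniformly over other samples; real hopping may
  correlate with index sequence similarity or library concentration.
* The alignment-bias assay trusts the external aligner's BAMs; it cannot
  detect reads the aligner placed at the wrong locus with high MAPQ under
  both genomes.
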