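# Methods

## Overview

`cnvdosage` implements a three-stage analysis of copy-number dosage
effects on transcript expression, plus a synthetic-data generator used to
calibrate the statistics and to test parameter recovery end to end. All
genomic coordinates are 0-based half-open internally; 1-based inclusive
inputs (caller tables, GFF3) are converted once at read time and nowhere
else.

## Consensus validation

Read-depth (RD) calls are the baseline set; split-read (SR) calls are the
validators. Three filters compose in order:

1. **Length window** — calls with length outside [50, 1,000,000] bp are
   discarded, independently per caller. Both bounds are inclusive.
2. **Coverage validation** — baseline call *b* is validated iff a *single*
   validator call *v* of the same CNV type, same animal, same chromosome
   satisfies `v.start ≤ b.start + s` and `v.end ≥ b.end − s` with slack
   s = 100 bp. The slack permits a deficit at each end independently; the
   validator may extend beyond the baseline without bound (coverage, not
   reciprocal overlap). A union-of-validators semantics is available as a
   non-default config switch (`ValidationConfig(union_coverage=True)`),
   because the single-call reading, while the plainer one, is not the only
   defensible interpretation of "fully covered".
3. **Gap exclusion** — a call sharing ≥ 1 bp with any reference-assembly
   gap is removed. Half-open adjacency is not overlap.

Each filter is idempotent, and the validated set is monotone in the slack.
The fast implementation (per-chromosome sorted validators with a prefix
maximum of end positions) is checked exactly against an all-pairs scan in
the test suite. No merging of calls within an animal is performed at any
stage.

## Annotation

Per transcript, the genome is partitioned into `coding` (exonic sequence
of the transcript — not CDS-restricted, since dosage acts at the DNA
level and UTR/CDS status is immaterial to a deletion), `intronic`, and
5000-bp strand-aware `upstream`/`downstream` flanks anchored at the TSS
and TTS, clipped at chromosome boundaries. A CNV receives a region class
for a transcript only if it intersects exactly one of {coding, intronic,
updown}, where updown pools the two flanks; otherwise it is discarded
*for that transcript only*. A CNV touching a flank and the body counts as
multi-region (conservative reading of the discard rule). CNVs touching no
transcript and no flank form the intergenic bucket of the region tallies;
tallies keep upstream and downstream separate.

Percent-of-transcript covered is the union of an animal's classified CNVs
of one type intersected with the transcript body, divided by the genomic
TSS–TTS extent. The genomic (unspliced) denominator is used because the
variants are DNA-level segments; a spliced denominator would mix exonic
and intronic coverage incommensurably.

## Statistics

**Signed-rank statistic.** W = ½Σ r̄(Dᵢ) + n(n+1)/4 with Dᵢ = Yᵢ − Xᵢ
(non-carrier minus carrier mean TPM) and mid-ranks on |Dᵢ|; zero
differences are dropped (n shrinks). This form is algebraically the sum
of positive ranks, which is how the exact null is computed: the
generating function Π(1+z^k)/2ⁿ, evaluated by convolution, for n ≤ 25 and
tie-free |D|; otherwise a normal approximation with tie-corrected
variance and continuity correction. The approximation's one-sided tail
probabilities are within 0.005 of exact at n = 20 (exhaustively
verified); a doubled two-sided p inherits twice that. Tests are two-sided
by default, with the direction reported from the sign of the median
difference; sidedness is a config/CLI option.

**Carrier contrast.** A carrier is an animal with ≥ 1 validated CNV of the
given type classified to the transcript in the given region class.
Transcripts with fewer than 1 or more than 5 carriers out of 6 are
excluded — a 6/6 transcript has no non-carrier mean, and the window keeps
the pairing meaningful. No multiple-testing correction is applied; the
six cells ({deletion, duplication} × {coding, intronic, updown}) are
reported with raw p at α = 0.05.

**Animal-effect control.** From transcripts overlapping no CNV in any
animal, each of 500 repetitions samples 100 transcripts (the count per
repetition is not fixed by the protocol this emulates; 100 gives the
signed-rank test reasonable power without exhausting small pools),
divides the six animals at random into two groups of three — one division
per repetition, shared by all of its transcripts, so a genuine animal
effect shifts every pair coherently — and applies the signed-rank test to
the paired group means. Reported: the full p distribution, the median p,
and the fraction significant at 0.05.

**Spearman / T.** R_S = 1 − 6Σd²/(n(n²−1)) on mid-ranks; with ties the
rank-difference form is replaced by the product-moment correlation of the
rank vectors (identical when tie-free). T = R_S√((n−2)/(1−R_S²)) is
referred to t(n−2); at |R_S| = 1 the permutation-enumeration limit
(1/n! one-sided) is reported instead. The t reference was checked against
10,000 permutation draws by a KS test.

**Lilliefors.** KS distance from the normal CDF with estimated mean/sd;
since that distance is parameter-free under the null, the p-value is
Monte-Carlo (default 10,000 standard-normal samples, seeded), with the
(k+1)/(N+1) convention. The pipeline reports a Lilliefors p (2000 draws)
for each cell's paired differences; their strong non-normality is the
reason the contrasts are tested by ranks rather than a paired t-test.

**Coverage–expression correlation.** Per (animal, CNV type, region class)
cell: transcripts where the focal animal is a carrier and the carrier
count is within the 1–5 window; x = percent covered by the focal animal's
calls, y = carrier mean TPM − non-carrier mean TPM. Cells with n < 3 or
constant ranks are reported as not computable.

## Synthetic cohort

The generator emulates the study design the statistics were built for:
six animals; per-animal deletion counts of order 551–730 and duplication
counts of order 619–693 (expected 640 and 655 at carrier frequency 0.5,
so binomial per-animal counts land in those ranges); deletion lengths
300–530,600 bp and duplication lengths 900–346,200 bp as truncated
log-normals whose means sit near the reported ~3.9 kb and ~12.4 kb. The
length *distribution* inside the printed ranges is not documented
anywhere authoritative; the truncated log-normal is this package's
choice. Each planted locus is carried independently per animal with
frequency 0.5 — chosen a priori because symmetric carrier counts (k and
6−k equally likely) make the null paired-difference distribution an
exactly symmetric mixture, which the signed-rank test's symmetry
assumption requires, and because it exercises the whole 1–5-of-6 window.

70% of loci are placed entirely inside a single region (an exon, intron,
or flank) of a random transcript so single-class annotations dominate;
the rest land uniformly. Exon lengths are log-normal(log 300, 1.0) — the
heavy tail matters, since a duplication (≥ 900 bp) can only be
single-class-coding inside a long exon, and coding duplications are a
prominent feature of the data this emulates.

Caller views: read-depth breakpoints are rounded to a 100-bp grid
(emulating bin-limited resolution), split-read breakpoints get Gaussian
jitter (sd 3 bp), and each caller independently drops true calls (FN 5%)
and injects random calls (FP 5%).

Expression: pre-normalization abundance for transcript i in animal a is
`base_i · exp(−λ·length_i) · animal_a · ε`, with log-normal base
(log-sd 1.5), log-normal noise ε (log-sd 0.5), a small per-animal factor
(log-sd 0.05; it cancels exactly under TPM normalization), and a
multiplicative dosage factor for carriers — δ = 0.5 for deletions
(expression halves; δ = 0 models complete loss and yields exactly zero
carrier TPM), γ = 1.0 for duplications (no increase; a γ < 1 mode
emulates dosage rebalancing). The dosage factor applies only when the CNV
overlaps the transcript body; flank-only CNVs leave expression unchanged.
Dosage is per-transcript and coverage-independent by default; a
`proportional_dosage` switch scales the effect by the covered fraction
for sensitivity analyses. Columns are scaled to sum to 10⁶ (TPM).

λ = 3.9 × 10⁻⁵ per bp was calibrated once, by scanning, so that the
Spearman correlation between transcript body length and mean TPM on a
CNV-free 143-sample cohort sits at −0.27 (observed mean −0.272, per-seed
range −0.30 to −0.24 under the default transcriptome).

One RNG stream per generator stage, spawned from the master seed, so
changing e.g. false-positive rates does not shift transcript placement.
Fixed seed ⇒ byte-identical output files.

### What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes: carrier
sparsity, breakpoint-resolution mismatch between callers, length-decaying
heavy-tailed expression, multiplicative dosage. It does not simulate
reads, alignment, the callers' internal statistics, overlapping
transcripts/isoforms, or any linkage between loci. Passing tests
therefore demonstrate that the pipeline recovers planted effects and
holds its nominal level under these assumptions — not that the
assumptions hold in any particular real dataset.

Two desk-scale artifacts are worth knowing about:

* **TPM coupling.** With only hundreds of transcripts, heavy-tailed base
  expression makes per-sample TPM denominators noisy, inducing real
  per-animal factors that the random-split control correctly detects
  (fraction significant up to ~0.15 at 800 transcripts, ~0.05 by 8000).
  Real transcriptomes (tens of thousands of transcripts) do not have
  this; calibration checks of the control are run at 8000 transcripts.
* **Length confound in coverage correlations.** Under constant-multiplier
  dosage, the carrier/non-carrier difference scales with baseline
  expression, which is larger for short transcripts, while percent
  covered is also larger for short transcripts — so Fig-3-style cells can
  show significant correlations that reflect transcript length, not a
  coverage-dependent dosage mechanism. With no dosage effect (δ = γ = 1)
  the cells are null-calibrated.

## Problem sizes in the test suite

Unit and calibration tests run on scaled cohorts chosen as this package's
own testing sizes: typically a 14-Mb two-chromosome genome with 400–1100
transcripts and 120–640 calls per animal for seed-loop checks (type-I
over 200 seeds, recovery over 50 seeds), the default 130-Mb /
2500-transcript configuration for single-run checks and the acceptance
script, and 8000 transcripts for the animal-effect control calibration.
Effect sizes, carrier rules, α and all thresholds are identical to the
defaults at every scale.

## Known limitations

* The multi-region discard rule makes "coding" annotations of long CNVs
  rare by construction (a CNV spanning a whole exon almost always also
  touches an intron or flank); single-exon containment dominates.
* The exact Wilcoxon null is only used for n ≤ 25; pipeline contrasts are
  usually far larger and rely on the (verified) normal approximation.
* Transcripts are placed without mutual overlap; real overlapping loci
  and antisense transcripts would multiply per-CNV annotation records in
  ways the generator does not model.
* The validated-call audit counts calls, not loci: the same polymorphic
  locus appears once per carrier animal.
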