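# Methods

## Consensus calling

Discordant read-pair TE callers report an insertion point with limited
positional resolution, so two callers' predictions for the same event are
reconciled by a window rule: calls on the same chromosome and of the same
TE family match if their positions differ by at most `window_bp`
(default 100, inclusive).  Matching is constrained to be one-to-one.  When
one call is within the window of several others the assignment is solved
exactly: candidate pairs decompose into independent connected components,
and each component is solved with the Hungarian algorithm using a
prohibitive pseudo-cost for out-of-window pairs, which maximizes the
number of matched pairs and, among maximal matchings, minimizes the summed
distance.  A greedy nearest-first rule was considered and rejected: in
chained configurations (A at 0 and 90, B at 95 and 180, window 100) greedy
pairs only the closest two calls and drops a feasible second pair, so it
does not attain the optimal matched-pair count that the exact assignment
— and the package's own oracle tests — require.  The consensus position
is the arithmetic mean of the matched pair, rounded half-up; consensus
support is the maximum of the two calls' support, since the downstream
filter asks whether sufficient evidence exists, not for an average.

Distinct true events closer than the window can collapse into one
consensus call; this is accepted and documented rather than resolved,
as sub-window resolution is not recoverable from the inputs.

## Support filter

Consensus calls are kept iff `min_reads <= support <= depth_multiplier *
mean_depth`, both bounds inclusive (defaults 5 reads and 4×).  The filter
is applied after caller intersection by default; `call_cohort` exposes a
flag to disable it, and the CLI applies it in the `consensus` step.  The
lower bound truncates the low (noise) mode of the bimodal support
distribution; the upper bound removes calls in anomalously deep regions.

## Somatic classification

Normal and tumor consensus sets of a patient are matched with the same
window rule.  Matched loci are presumed germline; unmatched ones are
tissue-specific.  A tissue-specific insertion is *private* when no
same-family insertion lies within the window in any other patient (either
tissue) or in the same patient's other tissue.  The cohort summary counts
a shared locus once per patient; this convention makes the total/unique/
shared-percentage arithmetic internally consistent and is recorded in the
CLI output metadata.  The full somatic call additionally requires absence
from the population panel (`pipeline.panel_filter`), which removes the
dominant error mode — a germline insertion missed by chance in one tissue
of a singleton carrier masquerading as somatic.

## Frequency annotation

Insertions match the nearest same-family panel locus within the window.
Bins: private (no match), low (0 < AF < 0.05), high (AF ≥ 0.05).  The
boundary AF = 0.05 is assigned to the high bin (closed upper bin); a
`boundary_bin` flag flips it.  The normal-vs-tumor comparison reports a
two-sample KS test on the matched AF values with private mapped to 0 — a
KS test on three discrete bins alone would be statistically degenerate —
plus a chi-square on the 3×2 bin table as a companion statistic; neither
is privileged, both are reported.

## Enrichment statistic

Expected private-L1 counts split the observed L1 private total between
tissues by the all-TE private ratio, conserving the total exactly.  The
Fisher exact test needs integer tables, so expected counts are rounded
half-up (the smallest perturbation; unrounded values are reported
alongside).  The Fisher p-value is computed by exact integer
hypergeometric enumeration — tables with the observed margins whose
integer weight `C(r1,a)·C(r2,c)` does not exceed the observed table's are
summed — avoiding floating-point tie ambiguity entirely.  A conventional
alternative (L1 vs non-L1, normal vs tumor) is available behind
`method="l1-vs-other"` and labeled as such in the report.

## Feature screening

Context precedence is exonic > regulatory (enhancer) > intronic >
intergenic; exactly one label per insertion, with the 1-based insertion
point converted to a 0-based coordinate tested against half-open
intervals.  Enhancers link to the gene with the nearest TSS within a
50 kb cap (cap 0 disables linkage).  Driver candidates are tumor-private
insertions labeled exonic or regulatory whose gene is on the tumor
suppressor list; with per-gene expression deltas supplied, down-regulation
marks a candidate concordant with a loss-of-function mechanism.

## EM quantifier

The multi-mapper assignment is instance-level: abundance initialized
uniformly over loci, E-step distributing each read over its candidate loci
proportionally to current abundances, M-step summing incoming fractions,
iterated until the largest abundance change is below `tol` (1e-8) or
`max_iter` (200).  Total abundance equals the read count after every
iteration, and the observed-data log-likelihood is non-decreasing.  This
is a deliberate simplification of family-aware TE quantifiers: no
transcript-length normalization, no mapping qualities, no family-level
pooling.  Expression comparisons use log10(count + 1); the pseudocount of
1 maps zero counts to zero on the log scale.

## Synthetic cohort generator

The generator emulates the data regime of a nine-patient matched
normal/tumor whole-genome study at ~40× depth:

* **Genome**: three chromosomes totalling 45 Mb — large enough to hold
  thousands of loci at realistic spacing while keeping simulation fast.
* **Truth layout**: loci occupy distinct bins of width `2·min_spacing`
  (1 kb) with offsets in the first half of each bin, guaranteeing ≥ 500 bp
  between any two truth loci so the ±100 bp window can never fuse distinct
  events and truth matching is unambiguous.
* **Germline**: 1000 polymorphic loci, family weights 0.85/0.12/0.03 for
  Alu/L1/SVA (the approximate family composition of polymorphic human TE
  call sets), allele frequencies Beta(0.5, 2) — right-skewed with mean
  0.2, mimicking the low-frequency-heavy AF spectrum of population TE
  panels.  A patient carries a locus with probability 1 − (1 − AF)²
  (diploid, at least one allele), in both tissues.  The panel contains
  exactly the germline loci plus 500 extra loci absent from the cohort.
* **Somatic**: per sample and family, Poisson counts with rate 11 (normal
  and tumor), the tumor L1 rate multiplied by 2.  This yields ≈ 33
  normal-private and ≈ 44 tumor-private events per patient — an all-TE
  tumor/normal ratio of ≈ 1.33 and ≈ 700 private insertions per cohort,
  the regime of the analyzed study.
* **Callers**: two callers observe each carried locus independently with
  miss probability 0.02 each; reported positions get rounded-Gaussian
  jitter (sd 15 bp, truncated at ±window so true pairs stay mergeable).
  False positives arrive at 5% of a sample's true call count, placed in
  bins unused by truth (hence ≥ 500 bp from every true locus), with
  random family.
* **Support**: real calls draw from a negative binomial with mean
  `0.5 · mean_depth` (a heterozygous insertion is supported by roughly
  half the pairs) and shape 8; spurious calls draw from Poisson(2).
  The resulting per-caller support histograms are bimodal, and the noise
  mass below the 5-read cutoff matches the Poisson(2) CDF.
* **Expression**: per-sample negative-binomial counts — 2000 genes
  (mean 200) and the three family aggregates drawn identically in both
  tissues, and 145 full-length intact L1 loci (the size of the curated
  intact-L1 reference set) with mean 20 in normal and a 10-fold
  (log10 fold change 1.0) tumor increase.  The family aggregates are
  drawn independently of the intact loci: intact-L1 transcription is a
  negligible share of family-level read mass, so family totals stay
  tissue-balanced, reproducing the qualitative pattern that only the
  intact-L1 comparison is significant.
* **Reproducibility**: one global seed fans out through named
  `SeedSequence` children (truth, calls, features, expression); identical
  config + seed give byte-identical outputs.

What the generator does **not** emulate: read-level alignment artifacts,
reference-genome context (GC, mappability), target-site duplications,
clonal heterogeneity / VAF structure, position-dependent caller error, or
correlated errors between callers.  Passing tests therefore demonstrate
the correctness and statistical behavior of the downstream analysis under
its stated assumptions, not the performance of any real caller pair on
real genomes.

## Power-check conditions

The replicate-based checks of the L1-excess Fisher test use somatic rate
30 per family per sample (≈ 540 normal-private and ≈ 810 tumor-private
truth events per cohort, of which ≈ 270/540 are L1) with a reduced
germline background of 300 loci, which does not enter the L1 statistic.
At these counts a standard two-proportion power calculation for the
observed-vs-expected comparison gives z ≈ 3.9 at a true multiplier of 2,
i.e. > 95% power at α = 0.05, so a ≥ 90% empirical rejection rate over
100 replicates is expected with margin; at multiplier 1 the conservatism
of the exact test keeps the empirical type-I rate well below the nominal
5%.  With the paper-scale default rates (11 per family) a single cohort
typically yields p in the 0.001–0.05 range — significant, but without the
replicate-level power that the dedicated conditions provide.

## Problem sizes

Default test and acceptance runs use the 9-patient default cohort
(~1700 truth loci, ~13k caller calls), 100 replicate cohorts for each
rejection-rate estimate, exhaustive Fisher verification over all 2×2
tables with total ≤ 40, and brute-force oracles at ≤ 50 calls (matching),
≤ 8 observations (KS) and ≤ 3 loci / ≤ 20 reads (EM grid search).

## Known limitations

* Pairwise caller intersection only; no k-of-n generalization.
* No genotyping or VAF estimation; "somatic" is a presence/absence call.
* The EM quantifier is instance-level and unnormalized; its abundances
  are read counts, not TPM-like quantities.
* The private/unique convention (shared loci counted once per patient)
  is one of two defensible conventions; it is stated in output metadata.
* Whether the support filter precedes or follows caller intersection is
  configurable; the default (after intersection) changes few calls since
  consensus support is the pairwise maximum.
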