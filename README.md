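# tesomatic

Somatic transposable-element (TE) insertion and expression analysis for
matched normal/tumor whole-genome cohorts.

## The problem

The active human TE families — Alu, L1 and SVA — still copy themselves
into new genomic locations, in the germline and in somatic tissue.
Somatic insertions that disrupt exons or regulatory elements of tumor
suppressor genes are candidate cancer driver mutations.  Detecting them
from short-read DNA-seq is noisy: individual callers locate an insertion
only to within tens of base pairs and produce both spurious and missed
calls.  `tesomatic` implements the downstream analysis that turns two
callers' raw predictions from matched normal and tumor samples into
somatic insertion calls, enrichment statistics and driver candidates,
together with a synthetic cohort generator that makes every stage testable
against known truth.

## The method

For each sample, predictions from two independent callers are intersected:
calls of the same TE family within ±100 bp are treated as the same
insertion (one-to-one matching, maximizing matched pairs and breaking ties
by minimal summed distance), and only these consensus calls are kept.
Calls with fewer than 5 supporting reads, or more than 4× the sample's
mean sequencing depth, are removed — the support distribution is bimodal,
with the low mode enriched for false positives.

Per patient, normal and tumor consensus sets are matched with the same
window: insertions found in both tissues are presumed germline; insertions
found in one tissue of one patient with no same-family insertion within
the window anywhere else in the cohort are *private* — candidate somatic
events.  Each insertion is also annotated against a population panel of
known polymorphic TE loci with allele frequencies (AF) and binned as high
(AF ≥ 0.05), low (0 < AF < 0.05) or private (absent).

The tumor excess of private L1 insertions is tested by splitting the
private-L1 total between tissues in proportion to the all-TE private
counts (expected counts `E_t = L1_total · U_t / (U_n + U_t)`) and
comparing observed to expected with a two-sided Fisher exact test.
Normal/tumor frequency-bin and expression distributions are compared with
two-sample Kolmogorov–Smirnov tests; expression values are log10(count+1)
read counts, with TE quantification using an EM algorithm that fractionally
assigns multi-mapped reads to candidate loci in proportion to estimated
abundances, optionally restricted to full-length intact L1 loci.
Tumor-private insertions in exons or enhancers (nearest TSS within 50 kb)
of listed tumor suppressor genes are flagged as driver candidates,
annotated as concordant when the gene is down-regulated in the tumor.

## Worked example

```python
import tesomatic as ts

cohort = ts.simulate_cohort(ts.CohortConfig(seed=7))   # 9 patients, 2 tissues
result = ts.call_cohort(cohort)                        # consensus -> classification
s = result.summary

print(s.total_insertions, s.unique_insertions)         # 3450 696
print(ts.average_private_per_patient(s, 9))            # 77
print(ts.shared_fraction(s))                           # 79.8
print(ts.tumor_excess_ratio(s))                        # 1.4

report = ts.l1_excess_test(ts.unique_count_table(s))
print(report.observed, report.pvalue)                  # (86, 200) 0.004
```

The cohort contains 3450 consensus insertion loci, of which 696 are
private (one patient, one tissue) — on average 77 per patient, with 79.8%
of loci shared between tissues (germline).  Private insertions are
1.4-fold more frequent in tumor than normal tissue, and private L1
insertions specifically (86 normal vs 200 tumor, against an expected
120/166 split) are significantly tumor-enriched (Fisher p = 0.004),
reflecting the two-fold tumor L1 rate the generator was configured with.
Against the simulated truth, somatic detection reaches precision 1.00 and
recall 0.96 under the default caller error rates.

The same steps are available as a CLI (`tesomatic simulate`, `consensus`,
`classify`, `cohort-summary`, `annotate-freq`, `freq-test`, `l1-excess`,
`annotate-features`, `em-quant`, `expr-test`) over plain BED-derived TSV
files.

## Layout

- `tesomatic.simulate` — synthetic cohort generator (truth, caller calls,
  panel, features, expression)
- `tesomatic.consensus` — two-caller merging and support filtering
- `tesomatic.somatic` — tissue pairing, private insertions, summaries
- `tesomatic.frequency` — panel AF annotation and bin comparison
- `tesomatic.enrichment` — expected L1 counts and Fisher exact test
- `tesomatic.features` — genomic context and driver screening
- `tesomatic.expression` — EM multi-mapper quantification and KS comparison
- `tesomatic.pipeline` — end-to-end composition and truth evaluation
- `tesomatic.io`, `tesomatic.cli` — file formats and command-line surface

See `docs/methods.md` for the model, parameter and design details.
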