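"""Observed-vs-expected unique L1 counts and the Fisher exact test.

The question: do private L1 insertions accumulate in tumor tissue beyond
what the overall tumor/normal imbalance of private TE insertions predicts?
Expected L1 counts split the total number of private L1 insertions between
tissues in proportion to the all-TE private counts; the observed split is
compared to the expected split with a two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._util import round_half_up
from .somatic import CohortSummary


@dataclass(frozen=True)
class UniqueCountTable:
    """Private-insertion counts per tissue, for all TEs and for L1 alone."""

    all_te_unique_normal: int
    all_te_unique_tumor: int
    l1_unique_normal: int
    l1_unique_tumor: int

    def __post_init__(self) -> None:
        vals = (
            self.all_te_unique_normal,
            self.all_te_unique_tumor,
            self.l1_unique_normal,
            self.l1_unique_tumor,
        )
        if any(v < 0 for v in vals):
            raise ValueError("counts must be non-negative")
        if self.l1_unique_normal > self.all_te_unique_normal:
            raise ValueError("L1 normal count exceeds all-TE normal count")
        if self.l1_unique_tumor > self.all_te_unique_tumor:
            raise ValueError("L1 tumor count exceeds all-TE tumor count")


@dataclass
class L1ExcessReport:
    observed: tuple[int, int]
    expected: tuple[float, float]
    expected_rounded: tuple[int, int]
    tumor_obs_over_exp: float
    odds_ratio: float
    pvalue: float
    method: str


def unique_count_table(summary: CohortSummary) -> UniqueCountTable:
    """Build the unique-count table from a cohort summary."""
    ft = summary.unique_by_family_tissue
    return UniqueCountTable(
        all_te_unique_normal=summary.unique_by_tissue.get("normal", 0),
        all_te_unique_tumor=summary.unique_by_tissue.get("tumor", 0),
        l1_unique_normal=ft.get(("L1", "normal"), 0),
        l1_unique_tumor=ft.get(("L1", "tumor"), 0),
    )


def expected_l1_counts(t: UniqueCountTable) -> tuple[float, float]:
    """Split the L1 private total by the all-TE normal:tumor private ratio.

    Conserves the L1 total exactly: expected_normal + expected_tumor equals
    the observed number of private L1 insertions.
    """
    all_total = t.all_te_unique_normal + t.all_te_unique_tumor
    if all_total <= 0:
        raise ValueError("all-TE unique total must be positive")
    l1_total = t.l1_unique_normal + t.l1_unique_tumor
    expected_normal = l1_total * t.all_te_unique_normal / all_total
    return expected_normal, l1_total - expected_normal


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of non-negative integers.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than the observed table's.
    Comparisons are done on exact integer binomial products, so there is no
    floating-point tie ambiguity.  Returns (sample odds ratio, p-value).
    """
    (a, b), (c, d) = table
    cells = [int(a), int(b), int(c), int(d)]
    if any(v < 0 for v in cells):
        raise ValueError("table cells must be non-negative")
    if cells != [a, b, c, d]:
        raise ValueError("table cells must be integers")
    a, b, c, d = cells
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0  # a zero marginal admits a single table

    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w <= obs:
            num += w
    return odds, num / math.comb(n, c1)


def l1_excess_test(t: UniqueCountTable, method: str = "observed-expected") -> L1ExcessReport:
    """Fisher test of the tumor excess of private L1 insertions.

    ``method='observed-expected'`` compares the observed (normal, tumor) L1
    split against the expected split (rounded half-up to integers, as the
    Fisher test needs integer counts; unrounded values are also reported).
    ``method='l1-vs-other'`` is the conventional alternative: L1 vs non-L1
    private counts, normal vs tumor.
    """
    exp_n, exp_t = expected_l1_counts(t)
    obs = (t.l1_unique_normal, t.l1_unique_tumor)
    exp_r = (int(round_half_up(exp_n)), int(round_half_up(exp_t)))
    if method == "observed-expected":
        table = [list(obs), list(exp_r)]
    elif method == "l1-vs-other":
        table = [
            list(obs),
            [
                t.all_te_unique_normal - t.l1_unique_normal,
                t.all_te_unique_tumor - t.l1_unique_tumor,
            ],
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    odds, p = fisher_exact_2x2(table)
    ratio = obs[1] / exp_t if exp_t > 0 else math.nan
    return L1ExcessReport(
        observed=obs,
        expected=(exp_n, exp_t),
        expected_rounded=exp_r,
        tumor_obs_over_exp=ratio,
        odds_ratio=odds,
        pvalue=p,
        method=method,
    )
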