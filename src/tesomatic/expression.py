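"""Expression quantification with EM multi-mapper assignment.

Reads from repetitive elements often map to many near-identical loci.  The
quantifier here fractionally allocates each multi-mapped read among its
candidate loci in proportion to current locus abundance estimates
(E-step), then re-estimates abundances as the summed incoming fractions
(M-step), iterating to a fixed point.  It is an instance-level
simplification of family-aware TE quantifiers: no transcript-length
normalization and no mapping qualities, just the multi-mapper
reallocation principle.

Expression comparisons are distribution-level: two-sample KS on log10
transformed read counts (pseudocount 1), matching how pooled normal and
tumor expression profiles are contrasted per feature class (all genes, TE
families, or full-length intact L1 loci only).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TELocus:
    locus_id: str
    family: str
    intact_l1: bool = False


@dataclass
class ReadAssignmentProblem:
    loci: list[TELocus]
    reads: list[tuple[str, tuple[str, ...]]]  # (read_id, candidate locus ids)

    def __post_init__(self) -> None:
        known = {l.locus_id for l in self.loci}
        if len(known) != len(self.loci):
            raise ValueError("duplicate locus ids")
        for read_id, cands in self.reads:
            if not cands:
                raise ValueError(f"read {read_id!r} has no candidate loci")
            unknown = set(cands) - known
            if unknown:
                raise ValueError(f"read {read_id!r} references unknown loci {sorted(unknown)}")


@dataclass
class EMResult:
    abundance: pd.Series  # indexed by locus_id, sums to the read count
    n_iter: int
    log_likelihood: list[float]
    converged: bool


def _log_likelihood(theta: np.ndarray, sig_idx: list[np.ndarray], sig_n: np.ndarray) -> float:
    total = theta.sum()
    ll = 0.0
    for idx, n in zip(sig_idx, sig_n):
        s = theta[idx].sum()
        ll += n * (np.log(s) if s > 0 else -np.inf)
    return float(ll - sig_n.sum() * np.log(total))


def em_assign(
    problem: ReadAssignmentProblem, max_iter: int = 200, tol: float = 1e-8
) -> EMResult:
    """EM fixed-point estimate of per-locus read abundances.

    Initialization is uniform over loci; iteration stops when the largest
    per-locus abundance change falls below ``tol``.  Total abundance equals
    the number of reads after every iteration (each read always
    distributes exactly one unit of mass).
    """
    ids = [l.locus_id for l in problem.loci]
    index = {lid: k for k, lid in enumerate(ids)}
    n_loci = len(ids)
    n_reads = len(problem.reads)
    if n_loci == 0:
        raise ValueError("problem has no loci")

    # collapse reads sharing a candidate signature
    sig_counts = Counter(tuple(sorted(set(c))) for _, c in problem.reads)
    sig_idx = [np.array([index[c] for c in sig], dtype=np.int64) for sig in sig_counts]
    sig_n = np.array(list(sig_counts.values()), dtype=np.float64)

    theta = np.full(n_loci, n_reads / n_loci, dtype=np.float64)
    ll_trace = [_log_likelihood(theta, sig_idx, sig_n)] if n_reads else [0.0]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = np.zeros(n_loci)
        for idx, n in zip(sig_idx, sig_n):
            w = theta[idx]
            s = w.sum()
            if s > 0:
                new[idx] += n * w / s
            else:  # all candidates currently at zero: split evenly
                new[idx] += n / len(idx)
        ll_trace.append(_log_likelihood(new, sig_idx, sig_n) if n_reads else 0.0)
        delta = float(np.max(np.abs(new - theta))) if n_loci else 0.0
        theta = new
        if delta < tol:
            converged = True
            break
    return EMResult(
        abundance=pd.Series(theta, index=ids, name="abundance"),
        n_iter=n_iter,
        log_likelihood=ll_trace,
        converged=converged,
    )


def restrict_to_intact_l1(table: pd.DataFrame, intact_ids: set[str]) -> pd.DataFrame:
    """Keep only rows for full-length, intact L1 loci.

    Restricting to structurally intact elements isolates genuine
    L1-initiated transcription from passive read-through of fixed copies.
    """
    unknown = set(intact_ids) - set(table.index)
    if unknown:
        raise ValueError(f"unknown feature ids: {sorted(unknown)}")
    keep = [i for i in table.index if i in intact_ids]
    return table.loc[keep]


@dataclass
class ExpressionComparison:
    statistic: float
    pvalue: float
    normal_log10: np.ndarray
    tumor_log10: np.ndarray


def compare_expression(
    normal_counts, tumor_counts, pseudocount: float = 1.0
) -> ExpressionComparison:
    """Two-sample KS test on log10(count + pseudocount) distributions."""
    vn = np.asarray(normal_counts, dtype=np.float64).ravel()
    vt = np.asarray(tumor_counts, dtype=np.float64).ravel()
    if vn.size == 0 or vt.size == 0:
        raise ValueError("both count vectors must be non-empty")
    ln = np.log10(vn + pseudocount)
    lt = np.log10(vt + pseudocount)
    ks = stats.ks_2samp(ln, lt)
    return ExpressionComparison(float(ks.statistic), float(ks.pvalue), ln, lt)


def per_gene_log2_fold_change(
    gene_table: pd.DataFrame,
    normal_samples: Sequence[str],
    tumor_samples: Sequence[str],
    pseudocount: float = 1.0,
) -> Mapping[str, float]:
    """Auxiliary per-gene tumor-vs-normal log2 fold change for driver screening."""
    n = gene_table[list(normal_samples)].mean(axis=1) + pseudocount
    t = gene_table[list(tumor_samples)].mean(axis=1) + pseudocount
    return dict(np.log2(t / n))
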