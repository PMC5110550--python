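"""Genomic-context classification and candidate driver screening.

Tumor-private insertions are intersected with gene models, enhancer
intervals and a tumor-suppressor gene list.  Each insertion gets exactly
one context label with precedence exonic > regulatory (enhancer) >
intronic > intergenic.  Insertions landing in exons or enhancers of tumor
suppressor genes are flagged as candidate driver mutations; when per-gene
tumor-vs-normal expression changes are supplied, a candidate whose gene is
down-regulated is marked concordant (loss-of-function pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import round_half_up
from .consensus import ConsensusInsertion

CONTEXT_KINDS = ("exonic", "regulatory", "intronic", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """A transcript span with exons, all 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.gene_id}: malformed exon ({s}, {e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand != "-" else self.tx_end - 1


@dataclass(frozen=True)
class Enhancer:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"malformed enhancer interval ({self.start}, {self.end})")


@dataclass
class FeatureBundle:
    genes: list[GeneModel]
    enhancers: list[Enhancer]
    tumor_suppressors: set[str]
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def _tree(self, kind: str, chrom: str) -> IntervalTree:
        key = (kind, chrom)
        if key not in self._trees:
            t = IntervalTree()
            if kind == "exon":
                for g in self.genes:
                    if g.chrom == chrom:
                        for s, e in g.exons:
                            t.addi(s, e, g.gene_id)
            elif kind == "tx":
                for g in self.genes:
                    if g.chrom == chrom:
                        t.addi(g.tx_start, g.tx_end, g.gene_id)
            elif kind == "enhancer":
                for i, enh in enumerate(self.enhancers):
                    if enh.chrom == chrom:
                        t.addi(enh.start, enh.end, i)
            self._trees[key] = t
        return self._trees[key]


@dataclass(frozen=True)
class ContextLabel:
    insertion: ConsensusInsertion
    kind: str
    gene_id: str | None = None
    enhancer_index: int | None = None


@dataclass(frozen=True)
class CandidateDriver:
    insertion: ConsensusInsertion
    kind: str  # exonic or regulatory
    gene_id: str
    expression_delta: float | None
    concordant: bool | None  # None when no expression data supplied


def classify_context(insertion: ConsensusInsertion, features: FeatureBundle) -> ContextLabel:
    """Assign one genomic-context label to an insertion point.

    The 1-based insertion point maps to the 0-based coordinate pos-1 and is
    tested against half-open intervals.  Ties (overlapping genes) resolve
    to the lexicographically smallest gene_id for determinism.
    """
    point = insertion.pos - 1
    hits = features._tree("exon", insertion.chrom)[point]
    if hits:
        gene = min(h.data for h in hits)
        return ContextLabel(insertion, "exonic", gene_id=gene)
    enh = features._tree("enhancer", insertion.chrom)[point]
    if enh:
        return ContextLabel(insertion, "regulatory", enhancer_index=min(h.data for h in enh))
    tx = features._tree("tx", insertion.chrom)[point]
    if tx:
        gene = min(h.data for h in tx)
        return ContextLabel(insertion, "intronic", gene_id=gene)
    return ContextLabel(insertion, "intergenic")


def classify_contexts(
    insertions: Iterable[ConsensusInsertion], features: FeatureBundle
) -> list[ContextLabel]:
    return [classify_context(i, features) for i in insertions]


def summarize_contexts(labels: Sequence[ContextLabel]) -> pd.DataFrame:
    """Counts and one-decimal percentages per context class."""
    if not labels:
        return pd.DataFrame(columns=["count", "pct"])
    total = len(labels)
    rows = {}
    for kind in CONTEXT_KINDS:
        n = sum(lab.kind == kind for lab in labels)
        if n:
            rows[kind] = (n, round_half_up(100.0 * n / total, 1))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["count", "pct"])


def context_percentage(count: int, total: int) -> float:
    """Percentage of a context class among all insertions, one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, 1)


def nearest_tss_gene(
    chrom: str, point: int, features: FeatureBundle, cap_bp: int
) -> str | None:
    """Gene with the nearest TSS within ``cap_bp``; None beyond the cap.

    With cap 0 only a gene whose TSS coincides with the point qualifies,
    so enhancer candidates effectively never link to a gene.
    """
    best: tuple[int, str] | None = None
    for g in features.genes:
        if g.chrom != chrom:
            continue
        d = abs(g.tss - point)
        if d <= cap_bp and (best is None or (d, g.gene_id) < best):
            best = (d, g.gene_id)
    return best[1] if best else None


def flag_candidate_drivers(
    labels: Sequence[ContextLabel],
    features: FeatureBundle,
    expression_delta: Mapping[str, float] | None = None,
    tss_cap_bp: int = 50_000,
) -> list[CandidateDriver]:
    """Screen tumor-private insertion labels for tumor-suppressor hits.

    ``labels`` must come from tumor-private insertions only (the caller
    enforces the scope); shared/germline insertions are never candidates.
    Exonic candidates use the overlapped gene; regulatory candidates link
    the enhancer to the nearest TSS within ``tss_cap_bp``.
    """
    out: list[CandidateDriver] = []
    for lab in labels:
        if lab.kind == "exonic":
            gene = lab.gene_id
        elif lab.kind == "regulatory":
            gene = nearest_tss_gene(
                lab.insertion.chrom, lab.insertion.pos - 1, features, tss_cap_bp
            )
        else:
            continue
        if gene is None or gene not in features.tumor_suppressors:
            continue
        delta = None if expression_delta is None else expression_delta.get(gene)
        concordant = None if delta is None else bool(delta < 0)
        out.append(CandidateDriver(lab.insertion, lab.kind, gene, delta, concordant))
    out.sort(
        key=lambda c: (
            not c.concordant if c.concordant is not None else True,
            -(abs(c.expression_delta) if c.expression_delta is not None else 0.0),
            c.kind,  # exonic before regulatory
            c.gene_id,
        )
    )
    return out
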