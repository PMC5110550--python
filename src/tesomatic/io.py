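"""Readers and writers for the plain-text formats the pipeline exchanges.

Caller calls and panels travel as BED-derived TSV: 0-based half-open
single-bp intervals (start = pos - 1, end = pos).  Gene models are BED12,
enhancers BED3, tumor suppressors one gene id per line, expression tables
TSV matrices, and read assignments a two-column TSV of read id and
comma-separated candidate locus ids.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from typing import Sequence

import pandas as pd
import yaml

from .consensus import ConsensusInsertion, InsertionCall
from .expression import ReadAssignmentProblem, TELocus
from .features import Enhancer, FeatureBundle, GeneModel
from .frequency import PanelEntry
from .simulate import SyntheticCohort, TruthRecord

CALL_COLUMNS = ["chrom", "start", "end", "family", "support_reads", "caller_id", "sample_id", "tissue"]
PANEL_COLUMNS = ["chrom", "start", "end", "family", "af"]
TRUTH_COLUMNS = ["chrom", "pos", "family", "origin", "panel_af", "carriers"]


def write_calls(calls: Sequence[InsertionCall], path: str) -> None:
    df = pd.DataFrame(
        [
            (c.chrom, c.pos - 1, c.pos, c.family, c.support_reads, c.caller_id, c.sample_id, c.tissue)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> list[InsertionCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        InsertionCall(
            chrom=str(r.chrom),
            pos=int(r.end),
            family=str(r.family),
            support_reads=int(r.support_reads),
            caller_id=str(r.caller_id),
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
        )
        for r in df.itertuples()
    ]


def write_consensus(calls: Sequence[ConsensusInsertion], path: str) -> None:
    df = pd.DataFrame(
        [
            (c.chrom, c.pos - 1, c.pos, c.family, c.support_reads, c.sample_id, c.tissue)
            for c in calls
        ],
        columns=["chrom", "start", "end", "family", "support_reads", "sample_id", "tissue"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_consensus(path: str) -> list[ConsensusInsertion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ConsensusInsertion(
            chrom=str(r.chrom),
            pos=int(r.end),
            family=str(r.family),
            support_reads=int(r.support_reads),
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
        )
        for r in df.itertuples()
    ]


def write_panel(panel: Sequence[PanelEntry], path: str) -> None:
    df = pd.DataFrame(
        [(e.chrom, e.pos - 1, e.pos, e.family, e.af) for e in panel],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_panel(path: str) -> list[PanelEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    return [
        PanelEntry(chrom=str(r.chrom), pos=int(r.end), family=str(r.family), af=float(r.af))
        for r in df.itertuples()
    ]


def write_truth(truth: Sequence[TruthRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            (
                t.chrom,
                t.pos,
                t.family,
                t.origin,
                "" if t.panel_af is None else f"{t.panel_af:.17g}",
                ",".join(f"{p}:{ti}" for p, ti in t.carriers),
            )
            for t in truth
        ],
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# operation-style alias: serialize the truth set for downstream evaluation
write_truth_tables = write_truth


def read_truth(path: str) -> list[TruthRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "carriers": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    out = []
    for r in df.itertuples():
        carriers = tuple(
            tuple(tok.split(":", 1)) for tok in str(r.carriers).split(",") if tok
        )
        af = None if r.panel_af == "" else float(r.panel_af)
        out.append(
            TruthRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                family=str(r.family),
                origin=str(r.origin),
                carriers=carriers,  # type: ignore[arg-type]
                panel_af=af,
            )
        )
    return out


def write_genes_bed12(genes: Sequence[GeneModel], path: str) -> None:
    rows = []
    for g in genes:
        starts = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        rows.append(
            (
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                g.tx_start, g.tx_end, "0,0,0", len(g.exons), sizes, starts,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed12(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    genes = []
    for r in df.itertuples(index=False):
        chrom, start, end, name, _score, strand = r[0], int(r[1]), int(r[2]), str(r[3]), r[4], str(r[5])
        sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(r[11]).rstrip(",").split(",")]
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        genes.append(GeneModel(name, str(chrom), strand, start, end, exons))
    return genes


def write_enhancers_bed(enhancers: Sequence[Enhancer], path: str) -> None:
    pd.DataFrame([(e.chrom, e.start, e.end) for e in enhancers]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_enhancers_bed(path: str) -> list[Enhancer]:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return [Enhancer(str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]


def write_gene_list(ids, path: str) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


def read_gene_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_feature_bundle(features: FeatureBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_genes_bed12(features.genes, os.path.join(outdir, "genes.bed"))
    write_enhancers_bed(features.enhancers, os.path.join(outdir, "enhancers.bed"))
    write_gene_list(features.tumor_suppressors, os.path.join(outdir, "tumor_suppressors.txt"))


def read_feature_bundle(genes_path: str, enhancers_path: str, tsg_path: str) -> FeatureBundle:
    return FeatureBundle(
        genes=read_genes_bed12(genes_path),
        enhancers=read_enhancers_bed(enhancers_path),
        tumor_suppressors=read_gene_list(tsg_path),
    )


def write_read_problem(problem: ReadAssignmentProblem, loci_path: str, reads_path: str) -> None:
    pd.DataFrame(
        [(l.locus_id, l.family, int(l.intact_l1)) for l in problem.loci],
        columns=["locus_id", "family", "intact_l1"],
    ).to_csv(loci_path, sep="\t", index=False)
    pd.DataFrame(
        [(rid, ",".join(cands)) for rid, cands in problem.reads],
        columns=["read_id", "candidates"],
    ).to_csv(reads_path, sep="\t", index=False)


def read_read_problem(loci_path: str, reads_path: str) -> ReadAssignmentProblem:
    loci_df = pd.read_csv(loci_path, sep="\t")
    reads_df = pd.read_csv(reads_path, sep="\t")
    loci = [
        TELocus(str(r.locus_id), str(r.family), bool(r.intact_l1))
        for r in loci_df.itertuples()
    ]
    reads = [
        (str(r.read_id), tuple(str(r.candidates).split(",")))
        for r in reads_df.itertuples()
    ]
    return ReadAssignmentProblem(loci=loci, reads=reads)


def write_cohort(cohort: SyntheticCohort, outdir: str) -> None:
    """Serialize a synthetic cohort: per-caller per-sample call files plus
    panel, truth, features, expression tables and the read problem."""
    os.makedirs(outdir, exist_ok=True)
    calls_dir = os.path.join(outdir, "calls")
    os.makedirs(calls_dir, exist_ok=True)
    cfg = cohort.config
    for patient in cfg.patient_ids:
        for tissue in cfg.tissues:
            for caller in cfg.callers:
                write_calls(
                    cohort.calls_for(patient, tissue, caller),
                    os.path.join(calls_dir, f"{caller}_{patient}_{tissue}.tsv"),
                )
    write_panel(cohort.panel, os.path.join(outdir, "panel.tsv"))
    write_truth(cohort.truth, os.path.join(outdir, "truth.tsv"))
    write_feature_bundle(cohort.features, os.path.join(outdir, "features"))
    expr_dir = os.path.join(outdir, "expression")
    os.makedirs(expr_dir, exist_ok=True)
    for name, table in cohort.expression.items():
        table.to_csv(os.path.join(expr_dir, f"{name}.tsv"), sep="\t")
    write_read_problem(
        cohort.read_problem,
        os.path.join(outdir, "intact_l1_loci.tsv"),
        os.path.join(outdir, "read_assignments.tsv"),
    )
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(_plain(asdict(cfg)), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
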