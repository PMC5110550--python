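"""Synthetic matched normal/tumor TE-insertion cohort generator.

Produces a fully specified cohort — truth records, two emulated callers'
observed call sets, a population allele-frequency panel, genome features
and expression count tables — with the statistical structure the analysis
pipeline assumes:

* germline insertions shared across both tissues of a carrier patient and
  partially shared across patients, with panel-consistent Beta-distributed
  allele frequencies;
* somatic insertions private to one tissue of one patient, with a
  configurable tumor-biased excess of L1 events;
* two callers with positional jitter, false negatives and false
  positives, and a bimodal supporting-read distribution (a low-mean noise
  component for spurious calls, a negative-binomial component scaled to
  sequencing depth for real calls);
* paired expression counts with a tumor up-regulation effect confined to
  full-length intact L1 loci.

Truth loci are laid out on a grid of ``2 * min_spacing`` bins with offsets
inside the first half of each bin, which guarantees a minimum inter-locus
distance of ``min_spacing`` (500 bp by default) so the ±100 bp merge
window can never fuse two distinct truth loci.  False-positive calls are
placed in unused bins, hence also >= min_spacing from every truth locus.

A single global seed fans out to named child streams (truth layout,
caller observation, features, expression), so identical config + seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import InsertionCall, TE_FAMILIES
from .expression import ReadAssignmentProblem, TELocus
from .features import Enhancer, FeatureBundle, GeneModel
from .frequency import PanelEntry


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class SupportMixture:
    """Two-component supporting-read model.

    Real calls draw from a negative binomial with mean
    ``real_mean_ratio * mean_depth`` (a heterozygous insertion is covered
    by roughly half the discordant pairs at a site) and shape
    ``real_dispersion``; spurious calls draw from a Poisson with mean
    ``noise_mean``, putting most of their mass under the 5-read cutoff.
    """

    noise_mean: float = 2.0
    real_mean_ratio: float = 0.5
    real_dispersion: float = 8.0


@dataclass(frozen=True)
class ExpressionConfig:
    """Per-class count-distribution parameters for the expression tables."""

    n_genes: int = 2000
    gene_mean: float = 200.0
    gene_dispersion: float = 2.0
    te_family_mean: float = 5000.0
    te_family_dispersion: float = 5.0
    n_intact_l1: int = 145
    intact_l1_mean: float = 20.0
    intact_l1_dispersion: float = 3.0
    tumor_l1_log10_fc: float = 1.0
    em_n_reads: int = 2000
    em_multimap_rate: float = 0.3


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the analyzed regime: nine patients with matched
    normal and tumor whole genomes at ~40x depth, ~1000 polymorphic
    germline TE loci per cohort, tens of somatic insertions per sample
    split over Alu/L1/SVA, and a two-fold tumor excess of somatic L1
    events.  Somatic rates are expected events per sample per family.
    """

    n_patients: int = 9
    tissues: tuple[str, str] = ("normal", "tumor")
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 15_000_000),
        ("chr3", 10_000_000),
    )
    families: tuple[str, ...] = TE_FAMILIES
    family_weights: tuple[float, ...] = (0.85, 0.12, 0.03)
    n_germline_loci: int = 1000
    germline_af_beta: tuple[float, float] = (0.5, 2.0)
    n_panel_extra: int = 500
    somatic_rate_normal: float = 11.0
    somatic_rate_tumor: float = 11.0
    tumor_l1_multiplier: float = 2.0
    caller_jitter_sd: float = 15.0
    caller_fn_rate: float = 0.02
    caller_fp_rate: float = 0.05
    callers: tuple[str, str] = ("callerA", "callerB")
    support: SupportMixture = SupportMixture()
    mean_depth: float = 40.0
    min_spacing: int = 500
    merge_window: int = 100
    n_gene_models: int = 300
    n_enhancers: int = 200
    n_tumor_suppressors: int = 30
    expression: ExpressionConfig = ExpressionConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not self.families:
            raise ConfigError("family set must be non-empty")
        if len(self.family_weights) != len(self.families):
            raise ConfigError("family_weights must match families")
        if any(length <= 0 for _, length in self.genome) or not self.genome:
            raise ConfigError("genome chromosome lengths must be positive")
        for name, p in (
            ("caller_fn_rate", self.caller_fn_rate),
            ("caller_fp_rate", self.caller_fp_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.tumor_l1_multiplier < 1.0:
            raise ConfigError("tumor_l1_multiplier must be >= 1")
        if self.somatic_rate_normal < 0 or self.somatic_rate_tumor < 0:
            raise ConfigError("somatic rates must be non-negative")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.caller_jitter_sd < 0:
            raise ConfigError("caller_jitter_sd must be non-negative")
        if self.min_spacing < 1:
            raise ConfigError("min_spacing must be >= 1")

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]


@dataclass(frozen=True)
class TruthRecord:
    """A simulated insertion locus with its origin and carriers.

    Germline records carry both tissues of each carrier patient and have a
    panel allele frequency; somatic records carry exactly one tissue of
    exactly one patient and are absent from the panel.
    """

    chrom: str
    pos: int
    family: str
    origin: str  # "germline" | "somatic"
    carriers: tuple[tuple[str, str], ...]  # (patient_id, tissue)
    panel_af: float | None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    truth: list[TruthRecord]
    calls: list[InsertionCall]
    panel: list[PanelEntry]
    features: FeatureBundle
    expression: dict[str, pd.DataFrame]  # genes, te_families, intact_l1
    read_problem: ReadAssignmentProblem

    def calls_for(self, patient_id: str, tissue: str, caller_id: str) -> list[InsertionCall]:
        return [
            c
            for c in self.calls
            if c.sample_id == patient_id and c.tissue == tissue and c.caller_id == caller_id
        ]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{p}_{t}" for p in self.config.patient_ids for t in self.config.tissues
        ]


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _positions(
    rng: np.random.Generator, config: CohortConfig, n: int
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """Draw n loci on the spacing grid; returns (chrom,pos) plus used bin ids."""
    bin_width = 2 * config.min_spacing
    chrom_bins = [(name, length // bin_width) for name, length in config.genome]
    offsets_cum = np.cumsum([0] + [nb for _, nb in chrom_bins])
    total_bins = int(offsets_cum[-1])
    if n > total_bins:
        raise ConfigError(
            f"genome too small: need {n} loci but only {total_bins} spacing bins"
        )
    bins = rng.choice(total_bins, size=n, replace=False)
    offs = rng.integers(0, config.min_spacing, size=n)
    out: list[tuple[str, int]] = []
    for b, o in zip(bins, offs):
        ci = int(np.searchsorted(offsets_cum, b, side="right")) - 1
        local = int(b - offsets_cum[ci])
        out.append((chrom_bins[ci][0], local * bin_width + int(o) + 1))
    return out, np.asarray(bins), offsets_cum


def _simulate_truth(
    rng: np.random.Generator, config: CohortConfig
) -> tuple[list[TruthRecord], list[PanelEntry], np.ndarray, np.ndarray]:
    fams = list(config.families)
    weights = np.asarray(config.family_weights, dtype=float)
    weights = weights / weights.sum()
    a, b = config.germline_af_beta

    # somatic event counts per (patient, tissue, family)
    somatic_plan: list[tuple[str, str, str, int]] = []
    for patient in config.patient_ids:
        for tissue in config.tissues:
            base = (
                config.somatic_rate_normal
                if tissue == config.tissues[0]
                else config.somatic_rate_tumor
            )
            for fam in fams:
                rate = base
                if tissue == config.tissues[1] and fam == "L1":
                    rate *= config.tumor_l1_multiplier
                somatic_plan.append((patient, tissue, fam, int(rng.poisson(rate))))
    n_somatic = sum(k for *_, k in somatic_plan)
    n_total = config.n_germline_loci + config.n_panel_extra + n_somatic
    loci, used_bins, bin_cum = _positions(rng, config, n_total)

    truth: list[TruthRecord] = []
    panel: list[PanelEntry] = []
    cursor = 0

    # germline loci
    g_fams = rng.choice(len(fams), size=config.n_germline_loci, p=weights)
    g_afs = np.clip(rng.beta(a, b, size=config.n_germline_loci), 1e-6, 1.0)
    for i in range(config.n_germline_loci):
        chrom, pos = loci[cursor]
        cursor += 1
        fam = fams[int(g_fams[i])]
        af = float(g_afs[i])
        p_carrier = 1.0 - (1.0 - af) ** 2  # diploid: at least one allele
        carrier_mask = rng.random(config.n_patients) < p_carrier
        carriers = tuple(
            (p, t)
            for p, hit in zip(config.patient_ids, carrier_mask)
            if hit
            for t in config.tissues
        )
        truth.append(TruthRecord(chrom, pos, fam, "germline", carriers, af))
        panel.append(PanelEntry(chrom, pos, fam, af))

    # panel-only loci (known polymorphisms absent from this cohort)
    e_fams = rng.choice(len(fams), size=config.n_panel_extra, p=weights)
    e_afs = np.clip(rng.beta(a, b, size=config.n_panel_extra), 1e-6, 1.0)
    for i in range(config.n_panel_extra):
        chrom, pos = loci[cursor]
        cursor += 1
        panel.append(PanelEntry(chrom, pos, fams[int(e_fams[i])], float(e_afs[i])))

    # somatic loci
    for patient, tissue, fam, k in somatic_plan:
        for _ in range(k):
            chrom, pos = loci[cursor]
            cursor += 1
            truth.append(
                TruthRecord(chrom, pos, fam, "somatic", ((patient, tissue),), None)
            )
    return truth, panel, used_bins, bin_cum


def _simulate_calls(
    rng: np.random.Generator,
    config: CohortConfig,
    truth: Sequence[TruthRecord],
    used_bins: np.ndarray,
    bin_cum: np.ndarray,
) -> list[InsertionCall]:
    fams = list(config.families)
    weights = np.asarray(config.family_weights, dtype=float)
    weights = weights / weights.sum()
    bin_width = 2 * config.min_spacing
    chrom_names = [name for name, _ in config.genome]
    total_bins = int(bin_cum[-1])
    free_bins = np.setdiff1d(np.arange(total_bins), used_bins)

    carried: dict[tuple[str, str], list[TruthRecord]] = {
        (p, t): [] for p in config.patient_ids for t in config.tissues
    }
    for rec in truth:
        for p, t in rec.carriers:
            carried[(p, t)].append(rec)

    mix = config.support
    real_mean = mix.real_mean_ratio * config.mean_depth
    calls: list[InsertionCall] = []
    for patient in config.patient_ids:
        for tissue in config.tissues:
            recs = carried[(patient, tissue)]
            for caller in config.callers:
                n = len(recs)
                detected = rng.random(n) >= config.caller_fn_rate
                if config.caller_jitter_sd > 0:
                    jitter = np.rint(
                        rng.normal(0.0, config.caller_jitter_sd, size=n)
                    ).astype(np.int64)
                    jitter = np.clip(jitter, -config.merge_window, config.merge_window)
                else:
                    jitter = np.zeros(n, dtype=np.int64)
                support = _nb_counts(rng, real_mean, mix.real_dispersion, n)
                for i, rec in enumerate(recs):
                    if not detected[i]:
                        continue
                    calls.append(
                        InsertionCall(
                            chrom=rec.chrom,
                            pos=max(1, rec.pos + int(jitter[i])),
                            family=rec.family,
                            support_reads=int(support[i]),
                            caller_id=caller,
                            sample_id=patient,
                            tissue=tissue,
                        )
                    )
                # spurious calls, placed in bins unused by truth loci
                n_fp = int(rng.poisson(config.caller_fp_rate * n))
                if n_fp > 0 and len(free_bins) > 0:
                    fp_bins = rng.choice(free_bins, size=min(n_fp, len(free_bins)), replace=False)
                    fp_offs = rng.integers(0, config.min_spacing, size=len(fp_bins))
                    fp_fams = rng.choice(len(fams), size=len(fp_bins), p=weights)
                    fp_support = rng.poisson(mix.noise_mean, size=len(fp_bins))
                    for bidx, off, fi, sup in zip(fp_bins, fp_offs, fp_fams, fp_support):
                        ci = int(np.searchsorted(bin_cum, bidx, side="right")) - 1
                        local = int(bidx - bin_cum[ci])
                        calls.append(
                            InsertionCall(
                                chrom=chrom_names[ci],
                                pos=local * bin_width + int(off) + 1,
                                family=fams[int(fi)],
                                support_reads=int(sup),
                                caller_id=caller,
                                sample_id=patient,
                                tissue=tissue,
                            )
                        )
    return calls


def _simulate_features(rng: np.random.Generator, config: CohortConfig) -> FeatureBundle:
    chrom_names = [name for name, _ in config.genome]
    lengths = np.array([ln for _, ln in config.genome], dtype=float)
    probs = lengths / lengths.sum()

    genes: list[GeneModel] = []
    for i in range(config.n_gene_models):
        ci = int(rng.choice(len(chrom_names), p=probs))
        chrom, ln = config.genome[ci]
        span = int(rng.integers(5_000, 100_000))
        start = int(rng.integers(0, max(1, ln - span)))
        end = start + span
        n_exons = int(rng.integers(2, 9))
        seg = span // n_exons
        exons = []
        for k in range(n_exons):
            s0 = start + k * seg
            ex_len = int(rng.integers(80, min(500, seg)))
            ex_start = s0 + int(rng.integers(0, seg - ex_len))
            exons.append((ex_start, ex_start + ex_len))
        genes.append(
            GeneModel(
                gene_id=f"GENE{i + 1:04d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                tx_start=start,
                tx_end=end,
                exons=tuple(exons),
            )
        )

    enhancers: list[Enhancer] = []
    for i in range(config.n_enhancers):
        ln_e = int(rng.integers(500, 2000))
        if genes and i % 2 == 0:  # half placed upstream of a gene TSS
            g = genes[int(rng.integers(0, len(genes)))]
            offset = int(rng.integers(1_000, 50_000))
            start = g.tss - offset if g.strand == "+" else g.tss + offset
            chrom_len = dict(config.genome)[g.chrom]
            start = max(0, min(start, chrom_len - ln_e - 1))
            enhancers.append(Enhancer(g.chrom, start, start + ln_e))
        else:
            ci = int(rng.choice(len(chrom_names), p=probs))
            chrom, ln = config.genome[ci]
            start = int(rng.integers(0, ln - ln_e))
            enhancers.append(Enhancer(chrom, start, start + ln_e))

    n_tsg = min(config.n_tumor_suppressors, len(genes))
    tsg = set(
        genes[int(i)].gene_id
        for i in rng.choice(len(genes), size=n_tsg, replace=False)
    ) if genes else set()
    return FeatureBundle(genes=genes, enhancers=enhancers, tumor_suppressors=tsg)


def _simulate_expression(
    rng: np.random.Generator, config: CohortConfig
) -> tuple[dict[str, pd.DataFrame], ReadAssignmentProblem]:
    ec = config.expression
    samples = [f"{p}_{t}" for p in config.patient_ids for t in config.tissues]
    tumor_cols = [s for s in samples if s.endswith(config.tissues[1])]

    gene_ids = [f"GENE{i + 1:04d}" for i in range(ec.n_genes)]
    genes = pd.DataFrame(
        _nb_counts(rng, ec.gene_mean, ec.gene_dispersion, (ec.n_genes, len(samples))),
        index=gene_ids,
        columns=samples,
    )

    te = pd.DataFrame(
        _nb_counts(
            rng, ec.te_family_mean, ec.te_family_dispersion, (len(config.families), len(samples))
        ),
        index=list(config.families),
        columns=samples,
    )

    l1_ids = [f"L1_intact_{i + 1:04d}" for i in range(ec.n_intact_l1)]
    l1 = pd.DataFrame(0, index=l1_ids, columns=samples)
    fc = 10.0 ** ec.tumor_l1_log10_fc
    for s in samples:
        mean = ec.intact_l1_mean * (fc if s in tumor_cols else 1.0)
        l1[s] = _nb_counts(rng, mean, ec.intact_l1_dispersion, ec.n_intact_l1)

    # multi-mapper assignment problem over the intact L1 loci
    loci = [TELocus(lid, "L1", intact_l1=True) for lid in l1_ids]
    true_w = rng.dirichlet(np.ones(len(l1_ids)))
    reads = []
    origins = rng.choice(len(l1_ids), size=ec.em_n_reads, p=true_w)
    for r, o in enumerate(origins):
        cands = {l1_ids[int(o)]}
        if rng.random() < ec.em_multimap_rate:
            extra = rng.choice(len(l1_ids), size=int(rng.integers(1, 3)), replace=False)
            cands.update(l1_ids[int(e)] for e in extra)
        reads.append((f"r{r + 1:06d}", tuple(sorted(cands))))
    problem = ReadAssignmentProblem(loci=loci, reads=reads)

    tables = {"genes": genes, "te_families": te, "intact_l1": l1}
    return tables, problem


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate truth, observed calls, panel, features and expression tables."""
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_calls, rng_features, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    truth, panel, used_bins, bin_cum = _simulate_truth(rng_truth, config)
    calls = _simulate_calls(rng_calls, config, truth, used_bins, bin_cum)
    features = _simulate_features(rng_features, config)
    expression, problem = _simulate_expression(rng_expr, config)
    return SyntheticCohort(
        config=config,
        truth=truth,
        calls=calls,
        panel=panel,
        features=features,
        expression=expression,
        read_problem=problem,
    )


def error_free(config: CohortConfig) -> CohortConfig:
    """The same conditions with perfect callers (no FN/FP, no jitter)."""
    return replace(config, caller_fn_rate=0.0, caller_fp_rate=0.0, caller_jitter_sd=0.0)
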