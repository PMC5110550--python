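import pytest

from tesomatic import CohortConfig, ConsensusInsertion, InsertionCall, simulate_cohort


def make_call(
    pos,
    chrom="chr1",
    family="L1",
    support=20,
    caller="callerA",
    sample="P1",
    tissue="normal",
):
    return InsertionCall(
        chrom=chrom,
        pos=pos,
        family=family,
        support_reads=support,
        caller_id=caller,
        sample_id=sample,
        tissue=tissue,
    )


def make_consensus(pos, chrom="chr1", family="L1", support=20, sample="P1", tissue="normal"):
    return ConsensusInsertion(
        chrom=chrom,
        pos=pos,
        family=family,
        support_reads=support,
        sample_id=sample,
        tissue=tissue,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default nine-patient study conditions."""
    return simulate_cohort(CohortConfig(seed=20160929))


@pytest.fixture()
def small_config():
    """A reduced cohort for fast per-test simulation."""
    return CohortConfig(
        n_patients=3,
        n_germline_loci=200,
        n_panel_extra=50,
        somatic_rate_normal=5.0,
        somatic_rate_tumor=5.0,
        genome=(("chr1", 8_000_000), ("chr2", 6_000_000)),
        n_gene_models=60,
        n_enhancers=40,
        n_tumor_suppressors=10,
        seed=11,
    )
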