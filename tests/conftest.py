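import numpy as np
import pytest

from ketomr.pipeline import PipelineConfig
from ketomr.simulate import SyntheticScenario, generate_bundle
from ketomr.summary_data import GWASDataset, VariantAssociation


def make_assoc(
    variant_id="rs1",
    chrom="1",
    pos=100,
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=None,
    eaf=0.3,
    n=100_000,
):
    from ketomr.summary_data import derive_pvalue

    if pval is None:
        pval = derive_pvalue(beta, se)
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def default_bundle():
    """One realisation of the 5-archetype scenario, shared across tests."""
    return generate_bundle(SyntheticScenario(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=11)


@pytest.fixture
def tiny_dataset():
    """Four variants on one chromosome with distinct p-values."""
    assocs = [
        make_assoc("rs_a", pos=100, beta=0.5, se=0.05),
        make_assoc("rs_b", pos=200, beta=0.3, se=0.05),
        make_assoc("rs_c", pos=300, beta=0.2, se=0.05),
        make_assoc("rs_d", pos=400, beta=0.1, se=0.05),
    ]
    return GWASDataset("tiny", assocs)
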