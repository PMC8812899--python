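import numpy as np
import pytest

from ctmr.gwas_io import (
    HarmonizedPair,
    LDMatrix,
    SummaryStatsTable,
    VariantAssociation,
)


def make_variant(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=None,
    **kwargs,
):
    """A valid VariantAssociation with a p-value consistent with beta/se."""
    from scipy import stats

    if pvalue is None:
        pvalue = float(min(1.0, 2 * stats.norm.sf(abs(beta / se))))
        pvalue = max(pvalue, 5e-324)
    return VariantAssociation(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pairs():
    """Three harmonized pairs with a known non-trivial LD matrix."""
    pairs = [
        HarmonizedPair("s1", "A", "G", 0.30, 0.01, 0.045, 0.020),
        HarmonizedPair("s2", "C", "T", 0.22, 0.01, 0.020, 0.015),
        HarmonizedPair("s3", "A", "C", 0.40, 0.01, 0.070, 0.030),
    ]
    rho = np.array(
        [
            [1.0, 0.25, -0.10],
            [0.25, 1.0, 0.05],
            [-0.10, 0.05, 1.0],
        ]
    )
    ld = LDMatrix(["s1", "s2", "s3"], rho)
    return pairs, ld


@pytest.fixture
def exposure_table():
    return SummaryStatsTable(
        [
            make_variant("rs1", "A", "G", eaf=0.45, beta=-0.63, se=0.02, pvalue=1.53e-213),
            make_variant("rs2", "C", "T", eaf=0.93, beta=-0.55, se=0.05, pvalue=6.37e-24),
            make_variant("rs3", "C", "G", eaf=0.08, beta=-0.35, se=0.04, pvalue=1.06e-15),
            make_variant("rs4", "T", "G", eaf=0.97, beta=-0.46, se=0.07, pvalue=2.60e-10),
        ],
        trait_label="exposure",
    )
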