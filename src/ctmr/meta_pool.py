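"""Fixed-effects pooling of two GWAS of the same trait.

Implements the classical inverse-variance-weighted fixed-effects
meta-analysis (w_i = 1/se_i^2) used to combine two blood-pressure GWAS
before instrument selection, plus the concordance filter that retains only
variants whose effect direction agrees across both contributing studies and
whose pooled association is genome-wide significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .gwas_io import SummaryStatsTable, VariantAssociation

GENOME_WIDE_SIGNIFICANCE = 5.0e-8


def _two_sided_p_from_z(z: float) -> float:
    # Computed on the log scale first: |z| > 37 underflows the naive
    # 2*(1-Phi(|z|)) but published instruments reach p ~ 1e-213.
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def log10_two_sided_p(z: float) -> float:
    """log10 of the two-sided normal p-value, safe for very large |z|."""
    return float((stats.norm.logsf(abs(z)) + math.log(2.0)) / math.log(10.0))


@dataclass(frozen=True)
class PooledAssociation:
    """One SNP's inverse-variance pooled association across two GWAS."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_pooled: float
    se_pooled: float
    pvalue_pooled: float
    n_total: float
    beta_1: float
    beta_2: float
    log10_pvalue: float = 0.0

    @property
    def concordant(self) -> bool:
        """Same (nonzero) beta sign in both input GWAS."""
        return self.beta_1 * self.beta_2 > 0


def pool_fixed_effects(a: VariantAssociation, b: VariantAssociation) -> PooledAssociation:
    """Inverse-variance fixed-effects pooling of one SNP across two GWAS.

    Both inputs must already be aligned to the same effect allele; pooling
    differently oriented records is a harmonization error, not a statistics
    question, so it raises.
    """
    if a.snp_id != b.snp_id:
        raise ValueError(f"snp_id mismatch: {a.snp_id} vs {b.snp_id}")
    if (
        a.effect_allele.upper() != b.effect_allele.upper()
        or a.other_allele.upper() != b.other_allele.upper()
    ):
        raise ValueError(
            f"{a.snp_id}: allele mismatch "
            f"({a.effect_allele}/{a.other_allele} vs {b.effect_allele}/{b.other_allele}); "
            "harmonize before pooling"
        )
    w1, w2 = 1.0 / a.se**2, 1.0 / b.se**2
    beta = (w1 * a.beta + w2 * b.beta) / (w1 + w2)
    se = (w1 + w2) ** -0.5
    z = beta / se
    n_total = (a.n or 0.0) + (b.n or 0.0)
    return PooledAssociation(
        snp_id=a.snp_id,
        effect_allele=a.effect_allele.upper(),
        other_allele=a.other_allele.upper(),
        beta_pooled=beta,
        se_pooled=se,
        pvalue_pooled=_two_sided_p_from_z(z),
        n_total=n_total,
        beta_1=a.beta,
        beta_2=b.beta,
        log10_pvalue=log10_two_sided_p(z),
    )


def pool_tables(
    a: SummaryStatsTable, b: SummaryStatsTable
) -> list[PooledAssociation]:
    """Pool every SNP shared by two harmonized tables, in ``a``'s order."""
    out = []
    for rec in a:
        other = b.get(rec.snp_id)
        if other is not None:
            out.append(pool_fixed_effects(rec, other))
    return out


def concordance_filter(
    pooled: Iterable[PooledAssociation],
    gws_threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> list[PooledAssociation]:
    """Retain SNPs concordant across both GWAS and genome-wide significant.

    A beta of exactly zero in either study fails concordance (its sign is
    undefined).  Significance uses the log-scale p-value so that extreme
    associations (p far below float underflow) are retained correctly.
    """
    log10_threshold = math.log10(gws_threshold)
    return [
        p for p in pooled if p.concordant and p.log10_pvalue < log10_threshold
    ]


def pooled_to_table(
    pooled: Sequence[PooledAssociation],
    source_a: SummaryStatsTable,
    trait_label: str = "",
    trait_units: str = "",
) -> SummaryStatsTable:
    """Re-package pooled records as a summary-stats table.

    Positions, chromosome, and EAF are carried over from the first source
    GWAS (pooling does not change them materially for instrument selection).
    """
    records = []
    for p in pooled:
        src = source_a.get(p.snp_id)
        records.append(
            VariantAssociation(
                snp_id=p.snp_id,
                chrom=src.chrom if src else None,
                pos=src.pos if src else None,
                effect_allele=p.effect_allele,
                other_allele=p.other_allele,
                eaf=src.eaf if src else 0.5,
                beta=p.beta_pooled,
                se=p.se_pooled,
                pvalue=max(p.pvalue_pooled, 5e-324),
                n=p.n_total or None,
            )
        )
    return SummaryStatsTable(records, trait_label=trait_label, trait_units=trait_units)
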