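"""Bundled reference tables.

The package ships the published characteristics of the blood-pressure-lowering
variants used to proxy inhibition of three antihypertensive drug targets:
angiotensin-converting enzyme (ACE, 14 serum-ACE-concentration SNPs), the
beta-1 adrenergic receptor (ADRB1, 8 SBP SNPs), and the sodium-chloride
symporter (NCC/SLC12A3, 1 SBP SNP).  Betas are per additional copy of the
effect allele: SD of serum ACE concentration for the ACE instrument, mm Hg
of systolic blood pressure for ADRB1 and NCC.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gwas_io import SummaryStatsTable, VariantAssociation

_UNITS = {"ACE": "SD serum ACE", "ADRB1": "mm Hg SBP", "NCC": "mm Hg SBP"}


def load_instrument_variants(target: str | None = None) -> pd.DataFrame:
    """The bundled drug-target instrument table, optionally one target."""
    with resources.files("ctmr.data").joinpath("antihypertensive_instruments.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if target is not None:
        df = df[df["TARGET"] == target].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown target {target!r}")
    return df


def instrument_table(target: str) -> SummaryStatsTable:
    """The bundled instrument for one target as a summary-stats table."""
    df = load_instrument_variants(target)
    records = [
        VariantAssociation(
            snp_id=row.SNP,
            effect_allele=row.EA,
            other_allele=row.NEA,
            eaf=float(row.EAF),
            beta=float(row.BETA),
            se=float(row.SE),
            pvalue=float(row.P),
        )
        for row in df.itertuples(index=False)
    ]
    return SummaryStatsTable(records, trait_label=target, trait_units=_UNITS[target])
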