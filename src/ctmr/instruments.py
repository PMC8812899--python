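"""Cis instrument construction for protein drug targets.

A drug-target instrument is the set of variants in or near the gene encoding
the target that are strongly associated with the exposure (the target's
activity or a downstream trait such as systolic blood pressure), pruned so
that all retained pairs are in weak linkage disequilibrium.  Strength
diagnostics (variance explained r^2 and the F-statistic) guard against weak
instrument bias: F >= 10 is the conventional heuristic for "not weak".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .gwas_io import LDMatrix, SummaryStatsTable, VariantAssociation

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 100_000
DEFAULT_P_THRESHOLD = 5.0e-8
DEFAULT_R2_MAX = 0.10
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic footprint plus a symmetric cis flank."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start > end")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")

    @property
    def cis_start(self) -> int:
        return self.start - self.window_bp

    @property
    def cis_end(self) -> int:
        return self.end + self.window_bp

    def contains(self, chrom: str | None, pos: int | None) -> bool:
        """Closed-interval membership of a position in the cis window."""
        if chrom is None or pos is None:
            return False
        return str(chrom) == str(self.chrom) and self.cis_start <= pos <= self.cis_end


@dataclass
class Instrument:
    """Pruned cis variant set for one target with LD and strength diagnostics."""

    target: str
    exposure_label: str
    variants: list[VariantAssociation]
    ld: LDMatrix
    r2_total: float
    f_stat: float
    n_gwas: float
    r2_mode: str = "eaf_beta"

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"{self.target}: instrument has no variants")
        if [v.snp_id for v in self.variants] != self.ld.snp_ids:
            raise ValueError(f"{self.target}: LD matrix order mismatch")
        if not (0.0 <= self.r2_total < 1.0):
            raise ValueError(f"{self.target}: r2_total must be in [0, 1)")

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    @property
    def weak(self) -> bool:
        return self.f_stat < WEAK_INSTRUMENT_F


def select_cis_candidates(
    stats_table: SummaryStatsTable,
    region: GeneRegion,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[VariantAssociation]:
    """Genome-wide-significant variants inside the gene's cis window.

    The window is closed on both ends: a SNP exactly ``window_bp`` away from
    the gene boundary is retained.  Results are sorted by ascending p-value
    (ties: smaller SE first, then snp_id) — the order the greedy pruner needs.
    """
    if not any(str(r.chrom) == str(region.chrom) for r in stats_table if r.chrom):
        logger.warning(
            "no variants on chromosome %s for region %s", region.chrom, region.gene_symbol
        )
    hits = [
        r
        for r in stats_table
        if region.contains(r.chrom, r.pos) and r.pvalue < p_threshold
    ]
    hits.sort(key=lambda r: (r.pvalue, r.se, r.snp_id))
    return hits


def ld_prune_greedy(
    candidates: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[VariantAssociation]:
    """Greedy p-value-ranked LD pruning (clumping-style).

    Sweeps candidates from most to least significant, accepting a SNP only
    if its r^2 with every already-accepted SNP is strictly below ``r2_max``
    (r^2 exactly at the threshold is pruned).  Deterministic given the input
    order; always retains the most significant candidate.
    """
    ordered = sorted(candidates, key=lambda r: (r.pvalue, r.se, r.snp_id))
    kept: list[VariantAssociation] = []
    for cand in ordered:
        ok = True
        for acc in kept:
            i = ld.snp_ids.index(cand.snp_id)
            j = ld.snp_ids.index(acc.snp_id)
            if ld.r[i, j] ** 2 >= r2_max:
                ok = False
                break
        if ok:
            kept.append(cand)
    return kept


def variance_explained(
    variant: VariantAssociation,
    mode: Literal["eaf_beta", "z_n"] = "eaf_beta",
    n: float | None = None,
) -> float:
    """Proportion of exposure variance explained by one variant.

    ``eaf_beta``: r^2 = 2 f (1-f) beta^2, valid when beta is on a
    unit-variance (standardized) trait.  ``z_n``: r^2 = z^2 / (z^2 + n - 2)
    with z the two-sided normal quantile of the p-value — the univariable
    regression identity, usable when only p and n are published.
    """
    if mode == "eaf_beta":
        f = variant.eaf
        return float(2.0 * f * (1.0 - f) * variant.beta**2)
    if mode == "z_n":
        n = n if n is not None else variant.n
        if n is None or n <= 2:
            raise ValueError("z_n mode requires sample size n > 2")
        z = stats.norm.isf(variant.pvalue / 2.0)
        return float(z**2 / (z**2 + n - 2.0))
    raise ValueError(f"unknown mode {mode!r}")


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """First-stage F-statistic from total variance explained.

    F = r^2 (n - k - 1) / ((1 - r^2) k) for an instrument of k variants
    explaining r^2 of the exposure variance in a GWAS of n individuals.
    """
    if not (0.0 <= r2_total < 1.0):
        raise ValueError("r2_total must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return float(r2_total * (n - k - 1) / ((1.0 - r2_total) * k))


def total_variance_explained(
    variants: Sequence[VariantAssociation],
    mode: Literal["eaf_beta", "z_n"] = "eaf_beta",
    n: float | None = None,
    ld: LDMatrix | None = None,
) -> float:
    """Instrument-level r^2.

    By default per-SNP contributions are summed — a good approximation for
    panels pruned to weak LD.  Supplying ``ld`` instead deflates the sum via
    the quadratic form s' R^{-1} s of per-SNP correlations with the trait,
    which accounts for the residual correlation between variants.
    """
    per_snp = np.array([variance_explained(v, mode=mode, n=n) for v in variants])
    if ld is None:
        return float(min(per_snp.sum(), 1.0 - 1e-12))
    s = np.sqrt(per_snp) * np.sign([v.beta for v in variants])
    rinv = np.linalg.pinv(ld.r)
    return float(min(s @ rinv @ s, 1.0 - 1e-12))


def build_instrument(
    stats_table: SummaryStatsTable,
    region: GeneRegion,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_R2_MAX,
    r2_mode: Literal["eaf_beta", "z_n"] = "eaf_beta",
    n_gwas: float | None = None,
    target: str | None = None,
) -> Instrument:
    """Select, prune, and diagnose a cis instrument in one call."""
    candidates = select_cis_candidates(stats_table, region, p_threshold)
    if not candidates:
        raise ValueError(
            f"no genome-wide-significant cis candidates for {region.gene_symbol}"
        )
    kept = ld_prune_greedy(candidates, ld, r2_max)
    return _assemble(
        kept, ld, stats_table.trait_label, r2_mode, n_gwas,
        target or region.gene_symbol,
    )


def instrument_from_variants(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix,
    exposure_label: str = "",
    r2_mode: Literal["eaf_beta", "z_n"] = "eaf_beta",
    n_gwas: float | None = None,
    target: str = "",
) -> Instrument:
    """Wrap an externally chosen variant list (e.g. a published table)."""
    return _assemble(list(variants), ld, exposure_label, r2_mode, n_gwas, target)


def _assemble(
    kept: list[VariantAssociation],
    ld: LDMatrix,
    exposure_label: str,
    r2_mode: str,
    n_gwas: float | None,
    target: str,
) -> Instrument:
    ids = [v.snp_id for v in kept]
    sub_ld = ld.subset(ids)
    if n_gwas is None:
        ns = [v.n for v in kept if v.n is not None]
        n_gwas = float(max(ns)) if ns else float("nan")
    r2 = total_variance_explained(kept, mode=r2_mode, n=n_gwas)
    f = f_statistic(r2, n_gwas, len(kept)) if np.isfinite(n_gwas) else float("nan")
    return Instrument(
        target=target,
        exposure_label=exposure_label,
        variants=kept,
        ld=sub_ld,
        r2_total=r2,
        f_stat=f,
        n_gwas=n_gwas,
        r2_mode=r2_mode,
    )


def restrict_to_eqtls(instrument: Instrument, eqtl_ids: set[str]) -> Instrument:
    """Sensitivity filter: keep only variants with eQTL support; re-diagnose.

    Raises when no instrument variant has eQTL evidence — an instrument with
    zero variants is meaningless and must not propagate silently.
    """
    if not eqtl_ids:
        raise ValueError("eqtl_ids must be non-empty")
    kept = [v for v in instrument.variants if v.snp_id in eqtl_ids]
    if not kept:
        raise ValueError(f"{instrument.target}: no eQTL-supported variants")
    return _assemble(
        kept,
        instrument.ld,
        instrument.exposure_label,
        instrument.r2_mode,
        instrument.n_gwas,
        instrument.target,
    )


def read_gene_regions(
    path, window_bp: int = DEFAULT_WINDOW_BP, zero_based: bool = False
) -> list[GeneRegion]:
    """Read BED-like (chrom, start, end, gene_symbol) region definitions.

    ``zero_based=True`` treats starts as BED 0-based half-open and converts
    to the 1-based closed convention used throughout.
    """
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_symbol"],
        comment="#",
    )
    regions = []
    for row in df.itertuples(index=False):
        start = int(row.start) + 1 if zero_based else int(row.start)
        regions.append(
            GeneRegion(
                gene_symbol=str(row.gene_symbol),
                chrom=str(row.chrom),
                start=start,
                end=int(row.end),
                window_bp=window_bp,
            )
        )
    return regions
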