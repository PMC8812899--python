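"""Bayesian colocalization of two traits in a genomic region.

Tests, via per-variant approximate Bayes factors and enumeration of causal
configurations under a single-causal-variant-per-trait assumption, which of
five hypotheses the regional data support:

    H0 — neither trait has a genetic association in the region
    H1 / H2 — only trait 1 / only trait 2 is associated
    H3 — both associated, different causal variants
    H4 — both associated, one shared causal variant

Per-variant evidence uses the Wakefield approximate Bayes factor
log ABF = 1/2 log(1 - r) + r z^2 / 2 with r = W/(V + W), V the squared
standard error and W the squared prior effect SD.  All sums over
configurations run in log space (log-sum-exp), so regions with |z| of 40+
remain finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .gwas_io import SummaryStatsTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 300_000
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.20
SUPPORT_THRESHOLD = 0.80

TraitType = Literal["quantitative", "case_control"]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class RegionalStats:
    """Per-SNP association summaries for one trait within region bounds."""

    snp_ids: list[str]
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    trait_type: TraitType = "quantitative"
    region_start: int | None = None
    region_end: int | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        m = len(self.snp_ids)
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate snp_ids in region")
        if not (len(self.pos) == len(self.beta) == len(self.se) == m):
            raise ValueError("regional arrays must share one length")
        if np.any(self.se <= 0):
            raise ValueError("all SEs must be positive")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    def subset(self, snp_ids: Sequence[str]) -> "RegionalStats":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return RegionalStats(
            snp_ids=list(snp_ids),
            pos=self.pos[idx],
            beta=self.beta[idx],
            se=self.se[idx],
            trait_type=self.trait_type,
            region_start=self.region_start,
            region_end=self.region_end,
        )


@dataclass
class ColocResult:
    """Posterior probabilities of H0–H4 plus the evidence they came from."""

    pp: dict[str, float]
    priors: tuple[float, float, float]
    n_snps: int
    log_abf_trait1: np.ndarray = field(repr=False, default=None)
    log_abf_trait2: np.ndarray = field(repr=False, default=None)
    snp_ids: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")
        if any(not (0.0 <= v <= 1.0) for v in self.pp.values()):
            raise ValueError("each posterior must lie in [0, 1]")

    def supports(self, hypothesis: str, threshold: float = SUPPORT_THRESHOLD) -> bool:
        return self.pp[hypothesis] >= threshold


def define_region(
    stats_table: SummaryStatsTable,
    top_snp: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    trait_type: TraitType = "quantitative",
) -> RegionalStats:
    """Regional slice of a summary-stats table around a sentinel SNP.

    Retains SNPs within ``window_bp`` of the sentinel's position (closed
    interval); the sentinel itself is always retained.
    """
    top = stats_table.get(top_snp)
    if top is None:
        raise KeyError(f"top SNP {top_snp!r} not found in table")
    if top.pos is None:
        raise ValueError(f"top SNP {top_snp!r} has no position")
    lo, hi = top.pos - window_bp, top.pos + window_bp
    kept = [
        r
        for r in stats_table
        if r.snp_id == top_snp
        or (
            r.pos is not None
            and lo <= r.pos <= hi
            and (top.chrom is None or r.chrom == top.chrom)
        )
    ]
    return RegionalStats(
        snp_ids=[r.snp_id for r in kept],
        pos=np.array([r.pos for r in kept]),
        beta=np.array([r.beta for r in kept]),
        se=np.array([r.se for r in kept]),
        trait_type=trait_type,
        region_start=lo,
        region_end=hi,
    )


def log_abf(
    beta: float | np.ndarray,
    se: float | np.ndarray,
    prior_sd: float,
) -> float | np.ndarray:
    """Wakefield log approximate Bayes factor for a single association.

    r = W / (V + W) with V = se^2, W = prior_sd^2, z = beta/se:
    log ABF = 1/2 log(1 - r) + r z^2 / 2.  A point-null prior (prior_sd = 0)
    gives log ABF = 0 for any data.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * r * z**2
    return float(out) if out.ndim == 0 else out


def default_prior_sd(trait_type: TraitType) -> float:
    return PRIOR_SD_CASE_CONTROL if trait_type == "case_control" else PRIOR_SD_QUANTITATIVE


def coloc_posteriors(
    trait1: RegionalStats,
    trait2: RegionalStats,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities of the five regional hypotheses.

    The analysis is restricted to SNPs shared by both traits (a logged count
    of dropped SNPs is emitted).  Unnormalized hypothesis weights over the
    shared panel of J SNPs, with BF1_j, BF2_j the per-SNP Bayes factors:

        L0 = 1
        L1 = p1  * sum_j BF1_j
        L2 = p2  * sum_j BF2_j
        L3 = p1 p2 * (sum_j BF1_j * sum_k BF2_k - sum_j BF1_j BF2_j)
        L4 = p12 * sum_j BF1_j BF2_j

    computed entirely in log space.
    """
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0:
        raise ValueError("priors must be positive")
    shared = [s for s in trait1.snp_ids if s in set(trait2.snp_ids)]
    if not shared:
        raise ValueError("no shared SNPs between traits")
    n_dropped = (len(trait1) - len(shared)) + (len(trait2) - len(shared))
    if n_dropped:
        logger.info("coloc: %d SNPs present in only one trait dropped", n_dropped)
    t1 = trait1.subset(shared)
    t2 = trait2.subset(shared)

    sd1 = prior_sd1 if prior_sd1 is not None else default_prior_sd(t1.trait_type)
    sd2 = prior_sd2 if prior_sd2 is not None else default_prior_sd(t2.trait_type)
    labf1 = np.asarray(log_abf(t1.beta, t1.se, sd1))
    labf2 = np.asarray(log_abf(t2.beta, t2.se, sd2))

    log_s1 = float(logsumexp(labf1))          # log sum_j BF1_j
    log_s2 = float(logsumexp(labf2))          # log sum_j BF2_j
    log_s12 = float(logsumexp(labf1 + labf2))  # log sum_j BF1_j BF2_j

    log_l = np.empty(5)
    log_l[0] = 0.0
    log_l[1] = math.log(p1) + log_s1
    log_l[2] = math.log(p2) + log_s2
    # sum over ordered distinct pairs: sum_j sum_{k != j} BF1_j BF2_k
    log_cross = log_s1 + log_s2
    if log_s12 >= log_cross:  # single shared SNP: the distinct-pair sum is 0
        log_l[3] = -np.inf
    else:
        log_l[3] = (
            math.log(p1) + math.log(p2)
            + log_cross
            + math.log1p(-math.exp(log_s12 - log_cross))
        )
    log_l[4] = math.log(p12) + log_s12

    log_total = logsumexp(log_l)
    pp = np.exp(log_l - log_total)
    pp = pp / pp.sum()
    return ColocResult(
        pp=dict(zip(HYPOTHESES, (float(x) for x in pp))),
        priors=(p1, p2, p12),
        n_snps=len(shared),
        log_abf_trait1=labf1,
        log_abf_trait2=labf2,
        snp_ids=shared,
    )


def prior_sensitivity(
    trait1: RegionalStats,
    trait2: RegionalStats,
    p12_grid: Sequence[float] = (1e-6, 5e-6, 1e-5, 5e-5, 1e-4),
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    **kwargs,
) -> list[tuple[float, ColocResult]]:
    """PP.H4 as a function of the shared-causal-variant prior p12."""
    return [
        (p12, coloc_posteriors(trait1, trait2, priors=(p1, p2, p12), **kwargs))
        for p12 in p12_grid
    ]
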