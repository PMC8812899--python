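"""Synthetic cohorts with known ground truth for every pipeline stage.

Genotypes come from a Gaussian-copula model: a latent multivariate normal
with AR(1) correlation ld_rho^|i-j| is thresholded per variant at the
Hardy-Weinberg quantiles of its allele frequency, producing 0/1/2 dosages
with controllable pairwise LD.  This gives direct control of LD at desk
scale; it does not reproduce haplotype block structure or rare recombinant
haplotypes.

Exposure cohorts follow an additive model X_i = sum_j beta_j g_ij + eps_i
with the noise variance chosen so Var(X) = 1; binary outcomes follow a
logistic model on X with the intercept tuned by bisection to hit a target
case fraction.  What the generators emit are *marginal* per-SNP summary
statistics — linear for the exposure, logistic for the outcome — matching
what GWAS consortia publish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .coloc import RegionalStats
from .gwas_io import LDMatrix, SummaryStatsTable, VariantAssociation
from .grs import ExpressionPanel

DEFAULT_CHROM = "1"
DEFAULT_POS_START = 1_000_000
DEFAULT_POS_STEP = 10_000


@dataclass
class StudyConfig:
    """Parameters of one synthetic exposure -> binary-outcome study."""

    n: int = 20_000
    m: int = 8
    eafs: np.ndarray | None = None            # default: evenly spread in [0.1, 0.5]
    ld_rho: float = 0.3
    snp_effects: np.ndarray | None = None     # joint per-allele exposure effects
    theta: float = 0.1                        # causal log-odds per exposure unit
    case_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eafs is None:
            self.eafs = np.linspace(0.1, 0.5, self.m)
        self.eafs = np.asarray(self.eafs, dtype=float)
        if self.snp_effects is None:
            # modest, realistic per-allele effects on a unit-variance exposure
            self.snp_effects = np.full(self.m, 0.08)
        self.snp_effects = np.asarray(self.snp_effects, dtype=float)
        if len(self.eafs) != self.m or len(self.snp_effects) != self.m:
            raise ValueError("eafs and snp_effects must have length m")
        if np.any((self.eafs <= 0) | (self.eafs >= 1)):
            raise ValueError("eafs must lie strictly inside (0, 1)")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")


def _snp_ids(m: int) -> list[str]:
    return [f"rs{i+1}" for i in range(m)]


def _positions(m: int) -> np.ndarray:
    return DEFAULT_POS_START + DEFAULT_POS_STEP * np.arange(m)


def simulate_genotypes_ld(
    n: int,
    eafs: Sequence[float],
    ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """0/1/2 dosage matrix (n x m) with AR(1) latent LD.

    The latent normal for variant j is generated recursively,
    z_j = rho z_{j-1} + sqrt(1 - rho^2) e_j, then cut at the Hardy-Weinberg
    quantiles of eaf_j: P(0) = (1-f)^2, P(1) = 2f(1-f), P(2) = f^2.
    """
    eafs = np.asarray(eafs, dtype=float)
    m = len(eafs)
    z = np.empty((n, m))
    e = rng.standard_normal((n, m))
    z[:, 0] = e[:, 0]
    scale = math.sqrt(1.0 - ld_rho**2)
    for j in range(1, m):
        z[:, j] = ld_rho * z[:, j - 1] + scale * e[:, j]
    # per-variant HWE cutpoints on the latent scale
    p0 = (1.0 - eafs) ** 2
    p1 = 2.0 * eafs * (1.0 - eafs)
    t0 = stats.norm.ppf(p0)
    t1 = stats.norm.ppf(p0 + p1)
    g = (z > t0).astype(float) + (z > t1)
    return g


def empirical_ld(genotypes: np.ndarray, snp_ids: Sequence[str] | None = None) -> LDMatrix:
    """Signed LD correlation matrix from a dosage matrix."""
    r = np.corrcoef(genotypes, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    ids = list(snp_ids) if snp_ids is not None else _snp_ids(genotypes.shape[1])
    return LDMatrix(ids, r)


def _marginal_linear(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression of y on each genotype column.

    Returns (beta, se, p) vectors; closed-form least squares per column.
    """
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    beta = gc.T @ yc / sxx
    resid_ss = (yc**2).sum() - beta**2 * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    z = beta / se
    # normal rather than t reference: the GWAS summary-stat convention, and
    # indistinguishable at the cohort sizes simulated here
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, 5e-324, 1.0)


def _marginal_logistic(
    g: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression (intercept + dosage), all SNPs at once.

    Newton-Raphson on the 2-parameter model, vectorized across SNPs; the
    2x2 information matrix is inverted in closed form.  Matches a standard
    one-SNP-at-a-time maximum-likelihood fit to solver precision.
    """
    n, m = g.shape
    a = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a + g * b  # broadcasting: (n, m)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        # score components
        s0 = r.sum(axis=0)
        s1 = (g * r).sum(axis=0)
        # information matrix entries
        i00 = w.sum(axis=0)
        i01 = (w * g).sum(axis=0)
        i11 = (w * g**2).sum(axis=0)
        det = i00 * i11 - i01**2
        da = (i11 * s0 - i01 * s1) / det
        db = (i00 * s1 - i01 * s0) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    eta = a + g * b
    mu = expit(eta)
    w = mu * (1.0 - mu)
    i00 = w.sum(axis=0)
    i01 = (w * g).sum(axis=0)
    i11 = (w * g**2).sum(axis=0)
    det = i00 * i11 - i01**2
    se = np.sqrt(i00 / det)
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return b, se, np.clip(p, 5e-324, 1.0)


def _table_from_arrays(
    beta: np.ndarray,
    se: np.ndarray,
    p: np.ndarray,
    eafs: np.ndarray,
    n: float,
    trait_label: str,
    trait_units: str,
) -> SummaryStatsTable:
    m = len(beta)
    ids = _snp_ids(m)
    pos = _positions(m)
    records = [
        VariantAssociation(
            snp_id=ids[j],
            chrom=DEFAULT_CHROM,
            pos=int(pos[j]),
            effect_allele="A",
            other_allele="G",
            eaf=float(eafs[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(p[j]),
            n=n,
        )
        for j in range(m)
    ]
    return SummaryStatsTable(records, trait_label=trait_label, trait_units=trait_units)


def _tune_intercept(x: np.ndarray, theta: float, case_fraction: float) -> float:
    """Bisection for the logistic intercept hitting the target case fraction."""
    lo, hi = -50.0, 50.0

    def mean_risk(alpha: float) -> float:
        return float(np.mean(expit(alpha + theta * x)))

    if not (mean_risk(lo) < case_fraction < mean_risk(hi)):
        raise ValueError("case_fraction unreachable for this theta and exposure")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_risk(mid) < case_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_exposure_cohort(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    g = simulate_genotypes_ld(config.n, config.eafs, config.ld_rho, rng)
    genetic = g @ config.snp_effects
    var_gen = float(genetic.var())
    if var_gen >= 1.0:
        raise ValueError("genetic variance exceeds 1; reduce snp_effects")
    x = genetic + rng.normal(scale=math.sqrt(1.0 - var_gen), size=config.n)
    return g, x


def simulate_exposure_outcome_study(
    config: StudyConfig,
    sampling: Literal["cohort", "ascertained"] = "cohort",
    design: Literal["two_sample", "one_sample"] = "two_sample",
) -> tuple[SummaryStatsTable, SummaryStatsTable, dict]:
    """One exposure GWAS + one binary-outcome GWAS over a shared variant panel.

    The default design is two-sample: the exposure GWAS and the outcome GWAS
    are computed on independently drawn cohorts of size n over the same
    variant panel, mirroring the non-overlapping consortia that publish such
    statistics (a one-sample option exists for studying the correlated-error
    bias that sample overlap induces).  Returns (exposure table, outcome
    table, truth); ``truth`` carries the causal log-odds effect theta, the
    joint and implied marginal per-SNP exposure effects, the empirical LD
    matrix of the exposure cohort, and the raw arrays.

    By default outcome summary statistics are computed on the full outcome
    cohort; ``sampling="ascertained"`` instead analyses all cases plus an
    equal-size random control sample (for studying non-collapsibility).
    """
    rng = np.random.default_rng(config.seed)
    g_exp, x_exp = _draw_exposure_cohort(config, rng)
    bx, sx, px = _marginal_linear(g_exp, x_exp)

    if design == "two_sample":
        g_out, x_out = _draw_exposure_cohort(config, rng)
    else:
        g_out, x_out = g_exp, x_exp
    alpha = _tune_intercept(x_out, config.theta, config.case_fraction)
    risk = expit(alpha + config.theta * x_out)
    y = (rng.random(config.n) < risk).astype(float)

    if sampling == "ascertained":
        cases = np.flatnonzero(y == 1)
        controls = np.flatnonzero(y == 0)
        n_ctrl = min(len(cases), len(controls))
        keep = np.concatenate([cases, rng.choice(controls, size=n_ctrl, replace=False)])
        gy, yy = g_out[keep], y[keep]
    else:
        gy, yy = g_out, y
    by, sy, py = _marginal_logistic(gy, yy)

    eaf_hat = g_exp.mean(axis=0) / 2.0
    exposure = _table_from_arrays(bx, sx, px, eaf_hat, config.n, "exposure", "SD")
    outcome = _table_from_arrays(
        by, sy, py, gy.mean(axis=0) / 2.0, len(yy), "outcome", "log-odds"
    )
    # marginal exposure effects implied by the joint effects and genotype LD
    gcov = np.cov(g_exp, rowvar=False)
    beta_marginal = gcov @ config.snp_effects / np.diag(gcov)
    truth = {
        "theta": config.theta,
        "alpha": alpha,
        "snp_effects_joint": config.snp_effects.copy(),
        "snp_effects_marginal": beta_marginal,
        "ld": empirical_ld(g_exp),
        "case_fraction": float(y.mean()),
        "genotypes": g_exp,
        "exposure": x_exp,
        "outcome": y,
    }
    return exposure, outcome, truth


def simulate_coloc_region_pair(
    scenario: Literal["shared", "distinct", "null"],
    n_per_trait: int = 5_000,
    m: int = 50,
    ld_rho: float = 0.5,
    effect: float = 0.25,
    seed: int = 0,
) -> tuple[RegionalStats, RegionalStats]:
    """Regional summary statistics for two traits with known causal structure.

    ``shared``: one causal SNP drives both traits; ``distinct``: two causal
    SNPs far enough apart that their latent correlation is < 0.3, one per
    trait; ``null``: no causal SNP.  The two traits' statistics come from
    independently drawn cohorts over the same variant panel.
    """
    if scenario == "distinct" and m < 3:
        raise ValueError("distinct scenario needs m >= 3")
    rng = np.random.default_rng(seed)
    eafs = rng.uniform(0.1, 0.5, size=m)

    if scenario == "shared":
        c1 = c2 = m // 2
    elif scenario == "distinct":
        c1, c2 = 0, m - 1
        if ld_rho ** abs(c2 - c1) >= 0.3:
            raise ValueError("causal sites too correlated for a distinct scenario")
    else:
        c1 = c2 = None

    def one_trait(causal: int | None, sub_rng: np.random.Generator) -> RegionalStats:
        g = simulate_genotypes_ld(n_per_trait, eafs, ld_rho, sub_rng)
        gen = effect * g[:, causal] if causal is not None else 0.0
        noise_var = 1.0 - (np.var(gen) if causal is not None else 0.0)
        y = gen + sub_rng.normal(scale=math.sqrt(max(noise_var, 0.05)), size=n_per_trait)
        beta, se, _ = _marginal_linear(g, y)
        return RegionalStats(
            snp_ids=_snp_ids(m),
            pos=_positions(m),
            beta=beta,
            se=se,
            trait_type="quantitative",
        )

    t1 = one_trait(c1, np.random.default_rng(rng.integers(2**31)))
    t2 = one_trait(c2, np.random.default_rng(rng.integers(2**31)))
    return t1, t2


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset 0.375)."""
    ranks = stats.rankdata(values)
    n = len(values)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def simulate_expression_panel(
    n: int = 445,
    n_snps: int = 14,
    weights: np.ndarray | None = None,
    gene_effects: np.ndarray | Sequence[float] | None = None,
    n_genes: int | None = None,
    covariate_effects: Sequence[float] = (0.2, 0.1),
    eafs: np.ndarray | None = None,
    ld_rho: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionPanel, dict]:
    """Expression panel whose genes load on a genotype-driven score.

    Each gene's raw expression is gene_effect * standardized score +
    covariate contributions + Gaussian noise with variance chosen so the
    raw expression has unit variance; every gene is then inverse-normal
    transformed, as expression pipelines do before per-gene regression.
    Returns the panel plus a truth dict (planted per-gene effects, raw score).
    """
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = rng.normal(scale=0.3, size=n_snps)
    weights = np.asarray(weights, dtype=float)
    n_snps = len(weights)
    if eafs is None:
        eafs = rng.uniform(0.1, 0.5, size=n_snps)
    if gene_effects is None:
        if n_genes is None:
            raise ValueError("provide gene_effects or n_genes")
        gene_effects = np.zeros(n_genes)
    gene_effects = np.asarray(gene_effects, dtype=float)
    n_genes = len(gene_effects)
    cov_fx = np.asarray(covariate_effects, dtype=float)

    g = simulate_genotypes_ld(n, eafs, ld_rho, rng)
    raw_score = g @ weights
    sd = raw_score.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate score: zero variance")
    score_std = (raw_score - raw_score.mean()) / sd

    n_cov = len(cov_fx)
    covariates = rng.standard_normal((n, n_cov)) if n_cov else np.empty((n, 0))
    noise_var = 1.0 - gene_effects**2 - float(cov_fx @ cov_fx)
    if np.any(noise_var <= 0):
        raise ValueError("gene/covariate effects too large for unit-variance expression")
    raw = (
        np.outer(score_std, gene_effects)
        + covariates @ np.outer(cov_fx, np.ones(n_genes))
        + rng.standard_normal((n, n_genes)) * np.sqrt(noise_var)
    )
    expr = np.apply_along_axis(inverse_normal_transform, 0, raw)

    sample_ids = [f"S{i+1}" for i in range(n)]
    panel = ExpressionPanel(
        sample_ids=sample_ids,
        dosages=pd.DataFrame(g, index=sample_ids, columns=_snp_ids(n_snps)),
        expression=pd.DataFrame(
            expr, index=sample_ids, columns=[f"gene{k+1}" for k in range(n_genes)]
        ),
        covariates=pd.DataFrame(
            covariates, index=sample_ids, columns=[f"cov{c+1}" for c in range(n_cov)]
        ),
    )
    truth = {
        "weights": weights,
        "gene_effects": gene_effects,
        "raw_score": raw_score,
        "covariate_effects": cov_fx,
    }
    return panel, truth
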