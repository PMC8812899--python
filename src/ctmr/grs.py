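"""Weighted genetic risk scores and transcriptome-wide association scans.

A weighted genetic risk score (wGRS) summarizes an individual's genotype as
the dosage-weighted sum of per-allele effect weights.  The transcriptome
scan regresses each gene's (already inverse-normal-transformed) expression
on the standardized score plus user-supplied covariates — sex, genotype
principal components, batch, hidden expression factors, tissue location —
by ordinary least squares, with Bonferroni control across genes.  A simple
upper-tail hypergeometric test covers gene-set over-representation of the
scan's hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HITS_P = 5.0e-3  # scan p-value filter feeding enrichment analysis


@dataclass
class GRSWeights:
    """Per-allele effect weights over an ordered SNP panel."""

    snp_ids: list[str]
    weights: np.ndarray
    orientation_note: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.snp_ids):
            raise ValueError("weights and snp_ids must have equal length")
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("duplicate snp_ids in weights")
        if not np.any(self.weights != 0):
            raise ValueError("at least one weight must be nonzero")


@dataclass
class ExpressionPanel:
    """Samples x SNP dosages, samples x genes expression, samples x covariates."""

    sample_ids: list[str]
    dosages: pd.DataFrame      # samples x SNPs, values in [0, 2]
    expression: pd.DataFrame   # samples x genes
    covariates: pd.DataFrame   # samples x C (may have zero columns)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name, df in (
            ("dosages", self.dosages),
            ("expression", self.expression),
            ("covariates", self.covariates),
        ):
            if len(df) != n:
                raise ValueError(f"{name} has {len(df)} rows; expected {n} samples")
        if self.dosages.isna().any().any():
            # per-SNP mean imputation: the standard scoring convention
            self.dosages = self.dosages.fillna(self.dosages.mean())

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass
class TWASResult:
    """Per-gene score coefficients with Bonferroni significance flags."""

    table: pd.DataFrame  # index: gene; columns: beta, se, pvalue, significant
    alpha: float
    n_genes: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_genes

    def hits(self, p_threshold: float = DEFAULT_HITS_P) -> list[str]:
        return list(self.table.index[self.table["pvalue"] < p_threshold])

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def build_wgrs(
    panel: ExpressionPanel,
    weights: GRSWeights,
    standardize: bool = True,
) -> np.ndarray:
    """Per-sample weighted genetic risk score.

    score_i = sum_j w_j dosage_ij, optionally centered and scaled to unit SD
    (the scale on which per-SD regression coefficients are reported).
    """
    missing = [s for s in weights.snp_ids if s not in panel.dosages.columns]
    if missing:
        raise KeyError(f"weight SNPs absent from dosage matrix: {missing}")
    g = panel.dosages[weights.snp_ids].to_numpy(dtype=float)
    score = g @ weights.weights
    if standardize:
        sd = score.std(ddof=1)
        if sd == 0:
            raise ValueError("raw score has zero variance; cannot standardize")
        score = (score - score.mean()) / sd
    return score


def twas_scan(
    panel: ExpressionPanel,
    score: np.ndarray,
    alpha: float = 0.05,
) -> TWASResult:
    """OLS of every gene's expression on the score plus covariates.

    All genes share one design matrix [intercept | score | covariates], so
    the scan is a single batched least-squares solve; per-gene standard
    errors come from each gene's own residual variance with n - p degrees of
    freedom.  The reported coefficient is per SD of the score when the score
    was standardized.
    """
    score = np.asarray(score, dtype=float)
    n = panel.n_samples
    if len(score) != n:
        raise ValueError("score length does not match panel samples")
    cov = panel.covariates.to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), score] + ([cov] if cov.size else []))
    p = design.shape[1]
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        _name_collinear(design, panel.covariates.columns)
    if n <= p:
        raise ValueError(f"too few samples ({n}) for {p} design columns")

    y = panel.expression.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = xtx_inv @ design.T @ y                     # p x G
    resid = y - design @ coef
    sigma2 = (resid**2).sum(axis=0) / (n - p)         # per-gene residual variance
    se = np.sqrt(xtx_inv[1, 1] * sigma2)
    beta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    pvals = np.clip(pvals, 5e-324, 1.0)

    g = panel.expression.shape[1]
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "pvalue": pvals,
            "significant": pvals < alpha / g,
        },
        index=panel.expression.columns,
    )
    return TWASResult(table=table, alpha=alpha, n_genes=g)


def _name_collinear(design: np.ndarray, cov_names) -> None:
    """Raise naming which covariate columns are linearly dependent."""
    names = ["intercept", "score"] + list(cov_names)
    keep: list[int] = []
    dependent: list[str] = []
    for i in range(design.shape[1]):
        cols = keep + [i]
        if np.linalg.matrix_rank(design[:, cols]) == len(cols):
            keep.append(i)
        else:
            dependent.append(names[i])
    raise ValueError(f"rank-deficient covariates; collinear columns: {dependent}")


def hypergeometric_enrichment(
    hits: set[str],
    gene_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns the observed overlap |hits ∩ gene_set| and the probability of
    drawing at least that many gene-set members in |hits| draws without
    replacement from the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    overlap = len(hits & gene_set)
    # P(X >= overlap), X ~ Hypergeom(M=|universe|, K=|gene_set|, n=|hits|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(hits)))
    return overlap, min(p, 1.0)


def enrichment_scan(
    hits: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric test of every gene set, with Bonferroni adjustment."""
    rows = []
    m = len(gene_sets)
    for name, members in gene_sets.items():
        members = members & universe
        overlap, p = hypergeometric_enrichment(hits, members, universe)
        rows.append(
            {
                "gene_set": name,
                "n_set": len(members),
                "n_overlap": overlap,
                "pvalue": p,
                "p_adjusted": min(1.0, p * m),
                "significant": p < alpha / m,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Samples x SNPs dosage matrix from tab-delimited text (first col = sample)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression from tab-delimited text, transposed on load."""
    return pd.read_csv(path, sep="\t", index_col=0).T
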