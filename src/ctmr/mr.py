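"""Summary-data mendelian randomization estimators.

The workhorse is the LD-adjusted inverse-variance-weighted (IVW) estimator:
a generalized weighted regression of variant-outcome betas on
variant-exposure betas through the origin, with weight matrix
Omega = D rho D built from the outcome standard errors D and the signed LD
correlation matrix rho.  A multiplicative random-effects scale phi inflates
the standard error under over-dispersion of variant-level estimates and is
floored at 1 under under-dispersion (the residual standard error is never
allowed below the fixed-effects value).

Inference is normal-theory throughout (p-values and 95% CIs from the
standard normal), the convention for summary-data MR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedPair, LDMatrix

Z_95 = float(stats.norm.ppf(0.975))

Orientation = Literal["per_unit_lower_exposure", "per_unit_higher_exposure"]


@dataclass(frozen=True)
class MREstimate:
    """A causal effect on the outcome's log-odds scale per exposure unit."""

    theta: float
    se_theta: float
    pvalue: float
    phi: float
    j: int
    method: str
    orientation: Orientation = "per_unit_higher_exposure"

    def __post_init__(self) -> None:
        if not (self.se_theta > 0):
            raise ValueError("se_theta must be > 0")
        if self.phi < 1.0 - 1e-12:
            raise ValueError("phi is floored at 1")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.theta - Z_95 * self.se_theta)

    @property
    def ci_high(self) -> float:
        return math.exp(self.theta + Z_95 * self.se_theta)

    def flipped(self) -> "MREstimate":
        """The same estimate per unit *lower* exposure (theta negated)."""
        new_orientation = (
            "per_unit_lower_exposure"
            if self.orientation == "per_unit_higher_exposure"
            else "per_unit_higher_exposure"
        )
        return replace(self, theta=-self.theta, orientation=new_orientation)

    def format_or_ci(self, digits: int = 2) -> str:
        return (
            f"{self.odds_ratio:.{digits}f} "
            f"({self.ci_low:.{digits}f}–{self.ci_high:.{digits}f})"
        )


@dataclass
class MRInputSet:
    """Harmonized exposure/outcome pairs plus their LD, ready for IVW."""

    pairs: list[HarmonizedPair]
    ld: LDMatrix
    orientation: Orientation = "per_unit_higher_exposure"

    def __post_init__(self) -> None:
        if len(self.ld) != len(self.pairs):
            raise ValueError(
                f"LD dimension {len(self.ld)} != number of pairs {len(self.pairs)}"
            )
        if self.ld.snp_ids != [p.snp_id for p in self.pairs]:
            raise ValueError("LD matrix order must match pair order")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def bx(self) -> np.ndarray:
        return np.array([p.beta_exposure for p in self.pairs])

    @property
    def by(self) -> np.ndarray:
        return np.array([p.beta_outcome for p in self.pairs])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([p.se_outcome for p in self.pairs])

    def drop(self, snp_id: str) -> "MRInputSet":
        kept = [p for p in self.pairs if p.snp_id != snp_id]
        if len(kept) == len(self.pairs):
            raise KeyError(snp_id)
        return MRInputSet(kept, self.ld.subset([p.snp_id for p in kept]), self.orientation)


def _p_from_z(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-variant causal estimate: beta_outcome / beta_exposure.

    The standard error is first-order delta method, se_outcome/|beta_exposure|,
    which ignores uncertainty in the exposure association — adequate for the
    strong instruments this estimator is used with.
    """
    if pair.beta_exposure == 0:
        raise ValueError(f"{pair.snp_id}: undefined ratio (beta_exposure = 0)")
    theta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return MREstimate(
        theta=theta,
        se_theta=se,
        pvalue=_p_from_z(theta / se),
        phi=1.0,
        j=1,
        method="wald",
    )


def ivw_correlated(input_set: MRInputSet) -> MREstimate:
    """LD-adjusted IVW estimate with a multiplicative random-effects scale.

    With bx, by the exposure/outcome betas and Omega = D rho D:

        theta_hat = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by
        v         = (bx' Omega^-1 bx)^-1
        phi_hat^2 = (by - theta bx)' Omega^-1 (by - theta bx) / (j - 1)
        se        = sqrt(v) * max(1, phi_hat)

    With an identity LD matrix this reduces exactly to classical
    independent-variant IVW; with j = 1 it equals the Wald ratio.
    """
    j = len(input_set)
    if j == 0:
        raise ValueError("empty input set")
    if j == 1:
        est = wald_ratio(input_set.pairs[0])
        return replace(est, method="ivw_correlated", orientation=input_set.orientation)

    bx, by = input_set.bx, input_set.by
    d = input_set.se_outcome
    omega = np.outer(d, d) * input_set.ld.r
    try:
        omega_inv = np.linalg.inv(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular weight matrix Omega (collinear LD?)") from exc

    precision = float(bx @ omega_inv @ bx)
    if precision <= 0:
        raise ValueError("non-positive precision; check inputs")
    theta = float(bx @ omega_inv @ by) / precision
    v = 1.0 / precision
    resid = by - theta * bx
    phi_hat = math.sqrt(max(float(resid @ omega_inv @ resid), 0.0) / (j - 1))
    phi = max(1.0, phi_hat)
    se = math.sqrt(v) * phi
    return MREstimate(
        theta=theta,
        se_theta=se,
        pvalue=_p_from_z(theta / se),
        phi=phi,
        j=j,
        method="ivw_correlated",
        orientation=input_set.orientation,
    )


def scale_odds_ratio(estimate: MREstimate, scale: float) -> MREstimate:
    """Rescale an estimate to a multiple of the exposure unit.

    Everything is linear on the log-odds scale: theta, its SE, and hence the
    CI bounds are all multiplied by ``scale`` (e.g. 8 to express a per-1-mm-Hg
    effect as the effect of the blood-pressure lowering seen in trials).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    theta = estimate.theta * scale
    se = estimate.se_theta * scale
    return replace(estimate, theta=theta, se_theta=se, pvalue=_p_from_z(theta / se))


def leave_one_out(input_set: MRInputSet) -> list[tuple[str, MREstimate]]:
    """Re-estimate excluding each variant in turn (influence diagnostics)."""
    if len(input_set) < 2:
        raise ValueError("nothing to leave out (need j >= 2)")
    out = []
    for pair in input_set.pairs:
        out.append((pair.snp_id, ivw_correlated(input_set.drop(pair.snp_id))))
    return out


def mvmr_correlated(
    bx_matrix: np.ndarray,
    by: np.ndarray,
    se_outcome: np.ndarray,
    ld: LDMatrix,
    exposure_labels: Sequence[str] | None = None,
) -> list[MREstimate]:
    """Multivariable MR: joint estimation of E exposures from j variants.

    theta_hat = (B' Omega^-1 B)^-1 B' Omega^-1 by, with per-exposure SEs from
    the diagonal of (B' Omega^-1 B)^-1, inflated by phi = max(1, phi_hat)
    where phi_hat^2 uses residual degrees of freedom j - E.
    """
    b = np.atleast_2d(np.asarray(bx_matrix, dtype=float))
    by = np.asarray(by, dtype=float)
    se_outcome = np.asarray(se_outcome, dtype=float)
    j, n_exp = b.shape
    if n_exp < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")
    if j <= n_exp:
        raise ValueError(f"need more variants ({j}) than exposures ({n_exp})")
    if np.linalg.matrix_rank(b) < n_exp:
        raise ValueError("collinear exposures: bx_matrix is rank-deficient")

    omega = np.outer(se_outcome, se_outcome) * ld.r
    omega_inv = np.linalg.inv(omega)
    gram = b.T @ omega_inv @ b
    cov_unscaled = np.linalg.inv(gram)
    theta = cov_unscaled @ (b.T @ omega_inv @ by)
    resid = by - b @ theta
    phi_hat = math.sqrt(max(float(resid @ omega_inv @ resid), 0.0) / (j - n_exp))
    phi = max(1.0, phi_hat)

    labels = list(exposure_labels or [f"exposure_{i+1}" for i in range(n_exp)])
    estimates = []
    for e in range(n_exp):
        se = math.sqrt(cov_unscaled[e, e]) * phi
        estimates.append(
            MREstimate(
                theta=float(theta[e]),
                se_theta=se,
                pvalue=_p_from_z(theta[e] / se),
                phi=phi,
                j=j,
                method=f"mvmr:{labels[e]}",
            )
        )
    return estimates


@dataclass(frozen=True)
class EvidenceTier:
    label: str
    pvalue: float
    tier: Literal["strong", "weak", "little"]


def apply_multiplicity(
    estimates: Mapping[str, MREstimate] | Mapping[str, float],
    alpha: float = 0.05,
    weak_upper: float = 0.20,
    n_tests: int | None = None,
) -> list[EvidenceTier]:
    """Bonferroni evidence tiers across a family of tests.

    The significance threshold is alpha / (number of tests).  Results below
    it are "strong" evidence; those between the threshold and ``weak_upper``
    are "weak"; the rest "little".  ``n_tests`` overrides the family size
    when the supplied collection is a subset of a larger prespecified family.
    """
    if not estimates:
        raise ValueError("empty estimate collection")
    m = n_tests if n_tests is not None else len(estimates)
    threshold = alpha / m
    tiers = []
    for label, est in estimates.items():
        p = est.pvalue if isinstance(est, MREstimate) else float(est)
        if p < threshold:
            tier = "strong"
        elif p < weak_upper:
            tier = "weak"
        else:
            tier = "little"
        tiers.append(EvidenceTier(label=label, pvalue=p, tier=tier))
    return tiers


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def make_input_set(
    pairs: Iterable[HarmonizedPair],
    ld: LDMatrix,
    orientation: Orientation = "per_unit_higher_exposure",
) -> MRInputSet:
    """Build an MRInputSet, subsetting/reordering the LD matrix to the pairs."""
    pairs = list(pairs)
    sub = ld.subset([p.snp_id for p in pairs])
    return MRInputSet(pairs, sub, orientation)
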