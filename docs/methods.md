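# Methods

This note records the models implemented by `ctmr`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for reproducing results.

## Summary-statistic model and harmonization

All estimators consume per-variant summary associations: effect-allele,
other-allele, effect-allele frequency, beta, standard error, p-value, and
(optionally) sample size. Harmonization aligns an outcome record to the
exposure's effect allele by exact label match, by label swap (beta negated,
frequency complemented), or — for non-palindromic pairs only — by strand
complementation followed by the same two rules. Palindromic variants (A/T,
C/G) cannot be strand-resolved from labels; they are dropped when the
outcome effect-allele frequency lies within 0.5 ± 0.08. The 0.08 half-width
is the common harmonization default; it is configurable, and the ambiguity
is assessed in the outcome table because the exposure GWAS (being the
instrument source) is usually the better-curated dataset. Any allele pair
that matches none of the rules is reported as incompatible — nothing is
dropped silently.

Reported p-values are checked against |beta/se| on the log10 scale and a
warning (never a rejection) is emitted when they disagree by more than one
order of magnitude, since published tables round beta and SE heavily.

LD enters as a signed correlation matrix r (not r²): the sign changes the
quadratic forms materially, so supplying unsigned r² is an error rather
than a guess. Matrices are symmetrized, and indefinite inputs (common after
subsetting reference-panel estimates) are repaired by clipping negative
eigenvalues to zero and rescaling to a unit diagonal; the repair is logged.
Missing pairs in long-format LD input default to r = 0, which is
appropriate only for post-pruning panels — hence the logged warning.

## Pooling and instrument construction

Two GWAS of the same trait are pooled per SNP by fixed-effects
inverse-variance weighting: w_i = 1/se_i², pooled beta Σw_iβ_i/Σw_i, pooled
SE (Σw_i)^{-1/2}, two-sided normal p. P-values are computed on the log
scale (`norm.logsf`) because instruments reach |z| > 30, where the plain
survival function underflows. A variant passes the concordance filter only
if both input betas share a nonzero sign and the pooled association is
genome-wide significant (P < 5×10⁻⁸); a beta of exactly zero fails
(its sign is undefined — conservative). The two conditions commute, so the
order the filters are applied in is immaterial.

Cis candidates are variants inside the gene footprint extended by a
±100 kb flank — a closed interval measured from the gene's start and end,
not its midpoint — passing the significance threshold. Pruning is greedy
and p-value-ranked (clumping-style): sweep candidates from most to least
significant, keep a variant only if its r² with every kept variant is
strictly below 0.10 (a pair at exactly 0.10 is pruned). Ties on p break by
smaller SE, then lexicographic id, so the sweep is deterministic. Greedy
clumping was chosen because it always retains the top signal and is a
fixed point of itself; it does not attempt conditional analysis or
fine-mapping.

Instrument strength: per-variant variance explained is 2f(1−f)β² on a
standardized trait, or z²/(z²+n−2) when only p and n are published (the
univariable-regression identity, with n−2 in the denominator).
Instrument-level r² sums per-variant contributions by default — accurate
under weak post-pruning LD — with an optional LD-adjusted quadratic form
s'R⁻¹s for correlated panels. F = r²(n−k−1)/((1−r²)k) with the variant
count k exposed explicitly, since published F values are sensitive to the k
convention used.

## MR estimation

The LD-adjusted IVW estimator is generalized least squares through the
origin with weight matrix Ω = D ρ D (D = diag outcome SEs):

    θ̂ = (bx' Ω⁻¹ bx)⁻¹ bx' Ω⁻¹ by,  v = (bx' Ω⁻¹ bx)⁻¹.

Dispersion of variant-level estimates is absorbed multiplicatively:
φ̂² = residual quadratic form / (j−1), and se(θ̂) = √v · max(1, φ̂). The
floor implements the convention that under-dispersion must not shrink the
standard error below its fixed-effects value; over-dispersion inflates it.
With identity ρ the estimator reduces exactly to classical independent
IVW; with j = 1 to the Wald ratio by/bx, whose SE uses the first-order
delta method se_out/|bx| (exposure uncertainty ignored — adequate for
strong instruments, anti-conservative for weak ones).

Multivariable MR generalizes to θ̂ = (B'Ω⁻¹B)⁻¹B'Ω⁻¹by for a j×E matrix of
exposure betas, with residual degrees of freedom j−E (the standard
weighted-regression convention) and the same φ floor. Rank-deficient B is
rejected as collinear rather than silently regularized.

Inference throughout uses the standard normal (not t) for p-values and 95%
CIs — the summary-data MR convention. Estimates are computed per unit
*higher* exposure internally; `MREstimate.flipped()` negates θ for the
per-unit-lower (inhibition) framing, and `scale_odds_ratio` multiplies θ,
SE, and CI bounds by a positive scale on the log-odds scale (e.g. ×8 to
restate a per-1-mm-Hg effect as a trial-sized blood-pressure reduction).
Evidence tiers follow a Bonferroni rule: p < α/m is "strong", p < 0.20
"weak", otherwise "little".

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½log(1−r) + rz²/2, r = W/(V+W), with prior effect SDs W^½
defaulting to 0.15 for quantitative traits and 0.20 for case-control
(log-odds) traits. Configuration priors default to p1 = p2 = 1×10⁻⁴,
p12 = 1×10⁻⁵ — the standard single-causal-variant coloc defaults — and a
p12 sensitivity sweep is provided because PP(H4) can be prior-driven in
weak regions. Hypothesis weights are the standard sums over configurations
(one causal variant per trait at most), evaluated entirely in log space via
log-sum-exp so |z| of 40+ stays finite. The analysis is restricted to the
SNPs shared by both traits, with a logged count of those dropped. The
single-causal-variant assumption is a stated limitation: regions with
secondary signals dilute PP(H4), and conditional/masked colocalization is
out of scope.

## Weighted-GRS transcriptome scan

The score is the dosage-weighted sum of per-allele effect weights,
standardized to unit SD so that gene-level coefficients are per SD of
score. Missing dosages are mean-imputed per SNP before scoring. The scan is
one batched OLS: all genes share the design [intercept | score |
covariates], so coefficients for every gene come from a single solve, and
per-gene SEs use each gene's own residual variance with n−p degrees of
freedom (t reference). Covariates — sex, genotype PCs, batch, hidden
expression factors, tissue site — are accepted as a user-supplied matrix
and are not estimated here; rank deficiency is an error that names the
collinear columns. Hits (default p < 5×10⁻³) feed an upper-tail
hypergeometric over-representation test per gene set, Bonferroni-adjusted
across sets.

## Synthetic-data generator

Genotypes: a Gaussian copula. A latent AR(1) normal (parameter ld_rho) is
thresholded per variant at the Hardy–Weinberg quantiles of its allele
frequency, giving 0/1/2 dosages whose pairwise LD decays geometrically.
This gives direct, cheap control of LD at desk scale. It does **not**
reproduce haplotype-block structure, allele-frequency–LD coupling,
population stratification, relatedness, or imputation noise — so passing
recovery tests demonstrate estimator correctness under the stated model,
not robustness to those real-data features.

Studies: exposure X = Σβ_j g_j + ε with ε scaled so Var(X) = 1; binary
outcomes from a logistic model α + θX with α found by bisection to hit the
target case fraction (default 0.3). The default study conditions are
n = 20,000 per cohort, m = 8 variants with per-allele effects 0.08 on the
unit-variance exposure (per-SNP F ≈ 30–60, comfortably "strong"), latent
LD 0.3, θ = 0.1. The generator is **two-sample by default**: exposure and
outcome summary statistics come from independently drawn cohorts, matching
the non-overlapping consortia that publish such data. A one-sample option
exists deliberately: with a shared cohort the correlated sampling errors of
bx and by bias the IVW ratio upward by several percent at these sample
sizes, which is itself a known phenomenon worth demonstrating, but it is
not the design being emulated. Emitted statistics are marginal per-SNP
regressions (closed-form linear for the exposure; 2-parameter Newton
logistic for the outcome, vectorized across SNPs and verified against a
general-purpose maximum-likelihood fit in the tests), because marginal
associations are what consortia publish. The marginal ORs are
non-collapsible: they attenuate slightly relative to the conditional θ, an
effect bounded well under 10% at these settings and visible in the
recovery studies.

Regional pairs for colocalization draw two independent cohorts of 5,000
over the same 50-variant panel, with one shared causal variant, two
distinct causal variants at latent correlation < 0.3, or none. Expression
panels (default n = 445, 14 score SNPs) plant per-gene effects on the
standardized score plus Gaussian covariates, with residual variance chosen
so raw expression has unit variance, then apply a rank-based inverse normal
transform (Blom offset) per gene — so a planted effect of −0.42 is
approximately preserved on the analyzed scale.

All generators are deterministic given a seed and diverge across seeds.

## Problem sizes used in the checks

The recovery suites run at the sizes stated above: 200 studies
(400 in the acceptance script, to halve the Monte-Carlo error on the bias
estimate) of n = 20,000 for IVW bias and coverage; 100 replicates per
colocalization scenario at n = 5,000 per trait; 100 expression panels of
n = 445 plus one 1,000-gene null panel; 1,000 random 3–10-variant fixtures
for the GLS-oracle comparison; exhaustive hypergeometric enumeration up to
universe size 25.

## Known limitations

- The delta-method Wald SE and the normal inference are first-order; with
  very weak instruments both are anti-conservative.
- Instrument-level r² by summation overstates strength when pruning leaves
  residual LD; use the LD-adjusted variant for correlated panels.
- Colocalization assumes at most one causal variant per trait per region.
- The genotype model's limitations (above) mean simulation-based guarantees
  transfer to real data only insofar as the additive-marginal summary-stat
  abstraction holds.
- The pipeline's coloc stage triggers at nominal p < 0.05 per
  target×outcome, mirroring common practice; this is a screening rule, not
  an error-rate guarantee.
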