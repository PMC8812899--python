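# ctmr — drug-target cis mendelian randomization

`ctmr` is a Python toolkit for asking whether long-term pharmacological
modulation of a protein drug target would change the risk of a disease,
using only published GWAS summary statistics. Naturally occurring variants
in or near the gene encoding a target (cis variants) shift the target's
activity for a lifetime; treating them as instrumental variables lets the
effect of "genetically proxied inhibition" of the target on a binary
outcome be estimated without individual-level data. The motivating use case
is antihypertensive targets — angiotensin-converting enzyme (ACE), the β-1
adrenergic receptor (ADRB1), and the sodium-chloride symporter (NCC) —
against common cancer outcomes, and the package ships the published
characteristics of those instruments, but every component is generic.

The package is aimed at genetic epidemiologists and methodologists who want
the full pipeline — instrument construction, estimation, and sensitivity
analysis — as composable, tested functions, with a synthetic-data generator
so that every stage can be exercised against known ground truth.

## What it computes

**Instrument construction.** Two GWAS of the same trait are pooled by
inverse-variance fixed-effects meta-analysis (weights $w_i = 1/\mathrm{se}_i^2$),
with a concordance filter keeping only variants whose effect direction
agrees in both studies. Cis candidates are genome-wide-significant variants
($P < 5\times10^{-8}$) within ±100 kb of the gene, pruned by greedy
p-value-ranked clumping to pairwise $r^2 < 0.10$. Instrument strength is
diagnosed by variance explained, $r^2 = 2f(1-f)\beta^2$ (or
$z^2/(z^2+n-2)$ from a p-value), and the F-statistic
$F = r^2(n-k-1)/\big((1-r^2)k\big)$, with $F \ge 10$ the usual
"not weak" heuristic.

**Estimation.** After harmonizing exposure and outcome records to a common
effect allele (sign flips for swapped alleles, strand-complement matching,
and removal of palindromic SNPs with ambiguous allele frequencies), the
causal log-odds effect per exposure unit is estimated by LD-adjusted
inverse-variance-weighted regression through the origin:

$$\hat\theta = (b_x^\top \Omega^{-1} b_x)^{-1} b_x^\top \Omega^{-1} b_y,
\qquad \Omega = D\,\rho\,D,$$

where $b_x, b_y$ are variant–exposure and variant–outcome betas, $D$ the
diagonal of outcome standard errors, and $\rho$ the signed LD correlation
matrix. A multiplicative random-effects scale
$\hat\phi^2 = (b_y-\hat\theta b_x)^\top\Omega^{-1}(b_y-\hat\theta b_x)/(j-1)$
inflates the standard error under over-dispersion and is floored at 1.
Single-variant instruments reduce to the Wald ratio $b_y/b_x$. Sensitivity
machinery includes leave-one-out re-estimation, multivariable MR
(joint exposures via the same generalized-least-squares form), rescaling of
estimates to clinically meaningful exposure differences, and Bonferroni
evidence tiers.

**Colocalization.** Whether the exposure and the outcome share a single
causal variant in a region is assessed with Wakefield approximate Bayes
factors, $\log\mathrm{ABF} = \tfrac12\log(1-r) + r z^2/2$ with
$r = W/(V+W)$, enumerated over causal configurations into posterior
probabilities of hypotheses H0–H4; PP(H4) ≥ 0.80 is read as support for a
shared variant.

**Transcriptome scan.** A weighted genetic risk score
$s_i=\sum_j w_j g_{ij}$ proxies the exposure in an expression panel; each
gene's (inverse-normal-transformed) expression is regressed on the
standardized score plus covariates, with Bonferroni control across genes
and upper-tail hypergeometric tests for gene-set over-representation of the
hits.

## Worked example

Simulate a two-sample study with a known causal effect and estimate it:

```python
import numpy as np
from ctmr import (StudyConfig, simulate_exposure_outcome_study,
                  harmonize_pair, ivw_correlated, leave_one_out)
from ctmr.mr import make_input_set

cfg = StudyConfig(n=20_000, m=8, theta=0.3, snp_effects=np.full(8, 0.15), seed=7)
exposure, outcome, truth = simulate_exposure_outcome_study(cfg)

harm = harmonize_pair(exposure, outcome)
inp = make_input_set(harm.pairs, truth["ld"])
est = ivw_correlated(inp)
print(f"IVW: theta = {est.theta:.4f} (SE {est.se_theta:.4f}), phi = {est.phi:.3f}, j = {est.j}")
print(f"OR per 1-unit higher exposure: {est.format_or_ci()}   p = {est.pvalue:.2g}")
print(f"OR per 1-unit lower exposure : {est.flipped().format_or_ci()}")
```

prints

```
IVW: theta = 0.3183 (SE 0.0454), phi = 1.000, j = 8
OR per 1-unit higher exposure: 1.37 (1.26–1.50)   p = 2.3e-12
OR per 1-unit lower exposure : 0.73 (0.67–0.80)
```

The estimate 0.318 sits within one standard error of the planted log-odds
effect 0.3; `phi = 1.000` means the eight variant-level estimates are not
over-dispersed, so the fixed-effects standard error is reported. The flipped
odds ratio expresses the same effect per unit *lower* exposure — the
inhibition framing used when a variant lowers a drug target's activity.
Leave-one-out ORs for this fixture range 1.36–1.42, i.e. no single variant
drives the estimate.

The same analysis runs from the shell against files:

```bash
ctmr simulate --scenario study --n 20000 --m 8 --theta 0.3 --outdir sim/
ctmr mr sim/exposure.tsv sim/outcome.tsv --ld sim/ld.tsv --loo
ctmr run config.yaml          # full pipeline: pool → instrument → MR → coloc → report
```

Published instrument tables are bundled:

```python
from ctmr.datasets import instrument_table
ace = instrument_table("ACE")   # 14 serum-ACE cis variants with betas, SEs, EAFs
```

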