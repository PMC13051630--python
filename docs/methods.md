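# Methods

## The generative model behind the synthetic panels

`simdata` emulates the study system the analysis assumes: a diversity panel
of highly homozygous inbred accessions, a subset of which is test-crossed
into F1 hybrids, phenotyped for correlated positive-valued traits over
several years.

**Genotypes.** Each locus draws a population alternate-allele frequency
uniformly from `maf_range` (default 0.05–0.5, matching an MAF > 0.05 SNP
panel). Inbreds are homozygous (±1) by a Bernoulli draw at that frequency,
with a small residual heterozygosity rate (default 0.01 — inbred lines are
never perfectly fixed). Loci whose realized MAF does not exceed the lower
bound are redrawn for a bounded number of rounds, so the delivered panel is
genuinely polymorphic. True F1 genotypes follow Mendelian gamete sampling:
homozygous parents contribute their fixed allele, heterozygous parents one
allele uniformly.

**Trait architecture.** A trait is
`g_i = intercept + Σ_k a_k x_ik + Σ_k d_k·1[x_ik = 0]`
over a QTL subset of the loci. Additive effects are standard-normal draws
rescaled to unit additive variance in a random-mating (HWE) population at the
panel allele frequencies. Dominance effects are half-normal magnitudes with a
configurable sign (default positive — directional dominance), concentrated on
a fraction of the QTLs (default 0.1), and scaled so that in an HWE population
`Var(Σ d_k·1[het]) / Var(Σ a_k x_k)` equals `dominance_ratio`.

Two choices here deserve justification:

- *Where dominance is measured.* Dominance barely expresses in an inbred
  panel (almost no heterozygotes), so scaling it against the inbreds would be
  ill-defined. The ratio is instead defined in the random-mating population at
  the same allele frequencies — the population the F1s approximate — using
  the raw component variances above rather than the classical orthogonal
  partition. The raw definition is directly computable from the generated
  effects and genotypes, which is how the tests verify it.
- *Concentrated, directional dominance.* Genome-wide directional dominance
  makes every F1 beat its better parent (the summed dominance lift has a huge
  mean relative to its spread). Complementation of recessive defects at a few
  specific loci — the standard interpretation of heterosis in a selfing crop —
  concentrates the same dominance variance on few loci, producing realistic
  mixtures of non-, medium- and strong-heterosis crosses.

**Phenotypes.** `y_iy = g_i + year_y + e_iy` with i.i.d. Gaussian noise.
The noise variance is back-calculated from the target heritability of
accession means: `σ_ε² = σ_g² · n_years · (1 − h²)/h²`, where `σ_g²` is the
realized genetic variance of the founder panel (founders and F1s share one
noise level). Default `h2_target = 0.85` and three years with symmetric
offsets (±0.5 genetic SD).

**The trait suite.** Three measured base traits mimic a pungency study:
two strongly correlated content traits (additive-effect correlation 0.9,
positive dominance) and a weight-like trait DWP with negatively correlated
additive effects (−0.35) and *negative* directional dominance at 0.4 of the
content traits' dominance ratio — hybrids tend to fall below the parental
mean for it. Intercepts shift each trait's founder minimum three genetic SDs
above zero, so percent heterosis denominators are positive. Composites
(TCAPgDW = CAPgDW + DCAPgDW; per-fruit contents = content × DWP) are derived
from the raw yearly records before BLUP, giving seven traits in total.
Reciprocal-cross effects, linkage/recombination, epistasis, and G×E beyond
additive year offsets are deliberately not simulated.

**What passing tests do and do not show.** The generator reproduces the
statistical skeleton (homozygous training panel, heterozygous targets,
directional dominance, trait correlations, heritability range), not real
genomes: no linkage disequilibrium, population structure, or major-gene
segregation (e.g. pungency loss-of-function alleles). Results on it validate
the machinery and the dominance-error mechanism, not field-data accuracy
levels.

## Phenotype summarization

`fit_blup` fits `y = year (fixed) + accession (random) + residual` by REML.
The single ratio `γ = σ_g²/σ_ε²` is profiled: at each `γ`, fixed effects come
from closed-form GLS and the residual scale is profiled analytically, leaving
a 1-D bounded search over `log γ ∈ [−12, 12]` (tolerance 1e-8; the profile
restricted likelihood is unimodal in practice). Estimates at the lower
boundary are clamped to zero with a warning. Reported BLUPs are the mean of
the estimated year effects plus the shrunken accession effect, i.e. on the
trait scale, which keeps percent heterosis independent of year coding.
On balanced data this reproduces the ANOVA method-of-moments components and
the classical shrinkage form `μ̂ + (σ̂_g²/(σ̂_g² + σ̂_ε²/n))(ȳ_i − μ̂)`;
tests verify both, plus agreement with statsmodels' MixedLM on balanced and
unbalanced layouts.

`h_b² = σ_g²/(σ_g² + σ_ε²/n) × 100` with `n` = number of years. The per-fruit
composites use g/fruit × μg·gDW⁻¹ = μg/fruit for the unit product.

## Heterosis statistics

Percent MP/HP heterosis assumes positive-valued traits. Records whose
mid-parent or higher-parent BLUP is not strictly positive are flagged,
excluded from percent summaries, and counted in the log — percent heterosis
is meaningless with a non-positive denominator. Group boundaries use strict
inequalities; exact ties (probability ~0 on continuous data) fall to the less
extreme group (`MP = 0 → non`, `HP = 0 → medium`). Correlation p-values use
the exact t reference with `n − 2` df, with stars at 0.05/0.01/0.001. The
cross-matrix export tags the actually crossed direction `R` and mirrors the
value to the reciprocal cell tagged `F`; reciprocal differences are ignored
by design, so conflicting duplicate pairs are an error rather than averaged
silently.

## Genomic prediction

**Kernels.** Additive: codes centered by `2p_j − 1`,
`K = WW′/(2Σp_j q_j)` (VanRaden scaling; inbreds have diagonal ≈ 2).
Dominance: heterozygosity indicator centered by `2p_j q_j`,
`K_D = VV′/Σ(2p_j q_j)²`. Gaussian: `K = exp(−D²/θ)` with `D` Euclidean on
the codes and `θ` the median nonzero squared training distance (the median
heuristic is scale-free and frozen at training time). Centering frequencies,
`θ`, and marker means are always computed on the inbred training panel and
reused for the F1 kernels — the prediction panel never influences training.
Construction validates symmetry (1e-10), numerical PSD (min eigenvalue
≥ −1e-8), and the unit Gaussian diagonal.

**GBLUP.** Single kernel: the same profile-REML machinery as the phenotype
model with the overall mean as the only fixed effect. Two kernels
(additive + dominance): direct Nelder-Mead maximization of the restricted
likelihood over both log variance ratios with three restarts; the log
parameterization keeps components nonnegative. Predictions extend the BLUP:
`ŷ_new = μ̂ + Σ_k γ_k K_cross,k V₀⁻¹(y − μ̂)`, which tests verify equals the
joint mixed-model solve with unknown new phenotypes, and which reduces to
ridge regression at the REML-implied penalty for the additive kernel.

A design caveat: in an unrelated inbred panel with as many markers as
accessions the additive kernel is full-rank and near-identity, so `σ_g²` and
`σ_ε²` are weakly identified and REML can drift to the boundary. Variance
*shares* are therefore only interpreted (and tested) on rank-deficient
designs (n > p); predictions are insensitive to this, as the duality test
shows.

**Penalized regressions.** scikit-learn coordinate descent (lasso, elastic
net at mixing 0.5) and closed-form ridge on standardized markers; penalty
chosen by seeded 5-fold CV minimizing MSE over a log-spaced path, or fixed
via `alpha` for exactness tests. Coefficients are returned on the original
code scale. Whether the original analysis standardized markers or how its CV
was configured is not knowable; these are configuration, not inferred intent.

**Bayesian regressions.** Single-site Gibbs samplers sharing one
numba-compiled sweep: BRR (common effect variance, scaled-inverse-χ² prior,
ν = 4), Bayes A (per-marker variances), Bayes B/C (spike-and-slab with
`π ~ Beta(1, 9)`, initial 0.1, optionally fixed; B per-marker slab variances,
C a common slab). Hyperprior scales follow the usual R²-style partition of
the phenotypic variance (half to markers). Defaults 6,000 iterations with
1,000 burn-in (the pipeline uses 3,000/500 — point predictions from
posterior-mean effects stabilize much earlier, which the calibration tests
confirm). All draws with state-independent shapes are pre-generated from a
seeded Generator per iteration, so chains are exactly reproducible; the
sampler aborts with diagnostics on a non-finite state.

**Random forest.** scikit-learn's RandomForestRegressor behind the module's
fit/predict contract: 500 trees, mtry = p/3, seeded.

**F1 genotype estimation.** `g_F1 = (g_P1 + g_P2)/2` with ±0.5 adjusted to
±1, so estimated matrices stay on the {−1, 0, 1} code. This equals the
expected F1 dosage wherever both parents are homozygous; it is deliberately
wrong (deterministic) at the few residually heterozygous parental loci —
segregation is not modelled, matching the deterministic workflow.

## Evaluation

Accuracy is the per-(trait, model) Pearson correlation between observed F1
BLUPs and predictions; degenerate constant predictions are reported as
not-available with a reason code rather than silently dropped. The
error-factor analysis correlates `RSE = |observed − predicted|` with the
additive effect (raw — already nonnegative), |MP|, |HP| (absolute values, as
the error should grow with heterosis of either sign), and parental distance,
defaulting to the Gaussian-kernel GBLUP predictions but configurable.

To make the no-leakage guarantee literal — mutating F1 phenotypes must not
change a single prediction — the pipeline fits the phenotype mixed model
separately on the inbred panel (training inputs) and on the F1 panel
(evaluation targets), rather than once jointly: a joint fit would couple the
panels through shared variance components and year effects. A guard raises
if any F1 id appears in a training set.

One caution on interpreting RSE-vs-heterosis correlations: observed F1 BLUPs
enter both RSE and percent heterosis, so shared measurement noise inflates
the correlation even for purely additive traits. The test suite separates
the mechanism from the artifact by also scoring RSE against *true* simulated
genetic values, where the correlation vanishes without dominance.

## Problem sizes

Unit and property tests run on panels of 20–300 accessions and 30–600 loci.
The end-to-end checks use 150 inbreds × 3,000 loci (cross-prediction
recovery, five seeds) and 100 × 500 (dominance sweep, three seeds × three
ratios); `scripts/acceptance.py` runs the full study-scale configuration
(132 inbreds, 3,000 SNPs, 20 parents, 156 F1s, seven traits, all eleven
models) with the Gibbs chains at 2,000/400. These sizes were chosen as the
smallest at which the estimates of interest are stable.

## Known limitations

- No missing-genotype imputation: VCF sites with missing calls are dropped
  panel-wide, and numeric TSV input must be complete.
- The two-component (additive + dominance) REML is a direct numerical
  maximization, not an AI-REML; it is adequate at panel sizes of a few
  hundred but slower than specialized implementations.
- Heterosis percentages require positive-valued traits; traits crossing zero
  must be shifted or analyzed in absolute units.
- The count of F1s, markers, and accessions is data-driven throughout; no
  fixed panel size is assumed anywhere.
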