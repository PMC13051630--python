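# crosspred

Genomic prediction of F1 hybrid performance from parental data, with heterosis
analysis and a synthetic-data generator for inbred/F1 panels.

## The problem

In self-pollinated crops such as chili pepper, breeders would like to rank
candidate crosses *before* making and phenotyping them. For quantitative,
polygenic traits (the motivating case is capsaicinoid content — pungency),
the F1 phenotype is hard to anticipate from parental values alone because
hybrids are far more heterozygous than their inbred parents and frequently
show heterosis: the F1 exceeds the parental mean (mid-parent, MP) or even the
better parent (high-parent, HP).

`crosspred` implements the full analysis for this setting:

1. **Phenotype summarization.** Multi-year records are summarized per
   accession with the mixed model `y_iy = year_y + g_i + e_iy` (year fixed,
   accession random), fitted by REML. The package reports BLUPs and
   broad-sense heritability of accession means,
   `h_b² = σ_g² / (σ_g² + σ_ε²/n) × 100` with `n` replicate years.
2. **Heterosis.** Per F1, `MP% = (P_F1 − P_mid)/P_mid × 100` and
   `HP% = (P_F1 − P_max)/P_max × 100`; F1s are classified as
   non- (`MP < 0`), medium- (`MP > 0 & HP < 0`) or strong-heterosis
   (`HP > 0`), and heterosis is correlated with the parents' additive split
   `|P_P1 − P_P2|/2` and their Euclidean genotype distance.
3. **Genomic prediction of crosses.** Eleven models are trained on the inbred
   panel only — ridge / LASSO / elastic net, BRR / Bayes A / B / C Gibbs
   samplers, kernel GBLUP with additive (VanRaden), dominance, and Gaussian
   relationship matrices, and a random forest. F1 genotypes are *estimated*
   from the parents as `g_F1 = (g_P1 + g_P2)/2` on the {−1, 0, 1} code, with
   the half-doses ±0.5 snapped to ±1, and fed to the trained models.
4. **Error anatomy.** Per-F1 root square error `RSE = |observed − predicted|`
   is correlated with |MP|, |HP|, the additive split, and parental distance,
   quantifying how much heterosis — invisible to a model trained on
   homozygous material — degrades cross prediction.

Because the motivating field data are not public, the `simdata` module
generates panels with the same structure (≈130 highly homozygous inbreds at
≈3,000 SNPs with MAF > 0.05, 20 parents crossed into ≈156 F1s, correlated
positive-valued traits over 3 years, `h_b²` in the high 80s, tunable
directional dominance), so every stage is testable end to end.

## Worked example

```python
from crosspred import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    sim=SimConfig(n_inbred=60, n_loci=600, n_parents=12, n_f1=40, seed=7),
    seed=7,
    models=["gblup_gauss", "gblup_a", "ridge"],
    traits=["TCAPgDW", "DWP"],
)
art = run_pipeline(cfg)
print(art["accuracy"][["trait", "model", "r", "signif", "n"]])
```

prints

```
  trait       model        r signif  n
    DWP     gblup_a 0.690735    *** 40
    DWP gblup_gauss 0.700386    *** 40
    DWP       ridge 0.687470    *** 40
TCAPgDW     gblup_a 0.756346    *** 40
TCAPgDW gblup_gauss 0.755328    *** 40
TCAPgDW       ridge 0.758999    *** 40
```

— per trait and model, the Pearson correlation between observed F1 BLUPs and
predictions from estimated F1 genotypes, with significance stars and the
number of F1s. The same run's heterosis summary shows the simulated contrast
between a content trait (mostly positive, often strong heterosis) and the
weight-like trait DWP (negative dominance):

```
  trait  mp_mean  hp_mean  prop_non  prop_medium  prop_strong
    DWP     -9.6    -19.8      77.5         22.5          0.0
TCAPgDW     15.4      6.7       2.5         27.5         70.0
```

and the error-factor table for TCAPgDW shows prediction error tracking
heterosis, not the additive split or genetic distance:

```
          factor      r signif
 additive_effect -0.259   N.S.
abs_mp_heterosis  0.978    ***
abs_hp_heterosis  0.618    ***
        distance  0.129   N.S.
```

A `crosspred` command-line interface exposes the same stages
(`simulate`, `blup`, `heterosis`, `predict`, `evaluate`, `run-all`); see
`crosspred --help`.

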