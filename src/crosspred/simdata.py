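"""Synthetic inbred panels, F1 crosses, trait architectures, multi-year phenotypes.

The generator emulates the study system the analysis assumes: a panel of
highly homozygous inbred accessions genotyped at genome-wide biallelic SNPs
(MAF > 0.05), a subset of which is test-crossed into F1 hybrids, with a small
number of correlated, positive-valued quantitative traits (pungency-like
contents plus a negatively correlated weight-like trait) measured once per
accession over several years. Traits follow an additive + dominance model:

    g_i = intercept + sum_k a_k * x_ik + sum_k d_k * 1[x_ik == 0]

so dominance expresses almost exclusively in F1s (inbreds are nearly free of
heterozygous loci), which is the mechanism that produces mid-parent and
high-parent heterosis downstream. Every operation is a pure function of its
inputs and the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_core import CrossTable, GenotypeMatrix

_MAX_REGEN_ROUNDS = 100


@dataclass
class TraitArchitecture:
    """QTL positions and their additive/dominance effects for one trait.

    additive_effects apply per unit of the {-1, 0, 1} code; dominance_effects
    are added whenever the genotype is heterozygous (code 0). The intercept is
    in trait units and fixes the population baseline.
    """

    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        self.dominance_effects = np.asarray(self.dominance_effects, dtype=float)
        k = len(self.qtl_indices)
        if len(np.unique(self.qtl_indices)) != k:
            raise ValueError("qtl_indices must be unique")
        if (self.qtl_indices < 0).any():
            raise ValueError("qtl_indices must be nonnegative")
        if len(self.additive_effects) != k or len(self.dominance_effects) != k:
            raise ValueError("effect vectors must match qtl_indices in length")

    def genetic_values(self, g: GenotypeMatrix) -> np.ndarray:
        """intercept + additive dose effects + dominance at heterozygous loci."""
        if self.qtl_indices.size and self.qtl_indices.max() >= g.n_loci:
            raise ValueError("architecture references loci beyond the genotyped range")
        x = g.values[:, self.qtl_indices].astype(float)
        return (
            self.intercept
            + x @ self.additive_effects
            + (x == 0.0) @ self.dominance_effects
        )


@dataclass
class SimConfig:
    """Study-scale defaults: ~130 inbreds at ~3,000 SNPs, 20 parents, ~156 F1s,
    3 years, broad-sense heritability in the high-0.8s, moderate directional
    dominance."""

    n_inbred: int = 132
    n_loci: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    residual_het_rate: float = 0.01
    n_parents: int = 20
    n_f1: int = 156
    n_years: int = 3
    h2_target: float = 0.85
    dominance_ratio: float = 0.5
    n_qtl: int | None = None  # default: min(100, n_loci // 3)
    dominance_fraction: float = 0.1
    year_effects: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.residual_het_rate <= 0.2):
            raise ValueError("residual_het_rate must be in [0, 0.2]")
        if self.n_inbred < 1 or self.n_loci < 1:
            raise ValueError("n_inbred and n_loci must be positive")
        if self.n_parents > self.n_inbred:
            raise ValueError("n_parents cannot exceed n_inbred")
        if self.n_f1 > self.n_parents * (self.n_parents - 1) // 2:
            raise ValueError("n_f1 exceeds the number of unordered parent pairs")
        if not (0.0 < self.h2_target <= 1.0):
            raise ValueError("h2_target must be in (0, 1]")
        if self.dominance_ratio < 0:
            raise ValueError("dominance_ratio must be nonnegative")
        if not (0.0 < self.dominance_fraction <= 1.0):
            raise ValueError("dominance_fraction must be in (0, 1]")
        if self.n_qtl is None:
            self.n_qtl = min(100, max(2, self.n_loci // 3))
        if not (1 <= self.n_qtl <= self.n_loci):
            raise ValueError("n_qtl must be in [1, n_loci]")
        if self.year_effects is None:
            # modest symmetric year offsets on the (unit genetic SD) trait scale
            self.year_effects = tuple(
                0.5 * x for x in np.linspace(-1.0, 1.0, self.n_years)
            )
        if len(self.year_effects) != self.n_years:
            raise ValueError("year_effects must have one entry per year")


def simulate_founder_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate a panel of highly homozygous inbred accessions.

    Each locus draws a population alternate-allele frequency uniformly from
    ``maf_range``; each inbred is homozygous (+-1, Bernoulli by that frequency)
    except at loci flipped to heterozygous with probability
    ``residual_het_rate``. Loci whose realized MAF does not exceed the lower
    bound are regenerated for a bounded number of rounds.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_inbred, config.n_loci
    low, high = config.maf_range

    def draw(n_cols: int) -> np.ndarray:
        freqs = rng.uniform(low, high, size=n_cols)
        vals = np.where(rng.random((n, n_cols)) < freqs, 1, -1).astype(np.int8)
        if config.residual_het_rate > 0:
            het = rng.random((n, n_cols)) < config.residual_het_rate
            vals[het] = 0
        return vals

    values = draw(p)
    for _ in range(_MAX_REGEN_ROUNDS):
        freq = (values.astype(float) + 1.0).mean(axis=0) / 2.0
        bad = np.minimum(freq, 1.0 - freq) <= low
        if not bad.any():
            break
        values[:, bad] = draw(int(bad.sum()))
    else:
        raise RuntimeError(
            "monomorphic/low-MAF locus regeneration did not converge; "
            "widen maf_range or enlarge the panel"
        )

    accessions = [f"IB{i + 1:03d}" for i in range(n)]
    loci = [f"{(j % 12) + 1}:{(j // 12 + 1) * 1000}" for j in range(p)]
    return GenotypeMatrix(accessions, loci, values)


def make_crosses(
    genotypes: GenotypeMatrix,
    parent_ids: list[str],
    n_f1: int,
    seed: int,
) -> tuple[CrossTable, GenotypeMatrix]:
    """Sample distinct unordered parent pairs and simulate true F1 genotypes.

    Mother/father roles are assigned reproducibly at random. Per locus, each
    parent contributes one allele: a homozygote contributes its fixed allele, a
    heterozygote one allele sampled uniformly; the F1 code is the allele sum
    minus 1.
    """
    if len(set(parent_ids)) != len(parent_ids):
        raise ValueError("duplicate parent ids")
    rows = [genotypes.index_of(pid) for pid in parent_ids]
    n_pairs = len(parent_ids) * (len(parent_ids) - 1) // 2
    if n_f1 > n_pairs:
        raise ValueError("n_f1 exceeds the number of unordered parent pairs")

    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(len(parent_ids)) for j in range(i + 1, len(parent_ids))]
    chosen = rng.choice(len(pairs), size=n_f1, replace=False)
    records = []
    f1_values = np.empty((n_f1, genotypes.n_loci), dtype=np.int8)
    for k, pair_idx in enumerate(chosen):
        i, j = pairs[pair_idx]
        if rng.random() < 0.5:
            i, j = j, i
        mother, father = parent_ids[i], parent_ids[j]
        gm = genotypes.values[genotypes.index_of(mother)].astype(np.int8)
        gf = genotypes.values[genotypes.index_of(father)].astype(np.int8)
        # allele contributed by each parent: 0 = ref, 1 = alt
        am = np.where(gm == 0, rng.integers(0, 2, genotypes.n_loci), (gm + 1) // 2)
        af = np.where(gf == 0, rng.integers(0, 2, genotypes.n_loci), (gf + 1) // 2)
        f1_values[k] = (am + af - 1).astype(np.int8)
        records.append({"f1_id": f"F1_{k + 1:03d}", "mother_id": mother, "father_id": father})

    crosses = CrossTable(pd.DataFrame(records))
    f1 = GenotypeMatrix(crosses.f1_ids, list(genotypes.locus_ids), f1_values)
    return crosses, f1


def simulate_architecture(
    n_loci: int,
    n_qtl: int,
    dominance_ratio: float,
    seed: int,
    *,
    allele_freqs: np.ndarray | None = None,
    dominance_sign: float = 1.0,
    dominance_fraction: float = 0.1,
    intercept: float = 0.0,
) -> TraitArchitecture:
    """Draw a QTL set with additive effects and scaled directional dominance.

    Additive effects are standard-normal draws rescaled to unit additive
    variance in a random-mating (HWE) population at the supplied allele
    frequencies (default p = 0.25 at every locus). Dominance effects are
    half-normal magnitudes (directional by default: positive, producing
    predominantly positive heterosis), concentrated on a random
    ``dominance_fraction`` of the QTLs — complementation at a few specific
    loci rather than genome-wide overdominance — and scaled so the HWE
    variance of the dominance component over the additive component equals
    ``dominance_ratio``.
    """
    if n_qtl < 1:
        raise ValueError("n_qtl must be positive")
    if n_qtl > n_loci:
        raise ValueError("n_qtl cannot exceed n_loci")
    if dominance_ratio < 0:
        raise ValueError("dominance_ratio must be nonnegative")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(n_loci, size=n_qtl, replace=False))
    if allele_freqs is None:
        p = np.full(n_qtl, 0.25)
    else:
        allele_freqs = np.asarray(allele_freqs, dtype=float)
        if len(allele_freqs) != n_loci:
            raise ValueError("allele_freqs must have one entry per locus")
        p = allele_freqs[qtl]
    q = 1.0 - p
    a = rng.standard_normal(n_qtl)
    var_a = float(np.sum(a**2 * 2 * p * q))  # Var(sum a*x) under HWE, x = dose-1
    a = a / np.sqrt(var_a)

    if dominance_ratio == 0:
        d = np.zeros(n_qtl)
    else:
        if not (0.0 < dominance_fraction <= 1.0):
            raise ValueError("dominance_fraction must be in (0, 1]")
        n_dom = max(1, int(np.ceil(dominance_fraction * n_qtl)))
        dom_loci = rng.choice(n_qtl, size=n_dom, replace=False)
        d_raw = np.zeros(n_qtl)
        d_raw[dom_loci] = np.abs(rng.standard_normal(n_dom))
        h = 2 * p * q  # HWE heterozygosity
        var_d_raw = float(np.sum(d_raw**2 * h * (1 - h)))  # Var(sum d*1[het])
        d = dominance_sign * d_raw * np.sqrt(dominance_ratio / var_d_raw)
    return TraitArchitecture(qtl, a, d, intercept=intercept)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    config: SimConfig,
    *,
    trait: str = "sim_trait",
    calibration_ids: list[str] | None = None,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Simulate multi-year phenotype records for every genotyped accession.

    y_iy = g_i + year_effect_y + e_iy with i.i.d. Gaussian noise whose variance
    is set from the target broad-sense heritability of accession means:
    sigma_e^2 = sigma_g^2 * n_years * (1 - h2) / h2, where sigma_g^2 is the
    realized genetic variance of the calibration panel (default: all
    accessions; pass the founder ids so inbreds and F1s share one noise level).
    """
    if not (0.0 < config.h2_target <= 1.0):
        raise ValueError("h2_target must be in (0, 1]")
    rng = np.random.default_rng((config.seed + 104729 + seed_offset) % 2**31)
    g = arch.genetic_values(genotypes)
    calib = g
    if calibration_ids is not None:
        calib = g[[genotypes.index_of(a) for a in calibration_ids]]
    sigma_g2 = float(np.var(calib))
    if config.h2_target == 1.0:
        sigma_e2 = 0.0
    else:
        sigma_e2 = sigma_g2 * config.n_years * (1.0 - config.h2_target) / config.h2_target

    rows = []
    for y in range(config.n_years):
        noise = rng.normal(0.0, np.sqrt(sigma_e2), size=genotypes.n_accessions)
        vals = g + config.year_effects[y] + noise
        for acc, v in zip(genotypes.accession_ids, vals):
            rows.append({"accession": acc, "year": f"Y{y + 1}", "trait": trait, "value": float(v)})
    out = pd.DataFrame(rows)
    if not np.isfinite(out["value"]).all():
        raise RuntimeError("non-finite simulated phenotype")
    return out


def _positive_shift(values: np.ndarray, margin: float = 3.0) -> float:
    """Intercept shift that keeps the panel minimum ``margin`` SDs above zero."""
    sd = float(np.std(values))
    return float(-values.min() + margin * max(sd, 1e-12))


def correlated_architecture(
    base: TraitArchitecture,
    rho: float,
    seed: int,
    *,
    allele_freqs: np.ndarray | None = None,
    n_loci: int | None = None,
    dominance_ratio: float = 0.0,
    dominance_sign: float = 1.0,
    dominance_fraction: float = 0.1,
) -> TraitArchitecture:
    """New trait on the same QTL set with additive effects correlated ``rho``
    with the base trait's, mimicking a family of biochemically related traits."""
    rng = np.random.default_rng(seed)
    k = len(base.qtl_indices)
    if allele_freqs is None:
        p = np.full(k, 0.25)
    else:
        p = np.asarray(allele_freqs, dtype=float)[base.qtl_indices]
    q = 1.0 - p
    noise = rng.standard_normal(k)
    a = rho * base.additive_effects + np.sqrt(max(1 - rho**2, 0.0)) * noise / np.sqrt(
        np.sum(noise**2 * 2 * p * q)
    )
    a = a / np.sqrt(np.sum(a**2 * 2 * p * q))
    if dominance_ratio == 0:
        d = np.zeros(k)
    else:
        n_dom = max(1, int(np.ceil(dominance_fraction * k)))
        dom_loci = rng.choice(k, size=n_dom, replace=False)
        d_raw = np.zeros(k)
        d_raw[dom_loci] = np.abs(rng.standard_normal(n_dom))
        h = 2 * p * q
        d = dominance_sign * d_raw * np.sqrt(
            dominance_ratio / np.sum(d_raw**2 * h * (1 - h))
        )
    return TraitArchitecture(base.qtl_indices.copy(), a, d, intercept=0.0)


def simulate_trait_suite(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    *,
    founder_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, TraitArchitecture]]:
    """Simulate the three base measured traits of a pungency-style study.

    CAPgDW and DCAPgDW are strongly correlated contents with directional
    positive dominance; DWP is a weight-like trait with negatively correlated
    additive effects and directional *negative* dominance (hybrids tend to fall
    below the parental mean for it). Per-fruit composites are derived
    downstream. Returns long-format records plus the architectures used.
    """
    freqs = None
    calib = genotypes
    if founder_ids is not None:
        calib = genotypes.subset_accessions(founder_ids)
    freqs = calib.allele_freqs

    cap = simulate_architecture(
        genotypes.n_loci,
        config.n_qtl,
        config.dominance_ratio,
        config.seed + 11,
        allele_freqs=freqs,
        dominance_fraction=config.dominance_fraction,
    )
    dcap = correlated_architecture(
        cap, 0.9, config.seed + 13, allele_freqs=freqs,
        dominance_ratio=config.dominance_ratio, dominance_sign=1.0,
        dominance_fraction=config.dominance_fraction,
    )
    dwp = correlated_architecture(
        cap, -0.35, config.seed + 17, allele_freqs=freqs,
        dominance_ratio=0.4 * config.dominance_ratio, dominance_sign=-1.0,
        dominance_fraction=config.dominance_fraction,
    )
    # positive-valued traits: shift each baseline well clear of zero
    for arch, scale in ((cap, 1.0), (dcap, 0.5), (dwp, 1.0)):
        arch.additive_effects *= scale
        arch.dominance_effects *= scale
        g = arch.genetic_values(calib)
        arch.intercept = _positive_shift(g, margin=3.0)

    archs = {"CAPgDW": cap, "DCAPgDW": dcap, "DWP": dwp}
    records = []
    for off, (trait, arch) in enumerate(archs.items()):
        records.append(
            simulate_phenotypes(
                genotypes, arch, config, trait=trait,
                calibration_ids=founder_ids, seed_offset=1000 * (off + 1),
            )
        )
    return pd.concat(records, ignore_index=True), archs
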