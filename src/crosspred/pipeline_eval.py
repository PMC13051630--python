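"""End-to-end workflow: BLUPs -> heterosis -> gF1 -> train-on-inbreds GP -> error analysis.

The training stage sees only inbred accessions: the mixed model that feeds GP
training is fitted on inbred records alone, F1 BLUPs are fitted separately and
used exclusively as evaluation targets, and a leakage guard refuses any
training set containing an F1.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_core import (
    CrossTable,
    GenotypeMatrix,
    estimate_f1_genotypes,
    filter_maf,
    parental_distance,
    read_genotypes,
)
from .gp_models import MODELS, fit_model
from .heterosis import (
    build_heterosis_table,
    heterosis_correlates,
    heterosis_summary,
    pearson_with_stars,
)
from .pheno_blup import blup_series, derive_traits, fit_blup_all
from .simdata import SimConfig, make_crosses, simulate_founder_genotypes, simulate_trait_suite

log = logging.getLogger(__name__)

DEFAULT_MODELS = list(MODELS)


class LeakageError(RuntimeError):
    """Raised when an F1 accession would enter GP model training."""


def check_no_leakage(training_ids: list[str], f1_ids: list[str]) -> None:
    leaked = sorted(set(training_ids) & set(f1_ids))
    if leaked:
        raise LeakageError(
            f"F1 accessions present in the GP training set: {leaked[:5]}"
        )


def rse(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Per-accession root square error |observed - predicted|."""
    return np.abs(np.asarray(observed, float) - np.asarray(predicted, float))


@dataclass
class RunConfig:
    """Inputs and options for one full pipeline run.

    Either ``sim`` (synthetic panel) or the three input paths must be given.
    """

    sim: SimConfig | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    crosses_path: str | None = None
    traits: list[str] | None = None
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    outdir: str | None = None
    seed: int = 0
    maf_threshold: float = 0.05
    error_model: str = "gblup_gauss"
    bayes_n_iter: int = 3000
    bayes_burn_in: int = 500
    derive: bool = True
    round_decimals: int | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODELS]
        if unknown:
            raise ValueError(f"unsupported models {unknown}; choose from {MODELS}")
        if self.sim is None and not (
            self.genotypes_path and self.phenotypes_path and self.crosses_path
        ):
            raise ValueError("provide either a SimConfig or all three input paths")


def _model_seed(base: int, trait_i: int, model_i: int) -> int:
    return (base * 10007 + trait_i * 101 + model_i) % (2**31 - 1)


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = config.sim
        founders = simulate_founder_genotypes(sim)
        rng = np.random.default_rng(sim.seed + 1)
        parents = list(
            rng.choice(founders.accession_ids, size=sim.n_parents, replace=False)
        )
        crosses, f1_true = make_crosses(founders, parents, sim.n_f1, sim.seed + 2)
        all_true = GenotypeMatrix.concat(founders, f1_true)
        records, archs = simulate_trait_suite(
            all_true, sim, founder_ids=list(founders.accession_ids)
        )
        return founders, crosses, records, {"architectures": archs, "f1_true": f1_true}
    founders = read_genotypes(config.genotypes_path)
    crosses = CrossTable.from_csv(config.crosses_path)
    records = pd.read_csv(config.phenotypes_path)
    need = {"accession", "year", "trait", "value"}
    if not need.issubset(records.columns):
        raise ValueError(f"phenotype CSV needs columns {sorted(need)}")
    return founders, crosses, records, {}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return (and optionally write) artifacts.

    Stages: (A) per-panel BLUPs and heritability; heterosis tables and
    parental distances for F1s; (B) F1 genotype estimation from parents;
    (C) per trait x model GP training on inbreds only, F1 prediction,
    accuracy table, and RSE error-factor correlations.
    """
    founders, crosses, records, extras = _load_inputs(config)
    f1_ids = crosses.f1_ids
    inbred_ids = [a for a in founders.accession_ids if a not in set(f1_ids)]
    if len(inbred_ids) < founders.n_accessions:
        raise LeakageError("genotype panel for training contains F1 accessions")

    if config.derive:
        records = derive_traits(records)
    traits = config.traits or sorted(records["trait"].unique())

    founders_f = filter_maf(founders, config.maf_threshold)

    train_records = records[records["accession"].isin(inbred_ids)]
    f1_records = records[records["accession"].isin(f1_ids)]
    if f1_records.empty:
        raise ValueError("no phenotype records for F1 accessions")
    blup_train = fit_blup_all(train_records, traits)
    blup_f1 = fit_blup_all(f1_records, traits)

    distances = parental_distance(founders_f, crosses)
    het_tables = []
    for trait in traits:
        combined = pd.concat(
            [blup_series(blup_train, trait), blup_series(blup_f1, trait)]
        )
        het_tables.append(build_heterosis_table(combined, crosses, trait))
    het_all = pd.concat(het_tables, ignore_index=True)
    het_summary = heterosis_summary(het_all)
    het_corr = heterosis_correlates(het_all, distances)

    gf1 = estimate_f1_genotypes(founders_f, crosses)
    check_no_leakage(inbred_ids, f1_ids)

    rows = []
    for ti, trait in enumerate(traits):
        y_train = blup_series(blup_train, trait)
        observed = blup_series(blup_f1, trait).reindex(f1_ids)
        for mi, model in enumerate(config.models):
            fit = fit_model(
                model, y_train, founders_f,
                seed=_model_seed(config.seed, ti, mi), trait=trait,
                bayes_n_iter=config.bayes_n_iter, bayes_burn_in=config.bayes_burn_in,
            )
            check_no_leakage(fit.training_ids, f1_ids)
            pred = fit.predict(gf1)
            err = rse(observed.to_numpy(), pred)
            for fid, obs_v, pred_v, e in zip(f1_ids, observed, pred, err):
                rows.append(
                    {"f1_id": fid, "trait": trait, "model": model,
                     "observed": obs_v, "predicted": pred_v, "rse": e}
                )
    results = pd.DataFrame(rows)
    acc = accuracy(results)
    error_model = config.error_model
    if error_model not in config.models:
        error_model = config.models[0]
        log.info("error_model %r not in run; using %r", config.error_model, error_model)
    err_corr = error_factor_analysis(results, het_all, distances, model=error_model)

    artifacts = {
        "blup_train": blup_train,
        "blup_f1": blup_f1,
        "heterosis": het_all,
        "heterosis_summary": het_summary,
        "heterosis_correlates": het_corr,
        "distances": distances,
        "predictions": results,
        "accuracy": acc,
        "error_factors": err_corr,
        "crosses": crosses.table,
    }
    artifacts.update(extras)

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in artifacts.items():
            if isinstance(obj, pd.DataFrame):
                df = obj
                if config.round_decimals is not None:
                    df = df.round(config.round_decimals)
                df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "crosspred_version": __version__,
            "seed": config.seed,
            "sim_seed": config.sim.seed if config.sim else None,
            "models": config.models,
            "traits": traits,
            "n_inbred": len(inbred_ids),
            "n_f1": len(f1_ids),
            "n_loci": founders_f.n_loci,
            "n_prediction_rows": len(results),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return artifacts


def accuracy(results: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, model) Pearson correlation between observed and predicted.

    Degenerate constant predictions are reported as not-available with a
    reason code instead of a correlation.
    """
    rows = []
    for (trait, model), sub in results.groupby(["trait", "model"], sort=True):
        n = len(sub)
        pred = sub["predicted"].to_numpy(float)
        obs = sub["observed"].to_numpy(float)
        scale = max(1.0, float(np.abs(pred).mean()))
        if n < 3:
            rows.append({"trait": trait, "model": model, "r": np.nan,
                         "p_value": np.nan, "signif": "", "n": n,
                         "reason": "fewer than 3 F1s"})
            continue
        if np.std(pred) < 1e-10 * scale:
            rows.append({"trait": trait, "model": model, "r": np.nan,
                         "p_value": np.nan, "signif": "", "n": n,
                         "reason": "constant predictions"})
            continue
        r, p, star = pearson_with_stars(obs, pred)
        rows.append({"trait": trait, "model": model, "r": r, "p_value": p,
                     "signif": star, "n": n, "reason": ""})
    return pd.DataFrame(rows)


def error_factor_analysis(
    results: pd.DataFrame,
    heterosis: pd.DataFrame,
    distances: pd.DataFrame,
    model: str = "gblup_gauss",
) -> pd.DataFrame:
    """Correlate per-F1 RSE with inheritance statistics, per trait.

    Factors: additive effect (raw, already nonnegative), |MP heterosis|,
    |HP heterosis|, and parental genetic distance. Uses the predictions of
    ``model`` (the Gaussian-kernel GBLUP by default).
    """
    sub = results[results["model"] == model]
    if sub.empty:
        raise ValueError(f"no predictions for model {model!r}")
    merged = sub.merge(heterosis, on=["f1_id", "trait"]).merge(
        distances[["f1_id", "distance"]], on="f1_id"
    )
    factors = {
        "additive_effect": lambda d: d["additive_effect"],
        "abs_mp_heterosis": lambda d: d["mp_heterosis"].abs(),
        "abs_hp_heterosis": lambda d: d["hp_heterosis"].abs(),
        "distance": lambda d: d["distance"],
    }
    rows = []
    for trait, dsub in merged.groupby("trait"):
        ok = dsub[dsub["valid"]]
        for fname, getter in factors.items():
            if len(ok) < 3:
                raise ValueError("need at least 3 F1s per trait for correlations")
            try:
                r, p, star = pearson_with_stars(ok["rse"], getter(ok))
            except ValueError:
                r, p, star = np.nan, np.nan, ""
            rows.append({"trait": trait, "factor": fname, "model": model,
                         "r": r, "p_value": p, "signif": star, "n": len(ok)})
    return pd.DataFrame(rows)
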