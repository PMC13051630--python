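"""Multi-year phenotype summarization: REML mixed model, BLUPs, heritability.

The model is y_iy = year_y (fixed) + g_i (random accession effect) + e_iy.
The single variance ratio gamma = sigma_g^2 / sigma_e^2 is profiled out of the
restricted likelihood and found by a bounded 1-D search over log(gamma);
fixed effects come from closed-form GLS at each gamma. Broad-sense
heritability of accession means is h_b^2 = sigma_g^2 / (sigma_g^2 +
sigma_e^2 / n) * 100 with n the number of replicate years.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg, optimize

log = logging.getLogger(__name__)

BASE_TRAITS = ("CAPgDW", "DCAPgDW", "DWP")
DERIVED_TRAITS = ("TCAPgDW", "CAPFL", "DCAPFL", "TCAPFL")
ALL_TRAITS = BASE_TRAITS + DERIVED_TRAITS

_LOG_GAMMA_BOUNDS = (-12.0, 12.0)


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Append composite pungency traits to raw yearly records.

    Per (accession, year): TCAPgDW = CAPgDW + DCAPgDW (total content,
    ug.gDW^-1); per-fruit contents multiply each content by the placental dry
    weight per fruit, CAPFL = CAPgDW * DWP etc. (g/fruit * ug.gDW^-1 ->
    ug/fruit). Requires all three base traits in every cell.
    """
    wide = records.pivot_table(
        index=["accession", "year"], columns="trait", values="value", aggfunc="first"
    )
    missing = [t for t in BASE_TRAITS if t not in wide.columns]
    if missing:
        raise ValueError(f"missing base traits {missing} for derivation")
    if wide[list(BASE_TRAITS)].isna().any().any():
        bad = wide[wide[list(BASE_TRAITS)].isna().any(axis=1)].index[:5].tolist()
        raise ValueError(f"incomplete base-trait cells, e.g. {bad}")
    wide = wide.copy()
    wide["TCAPgDW"] = wide["CAPgDW"] + wide["DCAPgDW"]
    wide["CAPFL"] = wide["CAPgDW"] * wide["DWP"]
    wide["DCAPFL"] = wide["DCAPgDW"] * wide["DWP"]
    wide["TCAPFL"] = wide["TCAPgDW"] * wide["DWP"]
    long = (
        wide.reset_index()
        .melt(id_vars=["accession", "year"], var_name="trait", value_name="value")
        .dropna(subset=["value"])
    )
    return long.reset_index(drop=True)


def heritability(sigma2_g: float, sigma2_e: float, n: int) -> float:
    """Broad-sense heritability of accession means, in percent."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be nonnegative")
    if n < 1:
        raise ValueError("replicate count must be at least 1")
    if sigma2_g == 0 and sigma2_e == 0:
        raise ValueError("heritability undefined when both variances are zero")
    return sigma2_g / (sigma2_g + sigma2_e / n) * 100.0


def _reml_profile(y: np.ndarray, X: np.ndarray, H: np.ndarray):
    """Profile REML over gamma for V = gamma*H + I (residual scale profiled).

    Returns (gamma, sigma_e2, beta_hat, V0_inv_resid) where V0 = gamma*H + I
    and V0_inv_resid = V0^{-1} (y - X beta_hat). Shared by the phenotype mixed
    model (H = ZZ') and single-kernel GBLUP (H = K).
    """
    n, p = X.shape
    I = np.eye(n)

    def pieces(log_gamma: float):
        gamma = np.exp(log_gamma)
        V0 = gamma * H + I
        c, low = linalg.cho_factor(V0, lower=True)
        logdet_V0 = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = linalg.cho_solve((c, low), X)
        Vi_y = linalg.cho_solve((c, low), y)
        XtViX = X.T @ Vi_X
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-positive-definite design")
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        resid = y - X @ beta
        Vi_r = Vi_y - Vi_X @ beta
        quad = float(resid @ Vi_r)
        return gamma, logdet_V0, logdet_XtViX, beta, Vi_r, quad

    def neg_rell(log_gamma: float) -> float:
        try:
            _, ld_V, ld_X, _, _, quad = pieces(log_gamma)
        except np.linalg.LinAlgError:
            return 1e30
        if quad <= 0:
            return 1e30
        return 0.5 * ((n - p) * np.log(quad) + ld_V + ld_X)

    res = optimize.minimize_scalar(
        neg_rell, bounds=_LOG_GAMMA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    gamma, _, _, beta, Vi_r, quad = pieces(res.x)
    sigma_e2 = quad / (n - p)
    return gamma, sigma_e2, beta, Vi_r


def fit_blup(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Fit the year + accession mixed model by REML and return per-accession BLUPs.

    Returns a BLUP table with columns accession, trait, blup, sigma2_g,
    sigma2_e, n_reps, h2_b. The reported BLUP is the mean over estimated year
    effects plus the shrunken accession effect, i.e. on the trait scale.
    """
    df = records[records["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if df.duplicated(["accession", "year"]).any():
        raise ValueError("duplicate (accession, year) record")
    accessions = sorted(df["accession"].unique())
    years = sorted(df["year"].unique())
    if len(accessions) < 2:
        raise ValueError("need at least 2 accessions")
    if len(years) < 2:
        raise ValueError("need at least 2 years to separate genetic and residual variance")

    acc_idx = {a: i for i, a in enumerate(accessions)}
    yr_idx = {yv: i for i, yv in enumerate(years)}
    n_obs = len(df)
    y = df["value"].to_numpy(float)
    X = np.zeros((n_obs, len(years)))
    Z = np.zeros((n_obs, len(accessions)))
    for r, (acc, yr) in enumerate(zip(df["accession"], df["year"])):
        X[r, yr_idx[yr]] = 1.0
        Z[r, acc_idx[acc]] = 1.0

    gamma, sigma_e2, beta, Vi_r = _reml_profile(y, X, Z @ Z.T)
    sigma_g2 = gamma * sigma_e2
    lo, hi = np.exp(_LOG_GAMMA_BOUNDS[0]), np.exp(_LOG_GAMMA_BOUNDS[1])
    if gamma <= lo * 1.01:
        log.warning("genetic variance estimate at boundary for %s; clamped to 0", trait)
        sigma_g2 = 0.0
    if gamma >= hi * 0.99:
        log.warning("residual variance near zero for %s", trait)
        sigma_e2 = max(sigma_e2, 0.0)

    u = sigma_g2 / sigma_e2 * (Z.T @ Vi_r) if sigma_e2 > 0 else gamma * (Z.T @ Vi_r)
    baseline = float(beta.mean())
    blups = baseline + u
    h2 = heritability(sigma_g2, sigma_e2, len(years))
    return pd.DataFrame(
        {
            "accession": accessions,
            "trait": trait,
            "blup": blups,
            "sigma2_g": sigma_g2,
            "sigma2_e": sigma_e2,
            "n_reps": len(years),
            "h2_b": h2,
        }
    )


def fit_blup_all(records: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """BLUP every trait independently and stack the tables."""
    if traits is None:
        traits = sorted(records["trait"].unique())
    return pd.concat([fit_blup(records, t) for t in traits], ignore_index=True)


def blup_series(blup_table: pd.DataFrame, trait: str) -> pd.Series:
    """BLUP values for one trait as a Series indexed by accession."""
    sub = blup_table[blup_table["trait"] == trait]
    return pd.Series(sub["blup"].to_numpy(), index=sub["accession"].to_numpy())
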