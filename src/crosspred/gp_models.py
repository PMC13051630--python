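"""Eleven genomic prediction models trained on inbreds, applied to F1 genotypes.

Model menu: penalized regressions (ridge, lasso, en), Bayesian whole-genome
regressions (brr, bayes_a, bayes_b, bayes_c), kernel GBLUP variants (gblup_a,
gblup_ad, gblup_gauss), and a bagged-tree ensemble (rf).

Kernel centering frequencies, the Gaussian bandwidth, and marker means are
frozen at training time and reused when building prediction kernels for new
(F1) accessions, so the model never sees the prediction panel.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV, Ridge
from sklearn.model_selection import KFold

from .genotype_core import GenotypeMatrix
from .pheno_blup import _reml_profile

log = logging.getLogger(__name__)

KERNEL_KINDS = ("additive", "dominance", "gaussian")
MODELS = (
    "ridge", "lasso", "en",
    "brr", "bayes_a", "bayes_b", "bayes_c",
    "gblup_a", "gblup_ad", "gblup_gauss",
    "rf",
)

_SYM_TOL = 1e-10
_PSD_TOL = -1e-8


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclass
class KernelMatrix:
    """Genomic relationship matrix with the metadata needed to extend it."""

    kind: str
    accession_ids: list[str]
    values: np.ndarray
    bandwidth: float | None = None  # gaussian only
    freqs: np.ndarray | None = None  # training-panel allele frequencies
    denom: float | None = None  # additive/dominance scaling constant

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match accession ids")
        if np.max(np.abs(self.values - self.values.T)) > _SYM_TOL:
            raise ValueError("kernel is not symmetric")
        self.values = (self.values + self.values.T) / 2.0
        min_eig = float(np.linalg.eigvalsh(self.values)[0])
        if min_eig < _PSD_TOL:
            raise ValueError(f"kernel not PSD (min eigenvalue {min_eig:.3g})")
        if self.kind == "gaussian" and not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("gaussian kernel diagonal must be 1")


def _additive_design(values: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    # center the {-1,0,1} code by its HWE mean 2p - 1
    return values.astype(float) - (2.0 * freqs - 1.0)


def _dominance_design(values: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    h = 2.0 * freqs * (1.0 - freqs)
    return (values == 0).astype(float) - h


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a**2).sum(axis=1)[:, None]
    bb = (b**2).sum(axis=1)[None, :]
    d2 = aa + bb - 2.0 * a @ b.T
    return np.maximum(d2, 0.0)


def build_kernel(
    g: GenotypeMatrix,
    kind: str,
    bandwidth: float | None = None,
    freqs: np.ndarray | None = None,
) -> KernelMatrix:
    """Build an additive (VanRaden-scaled), dominance, or Gaussian kernel.

    additive:  K = WW' / (2 sum p_j q_j) with W the frequency-centered codes;
    dominance: K = VV' / sum (2 p_j q_j)^2 with V the centered heterozygosity;
    gaussian:  K_ij = exp(-D_ij^2 / theta), D Euclidean on codes, theta the
    median nonzero squared distance unless overridden.
    """
    if g.n_accessions < 2:
        raise ValueError("need at least 2 accessions for a kernel")
    if freqs is None:
        freqs = g.allele_freqs
    freqs = np.asarray(freqs, dtype=float)

    if kind == "additive":
        denom = float(2.0 * np.sum(freqs * (1.0 - freqs)))
        if denom <= 0:
            raise ValueError("all loci monomorphic: additive kernel undefined")
        W = _additive_design(g.values, freqs)
        K = W @ W.T / denom
        return KernelMatrix(kind, list(g.accession_ids), K, freqs=freqs, denom=denom)
    if kind == "dominance":
        h = 2.0 * freqs * (1.0 - freqs)
        denom = float(np.sum(h**2))
        if denom <= 0:
            raise ValueError("all loci monomorphic: dominance kernel undefined")
        V = _dominance_design(g.values, freqs)
        K = V @ V.T / denom
        return KernelMatrix(kind, list(g.accession_ids), K, freqs=freqs, denom=denom)
    if kind == "gaussian":
        d2 = _sq_dists(g.values.astype(float), g.values.astype(float))
        if bandwidth is None:
            nz = d2[np.triu_indices_from(d2, k=1)]
            nz = nz[nz > 0]
            if len(nz) == 0:
                raise ValueError("all accessions identical: gaussian bandwidth undefined")
            bandwidth = float(np.median(nz))
        K = np.exp(-d2 / bandwidth)
        np.fill_diagonal(K, 1.0)
        return KernelMatrix(kind, list(g.accession_ids), K, bandwidth=bandwidth, freqs=freqs)
    raise ValueError(f"unknown kernel kind {kind!r}")


def cross_kernel(
    g_new: GenotypeMatrix, g_train: GenotypeMatrix, kernel: KernelMatrix
) -> np.ndarray:
    """Kernel values between new accessions (rows) and the training panel,
    using the centering frequencies / bandwidth frozen in ``kernel``."""
    if g_new.locus_ids != g_train.locus_ids:
        raise ValueError("new and training panels must share the locus set")
    if kernel.kind == "additive":
        Wn = _additive_design(g_new.values, kernel.freqs)
        Wt = _additive_design(g_train.values, kernel.freqs)
        return Wn @ Wt.T / kernel.denom
    if kernel.kind == "dominance":
        Vn = _dominance_design(g_new.values, kernel.freqs)
        Vt = _dominance_design(g_train.values, kernel.freqs)
        return Vn @ Vt.T / kernel.denom
    if kernel.kind == "gaussian":
        if kernel.bandwidth is None:
            raise ValueError("gaussian kernel lacks a stored bandwidth")
        d2 = _sq_dists(g_new.values.astype(float), g_train.values.astype(float))
        return np.exp(-d2 / kernel.bandwidth)
    raise ValueError(f"unknown kernel kind {kernel.kind!r}")


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class GPFit:
    """A fitted genomic prediction model.

    Marker models store per-locus effects on the original code scale, so a
    prediction is ``intercept + X @ beta``. Kernel models store variance
    ratios and the random-effect working vector, plus the training genotypes
    needed to extend the kernel to new accessions.
    """

    model: str
    trait: str
    training_ids: list[str]
    intercept: float
    parameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def predict(self, g_new: GenotypeMatrix) -> np.ndarray:
        if self.model in ("gblup_a", "gblup_ad", "gblup_gauss"):
            g_train = self.parameters["training_genotypes"]
            k_cross = [
                cross_kernel(g_new, g_train, k) for k in self.parameters["kernels"]
            ]
            return predict_kernel(self, k_cross)
        if self.model == "rf":
            est = self.parameters["estimator"]
            locus_ids = self.parameters["locus_ids"]
            if g_new.locus_ids != locus_ids:
                raise ValueError("locus set mismatch with the trained model")
            return est.predict(g_new.values.astype(float))
        beta = self.parameters["beta"]
        if g_new.locus_ids != self.parameters["locus_ids"]:
            raise ValueError("locus set mismatch with the trained model")
        pred = self.intercept + g_new.values.astype(float) @ beta
        if not np.isfinite(pred).all():
            raise RuntimeError("non-finite prediction")
        return pred

    def fitted(self, g_train: GenotypeMatrix) -> np.ndarray:
        return self.predict(g_train)

    # minimal on-disk store (marker and kernel models)
    def save(self, path: str | Path) -> None:
        path = Path(path)
        if self.model == "rf":
            raise NotImplementedError("use joblib to persist the forest ensemble")
        meta = {
            "model": self.model,
            "trait": self.trait,
            "training_ids": self.training_ids,
            "intercept": self.intercept,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items()
                if isinstance(v, (int, float, str, bool))
            },
        }
        arrays: dict[str, np.ndarray] = {}
        if "beta" in self.parameters:
            arrays["beta"] = np.asarray(self.parameters["beta"])
            meta["locus_ids"] = self.parameters["locus_ids"]
        else:
            g = self.parameters["training_genotypes"]
            arrays["training_values"] = g.values
            meta["locus_ids"] = list(g.locus_ids)
            meta["kernels"] = []
            for i, k in enumerate(self.parameters["kernels"]):
                arrays[f"kernel_{i}"] = k.values
                arrays[f"freqs_{i}"] = np.asarray(k.freqs)
                meta["kernels"].append(
                    {"kind": k.kind, "bandwidth": k.bandwidth, "denom": k.denom}
                )
            arrays["gammas"] = np.asarray(self.parameters["gammas"])
            arrays["w"] = np.asarray(self.parameters["w"])
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GPFit":
        dat = np.load(path, allow_pickle=False)
        meta = json.loads(str(dat["meta"]))
        fit = cls(
            model=meta["model"], trait=meta["trait"],
            training_ids=list(meta["training_ids"]),
            intercept=float(meta["intercept"]), diagnostics=meta.get("diagnostics", {}),
        )
        if "beta" in dat:
            fit.parameters = {"beta": dat["beta"], "locus_ids": list(meta["locus_ids"])}
        else:
            g = GenotypeMatrix(meta["training_ids"], meta["locus_ids"], dat["training_values"])
            kernels = [
                KernelMatrix(
                    km["kind"], meta["training_ids"], dat[f"kernel_{i}"],
                    bandwidth=km["bandwidth"], freqs=dat[f"freqs_{i}"], denom=km["denom"],
                )
                for i, km in enumerate(meta["kernels"])
            ]
            fit.parameters = {
                "training_genotypes": g, "kernels": kernels,
                "gammas": dat["gammas"], "w": dat["w"],
            }
        return fit


# ---------------------------------------------------------------------------
# kernel GBLUP
# ---------------------------------------------------------------------------

def _as_aligned(y: pd.Series | np.ndarray, ids: list[str]) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [a for a in ids if a not in y.index]
        if missing:
            raise ValueError(f"phenotypes missing for accessions {missing[:5]}")
        return y.loc[ids].to_numpy(float)
    y = np.asarray(y, float)
    if len(y) != len(ids):
        raise ValueError("phenotype vector does not conform to kernel accessions")
    return y


def _neg_rell_multi(y, X, kernels_vals, log_gammas):
    from scipy import linalg

    n, p = X.shape
    V0 = np.eye(n)
    for lg, K in zip(log_gammas, kernels_vals):
        V0 = V0 + np.exp(lg) * K
    try:
        c, low = linalg.cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return 1e30, None
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    Vi_r = Vi_y - Vi_X @ beta
    quad = float(resid @ Vi_r)
    if quad <= 0:
        return 1e30, None
    sign, logdet_X = np.linalg.slogdet(XtViX)
    nll = 0.5 * ((n - p) * np.log(quad) + logdet_V0 + logdet_X)
    return nll, (beta, Vi_r, quad)


def fit_gblup(
    y: pd.Series | np.ndarray,
    kernels: list[KernelMatrix],
    genotypes: GenotypeMatrix | None = None,
    trait: str = "",
) -> GPFit:
    """Kernel GBLUP by REML with the overall mean as the only fixed effect.

    One kernel: spectral/profile REML over the single variance ratio. Two
    kernels (additive + dominance): direct maximization of the restricted
    likelihood over both ratios with multiple restarts, components kept
    nonnegative by log-parameterization.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    ids = list(kernels[0].accession_ids)
    for k in kernels:
        if list(k.accession_ids) != ids:
            raise ValueError("kernels indexed by different accessions")
    yv = _as_aligned(y, ids)
    n = len(ids)
    X = np.ones((n, 1))

    if len(kernels) == 1:
        gamma, sigma_e2, beta, Vi_r = _reml_profile(yv, X, kernels[0].values)
        gammas = np.array([gamma])
        w = Vi_r
        model = {"additive": "gblup_a", "gaussian": "gblup_gauss",
                 "dominance": "gblup_d"}[kernels[0].kind]
        diagnostics = {"sigma2_e": sigma_e2, "sigma2_g": gamma * sigma_e2}
    elif len(kernels) == 2:
        kvals = [k.values for k in kernels]
        best = None
        for start in ((0.0, 0.0), (1.5, -1.5), (-1.5, 1.5)):
            res = optimize.minimize(
                lambda lg: _neg_rell_multi(yv, X, kvals, lg)[0],
                np.array(start), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("two-component REML did not converge")
        nll, aux = _neg_rell_multi(yv, X, kvals, best.x)
        beta, Vi_r, quad = aux
        sigma_e2 = quad / (n - 1)
        gammas = np.exp(best.x)
        w = Vi_r
        model = "gblup_ad"
        diagnostics = {
            "sigma2_e": sigma_e2,
            "sigma2_a": gammas[0] * sigma_e2,
            "sigma2_d": gammas[1] * sigma_e2,
        }
    else:
        raise ValueError("at most two kernels supported")

    fit = GPFit(
        model=model, trait=trait, training_ids=ids, intercept=float(beta[0]),
        parameters={"kernels": kernels, "gammas": gammas, "w": w,
                    "training_genotypes": genotypes},
        diagnostics=diagnostics,
    )
    return fit


def predict_kernel(fit: GPFit, k_cross: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Kernel-BLUP extension: intercept + sum_k gamma_k K_cross,k w."""
    if isinstance(k_cross, np.ndarray):
        k_cross = [k_cross]
    gammas = fit.parameters["gammas"]
    if len(k_cross) != len(gammas):
        raise ValueError("one cross-kernel required per trained kernel")
    pred = np.full(k_cross[0].shape[0], fit.intercept, dtype=float)
    for gamma, kc in zip(gammas, k_cross):
        pred = pred + gamma * kc @ fit.parameters["w"]
    if not np.isfinite(pred).all():
        raise RuntimeError("non-finite kernel prediction")
    return pred


# ---------------------------------------------------------------------------
# penalized regression (scikit-learn coordinate descent / closed-form ridge)
# ---------------------------------------------------------------------------

def fit_penalized(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    penalty: str,
    folds: int = 5,
    seed: int = 0,
    alpha: float | None = None,
    trait: str = "",
) -> GPFit:
    """Elastic-net family on standardized markers; mixing 0 / 0.5 / 1 for
    ridge / en / lasso. The penalty strength is chosen by seeded k-fold CV
    (minimum MSE over a log-spaced path) unless ``alpha`` is given; returned
    coefficients are back-transformed to the original code scale."""
    if penalty not in ("ridge", "lasso", "en"):
        raise ValueError(f"unknown penalty {penalty!r}")
    yv = _as_aligned(y, list(g.accession_ids))
    if np.std(yv) == 0:
        raise ValueError("constant phenotype: penalized fit undefined")
    n = len(yv)
    if alpha is None and not (2 <= folds <= n):
        raise ValueError("need n >= folds >= 2 for cross-validation")

    X = g.values.astype(float)
    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    keep = sd_x > 0
    Xs = (X[:, keep] - mu_x[keep]) / sd_x[keep]

    if penalty == "ridge":
        if alpha is None:
            grid = np.logspace(-4, 6, 81)
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
            mse = np.zeros(len(grid))
            for tr, te in kf.split(Xs):
                for i, a in enumerate(grid):
                    m = Ridge(alpha=a).fit(Xs[tr], yv[tr])
                    mse[i] += np.mean((m.predict(Xs[te]) - yv[te]) ** 2)
            alpha = float(grid[int(np.argmin(mse))])
        est = Ridge(alpha=alpha).fit(Xs, yv)
    else:
        l1 = 1.0 if penalty == "lasso" else 0.5
        if alpha is None:
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
            est = ElasticNetCV(
                l1_ratio=l1, alphas=80, cv=kf, max_iter=50000, tol=1e-6,
            ).fit(Xs, yv)
            alpha = float(est.alpha_)
        est = ElasticNet(alpha=alpha, l1_ratio=l1, max_iter=50000, tol=1e-6).fit(Xs, yv)

    beta = np.zeros(g.n_loci)
    beta[keep] = est.coef_ / sd_x[keep]
    intercept = float(est.intercept_) - float(mu_x @ beta)
    return GPFit(
        model=penalty, trait=trait, training_ids=list(g.accession_ids),
        intercept=intercept,
        parameters={"beta": beta, "locus_ids": list(g.locus_ids)},
        diagnostics={"alpha": alpha, "n_nonzero": int(np.count_nonzero(beta))},
    )


# ---------------------------------------------------------------------------
# Bayesian whole-genome regression (Gibbs)
# ---------------------------------------------------------------------------

_VARIANT = {"brr": 0, "bayes_a": 1, "bayes_b": 2, "bayes_c": 3}


@njit(cache=False)
def _gibbs_sweep(Xt, xtx, resid, beta, incl, var_j, sigma_e2, log_odds_pi, spike, z, u):
    """One single-site Gibbs sweep over all markers (in-place).

    spike=True enables the spike-and-slab inclusion step (Bayes B/C);
    log_odds_pi = log(pi / (1 - pi)).
    """
    p, n = Xt.shape
    for j in range(p):
        xj = Xt[j]
        rj = 0.0
        for i in range(n):
            rj += xj[i] * resid[i]
        rj += xtx[j] * beta[j]
        vj = var_j[j]
        include = True
        if spike:
            c = xtx[j] + sigma_e2 / vj
            lo = log_odds_pi + 0.5 * (rj * rj / (sigma_e2 * c)) \
                + 0.5 * np.log(sigma_e2 / (vj * c))
            if lo > 35.0:
                prob = 1.0
            elif lo < -35.0:
                prob = 0.0
            else:
                prob = 1.0 / (1.0 + np.exp(-lo))
            include = u[j] < prob
        old = beta[j]
        if include:
            lhs = xtx[j] + sigma_e2 / vj
            newb = rj / lhs + z[j] * np.sqrt(sigma_e2 / lhs)
            incl[j] = 1.0
        else:
            newb = 0.0
            incl[j] = 0.0
        if newb != old:
            diff = old - newb
            for i in range(n):
                resid[i] += xj[i] * diff
            beta[j] = newb


def fit_bayes(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    model: str,
    n_iter: int = 6000,
    burn_in: int = 1000,
    seed: int = 0,
    pi_fixed: float | None = None,
    trait: str = "",
    nu: float = 4.0,
    r2: float = 0.5,
) -> GPFit:
    """Gibbs samplers for BRR / Bayes A / Bayes B / Bayes C.

    BRR: one marker-effect variance with a scaled-inverse-chi^2 prior; Bayes A:
    per-marker variances; Bayes B/C: spike-and-slab inclusion with sampled
    prior inclusion probability pi ~ Beta(1, 9) (B: per-marker slab variances,
    C: one slab variance). Hyperprior scales follow the usual R^2-style
    partition of the phenotypic variance (half to markers by default).
    Deterministic under a fixed seed; returns posterior-mean effects.
    """
    if model not in _VARIANT:
        raise ValueError(f"unknown Bayesian model {model!r}")
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    variant = _VARIANT[model]
    spike = variant >= 2

    yv = _as_aligned(y, list(g.accession_ids))
    n = len(yv)
    X = g.values.astype(float)
    mu_x = X.mean(axis=0)
    Xc = X - mu_x
    p = Xc.shape[1]
    Xt = np.ascontiguousarray(Xc.T)
    xtx = (Xc**2).sum(axis=0)

    vy = float(np.var(yv))
    if vy == 0:
        raise ValueError("constant phenotype")
    msx = float(np.sum(Xc.var(axis=0)))
    if msx == 0:
        raise ValueError("monomorphic marker panel")
    pi0 = pi_fixed if pi_fixed is not None else 0.1
    scale_b = r2 * vy * (nu + 2.0) / (nu * msx)
    if spike:
        scale_b = scale_b / max(pi0, 1e-3)
    nu_e = 4.0
    scale_e = (1.0 - r2) * vy * (nu_e + 2.0) / nu_e

    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    incl = np.ones(p)
    var_j = np.full(p, scale_b * nu / (nu + 2.0))
    sigma_e2 = max((1.0 - r2) * vy, 1e-8)
    mu = float(np.mean(yv))
    resid = yv - mu
    pi = float(pi0)

    kept = 0
    beta_acc = np.zeros(p)
    mu_acc = 0.0
    se_acc = 0.0
    sb_acc = 0.0
    pi_acc = 0.0

    for it in range(n_iter):
        z = rng.standard_normal(p)
        u = rng.random(p)
        pi_c = min(max(pi, 1e-8), 1.0 - 1e-8)
        _gibbs_sweep(
            Xt, xtx, resid, beta, incl, var_j, sigma_e2,
            np.log(pi_c / (1.0 - pi_c)), spike, z, u,
        )

        # intercept
        resid += mu
        mu = float(np.mean(resid)) + rng.standard_normal() * np.sqrt(sigma_e2 / n)
        resid -= mu

        # marker-effect variances
        if variant == 0 or variant == 3:  # common variance (BRR / Bayes C slab)
            m_in = float(incl.sum()) if spike else float(p)
            ssq = float(np.sum(beta**2))
            sigma_b2 = (ssq + nu * scale_b) / rng.chisquare(nu + m_in)
            var_j[:] = sigma_b2
        else:  # per-marker variances (Bayes A / Bayes B slabs)
            chi_in = rng.chisquare(nu + 1.0, size=p)
            var_in = (beta**2 + nu * scale_b) / chi_in
            if spike:
                chi_out = rng.chisquare(nu, size=p)
                var_out = nu * scale_b / chi_out
                var_j[:] = np.where(incl > 0, var_in, var_out)
            else:
                var_j[:] = var_in
            sigma_b2 = float(np.mean(var_j))

        # residual variance
        sse = float(resid @ resid)
        sigma_e2 = (sse + nu_e * scale_e) / rng.chisquare(n + nu_e)

        # inclusion probability
        if spike and pi_fixed is None:
            m_in = float(incl.sum())
            pi = float(rng.beta(1.0 + m_in, 9.0 + p - m_in))
        elif spike:
            pi = float(pi_fixed)

        if it % 200 == 0 and not (np.isfinite(sigma_e2) and np.isfinite(resid).all()):
            raise RuntimeError(
                f"divergent chain at iteration {it}: sigma_e2={sigma_e2!r}"
            )
        if it >= burn_in:
            kept += 1
            beta_acc += beta
            mu_acc += mu
            se_acc += sigma_e2
            sb_acc += sigma_b2
            pi_acc += pi

    beta_mean = beta_acc / kept
    mu_mean = mu_acc / kept
    intercept = mu_mean - float(mu_x @ beta_mean)
    return GPFit(
        model=model, trait=trait, training_ids=list(g.accession_ids),
        intercept=intercept,
        parameters={"beta": beta_mean, "locus_ids": list(g.locus_ids)},
        diagnostics={
            "n_iter": n_iter, "burn_in": burn_in,
            "sigma2_e": se_acc / kept, "sigma2_b": sb_acc / kept,
            "pi": pi_acc / kept if spike else 1.0,
        },
    )


# ---------------------------------------------------------------------------
# bagged trees
# ---------------------------------------------------------------------------

def fit_forest(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    n_trees: int = 500,
    seed: int = 0,
    trait: str = "",
) -> GPFit:
    """Bagged regression-tree ensemble on the numeric genotype codes
    (random-forest regression defaults: mtry = p/3, seeded)."""
    yv = _as_aligned(y, list(g.accession_ids))
    if len(yv) < 10:
        raise ValueError("need at least 10 training accessions for the forest")
    if not np.isfinite(yv).all():
        raise ValueError("non-finite phenotype: forest fit degenerate")
    est = RandomForestRegressor(
        n_estimators=n_trees, max_features=1.0 / 3.0, random_state=seed, n_jobs=1,
    ).fit(g.values.astype(float), yv)
    return GPFit(
        model="rf", trait=trait, training_ids=list(g.accession_ids),
        intercept=float(np.mean(yv)),
        parameters={"estimator": est, "locus_ids": list(g.locus_ids)},
        diagnostics={"n_trees": n_trees},
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def fit_model(
    model: str,
    y: pd.Series,
    g: GenotypeMatrix,
    seed: int = 0,
    trait: str = "",
    bayes_n_iter: int = 6000,
    bayes_burn_in: int = 1000,
) -> GPFit:
    """Train any of the eleven supported models on the given panel."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model in ("ridge", "lasso", "en"):
        return fit_penalized(y, g, model, seed=seed, trait=trait)
    if model in _VARIANT:
        return fit_bayes(
            y, g, model, n_iter=bayes_n_iter, burn_in=bayes_burn_in,
            seed=seed, trait=trait,
        )
    if model == "rf":
        return fit_forest(y, g, seed=seed, trait=trait)
    if model == "gblup_a":
        kernels = [build_kernel(g, "additive")]
    elif model == "gblup_gauss":
        kernels = [build_kernel(g, "gaussian")]
    else:  # gblup_ad
        kernels = [build_kernel(g, "additive"), build_kernel(g, "dominance")]
    return fit_gblup(y, kernels, genotypes=g, trait=trait)
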