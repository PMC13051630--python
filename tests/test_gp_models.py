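import numpy as np
import pandas as pd
import pytest

from crosspred.genotype_core import GenotypeMatrix
from crosspred.gp_models import (
    KernelMatrix,
    build_kernel,
    cross_kernel,
    fit_bayes,
    fit_forest,
    fit_gblup,
    fit_model,
    fit_penalized,
    predict_kernel,
)
from crosspred.simdata import (
    SimConfig,
    simulate_architecture,
    simulate_founder_genotypes,
    simulate_phenotypes,
)


def sim_panel(n, p, seed, h2=0.9, n_qtl=None, maf=(0.15, 0.5)):
    """Inbred panel + accession-mean phenotypes from an additive trait."""
    cfg = SimConfig(n_inbred=n, n_loci=p, n_parents=2, n_f1=1, seed=seed,
                    maf_range=maf, h2_target=h2)
    g = simulate_founder_genotypes(cfg)
    arch = simulate_architecture(p, n_qtl or max(p // 4, 2), 0.0, seed + 1,
                                 allele_freqs=g.allele_freqs)
    rec = simulate_phenotypes(g, arch, cfg, trait="t")
    y = rec.groupby("accession")["value"].mean().loc[list(g.accession_ids)]
    return g, y, arch


def flip_polarity(g: GenotypeMatrix, seed=0) -> GenotypeMatrix:
    flip = np.random.default_rng(seed).random(g.n_loci) < 0.5
    return GenotypeMatrix(
        list(g.accession_ids), list(g.locus_ids),
        np.where(flip, -g.values, g.values),
    )


class TestKernels:
    def test_duplicate_accessions_have_unit_gaussian_entry(self):
        values = np.array([[1, -1, 0, 1], [1, -1, 0, 1], [-1, 1, 1, -1]])
        g = GenotypeMatrix(["a", "b", "c"], list("wxyz"), values)
        k = build_kernel(g, "gaussian")
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_additive_kernel_mean_diagonal_near_one_under_hwe(self):
        # VanRaden scaling: E[diag] = 1 in a random-mating panel
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 400)
        values = rng.binomial(2, p, size=(300, 400)) - 1
        g = GenotypeMatrix([f"s{i}" for i in range(300)],
                           [f"m{j}" for j in range(400)], values)
        k = build_kernel(g, "additive")
        assert np.mean(np.diag(k.values)) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("kind", ["additive", "dominance", "gaussian"])
    def test_construction_invariants(self, small_founders, kind):
        k = build_kernel(small_founders, kind)
        assert np.max(np.abs(k.values - k.values.T)) < 1e-10
        assert np.linalg.eigvalsh(k.values)[0] >= -1e-8
        if kind == "gaussian":
            np.testing.assert_allclose(np.diag(k.values), 1.0)

    @pytest.mark.parametrize("kind", ["additive", "dominance", "gaussian"])
    def test_polarity_flip_invariance(self, small_founders, kind):
        k0 = build_kernel(small_founders, kind)
        k1 = build_kernel(flip_polarity(small_founders, 3), kind)
        np.testing.assert_allclose(k0.values, k1.values, atol=1e-10)

    def test_monomorphic_input_rejected(self):
        g = GenotypeMatrix(["a", "b"], ["m1"], np.array([[1], [1]]))
        with pytest.raises(ValueError):
            build_kernel(g, "additive")

    def test_corrupted_kernel_rejected(self, small_founders):
        k = build_kernel(small_founders, "additive")
        bad = k.values.copy()
        bad[0, 1] += 1e-6
        with pytest.raises(ValueError, match="symmetric"):
            KernelMatrix("additive", list(small_founders.accession_ids), bad)


class TestGblup:
    def test_constant_phenotype_predicts_the_mean(self, small_founders):
        y = pd.Series(3.5, index=small_founders.accession_ids)
        fit = fit_gblup(y, [build_kernel(small_founders, "additive")],
                        genotypes=small_founders)
        np.testing.assert_allclose(fit.predict(small_founders), 3.5, atol=1e-8)
        assert fit.diagnostics["sigma2_g"] == pytest.approx(0.0, abs=1e-8)

    def test_genetic_variance_share_recovered(self):
        # n > p so the kernel is rank-deficient and the residual variance is
        # identified; the panel genetic variance is sigma_g^2 * mean(diag K)
        # (inbreds double the additive kernel diagonal)
        g, y, _ = sim_panel(200, 100, seed=61, h2=0.9, n_qtl=50)
        k = build_kernel(g, "additive")
        fit = fit_gblup(y, [k], genotypes=g)
        panel_sg = fit.diagnostics["sigma2_g"] * np.mean(np.diag(k.values))
        share = panel_sg / (panel_sg + fit.diagnostics["sigma2_e"])
        assert 0.8 < share < 0.97

    def test_gaussian_reproduces_fitted_value_at_zero_distance(self):
        g, y, _ = sim_panel(30, 60, seed=62)
        fit = fit_gblup(y, [build_kernel(g, "gaussian")], genotypes=g)
        one = g.subset_accessions([g.accession_ids[4]])
        clone = GenotypeMatrix(["clone"], list(g.locus_ids), one.values)
        assert fit.predict(clone)[0] == pytest.approx(fit.predict(g)[4])

    def test_far_away_accession_predicted_at_the_intercept(self):
        g, y, _ = sim_panel(30, 60, seed=63)
        fit = fit_gblup(y, [build_kernel(g, "gaussian")], genotypes=g)
        k_zero = np.zeros((1, g.n_accessions))
        assert predict_kernel(fit, k_zero)[0] == pytest.approx(fit.intercept)

    def test_two_kernel_fit_runs_and_predicts_finite(self):
        g, y, _ = sim_panel(50, 100, seed=64)
        fit = fit_gblup(
            y, [build_kernel(g, "additive"), build_kernel(g, "dominance")],
            genotypes=g,
        )
        assert fit.model == "gblup_ad"
        assert np.isfinite(fit.predict(g)).all()

    def test_prediction_polarity_invariance(self):
        g, y, _ = sim_panel(40, 80, seed=65)
        fit0 = fit_gblup(y, [build_kernel(g, "additive")], genotypes=g)
        gf = flip_polarity(g, 7)
        fit1 = fit_gblup(y, [build_kernel(gf, "additive")], genotypes=gf)
        np.testing.assert_allclose(fit0.predict(g), fit1.predict(gf), atol=1e-8)

    def test_mismatched_indices_rejected(self, small_founders):
        y = pd.Series(1.0, index=[f"other{i}" for i in range(40)])
        with pytest.raises(ValueError):
            fit_gblup(y, [build_kernel(small_founders, "additive")])


class TestPenalized:
    def test_full_shrinkage_limit(self):
        g, y, _ = sim_panel(25, 40, seed=71)
        fit = fit_penalized(y, g, "lasso", alpha=1e9)
        assert np.all(fit.parameters["beta"] == 0)
        np.testing.assert_allclose(fit.predict(g), y.mean(), atol=1e-8)

    def test_ridge_matches_normal_equations_at_fixed_penalty(self):
        # 5 x 3 toy against the closed form on standardized markers
        values = np.array(
            [[-1, 1, 0], [1, -1, 1], [1, 1, -1], [-1, -1, -1], [0, 1, 1]]
        )
        g = GenotypeMatrix(list("abcde"), ["m1", "m2", "m3"], values)
        y = pd.Series([1.0, 2.0, 0.5, -1.0, 1.5], index=list("abcde"))
        alpha = 2.0
        fit = fit_penalized(y, g, "ridge", alpha=alpha)
        X = values.astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        yv = y.to_numpy()
        beta_s = np.linalg.solve(Xs.T @ Xs + alpha * np.eye(3), Xs.T @ (yv - yv.mean()))
        np.testing.assert_allclose(
            fit.parameters["beta"], beta_s / X.std(0), atol=1e-8
        )
        np.testing.assert_allclose(fit.predict(g), yv.mean() + Xs @ beta_s, atol=1e-8)

    def test_lasso_soft_thresholds_on_orthonormal_design(self):
        # columns orthogonal with unit standardized variance
        values = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]])
        g = GenotypeMatrix(list("abcd"), ["m1", "m2"], values)
        y = pd.Series([2.0, 0.5, -0.5, -2.0], index=list("abcd"))
        alpha = 0.3
        fit = fit_penalized(y, g, "lasso", alpha=alpha)
        X = values.astype(float)
        ols = X.T @ (y.to_numpy() - y.mean()) / len(y)
        soft = np.sign(ols) * np.maximum(np.abs(ols) - alpha, 0.0)
        np.testing.assert_allclose(fit.parameters["beta"], soft, atol=1e-6)

    def test_cross_validated_fit_detects_signal(self):
        g, y, _ = sim_panel(60, 80, seed=72)
        fit = fit_penalized(y, g, "en", seed=1)
        r = np.corrcoef(fit.predict(g), y)[0, 1]
        assert r > 0.5

    def test_constant_phenotype_rejected(self, small_founders):
        y = pd.Series(1.0, index=small_founders.accession_ids)
        with pytest.raises(ValueError, match="constant"):
            fit_penalized(y, small_founders, "ridge")

    def test_fixed_penalty_polarity_invariance(self):
        g, y, _ = sim_panel(30, 50, seed=73)
        fit0 = fit_penalized(y, g, "ridge", alpha=5.0)
        gf = flip_polarity(g, 11)
        fit1 = fit_penalized(y, gf, "ridge", alpha=5.0)
        np.testing.assert_allclose(fit0.predict(g), fit1.predict(gf), atol=1e-8)


class TestBayes:
    def test_null_data_shrinks_to_the_mean(self):
        rng = np.random.default_rng(81)
        cfg = SimConfig(n_inbred=40, n_loci=60, n_parents=2, n_f1=1, seed=81,
                        maf_range=(0.2, 0.5))
        g = simulate_founder_genotypes(cfg)
        y = pd.Series(rng.normal(0, 1, 40), index=g.accession_ids)
        fit = fit_bayes(y, g, "brr", n_iter=1500, burn_in=300, seed=1)
        pred = fit.predict(g)
        assert np.std(pred) < 0.6 * np.std(y.to_numpy())

    def test_deterministic_under_fixed_seed(self):
        g, y, _ = sim_panel(30, 40, seed=82)
        f1 = fit_bayes(y, g, "bayes_c", n_iter=800, burn_in=200, seed=4)
        f2 = fit_bayes(y, g, "bayes_c", n_iter=800, burn_in=200, seed=4)
        np.testing.assert_array_equal(f1.parameters["beta"], f2.parameters["beta"])

    @pytest.mark.parametrize("model", ["brr", "bayes_a", "bayes_b", "bayes_c"])
    def test_all_samplers_fit_signal(self, model):
        g, y, _ = sim_panel(50, 60, seed=83, n_qtl=10)
        fit = fit_bayes(y, g, model, n_iter=1500, burn_in=300, seed=2)
        r = np.corrcoef(fit.predict(g), y)[0, 1]
        assert r > 0.6

    def test_invalid_arguments(self, small_founders):
        y = pd.Series(np.arange(40.0), index=small_founders.accession_ids)
        with pytest.raises(ValueError, match="unknown"):
            fit_bayes(y, small_founders, "bayes_z")
        with pytest.raises(ValueError, match="n_iter"):
            fit_bayes(y, small_founders, "brr", n_iter=10, burn_in=10)


class TestForest:
    def test_constant_phenotype_gives_constant_predictions(self):
        g, y, _ = sim_panel(20, 30, seed=91)
        y[:] = 4.2
        fit = fit_forest(y, g, n_trees=20, seed=1)
        np.testing.assert_allclose(fit.predict(g), 4.2)

    def test_predictions_within_training_range(self):
        g, y, _ = sim_panel(40, 60, seed=92)
        fit = fit_forest(y, g, n_trees=100, seed=1)
        pred = fit.predict(g)
        assert pred.min() >= y.min() - 1e-9 and pred.max() <= y.max() + 1e-9

    def test_single_qtl_signal_detected_out_of_sample(self):
        cfg = SimConfig(n_inbred=80, n_loci=50, n_parents=2, n_f1=1, seed=93,
                        maf_range=(0.3, 0.5), h2_target=0.9)
        g = simulate_founder_genotypes(cfg)
        arch = simulate_architecture(50, 1, 0.0, 94, allele_freqs=g.allele_freqs)
        rec = simulate_phenotypes(g, arch, cfg, trait="t")
        y = rec.groupby("accession")["value"].mean().loc[list(g.accession_ids)]
        train, test = g.accession_ids[:60], g.accession_ids[60:]
        fit = fit_forest(y.loc[train], g.subset_accessions(train), n_trees=200, seed=5)
        pred = fit.predict(g.subset_accessions(test))
        assert np.corrcoef(pred, y.loc[test])[0, 1] > 0

    def test_too_small_panel_rejected(self):
        g, y, _ = sim_panel(20, 30, seed=95)
        with pytest.raises(ValueError, match="at least 10"):
            fit_forest(y.iloc[:5], g.subset_accessions(g.accession_ids[:5]))


class TestFitDispatchAndStore:
    def test_unknown_model_rejected(self, small_founders):
        y = pd.Series(np.arange(40.0), index=small_founders.accession_ids)
        with pytest.raises(ValueError, match="unknown model"):
            fit_model("superlearner", y, small_founders)

    def test_marker_fit_roundtrip(self, tmp_path):
        g, y, _ = sim_panel(25, 30, seed=96)
        fit = fit_penalized(y, g, "ridge", alpha=1.0)
        path = tmp_path / "fit.npz"
        fit.save(path)
        from crosspred.gp_models import GPFit

        back = GPFit.load(path)
        np.testing.assert_allclose(back.predict(g), fit.predict(g))

    def test_kernel_fit_roundtrip(self, tmp_path):
        g, y, _ = sim_panel(25, 30, seed=97)
        fit = fit_gblup(y, [build_kernel(g, "gaussian")], genotypes=g)
        path = tmp_path / "fit.npz"
        fit.save(path)
        from crosspred.gp_models import GPFit

        back = GPFit.load(path)
        np.testing.assert_allclose(back.predict(g), fit.predict(g))

    def test_cross_kernel_requires_matching_loci(self):
        g, y, _ = sim_panel(20, 30, seed=98)
        k = build_kernel(g, "additive")
        other = GenotypeMatrix(["x"], [f"zz{j}" for j in range(30)],
                               g.values[:1])
        with pytest.raises(ValueError, match="locus set"):
            cross_kernel(other, g, k)
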