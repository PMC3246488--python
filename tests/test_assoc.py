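"""Association scans: OLS, genomic control, mixed model, conditional."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pgskit
from pgskit import assoc

from conftest import random_genotype_matrix


class TestOlsScan:
    def test_hand_fixture_matches_textbook_formulas(self):
        rng = np.random.default_rng(0)
        gm = random_genotype_matrix(rng, 8, 3)
        y = rng.normal(size=8)
        scan = assoc.ols_scan(y, gm)
        for _, row in scan.iterrows():
            j = gm.snps.index[gm.snps["snp_id"] == row["snp_id"]][0]
            x = gm.dosage[:, j]
            sxx = np.sum((x - x.mean()) ** 2)
            sxy = np.sum((x - x.mean()) * (y - y.mean()))
            beta = sxy / sxx
            sse = np.sum((y - y.mean() - beta * (x - x.mean())) ** 2)
            se = np.sqrt(sse / (8 - 2) / sxx)
            assert row["beta"] == pytest.approx(beta, abs=1e-12)
            assert row["se"] == pytest.approx(se, abs=1e-12)

    def test_perfect_association(self):
        rng = np.random.default_rng(1)
        gm = random_genotype_matrix(rng, 200, 1)
        y = gm.dosage[:, 0].copy()
        scan = assoc.ols_scan(y, gm)
        assert scan.loc[0, "beta"] == pytest.approx(1.0, abs=1e-12)
        assert scan.loc[0, "se"] < 1e-8
        assert scan.loc[0, "p"] < 1e-100

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        gm = random_genotype_matrix(rng, 300, 2000)
        y = rng.permutation(rng.normal(size=300))
        scan = assoc.ols_scan(y, gm)
        frac = (scan["p"] < 0.05).mean()
        bound = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < bound

    def test_monomorphic_snps_skipped(self):
        rng = np.random.default_rng(3)
        gm = random_genotype_matrix(rng, 50, 5)
        gm.dosage[:, 2] = 1.0
        scan = assoc.ols_scan(rng.normal(size=50), gm)
        assert "m2" not in set(scan["snp_id"])
        assert len(scan) == 4

    def test_chi2_p_consistency(self):
        rng = np.random.default_rng(4)
        gm = random_genotype_matrix(rng, 100, 50)
        scan = assoc.ols_scan(rng.normal(size=100), gm)
        np.testing.assert_allclose(scan["p"],
                                   stats.chi2.sf(scan["chi2"], 1), atol=1e-10)


class TestGenomicKinship:
    def test_duplicated_sample_self_similarity(self):
        rng = np.random.default_rng(5)
        gm = random_genotype_matrix(rng, 40, 500)
        gm.dosage[1] = gm.dosage[0]
        kin = assoc.genomic_kinship(gm)
        assert kin.values[0, 1] == pytest.approx(kin.values[0, 0], abs=1e-12)
        assert kin.values[0, 1] == pytest.approx(kin.values[1, 1], abs=1e-12)

    def test_unrelated_offdiagonal_near_zero(self):
        rng = np.random.default_rng(6)
        gm = random_genotype_matrix(rng, 300, 2000)
        kin = assoc.genomic_kinship(gm)
        off = kin.values[~np.eye(300, dtype=bool)]
        # sample-frequency centering leaves an O(1/n) offset; the mean must
        # be negligible against the 0.5 scale of true first-degree pairs
        assert abs(off.mean()) < 0.01
        assert np.abs(off).max() < 0.25
        assert 0.95 < np.diag(kin.values).mean() < 1.05

    def test_symmetric_and_psd_after_ridge(self):
        rng = np.random.default_rng(7)
        gm = random_genotype_matrix(rng, 60, 300)
        kin = assoc.genomic_kinship(gm)
        np.testing.assert_allclose(kin.values, kin.values.T, atol=1e-12)
        w = np.linalg.eigvalsh(kin.values + 1e-8 * np.eye(60))
        assert w.min() > -1e-10


class TestGenomicControl:
    def test_lambda_of_null_median(self):
        assert assoc.gc_lambda([assoc.CHI2_1DF_MEDIAN] * 5) == pytest.approx(1.0)

    def test_lambda_sort_and_divide(self):
        assert assoc.gc_lambda([1.0, 2.0, 3.0]) == pytest.approx(
            2.0 / 0.4549364, abs=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            assoc.gc_lambda([])

    def test_identity_when_lambda_one(self):
        rng = np.random.default_rng(8)
        gm = random_genotype_matrix(rng, 100, 20)
        scan = assoc.ols_scan(rng.normal(size=100), gm)
        out = assoc.gc_correct(scan, 1.0)
        np.testing.assert_allclose(out.assoc["chi2"], scan["chi2"])
        np.testing.assert_allclose(out.assoc["p"], scan["p"])

    def test_corrected_p_is_chi2_tail(self):
        scan = pd.DataFrame({"snp_id": ["a"], "chrom": "1", "pos": [1],
                             "counted_allele": "A", "beta": [0.1],
                             "se": [0.05], "chi2": [3.841],
                             "p": [stats.chi2.sf(3.841, 1)], "method": "ols"})
        out = assoc.gc_correct(scan, 2.0)
        assert out.assoc.loc[0, "chi2"] == pytest.approx(1.9205)
        assert out.assoc.loc[0, "p"] == pytest.approx(
            stats.chi2.sf(1.9205, 1), abs=1e-12)

    def test_ranking_preserved(self):
        rng = np.random.default_rng(9)
        chi2 = rng.chisquare(1, size=1000)
        scan = pd.DataFrame({"snp_id": [f"s{i}" for i in range(1000)],
                             "chrom": "1", "pos": np.arange(1000),
                             "counted_allele": "A", "beta": 0.0, "se": 1.0,
                             "chi2": chi2, "p": stats.chi2.sf(chi2, 1),
                             "method": "ols"})
        out = assoc.gc_correct(scan, 1.7)
        assert (out.assoc["p"].rank().to_numpy()
                == scan["p"].rank().to_numpy()).all()

    def test_deflation_reported_but_not_applied(self):
        scan = pd.DataFrame({"snp_id": ["a"], "chrom": "1", "pos": [1],
                             "counted_allele": "A", "beta": [0.1],
                             "se": [0.05], "chi2": [2.0],
                             "p": [stats.chi2.sf(2.0, 1)], "method": "ols"})
        out = assoc.gc_correct(scan, 0.8)
        assert out.lambda_raw == pytest.approx(0.8)
        assert out.lambda_used == 1.0
        assert out.assoc.loc[0, "chi2"] == pytest.approx(2.0)


class TestNullLMM:
    def test_optimum_beats_random_admissible_points(self):
        rng = np.random.default_rng(10)
        gm = random_genotype_matrix(rng, 150, 800)
        kin = assoc.genomic_kinship(gm)
        y = rng.normal(size=150)
        vc = assoc.fit_null_lmm(y, kin)
        tot = vc.sigma_g2 + vc.sigma_e2
        for h in rng.uniform(0.0, 0.99, size=10):
            ll = assoc.lmm_loglik(y, kin, h * tot, (1 - h) * tot)
            assert vc.loglik >= ll - 1e-6

    def test_null_sigma_g2_near_boundary(self):
        # with no polygenic signal and an informative (family-structured)
        # kinship, the genetic component collapses toward the 0 boundary
        hits = 0
        for rep in range(12):
            cfg = pgskit.SimConfig(n_families=60, n_related=300,
                                   n_unrelated=50, n_male=170, n_snps=3000,
                                   rng_seed=500 + rep)
            samples = pgskit.simulate_pedigrees(cfg)
            gm = pgskit.drop_genotypes(samples, cfg)
            kin = assoc.genomic_kinship(gm)
            rng = np.random.default_rng(rep)
            vc = assoc.fit_null_lmm(rng.standard_normal(350), kin)
            if vc.heritability < 0.25:
                hits += 1
        assert hits >= 11

    def test_identity_kinship_degenerate(self):
        rng = np.random.default_rng(11)
        kin = assoc.KinshipMatrix(np.eye(80), [f"s{i}" for i in range(80)], 0)
        vc = assoc.fit_null_lmm(rng.normal(size=80), kin)
        assert vc.degenerate
        assert vc.sigma_g2 == 0.0

    def test_component_recovery_family_cohort(self):
        # sigma_g2 = sigma_e2 = 1 on a family cohort; genomic kinship
        errs_g, errs_e = [], []
        for rep in range(6):
            cfg = pgskit.SimConfig(n_families=100, n_related=600,
                                   n_unrelated=0, n_male=300, n_snps=6000,
                                   rng_seed=300 + rep)
            samples = pgskit.simulate_pedigrees(cfg)
            gm = pgskit.drop_genotypes(samples, cfg)
            A = pgskit.pedigree_relationship(samples)
            rng = np.random.default_rng(rep)
            L = np.linalg.cholesky(A + 1e-10 * np.eye(600))
            y = L @ rng.standard_normal(600) + rng.standard_normal(600)
            kin = assoc.genomic_kinship(gm)
            vc = assoc.fit_null_lmm(y, kin)
            errs_g.append(abs(vc.sigma_g2 - 1.0))
            errs_e.append(abs(vc.sigma_e2 - 1.0))
        assert np.mean(errs_g) <= 0.3
        assert np.mean(errs_e) <= 0.3


class TestMGScan:
    def test_collapses_to_ols_when_no_polygenic_variance(self):
        rng = np.random.default_rng(12)
        gm = random_genotype_matrix(rng, 120, 500)
        kin = assoc.genomic_kinship(gm)
        y = rng.normal(size=120)
        ols = assoc.ols_scan(y, gm)
        mg = assoc.mg_scan(y, gm, assoc.VarianceComponents(0.0, 1.0, 0.0), kin)
        np.testing.assert_allclose(mg["beta"], ols["beta"], atol=1e-8)
        np.testing.assert_allclose(mg["se"], ols["se"], atol=1e-8)
        np.testing.assert_allclose(mg["p"], ols["p"], atol=1e-8)

    def test_hand_fixture_matches_explicit_gls(self):
        rng = np.random.default_rng(13)
        gm = random_genotype_matrix(rng, 10, 2)
        y = rng.normal(size=10)
        B = rng.normal(size=(10, 3))
        K = B @ B.T / 3
        K = K / np.diag(K).mean()
        kin = assoc.KinshipMatrix((K + K.T) / 2, gm.sample_ids, 3)
        vc = assoc.VarianceComponents(0.6, 0.4, 0.0)
        mg = assoc.mg_scan(y, gm, vc, kin)
        V = 0.6 * (kin.values + 1e-8 * np.eye(10)) + 0.4 * np.eye(10)
        Vi = np.linalg.inv(V)
        for _, row in mg.iterrows():
            j = gm.snps.index[gm.snps["snp_id"] == row["snp_id"]][0]
            X = np.column_stack([np.ones(10), gm.dosage[:, j]])
            XtVi = X.T @ Vi
            coef = np.linalg.solve(XtVi @ X, XtVi @ y)
            resid = y - X @ coef
            s2 = (resid @ Vi @ resid) / (10 - 2)
            cov = s2 * np.linalg.inv(XtVi @ X)
            assert row["beta"] == pytest.approx(coef[1], abs=1e-8)
            assert row["se"] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-8)

    def test_family_calibration_contrast(self):
        # polygenic family trait: naive OLS inflated, MG calibrated
        cfg = pgskit.SimConfig(n_families=120, n_related=720, n_unrelated=80,
                               n_male=400, n_snps=2000, rng_seed=14)
        samples = pgskit.simulate_pedigrees(cfg)
        gm = pgskit.drop_genotypes(samples, cfg)
        truth = pgskit.TruePanel(polygenic_background_var=40.0,
                                 residual_sd=3.0)
        samples = pgskit.simulate_phenotype(gm, samples, truth, 14)
        model = pgskit.adjust_phenotype(samples)
        ols = assoc.ols_scan(model.residuals, gm)
        assert assoc.gc_lambda(ols["chi2"]) > 1.05
        kin = assoc.genomic_kinship(gm)
        vc = assoc.fit_null_lmm(model.residuals, kin)
        mg = assoc.mg_scan(model.residuals, gm, vc, kin)
        frac = (mg["p"] < 0.05).mean()
        bound = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < bound


class TestConditionalScan:
    def test_index_snp_never_reported(self):
        rng = np.random.default_rng(15)
        gm = random_genotype_matrix(rng, 100, 10)
        y = rng.normal(size=100)
        cond = assoc.conditional_scan(y, gm, gm.snps["snp_id"].tolist(), "m3")
        assert "m3" not in set(cond["snp_id"])
        assert (cond["conditioned_on"] == "m3").all()

    def test_collinear_snp_skipped(self):
        rng = np.random.default_rng(16)
        gm = random_genotype_matrix(rng, 100, 5)
        gm.dosage[:, 4] = gm.dosage[:, 0]
        cond = assoc.conditional_scan(rng.normal(size=100), gm,
                                      gm.snps["snp_id"].tolist(), "m0")
        assert "m4" not in set(cond["snp_id"])

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        # a SNP with exactly zero sample correlation with the index keeps
        # its marginal beta under conditioning
        rng = np.random.default_rng(17)
        n = 8
        x1 = np.array([0, 0, 1, 1, 2, 2, 1, 1], dtype=float)
        x2 = np.array([0, 1, 0, 1, 0, 1, 2, 1], dtype=float)
        x2 = x2 - (np.sum((x1 - x1.mean()) * (x2 - x2.mean()))
                   / np.sum((x1 - x1.mean()) ** 2)) * (x1 - x1.mean())
        x2 = np.round(x2 - x2.min())
        x2 = np.clip(x2, 0, 2)
        r = np.corrcoef(x1, x2)[0, 1]
        if abs(r) > 1e-10:  # construct an exactly orthogonal pair instead
            x1 = np.array([0, 0, 1, 1, 2, 2, 0, 2], dtype=float)
            x2 = np.array([0, 2, 0, 2, 0, 2, 1, 1], dtype=float)
        assert abs(np.corrcoef(x1, x2)[0, 1]) < 1e-10
        dosage = np.column_stack([x1, x2])
        snps = pd.DataFrame({"snp_id": ["idx", "other"], "chrom": "1",
                             "pos": [100, 200], "counted_allele": "A",
                             "other_allele": "G"})
        gm = pgskit.GenotypeMatrix(dosage, snps,
                                   [f"s{i}" for i in range(n)])
        y = rng.normal(size=n)
        marg = assoc.ols_scan(y, gm)
        cond = assoc.conditional_scan(y, gm, ["idx", "other"], "idx")
        b_marg = marg.loc[marg["snp_id"] == "other", "beta"].iloc[0]
        assert cond.loc[0, "beta"] == pytest.approx(b_marg, abs=1e-8)

    def test_ld_block_distinguishes_allelic_heterogeneity(self):
        # two causal SNPs in a block: secondary signal survives
        # conditioning; single causal SNP: signals vanish
        def min_conditional_p(two_causal, rep):
            cfg = pgskit.SimConfig(n_families=0, n_related=0,
                                   n_unrelated=500, n_male=None, n_snps=20,
                                   maf_min=0.2, ld_block_size=20, ld_rho=0.9,
                                   rng_seed=400 + rep)
            s = pgskit.simulate_pedigrees(cfg)
            gm = pgskit.drop_genotypes(s, cfg)
            idx = np.array([5, 14]) if two_causal else np.array([5])
            truth = pgskit.TruePanel(snp_indices=idx,
                                     true_beta=np.full(len(idx), 1.5),
                                     polygenic_background_var=0.0,
                                     residual_sd=4.0)
            s = pgskit.simulate_phenotype(gm, s, truth, 400 + rep)
            model = pgskit.adjust_phenotype(s)
            scan = assoc.ols_scan(model.residuals, gm)
            index_snp = scan.loc[scan["p"].idxmin(), "snp_id"]
            cond = assoc.conditional_scan(model.residuals, gm,
                                          scan["snp_id"].tolist(), index_snp)
            return cond["p"].min()

        two = np.array([min_conditional_p(True, r) for r in range(25)])
        one = np.array([min_conditional_p(False, r) for r in range(25)])
        assert (two < 0.01).mean() >= 0.8
        assert (one >= 0.01).mean() >= 0.8
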