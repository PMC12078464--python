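"""GRM construction, REML, association scan, LD scores and LDSC."""

import numpy as np
import pandas as pd
import pytest

from sesherit import (
    FamilyConfig,
    TraitModel,
    compute_grm,
    compute_ld_scores,
    cross_trait_ldsc,
    fit_bivariate_greml,
    fit_greml,
    ldsc_regression,
    prune_relatives,
    run_gwas,
    simulate_genotypes,
    simulate_pedigree,
    simulate_snp_phenotypes,
    simulate_unrelated_genotypes,
    standardize_genotypes,
)
from sesherit.simdata import GenotypeMatrix
from sesherit.snpherit import Grm


def corr2(off):
    m = np.full((2, 2), off)
    np.fill_diagonal(m, 1.0)
    return m


class TestStandardize:
    def test_standardized_values(self):
        genos = GenotypeMatrix(np.array([[0], [1], [2]], dtype=np.int8),
                               ["a", "b", "c"], ["s0"], np.array([0.5]))
        std = standardize_genotypes(genos, maf_min=0.0)
        np.testing.assert_allclose(std.W[:, 0], [-np.sqrt(2), 0.0, np.sqrt(2)])

    def test_maf_cutoff_drops_rare_snps(self):
        # column 0: one alt allele in 100 people -> MAF 0.005 < 0.01
        d = np.zeros((100, 2), dtype=np.int8)
        d[0, 0] = 1
        d[:50, 1] = 1
        genos = GenotypeMatrix(d, [f"i{k}" for k in range(100)], ["rare", "common"],
                               np.array([0.005, 0.25]))
        std = standardize_genotypes(genos, maf_min=0.01)
        assert std.snp_ids == ["common"]

    def test_zero_variance_dropped(self):
        d = np.ones((50, 2), dtype=np.int8)  # all-heterozygous column
        d[:25, 1] = 0
        genos = GenotypeMatrix(d, [f"i{k}" for k in range(50)], ["het", "ok"],
                               np.array([0.5, 0.25]))
        std = standardize_genotypes(genos, maf_min=0.0)
        assert std.snp_ids == ["ok"]

    def test_monomorphic_only_errors(self):
        d = np.zeros((10, 3), dtype=np.int8)
        genos = GenotypeMatrix(d, [f"i{k}" for k in range(10)], ["a", "b", "c"],
                               np.zeros(3))
        with pytest.raises(ValueError, match="MAF"):
            standardize_genotypes(genos, maf_min=0.01)


class TestGrm:
    def test_duplicated_individual_entry_near_one(self):
        genos = simulate_unrelated_genotypes(50, 3000, seed=1)
        d = np.vstack([genos.dosage, genos.dosage[:1]])
        dup = GenotypeMatrix(d, [f"i{k}" for k in range(51)], genos.snp_ids,
                             genos.allele_freqs)
        grm = compute_grm(standardize_genotypes(dup, 0.01))
        assert grm.matrix[0, 50] == pytest.approx(grm.matrix[0, 0], abs=1e-9)

    def test_unrelated_offdiagonals(self):
        genos = simulate_unrelated_genotypes(300, 5000, seed=2)
        grm = compute_grm(standardize_genotypes(genos, 0.01))
        off = grm.matrix[np.triu_indices(300, 1)]
        assert abs(off.mean()) < 0.01
        # sampling theory: SD of an off-diagonal entry is ~ 1/sqrt(N_snps)
        assert off.std() == pytest.approx(1 / np.sqrt(grm.n_snps), rel=0.2)
        assert np.diag(grm.matrix).mean() == pytest.approx(1.0, abs=0.02)

    def test_sib_pairs_near_half(self):
        ped = simulate_pedigree(FamilyConfig(100, 2, cousin_links=False), seed=3)
        genos = simulate_genotypes(ped, 2000, block_len=20, seed=4)
        cohort = ped.leaves()
        grm = compute_grm(standardize_genotypes(genos.subset(cohort), 0.01))
        sib_entries = [grm.matrix[2 * i, 2 * i + 1] for i in range(100)]
        assert np.mean(sib_entries) == pytest.approx(0.5, abs=0.05)

    def test_gcta_triplet_roundtrip(self, tmp_path):
        genos = simulate_unrelated_genotypes(20, 500, seed=5)
        grm = compute_grm(standardize_genotypes(genos, 0.01))
        grm.to_gcta(str(tmp_path / "test"))
        vals = np.fromfile(tmp_path / "test.grm.bin", dtype="<f4")
        assert len(vals) == 20 * 21 // 2
        np.testing.assert_allclose(vals, grm.matrix[np.tril_indices(20)], rtol=1e-5)

    def test_allele_flip_leaves_grm_unchanged(self):
        genos = simulate_unrelated_genotypes(60, 800, seed=6)
        grm = compute_grm(standardize_genotypes(genos, 0.01))
        rng = np.random.default_rng(7)
        flip = rng.random(800) < 0.5
        d = genos.dosage.copy()
        d[:, flip] = 2 - d[:, flip]
        flipped = GenotypeMatrix(d, genos.sample_ids, genos.snp_ids,
                                 genos.allele_freqs)
        grm2 = compute_grm(standardize_genotypes(flipped, 0.01))
        np.testing.assert_allclose(grm2.matrix, grm.matrix, atol=1e-10)


class TestPrune:
    def _grm(self, mat):
        n = mat.shape[0]
        return Grm(mat, 1000, [f"i{k}" for k in range(n)])

    def test_sib_pair_one_removed(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.5
        kept = prune_relatives(self._grm(m), cutoff=0.025)
        assert len(kept) == 3
        assert "i2" in kept and "i3" in kept

    def test_unrelated_all_kept(self):
        kept = prune_relatives(self._grm(np.eye(5)), cutoff=0.025)
        assert len(kept) == 5

    def test_clique_of_three_two_removed(self):
        m = np.eye(5)
        for i in range(3):
            for j in range(3):
                if i != j:
                    m[i, j] = 0.5
        kept = prune_relatives(self._grm(m), cutoff=0.025)
        # brute force on the 3-clique: exactly one clique member can stay
        assert len(kept) == 3
        assert sum(k in kept for k in ("i0", "i1", "i2")) == 1

    def test_deterministic_tie_break(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.5
        m[2, 3] = m[3, 2] = 0.5
        a = prune_relatives(self._grm(m), 0.025)
        b = prune_relatives(self._grm(m), 0.025)
        assert a == b


@pytest.fixture(scope="module")
def greml_sim():
    genos = simulate_unrelated_genotypes(1200, 3000, seed=10)
    model = TraitModel(var_a=0.25, var_c=0.0, var_e=0.75, snp_mode=True,
                       traits=("t",))
    ph = simulate_snp_phenotypes(genos, model, seed=11)
    grm = compute_grm(standardize_genotypes(genos, 0.01))
    return genos, ph, grm


class TestGreml:
    def test_pure_noise_h2_near_zero(self, greml_sim):
        genos, ph, grm = greml_sim
        rng = np.random.default_rng(12)
        fit = fit_greml(rng.standard_normal(1200), None, grm)
        assert fit.h2 < 3 * max(fit.se_h2, 0.02)

    def test_noise_free_genetic_trait_h2_one(self):
        # with fewer SNPs than samples the GRM has a null space, so a trait
        # built exactly from the SNPs pins the residual variance at zero
        genos = simulate_unrelated_genotypes(500, 200, seed=13)
        std = standardize_genotypes(genos, 0.01)
        rng = np.random.default_rng(13)
        y = std.W @ rng.standard_normal(std.W.shape[1])
        fit = fit_greml(y, None, compute_grm(std))
        assert fit.h2 > 0.98
        assert fit.boundary

    def test_recovery_and_haseman_elston_agreement(self, greml_sim):
        genos, ph, grm = greml_sim
        y = ph["t"].to_numpy()
        sex = (ph["sex"] == 2).to_numpy(float)[:, None]
        fit = fit_greml(y, sex, grm)
        assert fit.h2 == pytest.approx(0.25, abs=2 * fit.se_h2)
        # Haseman-Elston cross-product regression as an independent oracle
        yz = (y - y.mean()) / y.std()
        iu = np.triu_indices(len(y), 1)
        he = np.polyfit(grm.matrix[iu], np.outer(yz, yz)[iu], 1)[0]
        assert fit.h2 == pytest.approx(he, abs=0.06)

    def test_incomplete_phenotype_rejected(self, greml_sim):
        _, _, grm = greml_sim
        y = np.ones(1200)
        y[0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_greml(y, None, grm)


class TestBivariateGreml:
    def test_identical_traits_rg_one(self, greml_sim):
        genos, ph, grm = greml_sim
        y = ph["t"].to_numpy()
        fit = fit_bivariate_greml(y, y, None, grm)
        assert fit.r_g == pytest.approx(1.0, abs=0.01)
        assert min(fit.h2) > 0.05

    def test_recovery(self):
        genos = simulate_unrelated_genotypes(1500, 2500, seed=14)
        model = TraitModel(var_a=0.3, var_c=0.0, var_e=0.7, R_A=corr2(0.8),
                           R_E=corr2(0.0), snp_mode=True, traits=("x", "y"))
        ph = simulate_snp_phenotypes(genos, model, seed=15)
        grm = compute_grm(standardize_genotypes(genos, 0.01))
        fit = fit_bivariate_greml(ph["x"].to_numpy(), ph["y"].to_numpy(), None, grm)
        assert fit.r_g == pytest.approx(0.8, abs=2 * max(fit.se_rg, 0.03))

    def test_independent_architectures_rg_zero(self):
        genos = simulate_unrelated_genotypes(1000, 2000, seed=16)
        model = TraitModel(var_a=0.3, var_c=0.0, var_e=0.7, R_A=corr2(0.0),
                           R_E=corr2(0.0), snp_mode=True, traits=("x", "y"))
        ph = simulate_snp_phenotypes(genos, model, seed=17)
        grm = compute_grm(standardize_genotypes(genos, 0.01))
        fit = fit_bivariate_greml(ph["x"].to_numpy(), ph["y"].to_numpy(), None, grm)
        assert abs(fit.r_g) < 2.5 * max(fit.se_rg, 0.05)


class TestGwas:
    def test_null_trait_mean_chi2_one(self):
        genos = simulate_unrelated_genotypes(800, 3000, seed=20)
        rng = np.random.default_rng(21)
        ss = run_gwas(rng.standard_normal(800), genos)
        assert ss["CHISQ"].mean() == pytest.approx(1.0, abs=0.08)

    def test_causal_snp_noncentrality(self):
        # one SNP explaining 5% of variance at n=2000: E[chi2] ~ 1 + n*0.05
        rng = np.random.default_rng(22)
        genos = simulate_unrelated_genotypes(2000, 50, seed=23)
        w = standardize_genotypes(genos, 0.0).W[:, 0]
        y = np.sqrt(0.05) * w + np.sqrt(0.95) * rng.standard_normal(2000)
        chi2 = run_gwas(y, genos).set_index("SNP").loc["snp0", "CHISQ"]
        assert 40 < chi2 < 180  # noncentral chi2(1, ncp~100): +-3.5 SD band

    def test_constant_snp_absent(self):
        d = np.ones((100, 2), dtype=np.int8)
        d[:, 1] = np.tile([0, 1], 50)
        genos = GenotypeMatrix(d, [f"i{k}" for k in range(100)], ["const", "ok"],
                               np.array([0.5, 0.25]))
        rng = np.random.default_rng(24)
        with pytest.warns(UserWarning, match="zero-variance"):
            ss = run_gwas(rng.standard_normal(100), genos)
        assert list(ss["SNP"]) == ["ok"]


class TestLdScores:
    def test_uncorrelated_snps_ell_near_one(self):
        genos = simulate_unrelated_genotypes(500, 400, seed=30)
        ld = compute_ld_scores(genos, window_snps=50)
        assert ld.frame["L2"].mean() == pytest.approx(1.0, abs=0.05)

    def test_duplicated_snp_ell_two(self):
        genos = simulate_unrelated_genotypes(500, 100, seed=31)
        d = genos.dosage.copy()
        d[:, 1] = d[:, 0]
        dup = GenotypeMatrix(d, genos.sample_ids, genos.snp_ids, genos.allele_freqs)
        ld = compute_ld_scores(dup, window_snps=20)
        assert ld.frame.loc[0, "L2"] == pytest.approx(2.0, abs=0.15)
        assert ld.frame.loc[1, "L2"] == pytest.approx(2.0, abs=0.15)

    def test_perfect_block_ell_k(self):
        genos = simulate_unrelated_genotypes(500, 60, seed=32)
        d = genos.dosage.copy()
        for j in range(5):
            d[:, j] = d[:, 0]
        block = GenotypeMatrix(d, genos.sample_ids, genos.snp_ids, genos.allele_freqs)
        ld = compute_ld_scores(block, window_snps=20)
        for j in range(5):
            assert ld.frame.loc[j, "L2"] == pytest.approx(5.0, abs=0.3)

    def test_small_panel_rejected_and_window_truncated(self):
        small = simulate_unrelated_genotypes(20, 100, seed=33)
        with pytest.raises(ValueError, match="50 samples"):
            compute_ld_scores(small)
        genos = simulate_unrelated_genotypes(100, 30, seed=34)
        with pytest.warns(UserWarning, match="truncating"):
            compute_ld_scores(genos, window_snps=100)


class TestLdscRegression:
    def test_flat_chi2_zero_h2_unit_intercept(self):
        ss = pd.DataFrame({"SNP": [f"s{j}" for j in range(2000)], "A1": "A",
                           "A2": "B", "N": 1000, "CHISQ": 1.0})
        rng = np.random.default_rng(40)
        from sesherit.snpherit import LdScores

        ld = LdScores(pd.DataFrame({"SNP": ss["SNP"],
                                    "L2": rng.uniform(1, 5, 2000)}), 100, 2000)
        fit = ldsc_regression(ss, ld, n_blocks=50)
        assert fit.h2 == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_point_estimate_invariant_to_snp_permutation(self):
        genos = simulate_unrelated_genotypes(800, 2500, seed=41, block_len=25,
                                             n_ancestral_haplotypes=15)
        model = TraitModel(var_a=0.3, var_c=0.0, var_e=0.7, snp_mode=True,
                           traits=("t",))
        ph = simulate_snp_phenotypes(genos, model, seed=42)
        ss = run_gwas(ph["t"].to_numpy(), genos)
        ld = compute_ld_scores(genos, window_snps=50)
        base = ldsc_regression(ss, ld, n_blocks=40)
        rng = np.random.default_rng(43)
        perm = rng.permutation(len(ss))
        fit = ldsc_regression(ss.iloc[perm].reset_index(drop=True), ld, n_blocks=40)
        assert fit.h2 == pytest.approx(base.h2, abs=1e-9)
        assert fit.intercept == pytest.approx(base.intercept, abs=1e-9)

    def test_too_few_blocks_rejected(self):
        ss = pd.DataFrame({"SNP": ["s0"], "A1": "A", "A2": "B", "N": 100,
                           "CHISQ": 1.0})
        from sesherit.snpherit import LdScores

        ld = LdScores(pd.DataFrame({"SNP": ["s0"], "L2": [1.0]}), 10, 1)
        with pytest.raises(ValueError, match="blocks"):
            ldsc_regression(ss, ld, n_blocks=1)

    def test_cross_trait_identical_stats_rg_one(self):
        genos = simulate_unrelated_genotypes(800, 2500, seed=44, block_len=25,
                                             n_ancestral_haplotypes=15)
        model = TraitModel(var_a=0.4, var_c=0.0, var_e=0.6, snp_mode=True,
                           traits=("t",))
        ph = simulate_snp_phenotypes(genos, model, seed=45)
        ss = run_gwas(ph["t"].to_numpy(), genos)
        ld = compute_ld_scores(genos, window_snps=50)
        fit = cross_trait_ldsc(ss, ss, ld, n_blocks=40)
        assert fit.r_g == pytest.approx(1.0, abs=1e-6)

    def test_allele_flip_invariance_end_to_end(self):
        genos = simulate_unrelated_genotypes(400, 600, seed=46, block_len=20,
                                             n_ancestral_haplotypes=10)
        model = TraitModel(var_a=0.3, var_c=0.0, var_e=0.7, snp_mode=True,
                           traits=("t",))
        ph = simulate_snp_phenotypes(genos, model, seed=47)
        y = ph["t"].to_numpy()
        rng = np.random.default_rng(48)
        flip = rng.random(600) < 0.5
        d = genos.dosage.copy()
        d[:, flip] = 2 - d[:, flip]
        flipped = GenotypeMatrix(d, genos.sample_ids, genos.snp_ids,
                                 genos.allele_freqs)
        for g1, g2 in [(genos, flipped)]:
            ss1, ss2 = run_gwas(y, g1), run_gwas(y, g2)
            np.testing.assert_allclose(ss1["CHISQ"], ss2["CHISQ"], atol=1e-9)
            l1 = compute_ld_scores(g1, window_snps=30).frame["L2"]
            l2 = compute_ld_scores(g2, window_snps=30).frame["L2"]
            np.testing.assert_allclose(l1, l2, atol=1e-9)
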