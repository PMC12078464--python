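"""ACE/AE maximum likelihood: closed-form oracles, nesting, recovery."""

import numpy as np
import pandas as pd
import pytest

from sesherit import (
    BivariateACE,
    FamilyACE,
    IBDAE,
    FamilyConfig,
    TraitModel,
    build_pair_table,
    falconer,
    fit_bivariate,
    fit_ibd_ae,
    fit_univariate,
    sensitivity_sweep,
    simulate_pedigree,
    simulate_phenotypes,
    two_class_moments,
)
from sesherit.pedigree import pairs_to_frame


def exact_moment_pairs(spec, n_per_class=4000, seed=0):
    """Pair data whose empirical within-class moments match the target exactly.

    ``spec``: list of (relationship, r_g, target correlation).  Each class's
    (y1, y2) sample is whitened empirically and re-colored, so sample means
    are exactly 0, variances exactly 1 and correlations exactly the target —
    making ML estimates comparable to closed forms at machine-ish precision.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for rel, rg, rho in spec:
        z = rng.standard_normal((n_per_class, 2))
        z = z - z.mean(axis=0)
        cov = np.cov(z, rowvar=False, bias=True)
        z = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
        target = np.array([[1.0, rho], [rho, 1.0]])
        y = z @ np.linalg.cholesky(target).T
        frames.append(pd.DataFrame({
            "relationship": rel, "r_g": rg,
            "y1_t": y[:, 0], "y2_t": y[:, 1],
        }))
    return pd.concat(frames, ignore_index=True)


class TestClosedFormOracles:
    def test_ml_equals_method_of_moments_two_class(self):
        # targets: r_sib = 0.5 a2 + c2 = 0.45, r_cousin = 0.125 a2 + 0.6 c2 = 0.2
        # hand-solved: a2 = 0.4, c2 = 0.25, e2 = 0.35
        pairs = exact_moment_pairs(
            [("fullsib", 0.5, 0.45), ("first_cousin", 0.125, 0.20)]
        )
        fit = fit_univariate(pairs, "t", "ACE", rc_cousin=0.6, covariates=())
        assert fit.a2 == pytest.approx(0.40, abs=2e-3)
        assert fit.c2 == pytest.approx(0.25, abs=2e-3)
        assert fit.e2 == pytest.approx(0.35, abs=2e-3)
        a2, c2, e2 = two_class_moments(0.45, 0.20, 0.6)
        assert (a2, c2, e2) == pytest.approx((0.40, 0.25, 0.35), abs=1e-12)

    def test_ml_equals_falconer_twin_design(self):
        # a2 = 2 (r_MZ - r_DZ) = 0.4, c2 = 2 r_DZ - r_MZ = 0.2
        pairs = exact_moment_pairs([("MZ", 1.0, 0.6), ("DZ", 0.5, 0.4)])
        fit = fit_univariate(pairs, "t", "ACE", rc_cousin=0.0, covariates=())
        assert fit.a2 == pytest.approx(0.40, abs=2e-3)
        assert fit.c2 == pytest.approx(0.20, abs=2e-3)
        assert falconer(0.6, 0.4) == pytest.approx((0.4, 0.2, 0.4), abs=1e-12)

    def test_no_cross_member_covariance_all_e(self):
        pairs = exact_moment_pairs(
            [("fullsib", 0.5, 0.0), ("first_cousin", 0.125, 0.0), ("MZ", 1.0, 0.0)]
        )
        fit = fit_univariate(pairs, "t", "ACE", rc_cousin=0.0, covariates=())
        assert fit.a2 == pytest.approx(0.0, abs=2e-3)
        assert fit.c2 == pytest.approx(0.0, abs=2e-3)
        assert fit.e2 == pytest.approx(1.0, abs=3e-3)
        assert fit.boundary


@pytest.fixture(scope="module")
def rho6_data():
    """Pedigree data generated with a2=0.4, c2=0.2, cousin rho_c=0.6."""
    ped = simulate_pedigree(FamilyConfig(3000, 2, cousin_links=True), seed=30)
    ped2 = simulate_pedigree(
        FamilyConfig(600, 2, twin_rate_mz=1.0, cousin_links=False), seed=31,
        id_prefix="T",
    )
    from sesherit import Pedigree

    ped = Pedigree.concat([ped, ped2])
    model = TraitModel(var_a=0.4, var_c=0.2, var_e=0.4, rho_c_cousin=0.6)
    ph = simulate_phenotypes(ped, model, seed=32)
    pairs = pairs_to_frame(ped.classify_pairs())
    return build_pair_table(pairs, ph, "education", covariates=())


class TestFamilyACE:
    def test_free_rho_nests_fixed(self, rho6_data):
        free = fit_univariate(rho6_data, "education", "ACE", "free", covariates=())
        for fixed_val in (0.0, 0.3, 0.6, 1.0):
            fixed = fit_univariate(rho6_data, "education", "ACE", fixed_val, covariates=())
            assert free.loglik >= fixed.loglik - 1e-4

    def test_ae_absorbs_shared_environment(self, rho6_data):
        ace = fit_univariate(rho6_data, "education", "ACE", 0.6, covariates=())
        ae = fit_univariate(rho6_data, "education", "AE", covariates=())
        assert ae.a2 > ace.a2

    def test_misspecified_zero_rho_inflates_a2(self, rho6_data):
        at_zero = fit_univariate(rho6_data, "education", "ACE", 0.0, covariates=())
        # overlapping pairs understate the information-based SE, so recovery
        # is checked against the family-clustered sandwich SE
        at_true = fit_univariate(rho6_data, "education", "ACE", 0.6, covariates=(),
                                 robust_se="family")
        assert at_zero.a2 > at_true.a2
        assert at_true.a2 == pytest.approx(0.4, abs=2 * max(at_true.se["a2"], 0.02))

    def test_estimates_standardized(self, rho6_data):
        fit = fit_univariate(rho6_data, "education", "ACE", "free", covariates=())
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-9)
        lo, hi = fit.ci95("a2")
        assert 0.0 <= lo <= fit.a2 <= hi <= 1.0

    def test_sex_covariate_estimated(self):
        ped = simulate_pedigree(FamilyConfig(1500, 2), seed=33)
        model = TraitModel(var_a=0.4, var_c=0.2, var_e=0.4, beta_sex=0.5)
        ph = simulate_phenotypes(ped, model, seed=34)
        pairs = pairs_to_frame(ped.classify_pairs())
        tab = build_pair_table(pairs, ph, "education", covariates=("sex",))
        fit = FamilyACE("ACE", 0.0, covariates=("sex",)).fit(tab, "education").fit_
        assert fit.beta["sex"] == pytest.approx(0.5, abs=0.1)

    def test_identifiability_errors(self):
        sibs_only = exact_moment_pairs([("fullsib", 0.5, 0.4)], n_per_class=500)
        with pytest.raises(ValueError, match="distinct"):
            fit_univariate(sibs_only, "t", "ACE", 0.0, covariates=())
        two_class = exact_moment_pairs(
            [("fullsib", 0.5, 0.4), ("first_cousin", 0.125, 0.2)], n_per_class=500
        )
        with pytest.raises(ValueError, match="free"):
            fit_univariate(two_class, "t", "ACE", "free", covariates=())
        with pytest.raises(ValueError):
            fit_univariate(sibs_only, "t", "AE", covariates=())

    def test_family_clustered_se_available(self, rho6_data):
        df = rho6_data.copy()
        df["family"] = np.arange(len(df)) // 4
        fit = FamilyACE("ACE", 0.6, covariates=(), robust_se="family").fit(df, "education").fit_
        assert fit.se["a2"] > 0


class TestSensitivitySweep:
    def test_default_grid_has_21_fits(self, rho6_data):
        sweep = sensitivity_sweep(rho6_data, "education", covariates=())
        assert len(sweep) == 21
        np.testing.assert_allclose(np.diff(sweep["rho_c_assumed"]), 0.05)

    def test_attenuation_direction(self, rho6_data):
        sweep = sensitivity_sweep(rho6_data, "education",
                                  rc_grid=[0.0, 0.6], covariates=())
        assert sweep.loc[0, "a2"] > sweep.loc[1, "a2"]

    def test_empty_grid_rejected(self, rho6_data):
        with pytest.raises(ValueError):
            sensitivity_sweep(rho6_data, "education", rc_grid=[], covariates=())


def ibd_pairs_from_model(a2, n_pairs, seed, r_sd=0.04):
    """Direct draw from the AE pair model with per-pair genome sharing."""
    rng = np.random.default_rng(seed)
    r = np.clip(rng.normal(0.5, r_sd, n_pairs), 0, 1)
    y = np.empty((n_pairs, 2))
    for i in range(n_pairs):
        c = a2 * r[i]
        L = np.linalg.cholesky([[1.0, c], [c, 1.0]])
        y[i] = L @ rng.standard_normal(2)
    return pd.DataFrame({"relationship": "fullsib", "r_g": r,
                         "y1_t": y[:, 0], "y2_t": y[:, 1]})


class TestIBDAE:
    def test_recovers_heritability(self):
        df = ibd_pairs_from_model(0.4, 6000, seed=40)
        fit = fit_ibd_ae(df, "t", covariates=())
        assert fit.a2 == pytest.approx(0.4, abs=2 * fit.se["a2"])

    def test_independent_phenotype_gives_zero(self):
        df = ibd_pairs_from_model(0.0, 3000, seed=41)
        fit = fit_ibd_ae(df, "t", covariates=())
        assert fit.a2 < 2 * max(fit.se["a2"], 0.02)

    def test_constant_sharing_unidentifiable(self):
        df = ibd_pairs_from_model(0.4, 100, seed=42, r_sd=0.0)
        with pytest.raises(ValueError, match="IBD variance zero"):
            fit_ibd_ae(df, "t", covariates=())


def bivariate_family_data(r_A, r_C, r_E, seed, n_fam=2500, n_twin=500,
                          var=(0.4, 0.3, 0.3), rho_c=0.6):
    from sesherit import Pedigree

    def c2(off):
        m = np.full((2, 2), off)
        np.fill_diagonal(m, 1.0)
        return m

    ped = Pedigree.concat([
        simulate_pedigree(FamilyConfig(n_fam, 2, cousin_links=True), seed=seed),
        simulate_pedigree(FamilyConfig(n_twin, 2, twin_rate_mz=1.0,
                                       cousin_links=False), seed=seed + 1, id_prefix="T"),
    ])
    model = TraitModel(var_a=var[0], var_c=var[1], var_e=var[2],
                       R_A=c2(r_A), R_C=c2(r_C), R_E=c2(r_E),
                       rho_c_cousin=rho_c, traits=("x", "y"))
    ph = simulate_phenotypes(ped, model, seed=seed + 2)
    pairs = pairs_to_frame(ped.classify_pairs())
    return build_pair_table(pairs, ph, ("x", "y"), covariates=())


class TestBivariate:
    def test_duplicated_trait_perfect_correlations(self):
        tab = bivariate_family_data(0.5, 0.5, 0.5, seed=50, n_fam=800, n_twin=200)
        tab = tab.assign(y1_y=tab["y1_x"], y2_y=tab["y2_x"])
        fit = fit_bivariate(tab, ("x", "y"), "ACE", rc_cousin=0.6, covariates=())
        assert fit.r_A == pytest.approx(1.0, abs=0.02)
        assert fit.r_C == pytest.approx(1.0, abs=0.02)
        assert fit.r_E == pytest.approx(1.0, abs=0.02)
        assert fit.r_phenotypic == pytest.approx(1.0, abs=1e-3)
        assert fit.boundary

    def test_independent_traits_zero_correlations(self):
        tab = bivariate_family_data(0.0, 0.0, 0.0, seed=51, n_fam=1500, n_twin=300)
        fit = fit_bivariate(tab, ("x", "y"), "ACE", rc_cousin=0.6, covariates=())
        for val in (fit.r_A, fit.r_C, fit.r_E):
            assert abs(val) < 0.15

    def test_recovery_of_component_correlations(self):
        tab = bivariate_family_data(0.9, 1.0, 0.3, seed=52)
        fit = fit_bivariate(tab, ("x", "y"), "ACE", rc_cousin=0.6, covariates=())
        assert fit.r_A == pytest.approx(0.9, abs=2 * max(fit.se["r_A"], 0.02))
        assert fit.r_C == pytest.approx(1.0, abs=2 * max(fit.se["r_C"], 0.02))
        assert fit.r_E == pytest.approx(0.3, abs=2 * max(fit.se["r_E"], 0.02))

    def test_zero_component_variance_marked_unestimable(self):
        tab = bivariate_family_data(0.5, 0.9, 0.2, seed=53, n_fam=1200, n_twin=300,
                                    var=(0.5, 0.0, 0.5))
        fit = fit_bivariate(tab, ("x", "y"), "ACE", rc_cousin=0.6, covariates=())
        assert "r_C" in fit.unestimable
        assert np.isnan(fit.r_C)
        # the estimable components are still returned
        assert np.isfinite(fit.r_A) and np.isfinite(fit.r_E)

    def test_ibd_mode_per_pair_sharing(self):
        rng = np.random.default_rng(54)
        n = 4000
        r = np.clip(rng.normal(0.5, 0.04, n), 0, 1)
        a2, rA, rE = 0.4, 0.8, 0.1
        gxy = rA * a2
        exy = rE * 0.6
        ys = np.empty((n, 4))
        for i in range(n):
            S = np.array([[1.0, gxy + exy], [gxy + exy, 1.0]])
            B = np.array([[a2 * r[i], gxy * r[i]], [gxy * r[i], a2 * r[i]]])
            top = np.block([[S, B], [B, S]])
            ys[i] = np.linalg.cholesky(top) @ rng.standard_normal(4)
        tab = pd.DataFrame({"relationship": "fullsib", "r_g": r,
                            "y1_x": ys[:, 0], "y1_y": ys[:, 1],
                            "y2_x": ys[:, 2], "y2_y": ys[:, 3]})
        fit = BivariateACE("AE", covariates=()).fit(tab, ("x", "y")).fit_
        assert fit.r_A == pytest.approx(rA, abs=2 * max(fit.se["r_A"], 0.05))
        assert fit.r_E == pytest.approx(rE, abs=2 * max(fit.se["r_E"], 0.05))
        assert fit.r_C is None


class TestBuildPairTable:
    def test_missing_phenotypes_dropped(self):
        ped = simulate_pedigree(FamilyConfig(20, 2), seed=60)
        ph = simulate_phenotypes(ped, TraitModel(), seed=61)
        ph.loc[0, "education"] = np.nan
        lost = ph.loc[0, "iid"]
        pairs = pairs_to_frame(ped.classify_pairs())
        tab = build_pair_table(pairs, ph, "education", covariates=())
        assert not ((tab["id1"] == lost) | (tab["id2"] == lost)).any()
        assert tab[["y1_education", "y2_education"]].notna().all().all()
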