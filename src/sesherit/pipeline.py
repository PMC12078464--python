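"""Measure preprocessing and end-to-end orchestration.

Preprocessing mirrors how registry panels are turned into analysis traits:
monetary values are log-transformed after setting zero/negative entries to
one, income/wealth/occupation are averaged over the 11-year age window, and
education takes the highest attainment in the window; traits are then
residualized on covariates (sex) and z-scored.

``run_full_analysis`` drives the whole battery on one configuration:
simulate (or load) pedigree, genotypes and phenotypes; build relative pairs;
fit the enabled estimators (family-pedigree AE / ACE with fixed or free
cousin shared-environment correlation, sibling IBD AE, GREML, LD-score
regression); assemble phenotypic and component correlation matrices from
bivariate fits; and run the PCA battery.  Everything is seeded, so a fixed
seed reproduces the report bundle exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .famvarcomp import (
    BivariateACE,
    FamilyACE,
    IBDAE,
    build_pair_table,
    sensitivity_sweep,
)
from .pedigree import Pedigree, REL_COUSIN, REL_FULLSIB, REL_MZ, REL_DZ, pairs_to_frame
from .sesstructure import (
    ComponentCorrMatrix,
    assemble_matrix,
    bootstrap_component_pca,
    parallel_analysis,
    pca,
)
from .simdata import (
    FamilyConfig,
    TraitModel,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_registry_panel,
    simulate_snp_phenotypes,
    simulate_unrelated_genotypes,
    TRAITS,
)
from .snpherit import (
    compute_grm,
    compute_ld_scores,
    cross_trait_ldsc,
    fit_bivariate_greml,
    fit_greml,
    ldsc_regression,
    prune_relatives,
    run_gwas,
    standardize_genotypes,
)
from .pedigree import estimate_ibd_sharing

MONETARY_TRAITS = ("income", "wealth")

#: toy education-code -> years-of-schooling map (user-supplied in real use)
TOY_ISCED_YEARS = {0: 2, 1: 7, 2: 9, 3: 12, 4: 13, 5: 14, 6: 16, 7: 18, 8: 21}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def log_transform_monetary(values) -> np.ndarray:
    """Natural log after setting zero and negative values to one."""
    try:
        v = np.asarray(values, dtype=float)
    except (ValueError, TypeError) as exc:
        raise TypeError("monetary values must be numeric") from exc
    return np.log(np.where(v <= 0, 1.0, v))


def collapse_window(panel: pd.DataFrame, trait: str) -> pd.Series:
    """Collapse a yearly panel column to one value per person.

    Income, wealth and occupation average the available yearly values
    (monetary traits log-transformed first); education takes the highest
    attainment in the window.  Persons with no observed year are dropped.
    """
    sub = panel.dropna(subset=[trait])
    if trait == "education":
        return sub.groupby("iid")[trait].max()
    if trait in MONETARY_TRAITS:
        vals = sub.assign(_v=log_transform_monetary(sub[trait]))
        return vals.groupby("iid")["_v"].mean().rename(trait)
    return sub.groupby("iid")[trait].mean()


def collapse_panel(panel: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    out = pd.concat([collapse_window(panel, t) for t in traits], axis=1)
    out.columns = list(traits)
    return out.reset_index()


def residualize_and_standardize(trait, covariates) -> np.ndarray:
    """OLS residuals of the trait on covariates (plus intercept), z-scored."""
    y = np.asarray(trait, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates must be complete for included samples")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std()
    if sd < 1e-12:
        raise ValueError("constant residual: trait is fully explained by covariates")
    return resid / sd


def map_codes(values, mapping: dict | str | Path) -> np.ndarray:
    """Apply a user-supplied code->value mapping (dict or two-column TSV)."""
    if not isinstance(mapping, dict):
        df = pd.read_csv(mapping, sep="\t", header=None)
        mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return np.array([mapping[v] for v in values], dtype=float)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run (all sizes desk-scale)."""

    seed: int = 0
    out_dir: str | None = None
    # synthetic-data generation (used when no input paths are given)
    n_families: int = 800
    offspring_per_sibship: int = 2
    twin_rate_mz: float = 0.05
    twin_rate_dz: float = 0.05
    n_sib_only_families: int = 0
    m_snps: int = 2000
    block_len: int = 25
    n_unrelated: int = 1200
    m_snps_unrelated: int = 4000
    n_ancestral_haplotypes: int = 20
    var_a: tuple = (0.4, 0.3, 0.3, 0.25)
    var_c: tuple = (0.25, 0.1, 0.15, 0.3)
    rho_c_cousin: float = 0.6
    r_offdiag_a: float = 0.7
    r_offdiag_c: float = 1.0
    r_offdiag_e: float = 0.15
    beta_sex: float = 0.2
    snp_h2: tuple = (0.2, 0.15, 0.1, 0.12)
    panel_noise_sd: float = 0.15
    panel_zero_rate: float = 0.02
    # method toggles
    fp_ae: bool = True
    fp_ace_fixed: bool = True
    fp_ace_free: bool = True
    ibd: bool = True
    greml: bool = True
    ldsc: bool = True
    run_sensitivity: bool = False
    run_structure: bool = True
    # filters and knobs
    maf_min: float = 0.01
    grm_cutoff: float = 0.025
    ld_window_snps: int = 200
    ldsc_blocks: int = 100
    n_boot: int = 10_000
    n_parallel_sims: int = 500
    sensitivity_trait: str = "education"

    def validate(self) -> None:
        if not any((self.fp_ae, self.fp_ace_fixed, self.fp_ace_free, self.ibd,
                    self.greml, self.ldsc)):
            raise ValueError("at least one method must be enabled")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min out of range")
        if self.grm_cutoff <= 0:
            raise ValueError("grm_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ReportBundle:
    heritability: pd.DataFrame
    shared_env: pd.DataFrame
    sensitivity: pd.DataFrame | None
    matrices: list[ComponentCorrMatrix]
    pca_results: dict
    metadata: dict
    errors: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.heritability.to_csv(out / "heritability.tsv", sep="\t", index=False)
        self.shared_env.to_csv(out / "shared_env.tsv", sep="\t", index=False)
        if self.sensitivity is not None:
            self.sensitivity.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        blocks = []
        for m in self.matrices:
            df = m.to_frame().reset_index(names="indicator")
            df.insert(0, "source", m.source)
            df.insert(0, "method", m.method)
            blocks.append(df)
        if blocks:
            pd.concat(blocks, ignore_index=True).to_csv(
                out / "correlation_matrices.tsv", sep="\t", index=False
            )
        manifest = dict(self.metadata)
        manifest["errors"] = self.errors
        manifest["pca"] = {
            key: {
                "explained": list(map(float, r["explained"])),
                "n_retained": r["n_retained"],
                "explained_lo": list(map(float, r.get("explained_lo", []))),
                "explained_hi": list(map(float, r.get("explained_hi", []))),
            }
            for key, r in self.pca_results.items()
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _corr_full(t: int, off: float) -> np.ndarray:
    m = np.full((t, t), off)
    np.fill_diagonal(m, 1.0)
    return m


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every enabled estimator on one (simulated) data build."""
    config.validate()
    rng_seed = config.seed
    errors: list[str] = []
    herit_rows: list[dict] = []
    shared_rows: list[dict] = []
    matrices: list[ComponentCorrMatrix] = []
    pca_results: dict = {}
    t = len(TRAITS)

    model = TraitModel(
        var_a=np.array(config.var_a),
        var_c=np.array(config.var_c),
        var_e=1.0 - np.array(config.var_a) - np.array(config.var_c),
        R_A=_corr_full(t, config.r_offdiag_a),
        R_C=_corr_full(t, config.r_offdiag_c),
        R_E=_corr_full(t, config.r_offdiag_e),
        rho_c_cousin=config.rho_c_cousin,
        beta_sex=config.beta_sex,
    )

    # ---- synthetic build -------------------------------------------------
    peds = [simulate_pedigree(
        FamilyConfig(config.n_families, config.offspring_per_sibship,
                     config.twin_rate_mz, config.twin_rate_dz, cousin_links=True),
        seed=rng_seed, id_prefix="F",
    )]
    if config.n_sib_only_families:
        peds.append(simulate_pedigree(
            FamilyConfig(config.n_sib_only_families, config.offspring_per_sibship,
                         config.twin_rate_mz, config.twin_rate_dz, cousin_links=False),
            seed=rng_seed + 1, id_prefix="S",
        ))
    ped = Pedigree.concat(peds)
    pheno_latent = simulate_phenotypes(ped, model, seed=rng_seed + 2)
    panel = simulate_registry_panel(
        pheno_latent, noise_sd=config.panel_noise_sd,
        zero_rate=config.panel_zero_rate, seed=rng_seed + 3,
    )
    traits_df = collapse_panel(panel).merge(
        pheno_latent[["iid", "family", "sex"]], on="iid"
    )
    for trait in TRAITS:
        traits_df[trait] = residualize_and_standardize(
            traits_df[trait], (traits_df["sex"] == 2).astype(float)
        )

    pairs = pairs_to_frame(ped.classify_pairs())

    def record(method, trait, est, se):
        herit_rows.append({
            "method": method, "indicator": trait, "h2": est, "se": se,
            "lo95": max(est - 1.96 * se, 0.0), "hi95": min(est + 1.96 * se, 1.0),
        })

    # ---- family-pedigree fits -------------------------------------------
    fp_bivs: dict[tuple[str, str], object] = {}
    free_fits: dict[str, object] = {}
    for trait in TRAITS:
        table = build_pair_table(pairs, traits_df, trait, covariates=())
        try:
            if config.fp_ae:
                f = FamilyACE("AE", covariates=()).fit(table, trait).fit_
                record("fp_ae", trait, f.a2, f.se["a2"])
            if config.fp_ace_fixed:
                f = FamilyACE("ACE", rc_cousin=0.0, covariates=()).fit(table, trait).fit_
                record("fp_ace_rc0", trait, f.a2, f.se["a2"])
                shared_rows.append({"method": "fp_ace_rc0", "indicator": trait,
                                    "c2": f.c2, "se": f.se["c2"]})
            if config.fp_ace_free:
                f = FamilyACE("ACE", rc_cousin="free", covariates=()).fit(table, trait).fit_
                free_fits[trait] = f
                record("fp_ace_free", trait, f.a2, f.se["a2"])
                shared_rows.append({"method": "fp_ace_free", "indicator": trait,
                                    "c2": f.c2, "se": f.se["c2"],
                                    "rho_c": f.rho_c, "se_rho_c": f.se.get("rho_c")})
        except Exception as exc:  # pragma: no cover - stage guard
            errors.append(f"family_pedigree[{trait}]: {exc}")

    sensitivity = None
    if config.run_sensitivity:
        table = build_pair_table(pairs, traits_df, config.sensitivity_trait, covariates=())
        sensitivity = sensitivity_sweep(table, config.sensitivity_trait, covariates=())

    # ---- IBD AE ----------------------------------------------------------
    genos = None
    ibd_pairs = None
    if config.ibd or config.fp_ace_free:
        try:
            genos = simulate_genotypes(
                ped, config.m_snps, block_len=config.block_len, seed=rng_seed + 4
            )
        except Exception as exc:  # pragma: no cover
            errors.append(f"genotypes: {exc}")
    if config.ibd and genos is not None:
        try:
            sibs = pairs[pairs["relationship"].isin([REL_FULLSIB, REL_DZ])]
            shared = estimate_ibd_sharing(genos, sibs, min_informative_snps=50)
            ibd_pairs = shared.merge(
                sibs[["id1", "id2", "relationship"]], on=["id1", "id2", "relationship"]
            )
            for trait in TRAITS:
                table = build_pair_table(
                    ibd_pairs, traits_df, trait, covariates=(), r_g_column="r_hat"
                )
                f = IBDAE(covariates=()).fit(table, trait).fit_
                record("ibd_ae", trait, f.a2, f.se["a2"])
        except Exception as exc:
            errors.append(f"ibd: {exc}")

    # ---- SNP-based methods ----------------------------------------------
    sumstats = {}
    ld = None
    grm_pruned = None
    u_pheno = None
    if config.greml or config.ldsc:
        try:
            u_genos = simulate_unrelated_genotypes(
                config.n_unrelated, config.m_snps_unrelated, seed=rng_seed + 5,
                block_len=config.block_len,
                n_ancestral_haplotypes=config.n_ancestral_haplotypes,
            ).filter_maf(config.maf_min)
            u_model = TraitModel(
                var_a=np.array(config.snp_h2), var_c=0.0,
                var_e=1.0 - np.array(config.snp_h2),
                R_A=_corr_full(t, config.r_offdiag_a),
                R_E=_corr_full(t, config.r_offdiag_e),
                beta_sex=config.beta_sex,
            )
            u_pheno = simulate_snp_phenotypes(u_genos, u_model, seed=rng_seed + 6)
            std = standardize_genotypes(u_genos, maf_min=config.maf_min)
            grm = compute_grm(std)
            kept = prune_relatives(grm, cutoff=config.grm_cutoff)
            idx = [grm.sample_ids.index(s) for s in kept]
            from .snpherit import Grm as _Grm

            grm_pruned = _Grm(grm.matrix[np.ix_(idx, idx)], grm.n_snps, kept)
            covar = (u_pheno.set_index("iid").loc[kept, "sex"] == 2).astype(float)
            covar = covar.to_numpy()[:, None]
            if config.greml:
                for trait in TRAITS:
                    yv = u_pheno.set_index("iid").loc[kept, trait].to_numpy(float)
                    f = fit_greml(yv, covar, grm_pruned)
                    record("greml", trait, f.h2, f.se_h2)
            if config.ldsc:
                ld = compute_ld_scores(u_genos, window_snps=config.ld_window_snps)
                sex_cov = (u_pheno["sex"] == 2).astype(float).to_numpy()[:, None]
                for trait in TRAITS:
                    ss = run_gwas(u_pheno[trait].to_numpy(float), u_genos, sex_cov)
                    sumstats[trait] = ss
                    f = ldsc_regression(ss, ld, n_blocks=config.ldsc_blocks)
                    record("ldsc", trait, f.h2, f.se_h2)
        except Exception as exc:
            errors.append(f"snp_methods: {exc}")

    # ---- correlation structure ------------------------------------------
    if config.run_structure:
        phen_corr = np.corrcoef(traits_df[list(TRAITS)].to_numpy(), rowvar=False)
        matrices.append(ComponentCorrMatrix(
            "phenotypic", "registry", phen_corr, n_effective=len(traits_df)
        ))
        vals = {s: {} for s in ("A", "C", "E")}
        ses = {s: {} for s in ("A", "C", "E")}
        for i in range(t):
            for j in range(i + 1, t):
                tx, ty = TRAITS[i], TRAITS[j]
                try:
                    table = build_pair_table(pairs, traits_df, (tx, ty), covariates=())
                    bf = BivariateACE(
                        "ACE", rc_cousin=config.rho_c_cousin, covariates=()
                    ).fit(table, (tx, ty)).fit_
                    for s, v in (("A", bf.r_A), ("C", bf.r_C), ("E", bf.r_E)):
                        vals[s][(tx, ty)] = v
                        ses[s][(tx, ty)] = bf.se.get(f"r_{s}", np.nan)
                except Exception as exc:
                    errors.append(f"structure[bivariate {tx}/{ty}]: {exc}")
        n_eff = int(len(pairs))
        for s in ("A", "C", "E"):
            try:
                matrices.append(assemble_matrix(
                    vals[s], s, "family_pedigree", se_values=ses[s], n_effective=n_eff
                ))
            except Exception as exc:
                errors.append(f"structure[matrix {s}]: {exc}")
        if config.ldsc and ld is not None and len(sumstats) == t:
            try:
                lvals = {}
                for i in range(t):
                    for j in range(i + 1, t):
                        tx, ty = TRAITS[i], TRAITS[j]
                        ct = cross_trait_ldsc(sumstats[tx], sumstats[ty], ld,
                                              n_blocks=config.ldsc_blocks)
                        lvals[(tx, ty)] = np.clip(ct.r_g, -1.0, 1.0)
                matrices.append(assemble_matrix(
                    lvals, "A", "ldsc", n_effective=config.n_unrelated
                ))
            except Exception as exc:
                errors.append(f"structure[ldsc matrix]: {exc}")
        for mat in matrices:
            key = f"{mat.method}:{mat.source}"
            try:
                res = pca(mat)
                pa = parallel_analysis(
                    corr=mat.values, n_obs=mat.n_effective or 1000,
                    n_sims=max(config.n_parallel_sims, 100), seed=rng_seed + 9,
                )
                boot = bootstrap_component_pca(
                    mat, n=mat.n_effective or 1000, n_boot=config.n_boot,
                    seed=rng_seed + 10,
                )
                pca_results[key] = {
                    "explained": res.explained,
                    "n_retained": pa["n_retained"],
                    "explained_lo": boot.ci["explained_lo"],
                    "explained_hi": boot.ci["explained_hi"],
                }
            except Exception as exc:
                errors.append(f"structure[pca {key}]: {exc}")

    heritability = pd.DataFrame(herit_rows)
    shared_env = pd.DataFrame(shared_rows)
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "deviations": [
            "per-SNP association uses OLS with covariates, not a sparse-GRM mixed model",
            "relative pairs enter the family likelihood as independent (pseudo-likelihood)",
        ],
    }
    bundle = ReportBundle(heritability, shared_env, sensitivity, matrices,
                          pca_results, metadata, errors)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
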