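"""Synthetic families, genotypes and multi-trait ACE phenotypes.

Everything downstream of this module is validated by parameter recovery:
pedigrees with monozygotic/dizygotic twin, full-sibling and first-cousin
pairs; biallelic genotypes gene-dropped through the pedigree so realized
sibling sharing varies around 0.5; and phenotypes whose additive-genetic (A),
shared-environment (C) and non-shared (E) structure — including cross-trait
correlation matrices and the cousin shared-environment correlation — is known
exactly.

The family-level phenotype draw uses the Kronecker covariance
``relatedness (x) trait-correlation`` per variance source, so pairwise moments
equal ``a^2 * r_g + c^2 * r_c`` trait-by-trait and
``a_x a_y r_A r_g + c_x c_y r_C r_c`` across traits by construction.
Recombination is modeled as independent blocks of ``block_len`` SNPs with one
grandparental origin each — enough to create variance in realized sibling
sharing without a centimorgan map.  Optional linkage disequilibrium is created
by drawing founder haplotypes from a small ancestral pool per block, and
optional population stratification by Balding-Nichols per-SNP allele-frequency
divergence between subpopulations plus a phenotype mean offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pedigree import Pedigree, REL_COUSIN, REL_DZ, REL_FULLSIB, REL_MZ

TRAITS = ("education", "occupation", "income", "wealth")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class FamilyConfig:
    """Shape of the simulated extended families.

    With ``cousin_links`` each family is three generations: a founder
    grandparent couple, two sibling parents each mated to an unrelated
    founder, and one phenotyped sibship per parent couple (the children of the
    two sibships are first cousins).  Without it each family is one nuclear
    sibship.  ``offspring_per_sibship`` is an int or an inclusive
    ``(low, high)`` range sampled per sibship.  At most one twin pair is
    placed per sibship, MZ with probability ``twin_rate_mz`` and DZ with
    ``twin_rate_dz``.
    """

    n_families: int = 100
    offspring_per_sibship: int | tuple[int, int] = 2
    twin_rate_mz: float = 0.0
    twin_rate_dz: float = 0.0
    cousin_links: bool = True

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("twin_rate_mz", "twin_rate_dz"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.twin_rate_mz + self.twin_rate_dz > 1.0:
            raise ValueError("twin_rate_mz + twin_rate_dz must not exceed 1")
        k = self.offspring_per_sibship
        if isinstance(k, tuple):
            if k[0] < 1 or k[1] < k[0]:
                raise ValueError("invalid offspring_per_sibship range")
        elif k < 1:
            raise ValueError("offspring_per_sibship must be >= 1")


def _as_corr(mat, t: int, name: str) -> np.ndarray:
    if mat is None:
        return np.eye(t)
    m = np.asarray(mat, dtype=float)
    if m.shape != (t, t):
        raise ValueError(f"{name} must be {t}x{t}")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return m


@dataclass
class TraitModel:
    """Generating A/C/E structure for the simulated traits.

    ``var_a``, ``var_c``, ``var_e`` are per-trait variance fractions summing
    to one (scalars broadcast over traits).  ``R_A``, ``R_C``, ``R_E`` are the
    cross-trait correlation matrices of the three sources.  ``rho_c_cousin``
    is the shared-environment correlation applied between first cousins
    (siblings and twins get 1).  In ``snp_mode`` the A part of each trait is a
    weighted sum of ``m_causal`` standardized SNP dosages instead of the
    pedigree-expectation draw.
    """

    var_a: float | np.ndarray = 0.4
    var_c: float | np.ndarray = 0.2
    var_e: float | np.ndarray = 0.4
    R_A: np.ndarray | None = None
    R_C: np.ndarray | None = None
    R_E: np.ndarray | None = None
    rho_c_cousin: float = 0.0
    beta_sex: float | np.ndarray = 0.0
    snp_mode: bool = False
    m_causal: int | None = None
    strat_offset: float = 0.0
    traits: tuple[str, ...] = TRAITS

    def resolved(self) -> "TraitModel":
        t = len(self.traits)
        out = TraitModel(
            var_a=np.broadcast_to(np.asarray(self.var_a, float), (t,)).copy(),
            var_c=np.broadcast_to(np.asarray(self.var_c, float), (t,)).copy(),
            var_e=np.broadcast_to(np.asarray(self.var_e, float), (t,)).copy(),
            R_A=_as_corr(self.R_A, t, "R_A"),
            R_C=_as_corr(self.R_C, t, "R_C"),
            R_E=_as_corr(self.R_E, t, "R_E"),
            rho_c_cousin=self.rho_c_cousin,
            beta_sex=np.broadcast_to(np.asarray(self.beta_sex, float), (t,)).copy(),
            snp_mode=self.snp_mode,
            m_causal=self.m_causal,
            strat_offset=self.strat_offset,
            traits=self.traits,
        )
        total = out.var_a + out.var_c + out.var_e
        if not np.allclose(total, 1.0):
            raise ValueError("var_a + var_c + var_e must equal 1 for every trait")
        if not 0.0 <= out.rho_c_cousin <= 1.0:
            raise ValueError("rho_c_cousin must lie in [0, 1]")
        return out


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (0/1/2) for a set of samples.

    ``allele_freqs`` are the founder-population frequencies the SNPs were
    drawn from (used for standardization); ``populations`` is an optional
    per-sample subpopulation label when stratification was simulated.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    allele_freqs: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match sample/snp ids")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset(self, sample_ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        pops = None if self.populations is None else self.populations[rows]
        return GenotypeMatrix(
            self.dosage[rows], list(sample_ids), list(self.snp_ids), self.allele_freqs, pops
        )

    def filter_maf(self, maf_min: float) -> "GenotypeMatrix":
        """Drop SNPs whose empirical minor-allele frequency is below the cutoff."""
        p = self.dosage.mean(axis=0) / 2.0
        keep = np.minimum(p, 1.0 - p) >= maf_min
        return GenotypeMatrix(
            self.dosage[:, keep],
            list(self.sample_ids),
            [s for s, k in zip(self.snp_ids, keep) if k],
            self.allele_freqs[keep],
            self.populations,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snp_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        dosage = df.to_numpy(dtype=np.int8)
        n = max(dosage.shape[0], 1)
        freqs = dosage.mean(axis=0) / 2.0
        return cls(dosage, [str(i) for i in df.index], list(df.columns), freqs)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(config: FamilyConfig, seed: int, id_prefix: str = "F") -> Pedigree:
    """Simulate extended families with the requested relationship classes.

    Deterministic for a fixed seed.  The phenotyped study cohort is the leaf
    generation (``Pedigree.leaves()``).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, int, str]] = []
    twin_counter = 0

    def rsex() -> int:
        return int(rng.integers(1, 3))

    def sibship_size() -> int:
        k = config.offspring_per_sibship
        if isinstance(k, tuple):
            return int(rng.integers(k[0], k[1] + 1))
        return int(k)

    def add_sibship(fam: str, tag: str, father: str, mother: str) -> None:
        nonlocal twin_counter
        size = sibship_size()
        u = rng.random()
        zyg = None
        if u < config.twin_rate_mz:
            zyg = "MZ"
        elif u < config.twin_rate_mz + config.twin_rate_dz:
            zyg = "DZ"
        if zyg is not None:
            size = max(size, 2)
        sexes = [rsex() for _ in range(size)]
        zygs = ["0"] * size
        if zyg is not None:
            twin_counter += 1
            zygs[0] = zygs[1] = f"{zyg}{id_prefix}{twin_counter}"
            if zyg == "MZ":
                sexes[1] = sexes[0]
        for i in range(size):
            rows.append((f"{fam}_{tag}c{i}", father, mother, sexes[i], zygs[i]))

    for f in range(config.n_families):
        fam = f"{id_prefix}{f}"
        if config.cousin_links:
            gpa, gma = f"{fam}_gpa", f"{fam}_gma"
            rows.append((gpa, "0", "0", 1, "0"))
            rows.append((gma, "0", "0", 2, "0"))
            for branch in ("a", "b"):
                parent = f"{fam}_p{branch}"
                spouse = f"{fam}_s{branch}"
                psex = rsex()
                rows.append((parent, gpa, gma, psex, "0"))
                rows.append((spouse, "0", "0", 3 - psex, "0"))
                father, mother = (parent, spouse) if psex == 1 else (spouse, parent)
                add_sibship(fam, branch, father, mother)
        else:
            fa, mo = f"{fam}_fa", f"{fam}_mo"
            rows.append((fa, "0", "0", 1, "0"))
            rows.append((mo, "0", "0", 2, "0"))
            add_sibship(fam, "a", fa, mo)

    table = pd.DataFrame(rows, columns=Pedigree.COLUMNS)
    return Pedigree(table)


# ---------------------------------------------------------------------------
# genotype simulation (gene dropping)
# ---------------------------------------------------------------------------


def _expand_blocks(choices: np.ndarray, block_len: int, m: int) -> np.ndarray:
    return np.repeat(choices, block_len, axis=1)[:, :m]


def _pool_haplotypes(
    n_haps: int,
    pool: np.ndarray,
    block_len: int,
    rng: np.random.Generator,
    pool_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Mosaic haplotypes from an ancestral pool, one pool member per block."""
    n_ancestral, m = pool.shape
    n_blocks = -(-m // block_len)
    if pool_weights is None:
        picks = rng.integers(0, n_ancestral, size=(n_haps, n_blocks), dtype=np.int16)
    else:
        cum = np.cumsum(pool_weights)
        cum = cum / cum[-1]
        picks = np.searchsorted(cum, rng.random((n_haps, n_blocks))).astype(np.int16)
    out = np.empty((n_haps, m), dtype=np.int8)
    cols = np.arange(m)[None, :]
    for lo in range(0, n_haps, 4000):
        hi = min(lo + 4000, n_haps)
        exp = _expand_blocks(picks[lo:hi], block_len, m)
        out[lo:hi] = pool[exp, cols]
    return out



def _pop_freqs_bn(freqs, fst, rng):
    """Balding-Nichols draw of one subpopulation's allele frequencies."""
    a = freqs * (1.0 - fst) / fst
    b = (1.0 - freqs) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)


def _resample_alleles(hap, pop_freqs, rate, rng):
    """Replace each allele with prob ``rate`` by a Bernoulli(pop freq) draw.

    Applied on top of shared ancestral-pool mosaics, this differentiates the
    subpopulations SNP-by-SNP (independently of the block LD structure), so
    stratification confounding is uncorrelated with LD scores - the regime
    where it inflates the LD-score regression intercept rather than the slope.
    """
    pf32 = pop_freqs.astype(np.float32)
    for lo in range(0, hap.shape[0], 4000):
        hi = min(lo + 4000, hap.shape[0])
        mask = rng.random((hi - lo, hap.shape[1]), dtype=np.float32) < rate
        new = (rng.random((hi - lo, hap.shape[1]), dtype=np.float32) < pf32)
        hap[lo:hi] = np.where(mask, new.astype(np.int8), hap[lo:hi])
    return hap


def simulate_genotypes(
    ped: Pedigree,
    m_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_len: int = 50,
    seed: int = 0,
    n_ancestral_haplotypes: int | None = None,
    n_populations: int = 1,
    fst: float = 0.0,
    strat_resample: float = 0.2,
) -> GenotypeMatrix:
    """Gene-drop biallelic genotypes through a pedigree.

    Founders are drawn from population frequencies (uniform on ``maf_range``);
    each non-founder inherits one grandparental origin per block of
    ``block_len`` SNPs from each parent, so realized sibling sharing varies
    around 0.5.  MZ twins receive identical genotypes.

    With ``n_populations > 1`` whole families are assigned to subpopulations
    whose allele frequencies diverge per SNP via Balding-Nichols draws with
    parameter ``fst`` (applied to founder draws directly, or - when an
    ancestral pool provides LD - by resampling a ``strat_resample`` fraction
    of pool alleles, which keeps the differentiation independent of the LD
    blocks).
    """
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    if block_len < 1 or block_len > m_snps:
        raise ValueError("block_len must be in [1, m_snps]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=m_snps)
    ids = ped.individuals
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    n_blocks = -(-m_snps // block_len)

    founders = [i for i in ids if ped.is_founder(i)]
    pops = np.zeros(n, dtype=int)
    if n_populations > 1:
        # whole families belong to one subpopulation: label founders by family
        comp_of: dict[str, int] = {}
        g = nx.Graph()
        g.add_nodes_from(ids)
        for child in ids:
            f, m = ped.parents(child)
            if f is not None:
                g.add_edge(f, child)
                g.add_edge(m, child)
        for k, comp in enumerate(nx.connected_components(g)):
            lab = int(rng.integers(0, n_populations))
            for iid in comp:
                comp_of[iid] = lab
        pops = np.array([comp_of[i] for i in ids])

    haps = np.zeros((n, 2, m_snps), dtype=np.int8)
    pool = None
    if n_ancestral_haplotypes is not None:
        pool = (
            rng.random((n_ancestral_haplotypes, m_snps), dtype=np.float32)
            < freqs.astype(np.float32)
        ).astype(np.int8)
    for pop in range(max(n_populations, 1)):
        members = [i for i in founders if pops[index[i]] == pop]
        if not members:
            continue
        if pool is not None:
            hap = _pool_haplotypes(2 * len(members), pool, block_len, rng)
            if n_populations > 1 and fst > 0:
                # diverge around the pool's realized frequencies so the
                # confounding stays flat across LD scores
                pool_freqs = np.clip(pool.mean(axis=0), 0.02, 0.98)
                hap = _resample_alleles(
                    hap, _pop_freqs_bn(pool_freqs, fst, rng), strat_resample, rng
                )
        else:
            if n_populations > 1 and fst > 0:
                pop_freqs = _pop_freqs_bn(freqs, fst, rng)
            else:
                pop_freqs = freqs
            # chunked so no single giant temporary is allocated
            hap = np.empty((2 * len(members), m_snps), dtype=np.int8)
            pf32 = pop_freqs.astype(np.float32)
            for lo in range(0, hap.shape[0], 4000):
                hi = min(lo + 4000, hap.shape[0])
                hap[lo:hi] = rng.random((hi - lo, m_snps), dtype=np.float32) < pf32
        rows = [index[i] for i in members]
        haps[rows] = hap.reshape(len(members), 2, m_snps)

    by_depth: dict[int, list[str]] = {}
    for iid in ids:
        if not ped.is_founder(iid):
            by_depth.setdefault(ped.depth(iid), []).append(iid)
    for d in sorted(by_depth):
        children = by_depth[d]
        cidx = np.array([index[c] for c in children])
        for slot, pick_parent in enumerate((0, 1)):
            pidx = np.array(
                [index[ped.parents(c)[pick_parent]] for c in children]
            )
            # int8 mask + where keeps the temporaries small (vs int64 gather)
            for lo in range(0, len(children), 4000):
                hi = min(lo + 4000, len(children))
                choice = rng.integers(
                    0, 2, size=(hi - lo, n_blocks), dtype=np.int8
                )
                cexp = _expand_blocks(choice, block_len, m_snps).astype(bool)
                sub = pidx[lo:hi]
                haps[cidx[lo:hi], slot, :] = np.where(
                    cexp, haps[sub, 1, :], haps[sub, 0, :]
                )
    # MZ co-twins are genetically identical: copy the first twin's haplotypes
    for members in ped._twin_sets.values():
        a, b = sorted(members)
        if ped.zygosity(a) == "MZ":
            haps[index[b]] = haps[index[a]]

    dosage = haps.sum(axis=1, dtype=np.int8)
    snp_ids = [f"snp{j}" for j in range(m_snps)]
    return GenotypeMatrix(dosage, ids, snp_ids, freqs, pops if n_populations > 1 else None)


def simulate_unrelated_genotypes(
    n_samples: int,
    m_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    block_len: int = 50,
    n_ancestral_haplotypes: int | None = None,
    n_populations: int = 1,
    fst: float = 0.0,
    strat_resample: float = 0.2,
) -> GenotypeMatrix:
    """Founder-only genotypes for the SNP-based estimators (no pedigree).

    Stratification follows the same scheme as :func:`simulate_genotypes`.
    """
    if m_snps < 1 or n_samples < 1:
        raise ValueError("need at least one sample and one SNP")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=m_snps)
    pops = (
        rng.integers(0, n_populations, size=n_samples)
        if n_populations > 1
        else np.zeros(n_samples, dtype=int)
    )
    dosage = np.zeros((n_samples, m_snps), dtype=np.int8)
    pool = None
    if n_ancestral_haplotypes is not None:
        pool = (
            rng.random((n_ancestral_haplotypes, m_snps), dtype=np.float32)
            < freqs.astype(np.float32)
        ).astype(np.int8)
    for pop in range(max(n_populations, 1)):
        rows = np.where(pops == pop)[0]
        if rows.size == 0:
            continue
        if pool is not None:
            hap = _pool_haplotypes(2 * rows.size, pool, block_len, rng)
            if n_populations > 1 and fst > 0:
                pool_freqs = np.clip(pool.mean(axis=0), 0.02, 0.98)
                hap = _resample_alleles(
                    hap, _pop_freqs_bn(pool_freqs, fst, rng), strat_resample, rng
                )
            dosage[rows] = (
                hap.reshape(rows.size, 2, m_snps).sum(axis=1).astype(np.int8)
            )
        else:
            if n_populations > 1 and fst > 0:
                pf = _pop_freqs_bn(freqs, fst, rng)
            else:
                pf = freqs
            # two Bernoulli gametes; float32 uniforms are much faster at this size
            pf32 = pf.astype(np.float32)
            dosage[rows] = (
                (rng.random((rows.size, m_snps), dtype=np.float32) < pf32).astype(np.int8)
                + (rng.random((rows.size, m_snps), dtype=np.float32) < pf32).astype(np.int8)
            )
    ids = [f"I{i}" for i in range(n_samples)]
    snps = [f"snp{j}" for j in range(m_snps)]
    return GenotypeMatrix(dosage, ids, snps, freqs, pops if n_populations > 1 else None)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def _component_cov(var: np.ndarray, corr: np.ndarray) -> np.ndarray:
    s = np.sqrt(var)
    return corr * np.outer(s, s)


def _chol_psd(mat: np.ndarray) -> np.ndarray:
    # eigen-based factor tolerant of semi-definite matrices
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _snp_genetic_values(
    genos: GenotypeMatrix,
    sample_ids: list[str],
    model: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray:
    t = len(model.traits)
    m = genos.n_snps
    m_causal = model.m_causal or m
    causal = rng.choice(m, size=min(m_causal, m), replace=False)
    causal.sort()
    sub = genos.subset(sample_ids)
    p = genos.allele_freqs[causal]
    w = (sub.dosage[:, causal].astype(np.float64) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    # per-SNP effect vectors correlated across traits with R_A
    b = rng.standard_normal((len(causal), t)) @ _chol_psd(model.R_A).T
    g = w @ b
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - g.mean(axis=0)) / sd * np.sqrt(model.var_a)


def simulate_phenotypes(
    ped: Pedigree,
    model: TraitModel,
    genos: GenotypeMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw cohort phenotypes with the requested A/C/E structure.

    Trait vectors of each extended family's cohort members are drawn jointly
    with component covariances ``K (x) C_A`` (K = expected relatedness),
    ``Q (x) C_C`` (Q has sibling entries 1 and cousin entries
    ``rho_c_cousin``) and ``I (x) C_E``, where ``C_k`` are the trait
    covariance matrices implied by the variance fractions and ``R_k``.  In
    ``snp_mode`` the A part is built from genotype dosages instead.

    Returns a DataFrame with columns iid, family, sex and one column per trait.
    """
    model = model.resolved()
    rng = np.random.default_rng(seed)
    if model.snp_mode and genos is None:
        raise ValueError("snp_mode requires a genotype matrix")
    cohort = ped.leaves()
    t = len(model.traits)

    # connected components = extended families
    g = nx.Graph()
    g.add_nodes_from(ped.individuals)
    for child in ped.individuals:
        f, m = ped.parents(child)
        if f is not None:
            g.add_edge(f, child)
            g.add_edge(m, child)
    fam_of: dict[str, int] = {}
    for k, comp in enumerate(nx.connected_components(g)):
        for iid in comp:
            fam_of[iid] = k

    families: dict[int, list[str]] = {}
    for iid in cohort:
        families.setdefault(fam_of[iid], []).append(iid)

    # group families by identical (K, Q) structure so the factorization is
    # done once per structure and the draw is vectorized across families
    groups: dict[bytes, dict] = {}
    order: list[str] = []
    for fam, members in sorted(families.items()):
        members = sorted(members)
        order.extend(members)
        nf = len(members)
        K = np.eye(nf)
        Q = np.eye(nf)
        for i in range(nf):
            for j in range(i + 1, nf):
                K[i, j] = K[j, i] = ped.expected_relatedness(members[i], members[j])
                rel = ped.relationship(members[i], members[j])
                if rel in (REL_MZ, REL_DZ, REL_FULLSIB):
                    q = 1.0
                elif rel == REL_COUSIN:
                    q = model.rho_c_cousin
                else:
                    q = 0.0
                Q[i, j] = Q[j, i] = q
        key = K.tobytes() + Q.tobytes()
        grp = groups.setdefault(key, {"K": K, "Q": Q, "members": []})
        grp["members"].append(members)

    values = {}
    comps = {"A": (model.var_a, model.R_A), "C": (model.var_c, model.R_C),
             "E": (model.var_e, model.R_E)}
    for grp in groups.values():
        nf = len(grp["members"][0])
        rels = {"A": grp["K"], "C": grp["Q"], "E": np.eye(nf)}
        n_fam = len(grp["members"])
        total = np.zeros((n_fam, nf * t))
        for name, (var, corr) in comps.items():
            if name == "A" and model.snp_mode:
                continue
            cov = np.kron(rels[name], _component_cov(var, corr))
            L = _chol_psd(cov)
            z = rng.standard_normal((n_fam, nf * t))
            total += z @ L.T
        for fam_i, members in enumerate(grp["members"]):
            block = total[fam_i].reshape(nf, t)
            for row, iid in zip(block, members):
                values[iid] = row

    ordered = sorted(values)
    y = np.vstack([values[i] for i in ordered])
    if model.snp_mode:
        y = y + _snp_genetic_values(genos, ordered, model, rng)

    sex = np.array([ped.sex(i) for i in ordered])
    y = y + np.outer((sex == 2).astype(float), model.beta_sex)
    if model.strat_offset and genos is not None and genos.populations is not None:
        pop_of = dict(zip(genos.sample_ids, genos.populations))
        pop = np.array([pop_of[i] for i in ordered], dtype=float)
        y = y + model.strat_offset * (pop - pop.mean())[:, None]

    out = pd.DataFrame(y, columns=list(model.traits))
    out.insert(0, "sex", sex)
    out.insert(0, "family", [fam_of[i] for i in ordered])
    out.insert(0, "iid", ordered)
    return out


def simulate_snp_phenotypes(
    genos: GenotypeMatrix,
    model: TraitModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes for unrelated samples: SNP-driven A plus correlated noise.

    Used by the SNP-based estimators, where there is no family structure: the
    C fraction must be zero and E absorbs everything non-genetic.  The
    realized genetic values are rescaled so each trait's SNP heritability is
    exactly ``var_a``.
    """
    model = model.resolved()
    if np.any(model.var_c > 0):
        raise ValueError("unrelated-sample phenotypes cannot carry a C component")
    rng = np.random.default_rng(seed)
    ids = list(genos.sample_ids)
    g = _snp_genetic_values(genos, ids, model, rng)
    t = len(model.traits)
    e = rng.standard_normal((len(ids), t)) @ _chol_psd(
        _component_cov(model.var_e, model.R_E)
    ).T
    y = g + e
    sex = rng.integers(1, 3, size=len(ids))
    y = y + np.outer((sex == 2).astype(float), model.beta_sex)
    if model.strat_offset and genos.populations is not None:
        pop = genos.populations.astype(float)
        y = y + model.strat_offset * (pop - pop.mean())[:, None]
    out = pd.DataFrame(y, columns=list(model.traits))
    out.insert(0, "sex", sex)
    out.insert(0, "family", np.arange(len(ids)))
    out.insert(0, "iid", ids)
    return out


# ---------------------------------------------------------------------------
# registry panel emulation
# ---------------------------------------------------------------------------

_EDU_LEVELS = (9, 21)  # compulsory school .. doctoral, in years


def simulate_registry_panel(
    pheno: pd.DataFrame,
    window_years: int = 11,
    noise_sd: float = 0.2,
    zero_rate: float = 0.02,
    seed: int = 0,
    age_start: int = 35,
) -> pd.DataFrame:
    """Emulate yearly registry measurements over an age window.

    Monetary traits (income, wealth) are mapped from the latent standardized
    phenotype to a positive kroner-like scale by exponentiation, with yearly
    multiplicative noise and, at rate ``zero_rate``, zero (income) or zero or
    negative (wealth) entries.  Occupational prestige becomes a noisy yearly
    score on a SIOPS-like 16-78 scale.  Education becomes a nondecreasing
    yearly attainment series in years of schooling whose maximum is the final
    attainment (constant when ``noise_sd`` is 0).
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(pheno)
    years = np.arange(age_start, age_start + window_years)

    def z(col: str) -> np.ndarray:
        v = pheno[col].to_numpy(dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    frames = []
    z_inc, z_wea = z("income"), z("wealth")
    z_occ, z_edu = z("occupation"), z("education")
    final_years = np.clip(np.round(13 + 2.5 * z_edu), *_EDU_LEVELS).astype(int)
    ramp = (
        rng.integers(0, 3, size=n) if noise_sd > 0 else np.zeros(n, dtype=int)
    )
    for ti, year in enumerate(years):
        income = np.exp(12.0 + 0.5 * (z_inc + rng.normal(0, noise_sd, n)))
        wealth = np.exp(13.0 + 0.8 * (z_wea + rng.normal(0, noise_sd, n)))
        if zero_rate > 0:
            income[rng.random(n) < zero_rate] = 0.0
            hit = rng.random(n) < zero_rate
            neg = hit & (rng.random(n) < 0.5)
            wealth[hit] = 0.0
            wealth[neg] = -np.exp(rng.normal(10.0, 1.0, size=int(neg.sum())))
        occupation = np.clip(45.0 + 10.0 * (z_occ + rng.normal(0, noise_sd, n)), 16, 78)
        education = final_years - np.maximum(ramp - ti, 0)
        frames.append(
            pd.DataFrame(
                {
                    "iid": pheno["iid"].to_numpy(),
                    "age": year,
                    "education": education,
                    "occupation": occupation,
                    "income": income,
                    "wealth": wealth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True).sort_values(["iid", "age"], ignore_index=True)
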