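"""SNP-based heritability: GRM/REML and LD-score regression.

The genomic-relatedness path standardizes dosages column-wise, forms
``A = W W' / N``, greedily prunes close relatives, and maximizes the
restricted likelihood of ``y = X b + g + e`` with ``Var(y) = A sg2 + I se2``
by eigendecomposition of the projected GRM, reducing REML to a 1-parameter
profile optimization; ``h2 = sg2 / (sg2 + se2)``.

The summary-statistic path runs a per-SNP OLS association scan (a desk-scale
stand-in for a sparse mixed-model solver; the deviation is recorded in run
metadata by the pipeline), computes bias-adjusted LD scores
``l_j = sum_k r2(j,k) - (1 - r2)/(n-2)`` over an index window, and regresses
chi-square statistics on ``N l / M`` with iterative weights and a block
jackknife: the slope estimates SNP heritability and the intercept absorbs
confounding such as population stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .simdata import GenotypeMatrix


# ---------------------------------------------------------------------------
# genotype standardization and GRM
# ---------------------------------------------------------------------------


@dataclass
class StandardizedGenotypes:
    W: np.ndarray
    snp_ids: list[str]
    freqs: np.ndarray
    sample_ids: list[str]


@dataclass
class Grm:
    """Genomic relatedness matrix A = WW'/N with the SNP count N."""

    matrix: np.ndarray
    n_snps: int
    sample_ids: list[str]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    def to_gcta(self, prefix: str) -> None:
        """Write the GCTA binary triplet (grm.bin / grm.N.bin / grm.id)."""
        n = len(self.sample_ids)
        tri = self.matrix[np.tril_indices(n)]
        tri.astype("<f4").tofile(f"{prefix}.grm.bin")
        np.full(tri.shape, self.n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
        pd.DataFrame({"fid": self.sample_ids, "iid": self.sample_ids}).to_csv(
            f"{prefix}.grm.id", sep="\t", header=False, index=False
        )


def standardize_genotypes(
    genos: GenotypeMatrix, maf_min: float = 0.01
) -> StandardizedGenotypes:
    """Drop SNPs below the MAF cutoff and scale dosages to mean 0, variance 1.

    Columns become ``(x - 2p) / sqrt(2 p (1-p))`` with ``p`` the empirical
    allele frequency; monomorphic (zero-variance) SNPs are dropped.
    """
    dosage = np.asarray(genos.dosage, dtype=np.float64)
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= maf_min) & (dosage.std(axis=0) > 0)
    if not keep.any():
        raise ValueError("no SNPs survive MAF filter")
    p = p[keep]
    W = (dosage[:, keep] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    snp_ids = [s for s, k in zip(genos.snp_ids, keep) if k]
    return StandardizedGenotypes(W, snp_ids, p, list(genos.sample_ids))


def compute_grm(std: StandardizedGenotypes) -> Grm:
    """A = WW'/N over the standardized SNPs."""
    W = std.W
    if W.shape[1] == 0:
        raise ValueError("cannot build a GRM from zero SNPs")
    A = W @ W.T / W.shape[1]
    return Grm((A + A.T) / 2.0, W.shape[1], list(std.sample_ids))


def prune_relatives(grm: Grm, cutoff: float = 0.025) -> list[str]:
    """Greedy relative pruning: drop the sample with most above-cutoff partners.

    Iterates until no off-diagonal exceeds ``cutoff``; ties break on sample
    order, so the result is deterministic.  Returns the retained sample ids.
    """
    A = grm.matrix
    n = A.shape[0]
    adj = A > cutoff
    np.fill_diagonal(adj, False)
    keep = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1).astype(int)
    while True:
        active = np.where(keep)[0]
        if degree[active].max(initial=0) == 0:
            break
        worst = active[np.argmax(degree[active])]
        keep[worst] = False
        partners = np.where(adj[worst] & keep)[0]
        degree[partners] -= 1
        degree[worst] = 0
    return [s for s, k in zip(grm.sample_ids, keep) if k]


# ---------------------------------------------------------------------------
# GREML
# ---------------------------------------------------------------------------


@dataclass
class GremlFit:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    n_used: int
    converged: bool
    boundary: bool


def _reml_rotation(y_list, X, A):
    """Project out fixed effects and rotate onto GRM eigenvectors."""
    n = A.shape[0]
    X = np.column_stack([np.ones(n), X]) if X is not None else np.ones((n, 1))
    # orthonormal basis of the complement of the column space of X
    q, _ = np.linalg.qr(X)
    # complete to a full orthonormal basis; the trailing columns span the complement
    full, _ = np.linalg.qr(np.column_stack([q, np.eye(n)]))
    T = full[:, X.shape[1]:].T
    M = T @ A @ T.T
    lam, U = np.linalg.eigh((M + M.T) / 2.0)
    if lam.min() < -1e-8:
        warnings.warn("GRM is not positive semi-definite; shifting eigenvalues")
        lam = lam - lam.min()
    lam = np.clip(lam, 0.0, None)
    zs = [U.T @ (T @ y) for y in y_list]
    return lam, zs


class GREML(BaseEstimator):
    """Restricted maximum likelihood on a genomic relatedness matrix.

    ``fit(grm, y, covariates=...)`` maximizes the restricted likelihood of
    ``Var(y) = A sg2 + I se2`` on the eigenbasis of the projected GRM, where
    it separates into independent normal scalars, and profiles out the total
    variance so only the heritability ratio is searched.  Standard errors
    come from the observed information in ``(sg2, se2)``.
    """

    def fit(self, grm: Grm, y: np.ndarray, covariates: np.ndarray | None = None) -> "GREML":
        y = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError("y must be complete")
        lam, (z,) = _reml_rotation([y], covariates, grm.matrix)
        z2 = z**2
        k = len(z)

        def profile_nll(h):
            d = h * lam + (1.0 - h)
            if np.any(d <= 0):
                return 1e12
            v = float(np.mean(z2 / d))
            return 0.5 * (np.log(d).sum() + k * np.log(v) + k)

        res = minimize_scalar(profile_nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-8})
        h = float(res.x)
        d = h * lam + (1.0 - h)
        v = float(np.mean(z2 / d))
        sg, se_comp = v * h, v * (1.0 - h)

        def nll_comp(p):
            dd = p[0] * lam + p[1]
            if np.any(dd <= 0):
                return 1e12
            return 0.5 * float(np.log(dd).sum() + (z2 / dd).sum())

        eps = 1e-4 * max(v, 1e-8)
        H = np.zeros((2, 2))
        p0 = np.array([sg, se_comp])
        for i in range(2):
            for j in range(i, 2):
                ei, ej = np.zeros(2), np.zeros(2)
                ei[i] = eps
                ej[j] = eps
                H[i, j] = H[j, i] = (
                    nll_comp(p0 + ei + ej) - nll_comp(p0 + ei - ej)
                    - nll_comp(p0 - ei + ej) + nll_comp(p0 - ei - ej)
                ) / (4 * eps * eps)
        cov = _safe_inv(H)
        total = sg + se_comp
        J = np.array([se_comp, -sg]) / total**2
        se_h2 = float(np.sqrt(max(J @ cov @ J, 0.0)))

        self.fit_ = GremlFit(
            sigma_g2=sg,
            sigma_e2=se_comp,
            h2=h,
            se_h2=se_h2,
            loglik=-float(res.fun),
            n_used=grm.matrix.shape[0],
            converged=True,
            boundary=bool(h < 1e-6 or h > 1 - 1e-6),
        )
        self.h2_ = h
        self.se_h2_ = se_h2
        return self


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def fit_greml(y, covariates, grm: Grm) -> GremlFit:
    return GREML().fit(grm, y, covariates).fit_


@dataclass
class BivariateGremlFit:
    r_g: float
    se_rg: float
    h2: tuple[float, float]
    loglik: float
    unestimable: bool


def fit_bivariate_greml(
    y1, y2, covariates, grm: Grm
) -> BivariateGremlFit:
    """Bivariate REML genetic correlation on a shared GRM.

    On the GRM eigenbasis each eigenvalue contributes an independent
    bivariate normal with covariance ``lam * G + E`` (G, E the 2x2 genetic
    and residual covariance blocks); ``r_g = g12 / sqrt(g1 g2)`` is a direct
    parameter with an observed-information SE.
    """
    lam, (z1, z2) = _reml_rotation([np.asarray(y1, float), np.asarray(y2, float)],
                                   covariates, grm.matrix)
    v1, v2 = z1.var(), z2.var()
    # start the correlations at the empirical value, clipped off the
    # singular boundary (identical traits drive them to +-1)
    r0 = float(np.clip(np.corrcoef(z1, z2)[0, 1], -0.99, 0.99))
    start = np.array([0.3 * v1, 0.3 * v2, r0, 0.7 * v1, 0.7 * v2, r0])
    bounds = [(1e-10, None), (1e-10, None), (-0.9999, 0.9999),
              (1e-10, None), (1e-10, None), (-0.9999, 0.9999)]

    def nll(p):
        g1, g2, rg, e1, e2, re = p
        g12 = rg * np.sqrt(g1 * g2)
        e12 = re * np.sqrt(e1 * e2)
        m11 = g1 * lam + e1
        m22 = g2 * lam + e2
        m12 = g12 * lam + e12
        det = m11 * m22 - m12**2
        if np.any(det <= 0):
            return 1e12
        quad = (m22 * z1**2 - 2 * m12 * z1 * z2 + m11 * z2**2) / det
        return 0.5 * float(np.log(det).sum() + quad.sum())

    res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 1000})
    g1, g2, rg = res.x[0], res.x[1], res.x[2]
    h2 = (g1 / (g1 + res.x[3]), g2 / (g2 + res.x[4]))
    unest = bool(min(h2) < 1e-4)
    if unest:
        return BivariateGremlFit(np.nan, np.nan, h2, -res.fun, True)
    h = 1e-4 * np.maximum(1.0, np.abs(res.x))
    k = 6
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(res.x + ei + ej) - nll(res.x + ei - ej)
                - nll(res.x - ei + ej) + nll(res.x - ei - ej)
            ) / (4 * h[i] * h[j])
    cov = _safe_inv(H)
    se_rg = float(np.sqrt(max(cov[2, 2], 0.0)))
    return BivariateGremlFit(float(rg), se_rg, h2, -res.fun, False)


# ---------------------------------------------------------------------------
# GWAS association scan
# ---------------------------------------------------------------------------


def run_gwas(
    y: np.ndarray,
    genos: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    chunk_snps: int = 4096,
) -> pd.DataFrame:
    """Per-SNP linear association of ``y`` on dosage with covariates.

    Ordinary least squares with the covariates projected out of both the
    phenotype and each dosage column.  Zero-variance SNPs are skipped.
    Returns an LDSC-style summary-statistics frame with columns
    SNP, A1, A2, N, BETA, SE, Z, CHISQ.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    q, _ = np.linalg.qr(X)
    yr = y - q @ (q.T @ y)
    k = X.shape[1]
    dof = n - k - 1
    rows = []
    skipped = 0
    for start in range(0, genos.n_snps, chunk_snps):
        sl = slice(start, min(start + chunk_snps, genos.n_snps))
        G = genos.dosage[:, sl].astype(np.float64)
        G = G - q @ (q.T @ G)
        xx = np.einsum("ij,ij->j", G, G)
        ok = xx > 1e-12
        skipped += int((~ok).sum())
        xy = yr @ G
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, xy / xx, np.nan)
            rss = yr @ yr - np.where(ok, beta**2 * xx, 0.0)
            se = np.sqrt(rss / dof / xx)
        ids = genos.snp_ids[sl.start: sl.stop]
        sub = pd.DataFrame(
            {"SNP": ids, "A1": "A", "A2": "B", "N": n, "BETA": beta, "SE": se}
        )[ok]
        rows.append(sub)
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance SNPs in GWAS")
    ss = pd.concat(rows, ignore_index=True)
    ss["Z"] = ss["BETA"] / ss["SE"]
    ss["CHISQ"] = ss["Z"] ** 2
    return ss


# ---------------------------------------------------------------------------
# LD scores and LD-score regression
# ---------------------------------------------------------------------------


@dataclass
class LdScores:
    frame: pd.DataFrame  # columns SNP, L2
    window_snps: int
    m_total: int


def compute_ld_scores(
    ref: GenotypeMatrix, window_snps: int = 200, chunk: int = 2048
) -> LdScores:
    """Bias-adjusted LD scores over an index window.

    ``l_j = sum_k [r2(j,k) - (1 - r2)/(n - 2)]`` for SNPs within
    ``window_snps`` of j (self term included, contributing ~1).
    """
    n, m = ref.n_samples, ref.n_snps
    if n < 50:
        raise ValueError("LD reference panel needs at least 50 samples")
    if window_snps > m:
        warnings.warn("LD window exceeds panel SNP count; truncating")
        window_snps = m
    Z = np.asarray(ref.dosage, dtype=np.float64)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    w = window_snps
    ell = np.zeros(m)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        lo, hi = max(0, start - w), min(m, stop + w)
        R = Z[:, start:stop].T @ Z[:, lo:hi] / n
        r2 = R**2
        adj = r2 - (1.0 - r2) / (n - 2)
        rows = np.arange(start, stop)[:, None]
        cols = np.arange(lo, hi)[None, :]
        adj[np.abs(rows - cols) > w] = 0.0
        ell[start:stop] = adj.sum(axis=1)
    frame = pd.DataFrame({"SNP": ref.snp_ids, "L2": ell})
    return LdScores(frame, window_snps, m)


@dataclass
class LdscFit:
    h2: float
    se_h2: float
    intercept: float
    se_intercept: float
    n_snps: int
    n_blocks: int
    negative_h2: bool

    def h2_ci95(self) -> tuple[float, float]:
        return (self.h2 - 1.96 * self.se_h2, self.h2 + 1.96 * self.se_h2)

    def intercept_ci95(self) -> tuple[float, float]:
        return (
            self.intercept - 1.96 * self.se_intercept,
            self.intercept + 1.96 * self.se_intercept,
        )


def _wls(y, x, w):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(X, sw * y, rcond=None)
    return float(coef[0]), float(coef[1])


class LDScoreRegression(BaseEstimator):
    """LD-score regression of GWAS chi-square on N*l/M.

    The slope estimates SNP heritability; the intercept absorbs confounding
    (1 under the null of no bias).  Weights are iteratively set to
    ``1 / (1 + N h2 l / M)^2`` and standard errors come from a delete-one
    block jackknife over contiguous SNP blocks.
    """

    def __init__(self, n_blocks: int = 200, n_iter: int = 3):
        self.n_blocks = n_blocks
        self.n_iter = n_iter

    def fit(self, sumstats: pd.DataFrame, ld: LdScores, m_total: int | None = None) -> "LDScoreRegression":
        df = sumstats.merge(ld.frame, on="SNP", how="inner")
        if len(df) == 0:
            raise ValueError("no SNPs shared between summary statistics and LD scores")
        M = m_total if m_total is not None else ld.m_total
        chi2 = df["CHISQ"].to_numpy(float)
        N = df["N"].to_numpy(float)
        x = N * df["L2"].to_numpy(float) / M

        w = np.ones_like(x)
        h2 = 0.0
        for _ in range(self.n_iter):
            icpt, h2 = _wls(chi2, x, w)
            w = 1.0 / np.maximum(1.0 + np.maximum(h2, 0.0) * x, 1.0) ** 2
        n_blocks = min(self.n_blocks, len(df))
        if n_blocks < 2:
            raise ValueError("need at least 2 jackknife blocks")
        edges = np.linspace(0, len(df), n_blocks + 1).astype(int)
        slopes, icpts = [], []
        for b in range(n_blocks):
            mask = np.ones(len(df), dtype=bool)
            mask[edges[b]: edges[b + 1]] = False
            ib, sb = _wls(chi2[mask], x[mask], w[mask])
            slopes.append(sb)
            icpts.append(ib)
        slopes, icpts = np.array(slopes), np.array(icpts)
        fac = (n_blocks - 1) / n_blocks
        se_h2 = float(np.sqrt(fac * ((slopes - slopes.mean()) ** 2).sum()))
        se_icpt = float(np.sqrt(fac * ((icpts - icpts.mean()) ** 2).sum()))
        self.fit_ = LdscFit(
            h2=h2, se_h2=se_h2, intercept=icpt, se_intercept=se_icpt,
            n_snps=len(df), n_blocks=n_blocks, negative_h2=bool(h2 < 0),
        )
        self.h2_ = h2
        self.intercept_ = icpt
        return self


def ldsc_regression(
    sumstats: pd.DataFrame, ld: LdScores, m_total: int | None = None,
    n_blocks: int = 200,
) -> LdscFit:
    return LDScoreRegression(n_blocks).fit(sumstats, ld, m_total).fit_


@dataclass
class CrossTraitLdscFit:
    r_g: float
    se_rg: float
    gencov: float
    h2: tuple[float, float]
    n_snps: int


def cross_trait_ldsc(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ld: LdScores,
    m_total: int | None = None,
    n_blocks: int = 200,
) -> CrossTraitLdscFit:
    """Cross-trait LD-score regression: genetic covariance and correlation.

    Regresses ``z1 * z2`` on ``sqrt(N1 N2) l / M`` (slope = genetic
    covariance) and normalizes by the two slope heritabilities; the jackknife
    recomputes all three regressions per deleted block so the SE reflects
    their joint sampling error.
    """
    M = m_total if m_total is not None else ld.m_total
    df = (
        ss1.merge(ss2, on="SNP", suffixes=("_1", "_2"))
        .merge(ld.frame, on="SNP", how="inner")
        .reset_index(drop=True)
    )
    if len(df) == 0:
        raise ValueError("no shared SNPs")
    if not (df["A1_1"] == df["A1_2"]).all():
        raise ValueError("alleles not aligned between the two summary-statistic sets")
    z1, z2 = df["Z_1"].to_numpy(float), df["Z_2"].to_numpy(float)
    n1, n2 = df["N_1"].to_numpy(float), df["N_2"].to_numpy(float)
    ell = df["L2"].to_numpy(float)
    x_cov = np.sqrt(n1 * n2) * ell / M
    x1, x2 = n1 * ell / M, n2 * ell / M

    def estimates(mask):
        w = np.ones(int(mask.sum()))
        _, h1 = _wls(z1[mask] ** 2, x1[mask], w)
        _, h2_ = _wls(z2[mask] ** 2, x2[mask], w)
        for _ in range(2):
            w1 = 1.0 / np.maximum(1.0 + np.maximum(h1, 0) * x1[mask], 1.0) ** 2
            w2 = 1.0 / np.maximum(1.0 + np.maximum(h2_, 0) * x2[mask], 1.0) ** 2
            _, h1 = _wls(z1[mask] ** 2, x1[mask], w1)
            _, h2_ = _wls(z2[mask] ** 2, x2[mask], w2)
        wc = np.sqrt(w1 * w2)
        _, gcov = _wls((z1 * z2)[mask], x_cov[mask], wc)
        return h1, h2_, gcov

    full = np.ones(len(df), dtype=bool)
    h1, h2_, gcov = estimates(full)
    if h1 <= 0 or h2_ <= 0:
        raise ValueError("cross-trait genetic correlation unestimable: h2 <= 0")
    rg = gcov / np.sqrt(h1 * h2_)

    n_blocks = min(n_blocks, len(df))
    edges = np.linspace(0, len(df), n_blocks + 1).astype(int)
    rgs = []
    for b in range(n_blocks):
        mask = np.ones(len(df), dtype=bool)
        mask[edges[b]: edges[b + 1]] = False
        try:
            a, bb, g = estimates(mask)
            rgs.append(g / np.sqrt(max(a, 1e-12) * max(bb, 1e-12)))
        except np.linalg.LinAlgError:
            continue
    rgs = np.array(rgs)
    fac = (len(rgs) - 1) / len(rgs)
    se = float(np.sqrt(fac * ((rgs - rgs.mean()) ** 2).sum()))
    return CrossTraitLdscFit(float(rg), se, float(gcov), (h1, h2_), len(df))
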