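"""Dimensionality of the indicator correlation structure.

Assembles 4x4 phenotypic and component-wise (A/C/E) correlation matrices
across the socioeconomic indicators from pairwise bivariate fits, projects
them to the nearest positive semi-definite correlation matrix when the
pairwise estimates are incoherent, and analyzes their dimensionality with
PCA, Horn's parallel analysis (95th-percentile rule), a permutation test of
axis significance, and bootstrap confidence intervals (parametric
multivariate-normal by default, observation resampling when raw data are
available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_INDICATORS = ("education", "occupation", "income", "wealth")


@dataclass
class ComponentCorrMatrix:
    """Correlation matrix among indicators for one variance source."""

    source: str  # phenotypic | A | C | E
    method: str  # e.g. family_pedigree, ibd, greml, ldsc
    values: np.ndarray
    se: np.ndarray | None = None
    n_effective: int | None = None
    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    psd_adjustment: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.indicators)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match indicator count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.indicators, columns=self.indicators)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    explained: np.ndarray  # fractions, sum to 1
    loadings: np.ndarray  # columns = components, sign-fixed
    n_retained: int | None = None
    ci: dict[str, np.ndarray] = field(default_factory=dict)


def nearest_psd_correlation(mat: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Project to the nearest PSD matrix (eigenvalue clipping) and rescale
    the diagonal back to 1.  Returns (projected, max absolute entry change)."""
    m = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= -tol:
        return m, 0.0
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, float(np.abs(out - m).max())


def assemble_matrix(
    pair_values: dict[tuple[str, str], float],
    source: str,
    method: str,
    indicators: tuple[str, ...] = DEFAULT_INDICATORS,
    se_values: dict[tuple[str, str], float] | None = None,
    n_effective: int | None = None,
) -> ComponentCorrMatrix:
    """Fill a symmetric indicator correlation matrix from pairwise estimates.

    ``pair_values`` maps unordered indicator pairs to correlations (all
    ``k*(k-1)/2`` pairs must be present and estimable).  If the assembled
    matrix is not PSD — pairwise bivariate fits need not cohere — it is
    projected and the maximum entry change recorded as ``psd_adjustment``.
    """
    k = len(indicators)
    vals = np.eye(k)
    ses = np.zeros((k, k))
    lookup = {}
    for (a, b), v in pair_values.items():
        lookup[(a, b)] = v
        lookup[(b, a)] = v
    for i in range(k):
        for j in range(i + 1, k):
            key = (indicators[i], indicators[j])
            if key not in lookup:
                raise ValueError(f"missing indicator pair {key}")
            v = lookup[key]
            if v is None or not np.isfinite(v):
                raise ValueError(f"unestimable correlation for pair {key}")
            vals[i, j] = vals[j, i] = v
            if se_values is not None:
                s = se_values.get(key, se_values.get((key[1], key[0]), np.nan))
                ses[i, j] = ses[j, i] = s
    projected, change = nearest_psd_correlation(vals)
    return ComponentCorrMatrix(
        source=source,
        method=method,
        values=projected,
        se=ses if se_values is not None else None,
        n_effective=n_effective,
        indicators=indicators,
        psd_adjustment=change,
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca(mat: ComponentCorrMatrix | np.ndarray) -> PcaResult:
    """Eigendecomposition of a correlation matrix.

    Explained fractions are ``lambda_i / sum(lambda)``; loading signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    values = mat.values if isinstance(mat, ComponentCorrMatrix) else np.asarray(mat, float)
    w, v = np.linalg.eigh((values + values.T) / 2.0)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = _fix_signs(v[:, order])
    return PcaResult(eigenvalues=w, explained=w / w.sum(), loadings=v)


def parallel_analysis(
    data: np.ndarray | None = None,
    corr: np.ndarray | None = None,
    n_obs: int | None = None,
    n_sims: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> dict:
    """Horn's parallel analysis with the 95th-percentile retention rule.

    Retains components whose observed correlation-matrix eigenvalue exceeds
    the chosen quantile of eigenvalues from uncorrelated standard-normal data
    of the same shape.  Supply raw ``data`` (n x p) or a correlation matrix
    plus ``n_obs``.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for stable quantiles")
    if data is not None:
        data = np.asarray(data, float)
        n, p = data.shape
        observed = np.linalg.eigvalsh(np.corrcoef(data, rowvar=False))[::-1]
    else:
        if corr is None or n_obs is None:
            raise ValueError("need raw data, or a correlation matrix with n_obs")
        observed = np.linalg.eigvalsh(np.asarray(corr, float))[::-1]
        n, p = int(n_obs), np.asarray(corr).shape[0]
    if n <= p:
        raise ValueError("parallel analysis needs more observations than variables")
    rng = np.random.default_rng(seed)
    null = np.empty((n_sims, p))
    for s in range(n_sims):
        sim = rng.standard_normal((n, p))
        null[s] = np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    exceeds = observed > thresh
    # retention stops at the first non-exceeding component
    n_retained = int(np.argmin(exceeds)) if not exceeds.all() else p
    return {
        "observed": observed,
        "threshold": thresh,
        "n_retained": n_retained,
        "quantile": quantile,
    }


def pca_permutation_test(
    data: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Permutation test of PCA axis and loading significance.

    The null distribution is built by independently permuting each variable's
    values, which destroys all correlation while preserving marginals.  An
    axis is significant when its observed explained-variance fraction exceeds
    the (1 - alpha) null quantile; a variable contributes significantly to a
    significant axis when its squared loading exceeds the null quantile.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    data = np.asarray(data, float)
    n, p = data.shape
    rng = np.random.default_rng(seed)

    def contributions(r):
        # squared structure coefficients: (loading^2 * eigenvalue) is each
        # variable's squared correlation with the component score
        return r.loadings**2 * r.eigenvalues[None, :]

    res = pca(np.corrcoef(data, rowvar=False))
    obs_expl = res.explained
    obs_contrib = contributions(res)
    null_expl = np.empty((n_perm, p))
    null_contrib = np.empty((n_perm, p, p))
    for s in range(n_perm):
        perm = np.column_stack([rng.permutation(data[:, j]) for j in range(p)])
        r = pca(np.corrcoef(perm, rowvar=False))
        null_expl[s] = r.explained
        null_contrib[s] = contributions(r)
    expl_thresh = np.quantile(null_expl, 1 - alpha, axis=0)
    # sequential rule: an axis can only be significant if all larger axes are
    exceeds = obs_expl > expl_thresh
    axis_sig = np.logical_and.accumulate(exceeds)
    contrib_thresh = np.quantile(null_contrib, 1 - alpha, axis=0)
    load_sig = (obs_contrib > contrib_thresh) & axis_sig[None, :]
    return {
        "explained": obs_expl,
        "explained_threshold": expl_thresh,
        "axis_significant": axis_sig,
        "loading_significant": load_sig,
        "n_perm": n_perm,
    }


def bootstrap_component_pca(
    mat: ComponentCorrMatrix | np.ndarray,
    n: int | None = None,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    data: np.ndarray | None = None,
) -> PcaResult:
    """Bootstrap CIs for PCA explained variance and loadings.

    Default mode is a parametric bootstrap: draw ``n`` observations from a
    zero-mean multivariate normal with the estimated correlation, recompute
    the PCA per replicate, and take percentile intervals.  When raw ``data``
    are supplied, observations are resampled instead.
    """
    rng = np.random.default_rng(seed)
    if data is not None:
        data = np.asarray(data, float)
        n_obs, p = data.shape
        point = pca(np.corrcoef(data, rowvar=False))
    else:
        values = mat.values if isinstance(mat, ComponentCorrMatrix) else np.asarray(mat, float)
        if n is None and isinstance(mat, ComponentCorrMatrix):
            n = mat.n_effective
        if n is None:
            raise ValueError("parametric bootstrap needs the effective sample size n")
        values, _ = nearest_psd_correlation(values)
        p = values.shape[0]
        w, v = np.linalg.eigh(values)
        L = v * np.sqrt(np.clip(w, 0.0, None))
        point = pca(values)
    expl = np.empty((n_boot, p))
    load = np.empty((n_boot, p, p))
    for b in range(n_boot):
        if data is not None:
            sample = data[rng.integers(0, n_obs, n_obs)]
        else:
            sample = rng.standard_normal((n, p)) @ L.T
        r = pca(np.corrcoef(sample, rowvar=False))
        expl[b] = r.explained
        load[b] = r.loadings
    lo, hi = alpha / 2, 1 - alpha / 2
    point.ci = {
        "explained_lo": np.quantile(expl, lo, axis=0),
        "explained_hi": np.quantile(expl, hi, axis=0),
        "loadings_lo": np.quantile(load, lo, axis=0),
        "loadings_hi": np.quantile(load, hi, axis=0),
    }
    return point
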