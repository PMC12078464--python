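"""Maximum-likelihood ACE/AE variance components on relative pairs.

The family designs model each relative pair's trait values as bivariate
normal with common variance ``v = s_a + s_c + s_e`` and cross-member
covariance ``s_a * r_g + s_c * r_c``, where ``r_g`` is the genetic
correlation of the pair (pedigree expectation, or empirical genome sharing in
the IBD design) and ``r_c`` the shared-environment correlation (1 for
siblings and twins; fixed or free for first cousins).  Standardized variance
fractions ``a^2 = s_a / v`` etc. are reported, with ``h^2 = a^2``.

Pairs are treated as independent in the likelihood (a pseudo-likelihood,
since one person can appear in several pairs of an extended family);
family-clustered sandwich standard errors are available as an option.

Numerically, every pair covariance here has the exchangeable form
``[[S, B], [B, S]]`` (scalars for univariate fits, 2x2 trait blocks for
bivariate fits).  The orthogonal sum/difference transform
``u = (x1 + x2)/sqrt(2)``, ``w = (x1 - x2)/sqrt(2)`` block-diagonalizes it to
``S + B`` and ``S - B``, so the log-likelihood vectorizes over pairs even
when ``r_g`` differs per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .pedigree import REL_COUSIN

_LOG2PI = np.log(2.0 * np.pi)
_BOUND_EPS = 1e-6


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class VarCompFit:
    """Univariate ACE/AE fit on standardized-scale variance fractions."""

    a2: float
    c2: float
    e2: float
    rho_c: float | None
    se: dict[str, float]
    loglik: float
    n_pairs: dict[str, int]
    total_var: float
    mu: float
    beta: dict[str, float]
    components: str
    boundary: bool
    converged: bool

    @property
    def h2(self) -> float:
        return self.a2

    def ci95(self, name: str) -> tuple[float, float]:
        est = {"a2": self.a2, "c2": self.c2, "e2": self.e2, "rho_c": self.rho_c}[name]
        s = self.se.get(name, np.nan)
        return (max(est - 1.96 * s, 0.0), min(est + 1.96 * s, 1.0))


@dataclass
class BivariateFit:
    """Bivariate fit: per-trait fractions plus A/C/E cross-trait correlations."""

    a2: tuple[float, float]
    c2: tuple[float, float]
    e2: tuple[float, float]
    r_A: float
    r_C: float | None
    r_E: float
    r_phenotypic: float
    se: dict[str, float]
    loglik: float
    n_pairs: dict[str, int]
    components: str
    unestimable: list[str] = field(default_factory=list)
    boundary: bool = False
    converged: bool = True


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------


def build_pair_table(
    pairs: pd.DataFrame,
    pheno: pd.DataFrame,
    traits: str | tuple[str, str],
    covariates: tuple[str, ...] = ("sex",),
    r_g_column: str | None = None,
) -> pd.DataFrame:
    """Join a relative-pair list to per-individual phenotypes.

    ``traits`` is one trait name (univariate) or a pair (bivariate).  The
    result has columns ``y1_<trait>``/``y2_<trait>`` per trait plus
    ``<cov>1``/``<cov>2`` per covariate, carrying over ``relationship`` and
    ``r_g`` (replaced by ``r_g_column``, e.g. ``"r_hat"``, when given).
    """
    if isinstance(traits, str):
        traits = (traits,)
    ph = pheno.set_index("iid")
    out = pairs.copy()
    for suffix, col in (("1", "id1"), ("2", "id2")):
        members = ph.loc[out[col]]
        for t in traits:
            out[f"y{suffix}_{t}"] = members[t].to_numpy()
        for c in covariates:
            out[f"{c}{suffix}"] = members[c].to_numpy()
    if r_g_column is not None:
        out["r_g"] = out[r_g_column].to_numpy()
    if "family" in pheno.columns:
        out["family"] = ph.loc[out["id1"], "family"].to_numpy()
    return out.dropna(subset=[f"y{s}_{t}" for s in "12" for t in traits]).reset_index(
        drop=True
    )


def _design(pair_df: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Per-member covariate design matrices (n, k)."""
    if not covariates:
        z = np.zeros((len(pair_df), 0))
        return z, z
    x1 = np.column_stack([pair_df[f"{c}1"].to_numpy(float) for c in covariates])
    x2 = np.column_stack([pair_df[f"{c}2"].to_numpy(float) for c in covariates])
    # center so the intercept stays interpretable as the overall mean
    center = np.concatenate([x1, x2]).mean(axis=0)
    return x1 - center, x2 - center


def _numeric_hessian(f, p: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = len(p)
    h = rel_step * np.maximum(1.0, np.abs(p))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(p + ei + ej) - f(p + ei - ej) - f(p - ei + ej) + f(p - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _safe_cov(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _fraction_jacobian(s: np.ndarray) -> np.ndarray:
    """d(s_i / v)/d(s_j) for v = sum(s)."""
    v = s.sum()
    k = len(s)
    J = -np.outer(s, np.ones(k)) / v**2
    J[np.diag_indices(k)] += 1.0 / v
    return J


# ---------------------------------------------------------------------------
# univariate ACE / AE
# ---------------------------------------------------------------------------


class FamilyACE(BaseEstimator):
    """Pairwise maximum-likelihood ACE (or AE) variance-component model.

    Parameters
    ----------
    components:
        ``"ACE"`` or ``"AE"`` (no shared environment).
    rc_cousin:
        Shared-environment correlation assumed between first cousins: a value
        in [0, 1], or ``"free"`` to estimate it.  Ignored for AE.
    rc_sib:
        Shared-environment correlation for siblings and twins (default 1, the
        classical equal-environment assumption).
    covariates:
        Per-member mean covariates (columns ``<name>1``/``<name>2`` of the
        pair table); sex by default.
    robust_se:
        ``None`` for observed-information SEs, ``"family"`` for a
        family-clustered sandwich (requires a ``family`` column).

    Attributes (after ``fit``)
    --------------------------
    a2_, c2_, e2_, rho_c_, se_, loglik_, fit_ (full :class:`VarCompFit`).
    """

    def __init__(
        self,
        components: str = "ACE",
        rc_cousin: float | str = 0.0,
        rc_sib: float = 1.0,
        covariates: tuple[str, ...] = ("sex",),
        robust_se: str | None = None,
    ):
        self.components = components
        self.rc_cousin = rc_cousin
        self.rc_sib = rc_sib
        self.covariates = covariates
        self.robust_se = robust_se

    # -- internals ---------------------------------------------------------

    def _check_identifiable(self, pair_df: pd.DataFrame, free_rho: bool) -> None:
        rg = pair_df["r_g"].round(12)
        rc = np.where(pair_df["relationship"] == REL_COUSIN, -1.0, self.rc_sib)
        classes = set(zip(rg, rc))
        if self.components == "AE":
            if rg.nunique() < 2:
                raise ValueError(
                    "AE model needs at least two distinct genetic correlations"
                )
            return
        needed = 3 if free_rho else 2
        if len(classes) < needed:
            raise ValueError(
                f"ACE model with {'free' if free_rho else 'fixed'} cousin r_c needs "
                f">= {needed} distinct (r_g, r_c) classes, got {len(classes)}"
            )

    def fit(self, pair_df: pd.DataFrame, trait: str | None = None) -> "FamilyACE":
        if trait is None:
            ycols = [c for c in pair_df.columns if c.startswith("y1_")]
            if len(ycols) != 1:
                raise ValueError("trait must be given when the table has several traits")
            trait = ycols[0][3:]
        if self.components not in ("ACE", "AE"):
            raise ValueError("components must be 'ACE' or 'AE'")
        free_rho = self.components == "ACE" and self.rc_cousin == "free"
        if self.components == "AE" and isinstance(self.rc_cousin, str):
            raise ValueError("AE model has no cousin shared-environment parameter")
        self._check_identifiable(pair_df, free_rho)

        y1 = pair_df[f"y1_{trait}"].to_numpy(float)
        y2 = pair_df[f"y2_{trait}"].to_numpy(float)
        rg = pair_df["r_g"].to_numpy(float)
        is_cousin = (pair_df["relationship"] == REL_COUSIN).to_numpy()
        x1, x2 = _design(pair_df, tuple(self.covariates))
        k_cov = x1.shape[1]
        has_c = self.components == "ACE"

        v0 = np.concatenate([y1, y2]).var()
        start = [0.3 * v0] + ([0.2 * v0] if has_c else []) + [0.5 * v0]
        bounds = [(0.0, None)] * len(start)
        if free_rho:
            start.append(0.5)
            bounds.append((0.0, 1.0))
        start += [np.concatenate([y1, y2]).mean()] + [0.0] * k_cov
        bounds += [(None, None)] * (1 + k_cov)
        start = np.array(start)

        def unpack(p):
            i = 0
            s_a = p[i]; i += 1
            s_c = p[i] if has_c else 0.0
            i += int(has_c)
            s_e = p[i]; i += 1
            rho = p[i] if free_rho else (self.rc_cousin if has_c else 0.0)
            i += int(free_rho)
            mu = p[i]; i += 1
            beta = p[i:]
            return s_a, s_c, s_e, float(rho), mu, beta

        def per_pair_nll(p):
            s_a, s_c, s_e, rho, mu, beta = unpack(p)
            # finite-difference probes can step outside the bounds
            if min(s_a, s_c, s_e) < 0 or not 0.0 <= rho <= 1.0:
                return np.full(y1.shape, 1e8)
            rc = np.where(is_cousin, rho, self.rc_sib) if has_c else 0.0
            v = s_a + s_c + s_e
            c = s_a * rg + (s_c * rc if has_c else 0.0)
            lam_p = v + c
            lam_m = v - c
            if np.any(lam_p <= 0) or np.any(lam_m <= 0):
                return np.full(y1.shape, 1e8)
            e1 = y1 - mu - x1 @ beta
            e2 = y2 - mu - x2 @ beta
            u = (e1 + e2) ** 2 / 2.0
            w = (e1 - e2) ** 2 / 2.0
            return 0.5 * (
                2.0 * _LOG2PI + np.log(lam_p) + np.log(lam_m) + u / lam_p + w / lam_m
            )

        def nll(p):
            return float(per_pair_nll(p).sum())

        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500})
        if not res.success:  # one restart from a different corner
            alt = start.copy()
            alt[0] = 0.6 * v0
            res2 = minimize(nll, alt, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 1000})
            if res2.fun < res.fun:
                res = res2
        p = res.x
        s_a, s_c, s_e, rho, mu, beta = unpack(p)
        v = s_a + s_c + s_e

        n_var = 2 + int(has_c)
        boundary = bool(
            min(s_a, s_e, *( [s_c] if has_c else [] )) < _BOUND_EPS * v
            or (free_rho and (rho < _BOUND_EPS or rho > 1 - _BOUND_EPS))
        )

        H = _numeric_hessian(nll, p)
        cov = _safe_cov(H)
        if self.robust_se == "family":
            if "family" not in pair_df.columns:
                raise ValueError("family-clustered SEs need a 'family' column")
            cov = self._sandwich(per_pair_nll, p, cov, pair_df["family"].to_numpy())

        s_vec = np.array([s_a, s_c, s_e]) if has_c else np.array([s_a, s_e])
        Jfrac = _fraction_jacobian(s_vec)
        J = np.zeros((len(s_vec), len(p)))
        J[:, :n_var] = Jfrac
        frac_cov = J @ cov @ J.T
        frac_se = np.sqrt(np.clip(np.diag(frac_cov), 0.0, None))

        names = ["a2", "c2", "e2"] if has_c else ["a2", "e2"]
        se = dict(zip(names, frac_se))
        if not has_c:
            se["c2"] = 0.0
        if free_rho:
            se["rho_c"] = float(np.sqrt(max(cov[n_var, n_var], 0.0)))

        counts = pair_df["relationship"].value_counts().to_dict()
        self.fit_ = VarCompFit(
            a2=s_a / v,
            c2=(s_c / v) if has_c else 0.0,
            e2=s_e / v,
            rho_c=(rho if has_c else None) if (free_rho or has_c) else None,
            se=se,
            loglik=-res.fun,
            n_pairs={str(k): int(c) for k, c in counts.items()},
            total_var=v,
            mu=mu,
            beta=dict(zip(self.covariates, beta)),
            components=self.components,
            boundary=boundary,
            converged=bool(res.success),
        )
        self.a2_, self.c2_, self.e2_ = self.fit_.a2, self.fit_.c2, self.fit_.e2
        self.rho_c_ = self.fit_.rho_c
        self.se_ = se
        self.loglik_ = self.fit_.loglik
        return self

    @staticmethod
    def _sandwich(per_pair_nll, p, bread, families):
        k = len(p)
        h = 1e-5 * np.maximum(1.0, np.abs(p))
        scores = np.zeros((len(families), k))
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            scores[:, i] = (per_pair_nll(p + e) - per_pair_nll(p - e)) / (2 * h[i])
        fam = pd.Series(range(len(families))).groupby(pd.Series(families)).indices
        meat = np.zeros((k, k))
        for idx in fam.values():
            s = scores[list(idx)].sum(axis=0)
            meat += np.outer(s, s)
        return bread @ meat @ bread


class IBDAE(BaseEstimator):
    """AE model on sibling pairs with per-pair empirical genome sharing.

    Each pair's cross-member covariance is ``s_a * r_hat`` where ``r_hat`` is
    its estimated identity-by-descent proportion, so heritability is
    identified by the *variation* in realized sharing around 0.5.
    """

    def __init__(self, covariates: tuple[str, ...] = ("sex",)):
        self.covariates = covariates

    def fit(self, pair_df: pd.DataFrame, trait: str | None = None) -> "IBDAE":
        if trait is None:
            ycols = [c for c in pair_df.columns if c.startswith("y1_")]
            if len(ycols) != 1:
                raise ValueError("trait must be given when the table has several traits")
            trait = ycols[0][3:]
        df = pair_df.dropna(subset=["r_g"]).reset_index(drop=True)
        r = df["r_g"].to_numpy(float)
        if len(df) < 2 or float(np.var(r)) < 1e-8:
            raise ValueError("IBD variance zero: genome sharing does not vary across pairs")
        y1 = df[f"y1_{trait}"].to_numpy(float)
        y2 = df[f"y2_{trait}"].to_numpy(float)
        x1, x2 = _design(df, tuple(self.covariates))
        k_cov = x1.shape[1]
        v0 = np.concatenate([y1, y2]).var()
        start = np.array([0.3 * v0, 0.7 * v0, np.concatenate([y1, y2]).mean()] + [0.0] * k_cov)
        bounds = [(0.0, None), (1e-10, None), (None, None)] + [(None, None)] * k_cov

        def nll(p):
            s_a, s_e, mu = p[0], p[1], p[2]
            if s_a < 0 or s_e <= 0:
                return 1e12
            beta = p[3:]
            v = s_a + s_e
            c = s_a * r
            lam_p, lam_m = v + c, v - c
            if np.any(lam_p <= 0) or np.any(lam_m <= 0):
                return 1e12
            e1 = y1 - mu - x1 @ beta
            e2 = y2 - mu - x2 @ beta
            u = (e1 + e2) ** 2 / 2.0
            w = (e1 - e2) ** 2 / 2.0
            return float(
                0.5
                * (
                    2.0 * _LOG2PI * len(r)
                    + np.log(lam_p).sum()
                    + np.log(lam_m).sum()
                    + (u / lam_p).sum()
                    + (w / lam_m).sum()
                )
            )

        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500})
        p = res.x
        s_a, s_e = p[0], p[1]
        v = s_a + s_e
        H = _numeric_hessian(nll, p)
        cov = _safe_cov(H)
        J = np.zeros((2, len(p)))
        J[:, :2] = _fraction_jacobian(np.array([s_a, s_e]))
        frac_se = np.sqrt(np.clip(np.diag(J @ cov @ J.T), 0.0, None))
        self.fit_ = VarCompFit(
            a2=s_a / v,
            c2=0.0,
            e2=s_e / v,
            rho_c=None,
            se={"a2": frac_se[0], "e2": frac_se[1], "c2": 0.0},
            loglik=-res.fun,
            n_pairs={"sib_ibd": len(df)},
            total_var=v,
            mu=p[2],
            beta=dict(zip(self.covariates, p[3:])),
            components="AE",
            boundary=bool(min(s_a, s_e) < _BOUND_EPS * v),
            converged=bool(res.success),
        )
        self.a2_, self.e2_ = self.fit_.a2, self.fit_.e2
        self.se_ = self.fit_.se
        self.loglik_ = self.fit_.loglik
        return self


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------


class BivariateACE(BaseEstimator):
    """Bivariate ACE/AE pair model with direct component-correlation parameters.

    The model is parameterized so the cross-trait correlations of the A, C
    and E sources (``r_A``, ``r_C``, ``r_E``) are first-class parameters with
    delta-method (here: observed-information) standard errors.  Per pair the
    4-variate covariance over (X1, Y1, X2, Y2) has within-person block ``S``
    and cross-member block ``B(r_g, r_c)``; the sum/difference transform
    reduces it to two 2x2 blocks ``S + B`` and ``S - B``.
    """

    def __init__(
        self,
        components: str = "ACE",
        rc_cousin: float = 0.0,
        rc_sib: float = 1.0,
        covariates: tuple[str, ...] = ("sex",),
    ):
        self.components = components
        self.rc_cousin = rc_cousin
        self.rc_sib = rc_sib
        self.covariates = covariates

    def fit(self, pair_df: pd.DataFrame, traits: tuple[str, str]) -> "BivariateACE":
        tx, ty = traits
        if self.components not in ("ACE", "AE"):
            raise ValueError("components must be 'ACE' or 'AE'")
        has_c = self.components == "ACE"
        df = pair_df.dropna(subset=["r_g"]).reset_index(drop=True)
        y = {
            (1, "x"): df[f"y1_{tx}"].to_numpy(float),
            (1, "y"): df[f"y1_{ty}"].to_numpy(float),
            (2, "x"): df[f"y2_{tx}"].to_numpy(float),
            (2, "y"): df[f"y2_{ty}"].to_numpy(float),
        }
        rg = df["r_g"].to_numpy(float)
        rc = (
            np.where(df["relationship"] == REL_COUSIN, self.rc_cousin, self.rc_sib)
            if has_c
            else np.zeros(len(df))
        )
        x1, x2 = _design(df, tuple(self.covariates))
        k_cov = x1.shape[1]
        n = len(df)

        vx = np.concatenate([y[1, "x"], y[2, "x"]]).var()
        vy = np.concatenate([y[1, "y"], y[2, "y"]]).var()
        mx = np.concatenate([y[1, "x"], y[2, "x"]]).mean()
        my = np.concatenate([y[1, "y"], y[2, "y"]]).mean()

        # parameters: variances per trait (A[,C],E), correlations rA[,rC],rE,
        # means and covariate effects per trait
        start, bounds, names = [], [], []
        for tname, v0 in (("x", vx), ("y", vy)):
            comps = ("a", "c", "e") if has_c else ("a", "e")
            share = {"a": 0.3, "c": 0.2, "e": 0.5} if has_c else {"a": 0.4, "e": 0.6}
            for cname in comps:
                names.append(f"s_{cname}{tname}")
                start.append(share[cname] * v0)
                bounds.append((0.0, None))
        corr_names = ["r_A", "r_C", "r_E"] if has_c else ["r_A", "r_E"]
        # start component correlations at the empirical within-person
        # cross-trait correlation (clipped off the singular boundary)
        r0 = float(np.clip(
            np.corrcoef(
                np.concatenate([y[1, "x"], y[2, "x"]]),
                np.concatenate([y[1, "y"], y[2, "y"]]),
            )[0, 1],
            -0.99, 0.99,
        ))
        for cn in corr_names:
            names.append(cn)
            start.append(r0)
            bounds.append((-0.9999, 0.9999))
        names += ["mu_x", "mu_y"]
        start += [mx, my]
        bounds += [(None, None)] * 2
        for tname in ("x", "y"):
            for c in self.covariates:
                names.append(f"b_{c}_{tname}")
                start.append(0.0)
                bounds.append((None, None))
        start = np.array(start)
        pos = {nm: i for i, nm in enumerate(names)}

        def blocks(p):
            g = lambda nm: p[pos[nm]]
            for nm in names:
                if nm.startswith("s_") and p[pos[nm]] < 0:
                    return None
                if nm.startswith("r_") and abs(p[pos[nm]]) > 1:
                    return None
            sax, sex_ = g("s_ax"), g("s_ex")
            say, sey = g("s_ay"), g("s_ey")
            scx = g("s_cx") if has_c else 0.0
            scy = g("s_cy") if has_c else 0.0
            rA, rE = g("r_A"), g("r_E")
            rC = g("r_C") if has_c else 0.0
            gA = rA * np.sqrt(sax * say)
            gC = rC * np.sqrt(scx * scy)
            gE = rE * np.sqrt(sex_ * sey)
            S = np.array(
                [[sax + scx + sex_, gA + gC + gE], [gA + gC + gE, say + scy + sey]]
            )
            # cross-member block depends on the pair's (r_g, r_c)
            b11 = sax * rg + scx * rc
            b22 = say * rg + scy * rc
            b12 = gA * rg + gC * rc
            return S, b11, b12, b22

        def nll(p):
            blk = blocks(p)
            if blk is None:
                return 1e12
            S, b11, b12, b22 = blk
            bx = p[len(names) - 2 * k_cov: len(names) - k_cov]
            by = p[len(names) - k_cov:]
            e1x = y[1, "x"] - p[pos["mu_x"]] - x1 @ bx
            e2x = y[2, "x"] - p[pos["mu_x"]] - x2 @ bx
            e1y = y[1, "y"] - p[pos["mu_y"]] - x1 @ by
            e2y = y[2, "y"] - p[pos["mu_y"]] - x2 @ by
            ux, uy = (e1x + e2x) / np.sqrt(2), (e1y + e2y) / np.sqrt(2)
            wx, wy = (e1x - e2x) / np.sqrt(2), (e1y - e2y) / np.sqrt(2)
            total = 2.0 * _LOG2PI * n
            for sgn, (zx, zy) in ((1.0, (ux, uy)), (-1.0, (wx, wy))):
                m11 = S[0, 0] + sgn * b11
                m12 = S[0, 1] + sgn * b12
                m22 = S[1, 1] + sgn * b22
                det = m11 * m22 - m12**2
                if np.any(det <= 0) or np.any(m11 <= 0):
                    return 1e12
                quad = (m22 * zx**2 - 2 * m12 * zx * zy + m11 * zy**2) / det
                total += np.log(det).sum() + quad.sum()
            return float(0.5 * total)

        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 2000, "maxfun": 200000})
        p = res.x
        g = lambda nm: float(p[pos[nm]])

        H = _numeric_hessian(nll, p)
        cov = _safe_cov(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se = {nm: float(se_all[pos[nm]]) for nm in corr_names}

        def fracs(tname):
            comps = ["a", "c", "e"] if has_c else ["a", "e"]
            s = np.array([g(f"s_{c}{tname}") for c in comps])
            v = s.sum()
            idx = [pos[f"s_{c}{tname}"] for c in comps]
            J = np.zeros((len(s), len(p)))
            J[:, idx] = _fraction_jacobian(s)
            fr_se = np.sqrt(np.clip(np.diag(J @ cov @ J.T), 0.0, None))
            fr = dict(zip(comps, s / v))
            for c, sv in zip(comps, fr_se):
                se[f"{c}2_{tname}"] = float(sv)
            return fr, v

        fx, vxx = fracs("x")
        fy, vyy = fracs("y")

        unestimable = []
        for cn, (kx, ky) in (("r_A", ("s_ax", "s_ay")), ("r_C", ("s_cx", "s_cy")),
                             ("r_E", ("s_ex", "s_ey"))):
            if cn not in corr_names:
                continue
            if g(kx) < _BOUND_EPS * vxx or g(ky) < _BOUND_EPS * vyy:
                unestimable.append(cn)
                se[cn] = np.nan

        S, *_ = blocks(p)
        rp = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        counts = df["relationship"].value_counts().to_dict() if "relationship" in df else {}
        boundary = bool(
            any(abs(abs(g(cn)) - 1.0) < 2e-3 for cn in corr_names)
            or any(f < _BOUND_EPS for f in (*fx.values(), *fy.values()))
        )
        self.fit_ = BivariateFit(
            a2=(fx["a"], fy["a"]),
            c2=(fx.get("c", 0.0), fy.get("c", 0.0)),
            e2=(fx["e"], fy["e"]),
            r_A=np.nan if "r_A" in unestimable else g("r_A"),
            r_C=(np.nan if "r_C" in unestimable else g("r_C")) if has_c else None,
            r_E=np.nan if "r_E" in unestimable else g("r_E"),
            r_phenotypic=float(rp),
            se=se,
            loglik=-res.fun,
            n_pairs={str(k): int(c) for k, c in counts.items()},
            components=self.components,
            unestimable=unestimable,
            boundary=boundary,
            converged=bool(res.success),
        )
        self.r_A_, self.r_C_, self.r_E_ = self.fit_.r_A, self.fit_.r_C, self.fit_.r_E
        self.se_ = se
        self.loglik_ = self.fit_.loglik
        return self


# ---------------------------------------------------------------------------
# functional wrappers and closed forms
# ---------------------------------------------------------------------------


def fit_univariate(
    pair_df: pd.DataFrame,
    trait: str | None = None,
    components: str = "ACE",
    rc_cousin: float | str = 0.0,
    covariates: tuple[str, ...] = ("sex",),
    robust_se: str | None = None,
) -> VarCompFit:
    est = FamilyACE(components, rc_cousin, covariates=covariates, robust_se=robust_se)
    return est.fit(pair_df, trait).fit_


def fit_ibd_ae(
    pair_df: pd.DataFrame,
    trait: str | None = None,
    covariates: tuple[str, ...] = ("sex",),
) -> VarCompFit:
    return IBDAE(covariates).fit(pair_df, trait).fit_


def fit_bivariate(
    pair_df: pd.DataFrame,
    traits: tuple[str, str],
    components: str = "ACE",
    rc_cousin: float = 0.0,
    covariates: tuple[str, ...] = ("sex",),
) -> BivariateFit:
    return BivariateACE(components, rc_cousin, covariates=covariates).fit(
        pair_df, traits
    ).fit_


def sensitivity_sweep(
    pair_df: pd.DataFrame,
    trait: str | None = None,
    rc_grid=None,
    covariates: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """One constrained ACE fit per assumed cousin shared-environment correlation.

    The default grid spans [0, 1] in steps of 0.05 (21 fits).  Returns a tidy
    frame with one row per grid point: estimates, SEs and 95% bounds.
    """
    if rc_grid is None:
        rc_grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    rc_grid = np.asarray(list(rc_grid), dtype=float)
    if rc_grid.size == 0:
        raise ValueError("empty sensitivity grid")
    if rc_grid.min() < 0 or rc_grid.max() > 1:
        raise ValueError("sensitivity grid must lie in [0, 1]")
    rows = []
    for val in rc_grid:
        f = fit_univariate(pair_df, trait, "ACE", float(val), covariates)
        row = {"rho_c_assumed": float(val)}
        for comp in ("a2", "c2", "e2"):
            est = getattr(f, comp)
            lo, hi = f.ci95(comp)
            row.update({comp: est, f"se_{comp}": f.se[comp], f"lo95_{comp}": lo,
                        f"hi95_{comp}": hi})
        row["loglik"] = f.loglik
        rows.append(row)
    return pd.DataFrame(rows)


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Classical twin closed form: a2 = 2(r_MZ - r_DZ), c2 = 2 r_DZ - r_MZ."""
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    return a2, c2, 1.0 - a2 - c2


def two_class_moments(r_sib: float, r_cousin: float, rho_c_cousin: float) -> tuple[float, float, float]:
    """Method-of-moments solution of r_s = a2/2 + c2, r_cuz = a2/8 + rho_c c2."""
    # linear system in (a2, c2)
    A = np.array([[0.5, 1.0], [0.125, rho_c_cousin]])
    a2, c2 = np.linalg.solve(A, np.array([r_sib, r_cousin]))
    return float(a2), float(c2), float(1.0 - a2 - c2)
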