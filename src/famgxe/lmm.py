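"""Linear mixed model with a polygenic random effect.

Fits y = X beta + g + e with g ~ N(0, sigma2_a * R) and residuals either
homogeneous or with a separate variance per residual group (here: by
medication status).  Variance components are estimated by REML; fixed
effects by generalized least squares at the optimum, with covariance
(X' V^-1 X)^-1.

Because R from disjoint pedigrees is block diagonal, V = sigma2_a R + D is
too, and every REML evaluation factors small per-family blocks instead of
the full matrix.  For per-SNP scans a :class:`GLSContext` freezes the
variance components from a covariates-only fit, whitens the data once, and
reduces each SNP to a small least-squares problem.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import DesignError, FamGxEError
from .relatedness import RelationshipMatrix

_VAR_FLOOR = 1e-10
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    """Additive (polygenic) variance and per-group residual variances, mm Hg^2."""

    sigma2_additive: float
    sigma2_resid: dict[str, float]

    def __post_init__(self):
        if self.sigma2_additive < 0 or any(v < 0 for v in self.sigma2_resid.values()):
            raise FamGxEError("variance components must be >= 0")


@dataclass
class LMMFit:
    beta: pd.Series
    covariance: pd.DataFrame
    vc: VarianceComponents
    loglik_reml: float
    loglik_ml: float
    converged: bool
    reason: str | None
    n_used: int
    iterations: int
    fixed_effect_names: list[str] = field(default_factory=list)

    def wald_block(self, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        b = self.beta[names].to_numpy()
        C = self.covariance.loc[names, names].to_numpy()
        return b, C


@dataclass
class LMMOptions:
    max_iter: int = 200
    tol: float = 1e-6
    restarts: int = 3


def _check_design(X: pd.DataFrame):
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        # name offending columns via pivoted QR
        from scipy.linalg import qr

        _, Rq, piv = qr(Xv, mode="economic", pivoting=True)
        d = np.abs(np.diag(Rq))
        tol = d.max() * max(Xv.shape) * np.finfo(float).eps if d.size else 0.0
        bad = [X.columns[piv[j]] for j in range(len(d)) if d[j] <= tol]
        raise DesignError(f"design matrix rank-deficient; collinear columns: {bad}")
    return Xv


class _BlockProblem:
    """Per-family sufficient statistics for the REML criterion.

    Equal-sized family blocks are stacked so each likelihood evaluation is a
    handful of batched Cholesky/solve calls rather than a Python loop."""

    def __init__(self, y, X, R: RelationshipMatrix, groups):
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = X.shape
        self.rhs = np.column_stack([X, self.y])
        self.groups = R.block_groups
        self.group_labels = list(dict.fromkeys(groups))
        self._glab = np.asarray(groups)

    def _dvec(self, resid: dict[str, float]) -> np.ndarray:
        d = np.empty(self.n)
        for g, s2 in resid.items():
            d[self._glab == g] = s2
        return d

    def criterion(self, sigma2_a, resid):
        """Returns (reml_ll, ml_ll, beta, XtViX_inv) or None if V not PD."""
        dvec = self._dvec(resid)
        logdetV = 0.0
        M = np.zeros((self.p + 1, self.p + 1))
        for idx, Rst in self.groups:
            s = idx.shape[1]
            Vs = sigma2_a * Rst + dvec[idx][:, :, None] * np.eye(s)
            try:
                Ls = np.linalg.cholesky(Vs)
            except np.linalg.LinAlgError:
                return None
            logdetV += 2.0 * np.log(np.einsum("bii->bi", Ls)).sum()
            Rh = self.rhs[idx]
            sol = np.linalg.solve(Vs, Rh)
            M += np.einsum("bsp,bsq->pq", Rh, sol)
        XtViX, XtViy, ytViy = M[: self.p, : self.p], M[: self.p, self.p], M[self.p, self.p]
        try:
            cf = cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return None
        beta = cho_solve(cf, XtViy)
        rss = ytViy - beta @ XtViy
        sign, logdet_xx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        reml = -0.5 * ((self.n - self.p) * _LOG2PI + logdetV + logdet_xx + rss)
        ml = -0.5 * (self.n * _LOG2PI + logdetV + rss)
        cov = cho_solve(cf, np.eye(self.p))
        return reml, ml, beta, cov


def fit_lmm(
    y,
    X: pd.DataFrame,
    R: RelationshipMatrix,
    residual_groups=None,
    options: LMMOptions | None = None,
    fixed_vc: VarianceComponents | None = None,
) -> LMMFit:
    """REML fit of the polygenic mixed model.

    Parameters
    ----------
    y, X
        Outcome and named design matrix, aligned row-wise with ``R``.
    residual_groups
        Per-row labels defining residual-variance groups (None = one group,
        the homogeneous model).
    fixed_vc
        Skip estimation and run GLS at the supplied components.
    """
    options = options or LMMOptions()
    y = np.asarray(y, dtype=float)
    if len(y) != R.n or len(X) != R.n:
        raise FamGxEError("y/X/R dimensions disagree")
    Xv = _check_design(X)
    groups = (
        ["all"] * len(y)
        if residual_groups is None
        else [str(g) for g in np.asarray(residual_groups)]
    )
    prob = _BlockProblem(y, Xv, R, groups)
    names = list(X.columns)

    if fixed_vc is not None:
        resid = {g: fixed_vc.sigma2_resid.get(g, np.nan) for g in prob.group_labels}
        if any(np.isnan(v) for v in resid.values()):
            raise FamGxEError("fixed_vc lacks a residual variance for some group")
        out = prob.criterion(fixed_vc.sigma2_additive, resid)
        if out is None:
            raise FamGxEError("supplied variance components give a singular model")
        reml, ml, beta, cov = out
        return LMMFit(
            pd.Series(beta, index=names),
            pd.DataFrame(cov, index=names, columns=names),
            fixed_vc, reml, ml, True, None, len(y), 0, names,
        )

    vy = float(np.var(y)) or 1.0
    labels = prob.group_labels
    k = 1 + len(labels)  # parameters: log sigma2_a, log sigma2 per group

    def unpack(theta):
        s = np.exp(theta)
        return s[0], dict(zip(labels, s[1:]))

    def nll(theta):
        out = prob.criterion(*unpack(theta))
        return np.inf if out is None else -out[0]

    bounds = [(np.log(_VAR_FLOOR), np.log(1e6 * vy))] * k
    starts = []
    for h in (0.3, 0.05, 0.7)[: max(1, options.restarts)]:
        starts.append(np.log(np.r_[max(h * vy, 1e-6), [max((1 - h) * vy, 1e-6)] * len(labels)]))

    best, best_val, iters = None, np.inf, 0
    for x0 in starts:
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.max_iter, "ftol": options.tol, "gtol": 1e-8},
        )
        iters += res.nit
        if np.isfinite(res.fun) and res.fun < best_val:
            best, best_val = res, res.fun

    if best is None or not np.isfinite(best_val):
        return LMMFit(
            pd.Series(np.nan, index=names),
            pd.DataFrame(np.nan, index=names, columns=names),
            VarianceComponents(0.0, {g: 0.0 for g in labels}),
            -np.inf, -np.inf, False, "optimizer failed", len(y), iters, names,
        )

    sigma2_a, resid = unpack(best.x)
    reml, ml, beta, cov = prob.criterion(sigma2_a, resid)
    vc = VarianceComponents(float(sigma2_a), {g: float(v) for g, v in resid.items()})
    converged = bool(best.success)
    return LMMFit(
        pd.Series(beta, index=names),
        pd.DataFrame(cov, index=names, columns=names),
        vc, float(reml), float(ml), converged,
        None if converged else f"optimizer: {best.message}",
        len(y), iters, names,
    )


def residual_heterogeneity_lrt(fit_hom: LMMFit, fit_het: LMMFit, use: str = "reml") -> dict:
    """Likelihood-ratio test of medication-specific residual variances.

    Both fits must share rows and fixed effects; the heterogeneous model
    (two residual variances) nests the homogeneous one, giving a 1-df
    chi-square test.  REML likelihoods are valid here because the fixed
    effects are identical.
    """
    if fit_hom.fixed_effect_names != fit_het.fixed_effect_names:
        raise FamGxEError("LRT requires identical fixed effects")
    if fit_hom.n_used != fit_het.n_used:
        raise FamGxEError("LRT requires identical data rows")
    if len(fit_het.vc.sigma2_resid) <= len(fit_hom.vc.sigma2_resid):
        raise FamGxEError("heterogeneous model must add residual groups")
    ll = {"reml": (fit_hom.loglik_reml, fit_het.loglik_reml),
          "ml": (fit_hom.loglik_ml, fit_het.loglik_ml)}[use]
    stat = max(0.0, 2.0 * (ll[1] - ll[0]))
    return {"statistic": stat, "df": 1, "p": float(chi2.sf(stat, 1))}


class GLSContext:
    """Frozen-variance-component scan helper.

    Holds the per-block Cholesky factors of V at fixed components so
    whitening (L^-1 applied blockwise) and per-SNP GLS cost almost nothing.
    """

    def __init__(self, R: RelationshipMatrix, vc: VarianceComponents, residual_groups=None):
        groups = (
            ["all"] * R.n if residual_groups is None
            else [str(g) for g in np.asarray(residual_groups)]
        )
        glab = np.asarray(groups)
        dvec = np.empty(R.n)
        for g, s2 in vc.sigma2_resid.items():
            dvec[glab == g] = s2
        self.n = R.n
        self._factors = []
        for idx, Rst in R.block_groups:
            s = idx.shape[1]
            Vs = vc.sigma2_additive * Rst + dvec[idx][:, :, None] * np.eye(s)
            self._factors.append((idx, np.linalg.cholesky(Vs)))
        self.vc = vc

    def whiten(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        squeeze = A.ndim == 1
        if squeeze:
            A = A[:, None]
        out = np.empty_like(A, dtype=float)
        for idx, Ls in self._factors:
            out[idx.ravel()] = np.linalg.solve(Ls, A[idx]).reshape(-1, A.shape[1])
        return out[:, 0] if squeeze else out

    def gls(self, Xw: np.ndarray, yw: np.ndarray, names: list[str]):
        """OLS on whitened data; returns (beta, cov) or None if near-singular."""
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        if np.linalg.cond(XtX) > 1e10:
            return None
        cf = cho_factor(XtX)
        beta = cho_solve(cf, Xty)
        cov = cho_solve(cf, np.eye(len(names)))
        return pd.Series(beta, index=names), pd.DataFrame(cov, index=names, columns=names)
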