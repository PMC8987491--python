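"""Weighted linear mixed models with crossed or nested random intercepts.

Implements the lme4-style model

    y = X beta + sum_k Z_k u_k + eps,
    u_k ~ N(0, sigma_k^2 I),   eps_i ~ N(0, sigma^2 / w_i),

estimated by REML (or ML), with the residual variance profiled out.  The
random part is restricted to independent random intercepts per grouping
factor, which covers nested specifications (nest by combining labels, e.g.
``year`` and ``year:site``) and crossed ones alike.

The marginal covariance is V = sigma^2 * V0(theta) with
V0 = diag(1/w) + sum_k theta_k Z_k Z_k' and theta_k = sigma_k^2 / sigma^2.
All per-iteration work uses the Woodbury identity through the q x q matrix
M = I + S (Z'WZ) S, S = diag(sqrt(theta) expanded per level), so the cost is
O(q^3) per likelihood evaluation regardless of n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats, sparse


class SingularFitWarning(UserWarning):
    """A variance component was estimated at (or collapsed to) zero."""


@dataclass
class RandomTerm:
    """A random-intercept grouping factor: one intercept per level."""

    name: str
    codes: np.ndarray  # int codes in [0, n_levels) per observation
    levels: np.ndarray  # level labels, length n_levels

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomTerm":
        codes, levels = pd.factorize(np.asarray(labels))
        if (codes < 0).any():
            raise ValueError(f"random term {name!r} contains missing labels")
        return cls(name, codes.astype(np.int64), np.asarray(levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class MixedFit:
    """Result of a weighted mixed-model fit."""

    fe_names: list
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float  # residual variance (for unit weights)
    vc: dict  # term name -> variance
    theta: np.ndarray  # variance ratios sigma_k^2 / sigma^2
    loglik: float
    method: str  # "reml" | "ml"
    n_obs: int
    n_fe: int
    converged: bool
    singular: bool
    n_iter: int
    ranef: dict = field(default_factory=dict)  # term name -> pd.Series
    term_levels: dict = field(default_factory=dict)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald confidence intervals, shape (p, 2)."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    @property
    def aic(self) -> float:
        # parameters: fixed effects + variance components + residual variance
        k = self.n_fe + len(self.vc) + 1
        return -2.0 * self.loglik + 2.0 * k

    def fe_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.fe_names,
        )


def _build_z(terms: list[RandomTerm], n: int) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Column-stacked one-hot indicator matrix and per-column term index."""
    blocks = []
    owner = []
    for k, t in enumerate(terms):
        q = t.n_levels
        z = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), t.codes)), shape=(n, q)
        )
        blocks.append(z)
        owner.append(np.full(q, k))
    return sparse.hstack(blocks, format="csr"), np.concatenate(owner)


def fit_mixed(
    y,
    X,
    terms: list[RandomTerm],
    weights=None,
    method: str = "reml",
    fe_names=None,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> MixedFit:
    """Fit a weighted random-intercepts mixed model by REML or ML.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effects design, full column rank.
    terms : random-intercept grouping factors.
    weights : optional (n,) positive case weights; Var(eps_i) = sigma^2 / w_i.
    method : "reml" (default) or "ml".
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    if not terms:
        raise ValueError("at least one random term is required")
    if weights is None:
        w = np.ones(n)
        w_scale = 1.0
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != n:
            raise ValueError("weights length mismatch")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        # normalize to mean 1: the model is invariant to a constant weight
        # factor (absorbed by sigma^2), and a unit mean keeps the optimizer
        # path identical to the unweighted one for constant weights
        w_scale = float(w.mean())
        if np.ptp(w) == 0.0:
            w = np.ones(n)  # exactly constant == unweighted
        else:
            w = w / w_scale
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(p)]

    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")

    Z, owner = _build_z(terms, n)
    K = len(terms)
    q = Z.shape[1]

    # Sufficient cross-products (weights folded in once).
    WZ = Z.multiply(w[:, None]).tocsr()
    A = np.asarray((Z.T @ WZ).todense())  # q x q
    Xy = np.column_stack([X, y])
    ZtWXy = np.asarray(Z.T @ (Xy * w[:, None]))  # q x (p+1)
    XytWXy = Xy.T @ (Xy * w[:, None])  # (p+1) x (p+1)
    sum_log_w = float(np.sum(np.log(w)))

    def profile(theta):
        """GLS pieces for given variance ratios; returns dict."""
        s = np.sqrt(theta[owner])
        M = A * np.outer(s, s)
        M[np.diag_indices_from(M)] += 1.0
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        C = s[:, None] * ZtWXy
        sol = linalg.cho_solve(cf, C, check_finite=False)
        V = XytWXy - C.T @ sol  # [[X'V0i X, X'V0i y], [., y'V0i y]]
        Vxx = V[:p, :p]
        Vxy = V[:p, p]
        Vyy = V[p, p]
        beta = linalg.solve(Vxx, Vxy, assume_a="pos")
        rss = float(Vyy - Vxy @ beta)
        logdet_v0 = 2.0 * float(np.sum(np.log(np.diag(cf[0])))) - sum_log_w
        sign, logdet_vxx = np.linalg.slogdet(Vxx)
        return {
            "beta": beta,
            "rss": max(rss, 0.0),
            "logdet_v0": logdet_v0,
            "logdet_vxx": logdet_vxx,
            "Vxx": Vxx,
            "cf": cf,
            "s": s,
        }

    y_scale = float(np.var(y)) if n > 1 else 1.0

    def neg2_crit(theta):
        pr = profile(theta)
        rss = max(pr["rss"], 1e-300)
        if method == "reml":
            return pr["logdet_v0"] + pr["logdet_vxx"] + (n - p) * np.log(rss)
        return pr["logdet_v0"] + n * np.log(rss)

    # Degenerate (noise-free) data: y lies exactly in the column span of X.
    ols_beta, ols_res, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * X,
                                            np.sqrt(w) * y, rcond=None)
    ols_rss = float(np.sum((y - X @ ols_beta) ** 2 * w))
    degenerate = ols_rss <= 1e-12 * max(y_scale, 1.0) * n

    if degenerate:
        theta_hat = np.zeros(K)
        converged, n_iter = True, 0
    else:
        theta0 = np.full(K, 0.5)
        res = optimize.minimize(
            neg2_crit,
            theta0,
            method="L-BFGS-B",
            bounds=[(0.0, 1e8)] * K,
            options={"maxiter": maxiter, "ftol": tol, "gtol": tol},
        )
        theta_hat = np.maximum(res.x, 0.0)
        converged, n_iter = bool(res.success), int(res.nit)

    pr = profile(theta_hat)
    beta = pr["beta"]
    rss = pr["rss"]
    dof = n - p if method == "reml" else n
    sigma2 = rss / dof if not degenerate else 0.0
    vc = {t.name: float(theta_hat[k] * sigma2) for k, t in enumerate(terms)}
    # residual variance reported on the caller's weight scale
    # (Var(eps_i) = sigma2_reported / weights_i)
    sigma2_reported = sigma2 * w_scale

    singular = degenerate or bool(np.any(theta_hat <= 1e-8))
    if singular and not degenerate:
        warnings.warn(
            "variance component estimated at the zero boundary; "
            "fit is singular",
            SingularFitWarning,
            stacklevel=2,
        )

    # log-likelihood at the optimum
    if degenerate:
        loglik = np.inf
    else:
        if method == "reml":
            loglik = -0.5 * (
                (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                + pr["logdet_v0"]
                + pr["logdet_vxx"]
            )
        else:
            loglik = -0.5 * (
                n * (np.log(2.0 * np.pi * sigma2) + 1.0) + pr["logdet_v0"]
            )

    # covariance of beta and BLUPs (Woodbury reuse)
    sigma2_eff = sigma2 if sigma2 > 0 else 1e-300
    cov_params = sigma2_eff * linalg.inv(pr["Vxx"])

    resid = y - X @ beta
    g = np.asarray(Z.T @ (resid * w)).ravel()  # Z'W r
    s = pr["s"]
    ztv0r = g - A @ (s * linalg.cho_solve(pr["cf"], s * g, check_finite=False))
    u = theta_hat[owner] * ztv0r

    ranef = {}
    term_levels = {}
    off = 0
    for k, t in enumerate(terms):
        ranef[t.name] = pd.Series(u[off : off + t.n_levels], index=t.levels)
        term_levels[t.name] = t.levels
        off += t.n_levels

    return MixedFit(
        fe_names=list(fe_names),
        params=beta,
        cov_params=cov_params,
        sigma2=float(sigma2_reported),
        vc=vc,
        theta=theta_hat,
        loglik=float(loglik),
        method=method,
        n_obs=n,
        n_fe=p,
        converged=converged,
        singular=singular,
        n_iter=n_iter,
        ranef=ranef,
        term_levels=term_levels,
    )
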