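"""Internal logistic and penalized quasi-likelihood (PQL) solvers.

Two mixed logistic models are needed: a sample-level random effect whose
covariance is proportional to a (sparse) kinship matrix, and a per-subject
random intercept for repeated visits.  No installed package fits a logistic
model with an arbitrary kinship covariance, so both are fitted here by PQL:
iterate the working linear mixed model z = eta + (y - mu)/w with marginal
covariance V = W^-1 + sigma2 * K, profiling sigma2 by maximizing the working
REML criterion.  With sigma2 = 0 both reduce exactly to ordinary logistic
maximum likelihood (the IRLS fixed point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit


class ConvergenceError(RuntimeError):
    """Model failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(RuntimeError):
    """(Quasi-)complete separation: the MLE diverges; consider penalization."""


@dataclass
class FitResult:
    beta: np.ndarray
    cov: np.ndarray
    sigma2: float = 0.0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic_ml(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> FitResult:
    """Newton-Raphson logistic MLE with step halving and separation checks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    trace = []
    ll_old = -np.inf
    for it in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}", trace) from exc
        # step halving on the log-likelihood
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            ll = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = cand
        trace.append((it, ll, float(np.abs(step).max())))
        if np.abs(step).max() < tol or abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            ll_old = ll
            break
        ll_old = ll
    else:
        raise ConvergenceError(f"logistic fit did not converge in {max_iter} iterations", trace)

    if np.abs(beta).max() > 30:
        raise SeparationError(
            "separation detected (|coefficient| > 30); consider penalized estimation"
        )
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    return FitResult(beta=beta, cov=np.linalg.inv(H))


# ---------------------------------------------------------------------------
# PQL with dense kinship covariance


def _reml_dense(z, X, Winv, K, sigma2):
    n, p = X.shape
    V = np.diag(Winv) + sigma2 * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vi_z = np.linalg.solve(V, z)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_z)
    resid = z - X @ beta
    quad = float(resid @ np.linalg.solve(V, resid))
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    reml = -0.5 * (logdetV + logdetXtViX + quad)
    return reml, beta, np.linalg.inv(XtViX)


def pql_kinship(
    X: np.ndarray,
    y: np.ndarray,
    K: np.ndarray,
    sigma2: float | None = None,
    max_outer: int = 25,
    tol: float = 1e-6,
) -> FitResult:
    """Logistic PQL with random-effect covariance sigma2 * K (K dense, diag 1).

    ``sigma2=None`` profiles the variance component by working REML;
    a fixed ``sigma2`` (e.g. 0) skips profiling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    start = fit_logistic_ml(X, y)
    beta = start.beta
    b = np.zeros(len(y))
    s2 = 0.1 if sigma2 is None else float(sigma2)
    cov = start.cov
    trace = []
    for it in range(max_outer):
        eta = X @ beta + b
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-8, None)
        z = eta + (y - mu) / w
        Winv = 1.0 / w
        if sigma2 is None:
            res = minimize_scalar(
                lambda ls: -_reml_dense(z, X, Winv, K, np.exp(ls))[0],
                bounds=(np.log(1e-6), np.log(10.0)),
                method="bounded",
                options={"xatol": 1e-3},
            )
            s2 = float(np.exp(res.x))
        _, beta_new, cov = _reml_dense(z, X, Winv, K, s2)
        if beta_new is None:
            raise ConvergenceError("working covariance not positive definite", trace)
        if s2 > 0:
            V = np.diag(Winv) + s2 * K
            b = s2 * (K @ np.linalg.solve(V, z - X @ beta_new))
        else:
            b = np.zeros_like(b)
        delta = float(np.abs(beta_new - beta).max())
        trace.append((it, delta, s2))
        beta = beta_new
        if delta < tol:
            return FitResult(beta=beta, cov=cov, sigma2=s2)
    raise ConvergenceError(f"PQL did not converge in {max_outer} outer iterations", trace)


# ---------------------------------------------------------------------------
# PQL with per-group random intercept (block V_i = W_i^-1 + sigma2 * 1 1')


def _gls_random_intercept(z, X, w, groups, n_groups, sigma2):
    """Working GLS quantities via the Woodbury identity, vectorized by group.

    V^-1 = W - c_g w w' within each group, with c_g = sigma2 / (1 + sigma2 * s_g),
    s_g the group sum of weights.
    """
    s_g = np.bincount(groups, weights=w, minlength=n_groups)
    c_g = sigma2 / (1.0 + sigma2 * s_g)

    wX = X * w[:, None]
    wz = w * z
    Xbar = np.zeros((n_groups, X.shape[1]))
    np.add.at(Xbar, groups, wX)
    zbar = np.bincount(groups, weights=wz, minlength=n_groups)

    XtViX = X.T @ wX - (Xbar * c_g[:, None]).T @ Xbar
    XtViz = X.T @ wz - Xbar.T @ (c_g * zbar)
    ztViz = float(z @ wz - zbar @ (c_g * zbar))
    # log|V| = sum log(1 + sigma2 s_g) - sum log w
    logdetV = float(np.log1p(sigma2 * s_g).sum() - np.log(w).sum())
    return XtViX, XtViz, ztViz, logdetV


def _reml_random_intercept(z, X, w, groups, n_groups, sigma2):
    XtViX, XtViz, ztViz, logdetV = _gls_random_intercept(z, X, w, groups, n_groups, sigma2)
    beta = np.linalg.solve(XtViX, XtViz)
    quad = ztViz - float(beta @ XtViz)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    reml = -0.5 * (logdetV + logdetXtViX + quad)
    return reml, beta, np.linalg.inv(XtViX)


def pql_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    sigma2: float | None = None,
    max_outer: int = 40,
    tol: float = 1e-7,
) -> FitResult:
    """Logistic PQL with a per-group random intercept.

    ``groups`` is an integer array of group codes; ``sigma2=None`` profiles
    the intercept variance by working REML, a fixed value skips profiling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    codes, groups = np.unique(groups, return_inverse=True)
    n_groups = len(codes)

    beta = fit_logistic_ml(X, y).beta
    b_g = np.zeros(n_groups)
    s2 = 0.5 if sigma2 is None else float(sigma2)
    trace = []
    for it in range(max_outer):
        eta = X @ beta + b_g[groups]
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-8, None)
        z = eta + (y - mu) / w
        if sigma2 is None:
            res = minimize_scalar(
                lambda ls: -_reml_random_intercept(z, X, w, groups, n_groups, np.exp(ls))[0],
                bounds=(np.log(1e-8), np.log(50.0)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            s2 = float(np.exp(res.x))
        _, beta_new, cov = _reml_random_intercept(z, X, w, groups, n_groups, s2)
        # BLUP of the random intercepts: b_g = c_g * sum_i w_i (z_i - x_i beta)
        resid = z - X @ beta_new
        s_g = np.bincount(groups, weights=w, minlength=n_groups)
        rbar = np.bincount(groups, weights=w * resid, minlength=n_groups)
        b_g = (s2 / (1.0 + s2 * s_g)) * rbar if s2 > 0 else np.zeros(n_groups)
        delta = float(np.abs(beta_new - beta).max())
        trace.append((it, delta, s2))
        beta = beta_new
        if delta < tol:
            return FitResult(beta=beta, cov=cov, sigma2=s2)
    raise ConvergenceError(f"random-intercept PQL did not converge in {max_outer} iterations", trace)
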