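"""Logistic-regression engines.

Three fitters used by the regression layer:

* :func:`fit_logistic_glmm` - binomial GLMM with a single random intercept,
  maximum likelihood by adaptive Gauss-Hermite quadrature.  With a single
  scalar random effect the marginal likelihood factorises over groups into
  one-dimensional integrals; each is centred at its Laplace mode and scaled
  by the local curvature before quadrature (1 node = the Laplace
  approximation; the default 15 nodes is essentially exact for the cluster
  sizes seen here).
* :func:`fit_logistic_glm` - plain binomial GLM via statsmodels, with
  automatic detection of (quasi-)complete separation and a bias-reduced
  fallback.
* :func:`firth_logit` - Firth's bias-reduced logistic regression (Jeffreys
  penalty), used when separation makes the ML estimates diverge - common in
  pure samples at prevalence extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = ["LogisticFit", "fit_logistic_glmm", "fit_logistic_glm", "firth_logit"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class LogisticFit:
    """Common result container for the three engines."""

    beta: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    converged: bool
    method: str  # 'glm', 'firth' or 'glmm'
    sigma: float = 0.0  # random-intercept SD (glmm only)
    separation: bool = False
    n_obs: int = 0
    n_groups: int = 0

    @property
    def sigma2(self) -> float:
        return self.sigma**2


def _check_design(X: np.ndarray, names: Optional[list[str]] = None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an aliased column via QR pivoting on the diagonal of R
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = int(np.argmin(diag))
        label = names[bad] if names else f"column {bad}"
        raise ValueError(f"rank-deficient design matrix: term {label!r} is aliased")


def _bern_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def fit_logistic_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 15,
    names: Optional[list[str]] = None,
    beta0: Optional[np.ndarray] = None,
    sigma0: float = 0.5,
    maxiter: int = 300,
) -> LogisticFit:
    """ML fit of logit P(y=1) = X beta + u_g, u_g ~ N(0, sigma^2).

    Parameters are (beta, sigma) with sigma bounded below by ~0; standard
    errors come from the numerically differentiated observed information.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    codes, _ = _factorize(groups)
    order = np.argsort(codes, kind="stable")
    y_s, X_s, g_s = y[order], X[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(g_s) > 0])
    G = starts.size
    k = X.shape[1]

    nodes, weights = hermgauss(n_quad)
    logw = np.log(weights)
    sqrt2 = np.sqrt(2.0)

    def _negll(theta: np.ndarray) -> float:
        beta, sigma = theta[:k], theta[k]
        a = X_s @ beta
        # Newton iterations for the per-group posterior mode of z
        z = np.zeros(G)
        for _ in range(40):
            eta = a + sigma * z[g_s]
            p = expit(eta)
            score = sigma * np.add.reduceat(y_s - p, starts) - z
            curv = -(sigma**2) * np.add.reduceat(p * (1.0 - p), starts) - 1.0
            step = score / curv
            z = z - np.clip(step, -4.0, 4.0)
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = a + sigma * z[g_s]
        p = expit(eta)
        curv = -(sigma**2) * np.add.reduceat(p * (1.0 - p), starts) - 1.0
        tau = 1.0 / np.sqrt(-curv)
        # adaptive GH: integrate exp(g(z)) with g = loglik(z) - z^2/2
        M = np.empty((n_quad, G))
        for j in range(n_quad):
            zj = z + sqrt2 * tau * nodes[j]
            etaj = a + sigma * zj[g_s]
            gj = np.add.reduceat(_bern_loglik(etaj, y_s), starts) - 0.5 * zj**2
            M[j] = logw[j] + nodes[j] ** 2 + gj
        ll = np.sum(logsumexp(M, axis=0) + np.log(sqrt2 * tau)) - 0.5 * G * _LOG_2PI
        return -ll

    if beta0 is None:
        glm0 = fit_logistic_glm(y_s, X_s, names=names)
        beta0 = glm0.beta
    x0 = np.r_[beta0, max(sigma0, 1e-3)]
    bounds = [(None, None)] * k + [(1e-8, 25.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            _negll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
        )
    theta = res.x
    H = _num_hessian(_negll, theta, bounds)
    cov_full = np.linalg.pinv(H)
    bse_full = np.sqrt(np.clip(np.diag(cov_full), 0.0, np.inf))
    ll = -float(res.fun)
    return LogisticFit(
        beta=theta[:k],
        bse=bse_full[:k],
        cov=cov_full[:k, :k],
        loglik=ll,
        aic=2.0 * (k + 1) - 2.0 * ll,
        converged=bool(res.success),
        method="glmm",
        sigma=float(theta[k]),
        n_obs=y.size,
        n_groups=G,
    )


def _factorize(groups) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq


def _num_hessian(f, x: np.ndarray, bounds) -> np.ndarray:
    """Central-difference Hessian, with steps shrunk near parameter bounds."""
    n = x.size
    h = 1e-4 * (1.0 + np.abs(x))
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            h[i] = min(h[i], max((x[i] - lo) / 2.0, 1e-10))
    H = np.empty((n, n))
    fx = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * fx + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


def fit_logistic_glm(
    y: np.ndarray, X: np.ndarray, names: Optional[list[str]] = None
) -> LogisticFit:
    """Binomial GLM; falls back to Firth's bias-reduced fit on separation."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        beta = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 15.0 or np.max(bse) > 50.0:
            separated = True
    except Exception:
        separated = True
    if separated:
        return firth_logit(y, X)
    k = X.shape[1]
    return LogisticFit(
        beta=beta,
        bse=bse,
        cov=np.asarray(res.cov_params(), dtype=float),
        loglik=float(res.llf),
        aic=2.0 * k - 2.0 * float(res.llf),
        converged=bool(res.converged),
        method="glm",
        n_obs=y.size,
    )


def firth_logit(
    y: np.ndarray, X: np.ndarray, maxiter: int = 200, tol: float = 1e-9
) -> LogisticFit:
    """Firth's bias-reduced logistic regression (Jeffreys-prior penalty).

    Yields finite estimates under complete separation; the reported
    log-likelihood is the penalised one used for fitting.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    Finv = np.eye(k)
    for _ in range(maxiter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1.0 - p)
        F = (X * W[:, None]).T @ X
        Finv = np.linalg.pinv(F)
        h = W * np.einsum("ij,jk,ik->i", X, Finv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        step = Finv @ U
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    p = expit(eta)
    W = p * (1.0 - p)
    F = (X * W[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(F)
    ll = float(np.sum(_bern_loglik(eta, y)) + 0.5 * logdet)
    Finv = np.linalg.pinv(F)
    return LogisticFit(
        beta=beta,
        bse=np.sqrt(np.clip(np.diag(Finv), 0.0, np.inf)),
        cov=Finv,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        converged=converged,
        method="firth",
        separation=True,
        n_obs=n,
    )
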