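"""Restricted maximum likelihood core shared by the mixed-model fitters.

The model is ``y = X b + sum_k u_k + e`` with ``u_k ~ N(0, s2_k G_k)``; the
caller supplies the covariance kernels ``G_k`` (the last one is usually the
identity for the residual).  Variances are estimated on the log scale with
analytic score equations; small problems (n up to a few thousand) are handled
densely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["REMLResult", "reml_fit", "reml_single_kernel", "gls"]

_JITTER = 1e-8
_VAR_FLOOR = 1e-10


@dataclass
class REMLResult:
    variances: np.ndarray          # one entry per kernel, residual last
    beta: np.ndarray
    loglik: float                  # restricted log-likelihood (up to constant)
    converged: bool
    n_iter: int
    message: str = ""
    extras: dict = field(default_factory=dict)


def _chol(V: np.ndarray):
    """Cholesky with escalating jitter; raises if hopeless."""
    jitter = 0.0
    for _ in range(6):
        try:
            return linalg.cho_factor(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = _JITTER if jitter == 0.0 else jitter * 100
    raise linalg.LinAlgError("covariance matrix not positive definite")


def _neg_reml(theta, y, X, kernels, want_grad):
    n, p = X.shape
    s2 = np.exp(theta)
    V = np.zeros((n, n))
    for s, G in zip(s2, kernels):
        V += s * G
    c = _chol(V)
    ViX = linalg.cho_solve(c, X)
    Viy = linalg.cho_solve(c, y)
    XtViX = X.T @ ViX
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ np.linalg.solve(XtViX, ViX.T @ y)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    nll = 0.5 * (logdet_v + logdet_xvx + float(y @ Py))
    if not want_grad:
        return nll
    Vi = linalg.cho_solve(c, np.eye(n))
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    grad = np.empty_like(theta)
    for k, G in enumerate(kernels):
        tr_pg = float(np.sum(P * G))
        quad = float(Py @ (G @ Py))
        grad[k] = 0.5 * (tr_pg - quad) * s2[k]      # chain rule for log-variance
    return nll, grad


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    start: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> REMLResult:
    """Estimate variance components by dense REML.

    ``kernels`` must contain the residual kernel (identity) as its last
    element.  Returns variances on the original scale with GLS fixed effects
    evaluated at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if len(kernels) < 1:
        raise ValueError("at least one covariance kernel required")
    vary = float(np.var(y))
    if vary <= 0:
        vary = 1.0
    k = len(kernels)
    if start is None:
        start = np.full(k, vary / k)
    theta0 = np.log(np.maximum(start, _VAR_FLOOR * vary))
    bounds = [(np.log(vary * 1e-8), np.log(vary * 1e4))] * k

    res = optimize.minimize(
        _neg_reml,
        theta0,
        args=(y, X, kernels, True),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    f0 = _neg_reml(theta0, y, X, kernels, False)
    if not np.isfinite(res.fun) or res.fun > f0:
        res2 = optimize.minimize(
            _neg_reml,
            theta0,
            args=(y, X, kernels, False),
            method="Nelder-Mead",
            options={"maxiter": 200 * k, "fatol": 1e-6, "xatol": 1e-5},
        )
        if np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2
    s2 = np.exp(res.x)
    s2[s2 < _VAR_FLOOR * vary] = 0.0
    beta, _ = gls(y, X, kernels, s2)
    return REMLResult(
        variances=s2,
        beta=beta,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.get("nit", 0) or 0),
        message=str(res.message),
    )


def gls(y, X, kernels, variances):
    """Generalized least squares at fixed variances; returns (beta, alpha)
    where ``alpha = V^{-1} (y - X beta)`` is the BLUP working vector."""
    n = y.shape[0]
    V = np.zeros((n, n))
    nonzero = False
    for s, G in zip(variances, kernels):
        if s > 0:
            V += s * G
            nonzero = True
    if not nonzero:
        V = np.eye(n) * _JITTER
    c = _chol(V)
    ViX = linalg.cho_solve(c, X)
    Viy = linalg.cho_solve(c, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    alpha = linalg.cho_solve(c, y - X @ beta)
    return beta, alpha


def reml_single_kernel(y, X, K, grid_pad: float = 12.0):
    """Fast REML for ``V = s2_k K + s2_e I`` via one eigendecomposition.

    Profiles the residual variance and maximizes over the ratio
    ``lam = s2_k / s2_e`` in one dimension.  Returns (s2_k, s2_e, beta,
    loglik).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def nll_at(loglam):
        lam = np.exp(loglam)
        d = lam * w + 1.0
        Xd = Xt / d[:, None]
        XtViX = Xt.T @ Xd
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None
        beta = np.linalg.solve(XtViX, Xd.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / d))
        if rss <= 0:
            return np.inf, None
        s2e = rss / (n - p)
        nll = 0.5 * ((n - p) * np.log(s2e) + np.sum(np.log(d)) + logdet_xvx + (n - p))
        return nll, (lam, s2e, beta)

    grid = np.linspace(-grid_pad, grid_pad, 41)
    vals = [nll_at(g)[0] for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: nll_at(t)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    nll, parts = nll_at(res.x)
    if parts is None:
        raise RuntimeError("single-kernel REML failed to evaluate at optimum")
    lam, s2e, beta = parts
    s2k = lam * s2e
    if s2k < _VAR_FLOOR * max(s2e, 1.0):
        s2k = 0.0
    return s2k, s2e, beta, -float(nll)
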