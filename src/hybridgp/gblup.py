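"""Single-trait GBLUP: ``y = mu + xi_a (+ xi_d) + eps`` with
``xi_a ~ N(0, Ka s2_a)``, ``xi_d ~ N(0, Kd s2_d)``, ``eps ~ N(0, I s2_e)``.

The default solver is deterministic REML (eigendecomposition path for one
kernel, dense multi-kernel REML otherwise); a conjugate Gibbs sampler is
available to mirror Bayesian kernel-regression fits (posterior means
reported, seed-reproducible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from . import _reml
from .kinship import KinshipMatrix

__all__ = ["GPFit", "fit_gblup", "predict"]

_VAR_FLOOR = 1e-10


@dataclass
class GPFit:
    mu: float
    xi_a: pd.Series                 # additive effects for every kinship line
    xi_d: pd.Series | None
    var_a: float
    var_d: float
    var_e: float
    solver: str
    train_ids: list
    loglik: float = float("nan")
    n_iter: int = 0
    burn_in: int = 0


def _align(y: pd.Series, Ka: KinshipMatrix, train_ids) -> list:
    lines = Ka.line_ids
    if train_ids is None:
        train_ids = [l for l in lines if l in set(y.index)]
    missing = [t for t in train_ids if t not in set(lines)]
    if missing:
        raise ValueError(f"training ids absent from kinship: {missing[:5]}")
    missing_y = [t for t in train_ids if t not in set(y.index)]
    if missing_y:
        raise ValueError(f"phenotypes missing for training ids: {missing_y[:5]}")
    if len(train_ids) < 3:
        raise ValueError("need at least three training lines")
    return list(train_ids)


def fit_gblup(
    y: pd.Series,
    Ka: KinshipMatrix,
    Kd: KinshipMatrix | None = None,
    train_ids=None,
    solver: str = "reml",
    seed: int | None = None,
    n_iter: int = 15000,
    burn_in: int = 1000,
) -> GPFit:
    """Fit the additive (A) or additive+dominance (AD) GBLUP model on the
    training lines and evaluate genetic effects for every kinship line."""
    train_ids = _align(y, Ka, train_ids)
    yt = y.loc[train_ids].to_numpy(dtype=float)
    n = len(yt)
    X = np.ones((n, 1))
    K_tt = Ka.submatrix(train_ids)
    D_tt = Kd.submatrix(train_ids) if Kd is not None else None

    if solver == "reml":
        if D_tt is None:
            var_a, var_e, beta, ll = _reml.reml_single_kernel(yt, X, K_tt)
            var_d = 0.0
        else:
            res = _reml.reml_fit(yt, X, [K_tt, D_tt, np.eye(n)])
            var_a, var_d, var_e = (float(v) for v in res.variances)
            beta, ll = res.beta, res.loglik
        mu = float(np.atleast_1d(beta)[0])
        variances = [var_a] + ([var_d] if D_tt is not None else []) + [var_e]
        kernels = [K_tt] + ([D_tt] if D_tt is not None else []) + [np.eye(n)]
        try:
            _, alpha = _reml.gls(yt, X, kernels, variances)
        except linalg.LinAlgError:
            warnings.warn("singular mixed-model system; adding 1e-6 ridge")
            kernels[-1] = np.eye(n) * (1 + 1e-6)
            _, alpha = _reml.gls(yt, X, kernels, variances)
        xi_a = var_a * (Ka.submatrix(Ka.line_ids, train_ids) @ alpha)
        xi_d = (
            var_d * (Kd.submatrix(Kd.line_ids, train_ids) @ alpha)
            if D_tt is not None
            else None
        )
        return GPFit(
            mu=mu,
            xi_a=pd.Series(xi_a, index=Ka.line_ids),
            xi_d=pd.Series(xi_d, index=Kd.line_ids) if xi_d is not None else None,
            var_a=max(var_a, 0.0),
            var_d=max(var_d, 0.0) if D_tt is not None else 0.0,
            var_e=max(var_e, _VAR_FLOOR),
            solver="reml",
            train_ids=train_ids,
            loglik=float(ll),
        )
    elif solver == "gibbs":
        if seed is None:
            raise ValueError("gibbs solver requires a seed")
        return _gibbs(yt, Ka, Kd, train_ids, seed, n_iter, burn_in)
    raise ValueError(f"unknown solver {solver!r}")


def _sample_mvn(rng, C_chol_lower, rhs):
    """Draw from N(C^{-1} rhs, C^{-1}) given the lower Cholesky of C."""
    mean = linalg.cho_solve((C_chol_lower, True), rhs)
    z = rng.standard_normal(len(rhs))
    dev = linalg.solve_triangular(C_chol_lower.T, z, lower=False)
    return mean + dev


def _scaled_inv_chi2(rng, df, scale):
    return df * scale / rng.chisquare(df)


def _gibbs(yt, Ka, Kd, train_ids, seed, n_iter, burn_in):
    """Conjugate Gibbs sampler with scaled-inverse-chi-squared priors
    (df=5, scales from an even split of the phenotypic variance)."""
    rng = np.random.default_rng(seed)
    n = len(yt)
    vary = float(np.var(yt, ddof=1))
    df0 = 5.0
    n_kernels = 2 if Kd is not None else 1
    s0_g = vary * 0.5 / n_kernels * (df0 - 2) / df0
    s0_e = vary * 0.5 * (df0 - 2) / df0

    def prep(K: KinshipMatrix):
        Kt = K.submatrix(train_ids)
        Kt = Kt + np.eye(n) * 1e-8
        Kinv = np.linalg.inv(Kt)
        Kinv = (Kinv + Kinv.T) / 2
        return Kt, Kinv

    Ka_tt, Ka_inv = prep(Ka)
    kernels = [("a", Ka_tt, Ka_inv)]
    if Kd is not None:
        Kd_tt, Kd_inv = prep(Kd)
        kernels.append(("d", Kd_tt, Kd_inv))

    mu = float(yt.mean())
    xi = {name: np.zeros(n) for name, _, _ in kernels}
    s2 = {name: vary * 0.5 / n_kernels for name, _, _ in kernels}
    s2e = vary * 0.5
    sums = {name: np.zeros(n) for name, _, _ in kernels}
    sum_mu = 0.0
    sum_s2 = {name: 0.0 for name, _, _ in kernels}
    sum_s2e = 0.0
    kept = 0

    for it in range(n_iter):
        for name, Kt, Kinv in kernels:
            resid = yt - mu - sum(xi[o] for o in xi if o != name)
            C = Kinv / s2[name] + np.eye(n) / s2e
            L = np.linalg.cholesky(C)
            xi[name] = _sample_mvn(rng, L, resid / s2e)
            quad = float(xi[name] @ (Kinv @ xi[name]))
            s2[name] = max(
                _scaled_inv_chi2(rng, df0 + n, (quad + df0 * s0_g) / (df0 + n)),
                _VAR_FLOOR,
            )
        resid = yt - sum(xi.values())
        mu = float(rng.normal(resid.mean(), np.sqrt(s2e / n)))
        sse = float(((resid - mu) ** 2).sum())
        s2e = max(
            _scaled_inv_chi2(rng, df0 + n, (sse + df0 * s0_e) / (df0 + n)),
            _VAR_FLOOR,
        )
        if it >= burn_in:
            kept += 1
            sum_mu += mu
            sum_s2e += s2e
            for name in xi:
                sums[name] += xi[name]
                sum_s2[name] += s2[name]

    post_mu = sum_mu / kept
    post_xi = {name: sums[name] / kept for name in sums}
    post_s2 = {name: sum_s2[name] / kept for name in sum_s2}
    post_s2e = sum_s2e / kept

    # extend posterior-mean effects to non-training lines via the kinship
    xi_a_all = Ka.submatrix(Ka.line_ids, train_ids) @ (Ka_inv @ post_xi["a"])
    xi_a = pd.Series(xi_a_all, index=Ka.line_ids)
    xi_d = None
    var_d = 0.0
    if Kd is not None:
        xi_d_all = Kd.submatrix(Kd.line_ids, train_ids) @ (Kd_inv @ post_xi["d"])
        xi_d = pd.Series(xi_d_all, index=Kd.line_ids)
        var_d = post_s2["d"]
    return GPFit(
        mu=post_mu,
        xi_a=xi_a,
        xi_d=xi_d,
        var_a=post_s2["a"],
        var_d=var_d,
        var_e=post_s2e,
        solver="gibbs",
        train_ids=list(train_ids),
        n_iter=n_iter,
        burn_in=burn_in,
    )


def predict(fit: GPFit, target_ids) -> pd.Series:
    """Predicted phenotype ``mu + xi_a (+ xi_d)`` for each target line."""
    target_ids = list(target_ids)
    missing = [t for t in target_ids if t not in fit.xi_a.index]
    if missing:
        raise KeyError(f"ids absent from the fitted kinship: {missing[:5]}")
    pred = fit.mu + fit.xi_a.loc[target_ids]
    if fit.xi_d is not None:
        pred = pred + fit.xi_d.loc[target_ids]
    return pd.Series(pred.to_numpy(), index=target_ids, name="predicted")
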