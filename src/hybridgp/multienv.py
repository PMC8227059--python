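"""Multi-environment genomic prediction models on stacked per-environment
phenotypes.

SE fits one environment at a time (additive GBLUP).  AE shares a single
genetic main effect across environments (covariance ``G0 = J (x) Ka`` over
the stacked cells).  GxE adds an environment-specific genetic effect with
block-diagonal covariance ``G1`` (one Ka block per environment, each with its
own variance by default).  Residuals are homogeneous across environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _reml
from .gblup import GPFit, fit_gblup
from .kinship import KinshipMatrix

__all__ = [
    "StackedPhenotypes",
    "MultiEnvFit",
    "fit_se",
    "build_covariances",
    "fit_multienv",
]


@dataclass
class StackedPhenotypes:
    """Per-environment phenotypes in long form: columns line, env, y."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = {"line", "env", "y"} - set(self.data.columns)
        if missing:
            raise ValueError(f"stacked phenotypes missing columns: {sorted(missing)}")
        if self.data.duplicated(["line", "env"]).any():
            raise ValueError("duplicate (line, env) cells")

    @classmethod
    def from_env_series(cls, by_env: dict) -> "StackedPhenotypes":
        rows = [
            (line, env, float(val))
            for env, series in by_env.items()
            for line, val in series.items()
        ]
        return cls(pd.DataFrame(rows, columns=["line", "env", "y"]))

    @property
    def envs(self) -> list:
        return list(pd.unique(self.data["env"]))

    @property
    def lines(self) -> list:
        return list(pd.unique(self.data["line"]))

    def cells(self) -> list:
        return list(zip(self.data["line"], self.data["env"]))


@dataclass
class MultiEnvFit:
    model: str                       # "AE" or "GxE"
    mu: pd.Series                    # per-environment intercepts
    var_u: float                     # main-effect variance
    var_s: pd.Series                 # per-environment specific variances (0 for AE)
    var_e: float
    envs: list
    train_cells: list
    _ka: KinshipMatrix = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)
    _train_lines: list = field(repr=False, default=None)
    _train_envs: list = field(repr=False, default=None)
    loglik: float = float("nan")

    def predict(self, cells) -> pd.Series:
        """BLUP prediction mu_j + xi (+ xi_js) for (line, env) cells."""
        lines = self._ka.line_ids
        line_pos = {l: i for i, l in enumerate(lines)}
        K = self._ka.matrix()
        ti = np.array([line_pos[l] for l in self._train_lines])
        tenv = np.asarray(self._train_envs)
        preds = []
        index = []
        for line, env in cells:
            if env not in set(self.envs):
                raise KeyError(f"environment {env!r} not in fitted model")
            if line not in line_pos:
                raise KeyError(f"line {line!r} absent from the kinship")
            krow = K[line_pos[line], ti]
            c = self.var_u * krow
            vs = float(self.var_s.get(env, 0.0))
            if vs > 0:
                c = c + vs * krow * (tenv == env)
            preds.append(float(self.mu[env]) + float(c @ self._alpha))
            index.append((line, env))
        return pd.Series(
            preds, index=pd.MultiIndex.from_tuples(index, names=["line", "env"]),
            name="predicted",
        )


def fit_se(y_env: pd.Series, Ka: KinshipMatrix, train_ids=None, **kwargs) -> GPFit:
    """Single-environment model: additive GBLUP on one environment's BLUEs."""
    return fit_gblup(y_env, Ka, Kd=None, train_ids=train_ids, **kwargs)


def build_covariances(Ka: KinshipMatrix, env_list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-grid covariance structures over (line, env) cells.

    G0 has Ka in every environment block pair (main effect perfectly
    correlated across environments); the G1 template is block-diagonal with
    one Ka block per environment (scaled by its own variance at fit time).
    """
    env_list = list(env_list)
    if not env_list:
        raise ValueError("need at least one environment")
    n = len(Ka.line_ids)
    e = len(env_list)
    K = Ka.matrix()
    G0 = np.tile(K, (e, e))
    G1 = np.kron(np.eye(e), K)
    idx = pd.MultiIndex.from_product([env_list, Ka.line_ids], names=["env", "line"])
    return (
        pd.DataFrame(G0, index=idx, columns=idx),
        pd.DataFrame(G1, index=idx, columns=idx),
    )


def fit_multienv(
    stacked: StackedPhenotypes,
    Ka: KinshipMatrix,
    model: str = "GxE",
    masked_cells=None,
    homogeneous_specific: bool = False,
    var_s_fixed: float | None = None,
    solver: str = "reml",
    seed: int | None = None,
) -> MultiEnvFit:
    """Fit the AE or GxE stacked mixed model, excluding ``masked_cells``
    (pairs of (line, env)) from training; predictions for any cell come from
    :meth:`MultiEnvFit.predict`."""
    if model not in ("AE", "GxE"):
        raise ValueError(f"unknown multi-environment model {model!r}")
    if solver != "reml":
        raise ValueError("only the REML solver is implemented for stacked models")
    masked = set(map(tuple, masked_cells or ()))
    df = stacked.data
    keep = [i for i, cell in enumerate(zip(df["line"], df["env"])) if tuple(cell) not in masked]
    train = df.iloc[keep]
    envs = stacked.envs
    for env in envs:
        if (train["env"] == env).sum() == 0:
            raise ValueError(
                f"all cells of environment {env!r} are masked; the stacked model "
                "needs at least one training cell per environment"
            )
    lines = Ka.line_ids
    line_pos = {l: i for i, l in enumerate(lines)}
    unknown = set(train["line"]) - set(lines)
    if unknown:
        raise ValueError(f"lines absent from kinship: {sorted(unknown)[:5]}")

    y = train["y"].to_numpy(dtype=float)
    t_lines = list(train["line"])
    t_envs = list(train["env"])
    li = np.array([line_pos[l] for l in t_lines])
    K = Ka.matrix()
    G0c = K[np.ix_(li, li)]
    X = np.zeros((len(y), len(envs)))
    for j, env in enumerate(envs):
        X[np.asarray(t_envs) == env, j] = 1.0

    kernels = [G0c]
    names = ["u"]
    env_arr = np.asarray(t_envs)
    if model == "GxE" and (var_s_fixed is None or var_s_fixed > 0):
        if homogeneous_specific:
            mask = (env_arr[:, None] == env_arr[None, :]).astype(float)
            kernels.append(G0c * mask)
            names.append("s")
        else:
            for env in envs:
                sel = (env_arr == env).astype(float)
                kernels.append(G0c * np.outer(sel, sel))
                names.append(f"s:{env}")
    kernels.append(np.eye(len(y)))
    names.append("e")

    if model == "GxE" and var_s_fixed is not None:
        if var_s_fixed == 0:
            # specific kernels dropped above; reduces exactly to AE structure
            res = _reml.reml_fit(y, X, kernels)
        else:
            raise NotImplementedError("only var_s_fixed=0 is supported")
    else:
        res = _reml.reml_fit(y, X, kernels)

    var = dict(zip(names, (float(v) for v in res.variances)))
    var_u = var["u"]
    if model == "GxE" and var_s_fixed == 0:
        var_s = pd.Series(0.0, index=envs)
    elif model == "GxE":
        if homogeneous_specific:
            var_s = pd.Series(var["s"], index=envs)
        else:
            var_s = pd.Series({env: var[f"s:{env}"] for env in envs})
    else:
        var_s = pd.Series(0.0, index=envs)
    var_e = var["e"]

    _, alpha = _reml.gls(y, X, kernels, res.variances)
    mu = pd.Series(res.beta, index=envs)
    fit = MultiEnvFit(
        model=model,
        mu=mu,
        var_u=var_u,
        var_s=var_s,
        var_e=var_e,
        envs=envs,
        train_cells=list(zip(t_lines, t_envs)),
        _ka=Ka,
        _alpha=alpha,
        _train_lines=t_lines,
        _train_envs=t_envs,
        loglik=res.loglik,
    )
    return fit
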