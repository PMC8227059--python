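"""Multi-environment trial analysis: per-line BLUEs, ANOVA dissection of the
yield model ``y_ijk = mu + g_i + e_j + ge_ij + rep_(j)k + eps_ijk``, and
entry-mean broad-sense heritability ``H2 = s2_g / (s2_g + s2_ge/e + s2_e/(e r))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _reml

__all__ = [
    "TrialRecords",
    "BLUETable",
    "ANOVAResult",
    "fit_blue",
    "anova_ms",
    "heritability",
    "read_phenotypes_csv",
]

ACROSS = "across"


@dataclass
class TrialRecords:
    """Plot-level phenotype records: line, env, rep, block, yield."""

    data: pd.DataFrame
    true_genetic: pd.Series | None = None

    def __post_init__(self):
        required = {"line", "env", "rep", "yield"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype records missing columns: {sorted(missing)}")
        if "block" not in self.data.columns:
            self.data = self.data.assign(block=self.data["env"].astype(str))
        y = self.data["yield"].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("yields must be finite")
        if np.any(y <= 0):
            raise ValueError("yields must be positive")
        if self.data.duplicated(["line", "env", "rep"]).any():
            raise ValueError("duplicate (line, env, rep) records")

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.data["line"]))

    @property
    def envs(self) -> list[str]:
        return list(pd.unique(self.data["env"]))

    def n_replicates(self) -> int:
        return int(self.data.groupby(["line", "env"])["yield"].size().max())

    def is_balanced(self) -> bool:
        counts = self.data.groupby(["line", "env"])["yield"].size()
        full = len(self.lines) * len(self.envs)
        return len(counts) == full and counts.nunique() == 1

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_phenotypes_csv(path) -> TrialRecords:
    return TrialRecords(pd.read_csv(path))


@dataclass
class BLUETable:
    """Per-line fixed-effect estimates (mu + g_i), across environments or per
    environment."""

    estimates: pd.DataFrame  # columns: line, env, blue
    scope: str
    method: str = "reml"

    def series(self, env: str | None = None) -> pd.Series:
        key = ACROSS if env is None else env
        sub = self.estimates[self.estimates["env"] == key]
        if sub.empty:
            raise KeyError(f"no BLUEs for scope/environment {key!r}")
        return pd.Series(sub["blue"].to_numpy(), index=sub["line"].to_numpy(), name="blue")

    def frame(self) -> pd.DataFrame:
        """Lines x environments wide table (across scope: one column)."""
        return self.estimates.pivot(index="line", columns="env", values="blue")

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index=False)


@dataclass
class ANOVAResult:
    """Classical two-factor-with-replication decomposition plus the derived
    variance components.

    ``convention`` controls the component extraction: ``"paper"`` uses
    s2_g = (MS_genotype - MS_error)/(e*r) and s2_ge = (MS_gxe - MS_error)/r
    (matching the reference software output); ``"classical"`` uses the EMS
    rule s2_g = (MS_genotype - MS_gxe)/(e*r).  Negative estimates are
    truncated at zero.
    """

    table: pd.DataFrame  # index: source; columns DF, SS, MS, F, p
    var_g: float
    var_ge: float
    var_error: float
    n_environments: int
    n_replicates: int
    convention: str = "paper"

    SOURCES = ("Rep/Env", "Genotype", "Environment", "GxE", "Error")

    @classmethod
    def from_mean_squares(
        cls,
        ms_genotype: float,
        ms_gxe: float,
        ms_error: float,
        e: int,
        r: int,
        convention: str = "paper",
        ms_rep: float = np.nan,
        ms_env: float = np.nan,
    ) -> "ANOVAResult":
        """Build a result directly from published mean squares (no raw data)."""
        var_g, var_ge, var_error = _components(
            ms_genotype, ms_gxe, ms_error, e, r, convention
        )
        table = pd.DataFrame(
            {
                "DF": np.nan,
                "SS": np.nan,
                "MS": [ms_rep, ms_genotype, ms_env, ms_gxe, ms_error],
                "F": np.nan,
                "p": np.nan,
            },
            index=pd.Index(cls.SOURCES, name="source"),
        )
        return cls(table, var_g, var_ge, var_error, e, r, convention)


def _components(ms_g, ms_ge, ms_err, e, r, convention):
    if convention == "paper":
        var_g = (ms_g - ms_err) / (e * r)
        var_ge = (ms_ge - ms_err) / r
    elif convention == "classical":
        var_g = (ms_g - ms_ge) / (e * r)
        var_ge = (ms_ge - ms_err) / r
    else:
        raise ValueError(f"unknown component convention {convention!r}")
    return max(var_g, 0.0), max(var_ge, 0.0), max(ms_err, 0.0)


def anova_ms(records: TrialRecords, convention: str = "paper") -> ANOVAResult:
    """Balanced ANOVA of the trial model with sources Rep/Env, Genotype,
    Environment, GxE, Error; F statistics are taken against the error mean
    square."""
    if not records.is_balanced():
        raise ValueError(
            "ANOVA requires balanced records (every line in every environment "
            "with equal replication); use fit_blue for unbalanced data"
        )
    df = records.data
    lines, envs = records.lines, records.envs
    g, e = len(lines), len(envs)
    r = records.n_replicates()
    y = df["yield"].to_numpy(dtype=float)
    grand = y.mean()

    m_line = df.groupby("line")["yield"].mean()
    m_env = df.groupby("env")["yield"].mean()
    m_cell = df.groupby(["line", "env"])["yield"].mean()
    m_rep = df.groupby(["env", "rep"])["yield"].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_g = e * r * float(((m_line - grand) ** 2).sum())
    ss_e = g * r * float(((m_env - grand) ** 2).sum())
    ss_rep = g * float(((m_rep - m_env.reindex(m_rep.index.get_level_values(0)).to_numpy()) ** 2).sum())
    inter = (
        m_cell
        - m_line.reindex(m_cell.index.get_level_values(0)).to_numpy()
        - m_env.reindex(m_cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = r * float((inter**2).sum())
    ss_err = ss_total - ss_g - ss_e - ss_rep - ss_ge

    df_rep = e * (r - 1)
    df_g = g - 1
    df_e = e - 1
    df_ge = (g - 1) * (e - 1)
    df_err = g * e * r - 1 - df_rep - df_g - df_e - df_ge
    dfs = [df_rep, df_g, df_e, df_ge, df_err]
    sss = [ss_rep, ss_g, ss_e, ss_ge, ss_err]
    mss = [s / d if d > 0 else np.nan for s, d in zip(sss, dfs)]
    ms_err = mss[-1]
    fs, ps = [], []
    for i in range(4):
        if ms_err and ms_err > 0 and dfs[i] > 0 and df_err > 0:
            f = mss[i] / ms_err
            fs.append(f)
            ps.append(float(stats.f.sf(f, dfs[i], df_err)))
        else:
            fs.append(np.nan)
            ps.append(np.nan)
    fs.append(np.nan)
    ps.append(np.nan)
    table = pd.DataFrame(
        {"DF": dfs, "SS": sss, "MS": mss, "F": fs, "p": ps},
        index=pd.Index(ANOVAResult.SOURCES, name="source"),
    )
    var_g, var_ge, var_error = _components(mss[1], mss[3], ms_err, e, r, convention)
    return ANOVAResult(table, var_g, var_ge, var_error, e, r, convention)


def heritability(a: ANOVAResult) -> float:
    """Entry-mean broad-sense heritability from the extracted components."""
    denom = a.var_g + a.var_ge / a.n_environments + a.var_error / (
        a.n_environments * a.n_replicates
    )
    if denom <= 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return float(a.var_g / denom)


# ---------------------------------------------------------------------------
# BLUEs


def _design(labels: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(labels)
    Z = np.zeros((len(labels), len(cats.categories)))
    Z[np.arange(len(labels)), cats.codes] = 1.0
    return Z, list(cats.categories)


def fit_blue(records: TrialRecords, scope: str = "across_env", method: str = "auto") -> BLUETable:
    """Per-line fixed-effect estimates.

    ``across_env`` fits genotype as fixed with random environment, GxE, and
    replicate-within-environment (plus block-within-replicate when block
    labels are informative); ``per_env`` fits genotype fixed with random
    replicate within a single environment.  ``method="auto"`` takes a
    method-of-moments shortcut on balanced data and full REML otherwise.
    """
    if scope == "across_env":
        frames = [(_fit_blue_once(records.data, method), ACROSS)]
    elif scope == "per_env":
        frames = []
        for env in records.envs:
            sub = records.data[records.data["env"] == env]
            frames.append((_fit_blue_once(sub, method), env))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    used_method = frames[0][0][1]
    for (est, meth), env in frames:
        for line, val in est.items():
            rows.append((line, env, val))
        used_method = meth
    return BLUETable(
        estimates=pd.DataFrame(rows, columns=["line", "env", "blue"]),
        scope=scope,
        method=used_method,
    )


def _fit_blue_once(df: pd.DataFrame, method: str) -> tuple[pd.Series, str]:
    y = df["yield"].to_numpy(dtype=float)
    X, line_levels = _design(df["line"])
    if np.any(X.sum(axis=0) == 0):
        raise ValueError("every line must be observed at least once in scope")

    multi_env = df["env"].nunique() > 1
    counts = df.groupby(["line", "env"]).size()
    if not multi_env and counts.max() == 1:
        warnings.warn("unreplicated single-environment data; returning raw means")
        means = df.groupby("line")["yield"].mean()
        return means, "means"

    balanced = counts.nunique() == 1 and len(counts) == df["line"].nunique() * df["env"].nunique()
    if method == "auto" and balanced:
        # under balance the GLS genotype estimates reduce to line means
        means = df.groupby("line")["yield"].mean()
        return means.reindex(line_levels), "balanced_means"

    kernels = []
    if multi_env:
        Ze, _ = _design(df["env"])
        kernels.append(Ze @ Ze.T)
        Zge, _ = _design(df["line"].astype(str) + "\x1f" + df["env"].astype(str))
        kernels.append(Zge @ Zge.T)
    rep_key = df["env"].astype(str) + "\x1f" + df["rep"].astype(str)
    Zr, rep_levels = _design(rep_key)
    if len(rep_levels) > df["env"].nunique():
        kernels.append(Zr @ Zr.T)
    if "block" in df.columns:
        blk_key = rep_key + "\x1f" + df["block"].astype(str)
        Zb, blk_levels = _design(blk_key)
        if len(blk_levels) > len(rep_levels):
            kernels.append(Zb @ Zb.T)
    kernels.append(np.eye(len(y)))
    res = _reml.reml_fit(y, X, kernels)
    est = pd.Series(res.beta, index=line_levels, name="blue")
    return est, "reml"
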