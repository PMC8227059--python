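"""Evaluation designs: within-population k-fold CV, one-to-one and
three-to-one population transfer, and the CV1/CV2 multi-environment schemes.

Prediction accuracy (PA) is the Pearson correlation between predicted and
observed phenotypes of the validation set.  Per repeat, the held-out lines of
all folds are pooled before correlating; per-repeat PAs are stored so the
mean/SD summaries are recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import fit_gblup, predict
from .kinship import KinshipMatrix
from .multienv import StackedPhenotypes, fit_multienv, fit_se

__all__ = [
    "SchemeSpec",
    "CVResult",
    "prediction_accuracy",
    "run_within",
    "run_transfer",
    "run_cv_multienv",
]


@dataclass(frozen=True)
class SchemeSpec:
    scheme: str                    # within | one_to_one | three_to_one | cv1 | cv2
    model: str = "A"               # A | AD | SE | AE | GxE
    k_folds: int = 5
    n_repeats: int = 100
    environments: tuple = ()
    populations: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.scheme in ("within", "cv1", "cv2") and self.k_folds < 2:
            raise ValueError("cross-validation schemes need k_folds >= 2")


@dataclass
class CVResult:
    """Per-repeat prediction accuracies, one row per (repeat, env) or
    (repeat,) for single-response schemes."""

    per_repeat: pd.DataFrame  # columns: repeat, env, pa
    scheme: str
    model: str

    def summary(self) -> pd.DataFrame:
        return (
            self.per_repeat.groupby("env")["pa"].agg(["mean", "std", "count"]).reset_index()
        )

    def mean(self, env=None) -> float:
        df = self.per_repeat
        if env is not None:
            df = df[df["env"] == env]
        return float(df["pa"].mean())


def prediction_accuracy(predicted, observed) -> float:
    """Pearson correlation of predicted vs observed phenotypes."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have the same length")
    if p.size < 3:
        raise ValueError("need at least three paired values")
    if p.std() == 0 or o.std() == 0:
        raise ValueError("constant vector; correlation undefined")
    return float(np.corrcoef(p, o)[0, 1])


def _folds(ids, k, rng):
    """Random partition of ids into k folds of near-equal size."""
    ids = np.asarray(ids, dtype=object)
    perm = rng.permutation(len(ids))
    return [ids[perm[j::k]].tolist() for j in range(k)]


def run_within(
    blues: pd.Series,
    Ka: KinshipMatrix,
    Kd: KinshipMatrix | None = None,
    model: str = "A",
    spec: SchemeSpec | None = None,
) -> CVResult:
    """Repeated k-fold CV within one (or a pooled) population."""
    spec = spec or SchemeSpec(scheme="within", model=model)
    ids = [l for l in Ka.line_ids if l in set(blues.index)]
    if len(ids) < spec.k_folds:
        raise ValueError("population smaller than the number of folds")
    if model == "AD" and Kd is None:
        raise ValueError("AD model requires a dominance kinship")
    kd = Kd if model == "AD" else None
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_repeats):
        preds = {}
        for fold in _folds(ids, spec.k_folds, rng):
            train = [l for l in ids if l not in set(fold)]
            fit = fit_gblup(blues, Ka, Kd=kd, train_ids=train)
            preds.update(predict(fit, fold).to_dict())
        pooled = pd.Series(preds).loc[ids]
        rows.append((rep, "pooled", prediction_accuracy(pooled, blues.loc[ids])))
    return CVResult(
        per_repeat=pd.DataFrame(rows, columns=["repeat", "env", "pa"]),
        scheme="within",
        model=model,
    )


def run_transfer(
    blues: pd.Series,
    train_ids,
    valid_ids,
    Ka: KinshipMatrix,
    Kd: KinshipMatrix | None = None,
    model: str = "A",
) -> float:
    """One-to-one / three-to-one transfer: single fit on the training
    population(s), PA on the full validation population (no folds)."""
    train_ids, valid_ids = list(train_ids), list(valid_ids)
    overlap = set(train_ids) & set(valid_ids)
    if overlap:
        raise ValueError(f"training and validation populations overlap: {sorted(overlap)[:5]}")
    kd = Kd if model == "AD" else None
    if model == "AD" and Kd is None:
        raise ValueError("AD model requires a dominance kinship")
    fit = fit_gblup(blues, Ka, Kd=kd, train_ids=train_ids)
    pred = predict(fit, valid_ids)
    return prediction_accuracy(pred, blues.loc[valid_ids])


def run_cv_multienv(
    stacked: StackedPhenotypes,
    Ka: KinshipMatrix,
    model: str = "GxE",
    scheme: str = "cv1",
    spec: SchemeSpec | None = None,
    target_env=None,
) -> CVResult:
    """CV1 masks a fold's lines in every environment; CV2 masks them only in
    the target environment (each line stays observed somewhere).  PA is
    computed per environment on the masked cells pooled across folds.

    With ``model="SE"`` each environment is cross-validated independently
    (only meaningful under the CV1 masking pattern).
    """
    spec = spec or SchemeSpec(scheme=scheme, model=model)
    envs = stacked.envs
    if scheme not in ("cv1", "cv2"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "cv2" and len(envs) < 2:
        raise ValueError("CV2 requires at least two environments")
    if model == "SE":
        if scheme == "cv2":
            raise ValueError("the SE model has no cross-environment information; use CV1")
        return _cv_se(stacked, Ka, spec)
    if len(envs) < 2:
        raise ValueError("AE/GxE models need at least two environments")
    targets = envs if target_env is None else [target_env]
    for t in targets:
        if t not in envs:
            raise ValueError(f"target environment {t!r} not in stacked data")

    obs = stacked.data.set_index(["line", "env"])["y"]
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_repeats):
        folds = _folds(stacked.lines, spec.k_folds, rng)
        # CV1 masking does not depend on the target environment: fit once per
        # fold and score every target from the pooled predictions.
        mask_targets = [None] if scheme == "cv1" else targets
        masked_preds: dict[tuple, float] = {}
        for tgt in mask_targets:
            for fold in folds:
                fold_set = set(fold)
                masked = [
                    c
                    for c in stacked.cells()
                    if c[0] in fold_set and (tgt is None or c[1] == tgt)
                ]
                if not masked:
                    continue
                fit = fit_multienv(stacked, Ka, model=model, masked_cells=masked)
                masked_preds.update(fit.predict(masked).to_dict())
        for tgt in targets:
            pred_cells = [c for c in masked_preds if c[1] == tgt]
            if len(pred_cells) < 3:
                continue
            p = [masked_preds[c] for c in pred_cells]
            o = [obs.loc[c] for c in pred_cells]
            rows.append((rep, tgt, prediction_accuracy(p, o)))
    return CVResult(
        per_repeat=pd.DataFrame(rows, columns=["repeat", "env", "pa"]),
        scheme=scheme,
        model=model,
    )


def _cv_se(stacked: StackedPhenotypes, Ka: KinshipMatrix, spec: SchemeSpec) -> CVResult:
    obs = stacked.data.set_index(["line", "env"])["y"]
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_repeats):
        for env in stacked.envs:
            y_env = obs.xs(env, level="env")
            ids = list(y_env.index)
            preds = {}
            for fold in _folds(ids, spec.k_folds, rng):
                train = [l for l in ids if l not in set(fold)]
                fit = fit_se(y_env, Ka, train_ids=train)
                preds.update(predict(fit, fold).to_dict())
            pooled = pd.Series(preds).loc[ids]
            rows.append((rep, env, prediction_accuracy(pooled, y_env)))
    return CVResult(
        per_repeat=pd.DataFrame(rows, columns=["repeat", "env", "pa"]),
        scheme="cv1",
        model="SE",
    )
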