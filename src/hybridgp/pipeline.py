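"""End-to-end study orchestration from a single YAML config.

Stages run in dependency order (simulate -> qc -> structure -> trial ->
kinship -> evaluate); every intermediate lands on disk in a documented text
format and a manifest records config hash, per-stage seeds, output paths and
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, evaluate, kinship, qc, simulate, structure, trial

log = logging.getLogger("hybridgp")

STAGE_ORDER = ("simulate", "qc", "structure", "trial", "kinship", "evaluate")

_SCHEMA = {
    "schema_version": None,
    "seed": None,
    "stages": None,
    "simulate": {
        "n_markers", "n_chromosomes", "chrom_length_cm", "n_qtl", "mu",
        "additive_effect_sd", "dominance_effect_sd", "var_g", "var_ge",
        "var_rep", "var_error", "env_names", "env_means", "n_environments",
        "n_replicates", "maf_range", "ge_structure", "tester", "populations",
    },
    "qc": {"call_rate_min", "missing_rate_max", "maf_min", "impute_method"},
    "structure": {"n_components"},
    "trial": {"convention"},
    "kinship": {"center"},
    "evaluate": {"n_repeats", "k_folds", "schemes"},
}

_POP_KEYS = {"name", "type", "n_lines", "parents"}
_SCHEME_KEYS = {"scheme", "model", "populations", "target_env", "n_repeats", "k_folds"}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    if cfg.get("schema_version", 1) != 1:
        raise ConfigError("unsupported schema_version (expected 1)")
    for section, allowed in _SCHEMA.items():
        if allowed is None or section not in cfg:
            continue
        sub = cfg[section]
        if not isinstance(sub, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
    for pop in cfg.get("simulate", {}).get("populations", []) or []:
        bad = set(pop) - _POP_KEYS
        if bad:
            raise ConfigError(f"unknown population keys: {sorted(bad)}")
    for sch in cfg.get("evaluate", {}).get("schemes", []) or []:
        bad = set(sch) - _SCHEME_KEYS
        if bad:
            raise ConfigError(f"unknown scheme keys: {sorted(bad)}")
    stages = cfg.get("stages", list(STAGE_ORDER))
    bad = set(stages) - set(STAGE_ORDER)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: sha256}, seconds, skipped}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(out: Path, names: list[str], needed_by: str, producer: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise FileNotFoundError(
                f"stage {needed_by!r} needs {name!r}; run stage {producer!r} first"
            )


def build_simulation_config(cfg: dict, seed: int) -> simulate.SimulationConfig:
    sc = dict(cfg.get("simulate", {}))
    genome = simulate.GenomeMap.uniform(
        n_chromosomes=sc.pop("n_chromosomes", 10),
        length_cm=sc.pop("chrom_length_cm", 160.0),
        n_markers=sc.pop("n_markers", 2000),
    )
    pops = sc.pop("populations", None)
    if pops:
        peds = tuple(
            simulate.PedigreeSpec(
                name=p["name"],
                population_type=p["type"],
                n_lines=int(p["n_lines"]),
                parents=tuple(p.get("parents", ())),
            )
            for p in pops
        )
    else:
        peds = simulate.default_config().pedigrees
    for key in ("env_names", "env_means", "maf_range"):
        if key in sc and sc[key] is not None:
            sc[key] = tuple(sc[key])
    if "var_error" in sc and isinstance(sc["var_error"], list):
        sc["var_error"] = tuple(sc["var_error"])
    return simulate.SimulationConfig(genome=genome, pedigrees=peds, seed=seed, **sc)


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg, out: Path, seed: int) -> list[str]:
    sim_cfg = build_simulation_config(cfg, seed)
    study = simulate.simulate_study(sim_cfg)
    study.lines.to_tsv(out / "genotypes.tsv", out / "markers.tsv")
    study.founders.to_tsv(out / "founders.tsv")
    study.line_populations.rename("population").to_csv(out / "line_populations.csv", index_label="line")
    study.records.to_csv(out / "phenotypes.csv")
    study.records.true_genetic.rename("true_genetic").to_csv(out / "true_genetic.csv")
    with open(out / "tester.txt", "w") as fh:
        fh.write(sim_cfg.tester + "\n")
    return [
        "genotypes.tsv", "markers.tsv", "founders.tsv", "line_populations.csv",
        "phenotypes.csv", "true_genetic.csv", "tester.txt",
    ]


def _stage_qc(cfg, out: Path, seed: int) -> list[str]:
    _require(out, ["genotypes.tsv", "founders.tsv", "tester.txt"], "qc", "simulate")
    qcfg = cfg.get("qc", {})
    lines = qc.read_genotypes_tsv(out / "genotypes.tsv", out / "markers.tsv")
    founders = qc.read_genotypes_tsv(out / "founders.tsv", out / "markers.tsv")
    tester_id = (out / "tester.txt").read_text().strip()
    # tester rides along so allele coding stays consistent between parents
    combined = qc.GenotypeMatrix(
        np.vstack([lines.dosage, founders.line(tester_id)[None, :]]),
        lines.line_ids + [tester_id],
        lines.markers.copy(),
    )
    filtered = qc.filter_snps(
        combined,
        call_rate_min=qcfg.get("call_rate_min", 0.97),
        missing_rate_max=qcfg.get("missing_rate_max", 0.01),
        maf_min=qcfg.get("maf_min", 0.05),
    )
    report = filtered.filter_report
    imputed = qc.impute_missing(filtered, method=qcfg.get("impute_method", "major_allele"), seed=seed)
    coded = qc.code_alleles(imputed)
    n = coded.n_lines - 1
    line_part = coded.subset(lines=np.arange(n))
    tester_row = coded.dosage[n]
    hybrids = qc.infer_hybrid_genotypes(line_part, tester_row)
    hybrids.to_tsv(out / "Z.tsv", out / "W.tsv")
    with open(out / "qc_report.json", "w") as fh:
        json.dump({"n_input": report.n_input, "removed": report.removed,
                   "n_retained": report.n_retained}, fh, indent=2)
    return ["Z.tsv", "W.tsv", "qc_report.json"]


def _stage_structure(cfg, out: Path, seed: int) -> list[str]:
    _require(out, ["Z.tsv"], "structure", "qc")
    Z = qc.read_codes_tsv(out / "Z.tsv")
    pc = structure.pca(Z, n_components=cfg.get("structure", {}).get("n_components", 10))
    pc.scores.to_csv(out / "pca_scores.csv", index_label="line")
    pd.Series(pc.variance_explained, name="variance_explained").to_csv(
        out / "pca_variance.csv", index_label="component"
    )
    sim = structure.similarity_matrix(Z)
    sim.values.to_csv(out / "similarity.tsv", sep="\t", index_label="line")
    return ["pca_scores.csv", "pca_variance.csv", "similarity.tsv"]


def _stage_trial(cfg, out: Path, seed: int) -> list[str]:
    _require(out, ["phenotypes.csv"], "trial", "simulate")
    convention = cfg.get("trial", {}).get("convention", "paper")
    records = trial.read_phenotypes_csv(out / "phenotypes.csv")
    trial.fit_blue(records, scope="across_env").to_csv(out / "blues_across.csv")
    trial.fit_blue(records, scope="per_env").to_csv(out / "blues_per_env.csv")
    files = ["blues_across.csv", "blues_per_env.csv", "heritability.json"]
    herit = {}
    groups = {"all": records}
    pops_path = out / "line_populations.csv"
    if pops_path.exists():
        pops = pd.read_csv(pops_path, index_col=0)["population"]
        for pop, lids in pops.groupby(pops):
            sub = records.data[records.data["line"].isin(set(lids.index))]
            groups[pop] = trial.TrialRecords(sub.copy())
    for name, recs in groups.items():
        a = trial.anova_ms(recs, convention=convention)
        a.table.to_csv(out / f"anova_{name}.csv")
        files.append(f"anova_{name}.csv")
        herit[name] = round(trial.heritability(a), 2)
    with open(out / "heritability.json", "w") as fh:
        json.dump(herit, fh, indent=2)
    return files


def _stage_kinship(cfg, out: Path, seed: int) -> list[str]:
    _require(out, ["Z.tsv", "W.tsv"], "kinship", "qc")
    center = cfg.get("kinship", {}).get("center", False)
    Z = qc.read_codes_tsv(out / "Z.tsv")
    W = qc.read_codes_tsv(out / "W.tsv")
    kinship.additive_kinship(Z, center=center).to_tsv(out / "Ka.tsv")
    kinship.dominance_kinship(W, center=center).to_tsv(out / "Kd.tsv")
    return ["Ka.tsv", "Kd.tsv"]


def _stage_evaluate(cfg, out: Path, seed: int) -> list[str]:
    _require(out, ["Ka.tsv", "blues_across.csv", "blues_per_env.csv"], "evaluate", "kinship/trial")
    ecfg = cfg.get("evaluate", {})
    Ka = kinship.read_kinship_tsv(out / "Ka.tsv")
    Kd = kinship.read_kinship_tsv(out / "Kd.tsv", kind="dominance") if (out / "Kd.tsv").exists() else None
    blues_across = pd.read_csv(out / "blues_across.csv")
    y_across = pd.Series(blues_across["blue"].to_numpy(), index=blues_across["line"])
    per_env = pd.read_csv(out / "blues_per_env.csv")
    stacked = evaluate.StackedPhenotypes(per_env.rename(columns={"blue": "y"})[["line", "env", "y"]])
    pops = None
    if (out / "line_populations.csv").exists():
        pops = pd.read_csv(out / "line_populations.csv", index_col=0)["population"]

    default_reps = ecfg.get("n_repeats", 10)
    default_folds = ecfg.get("k_folds", 5)
    schemes = ecfg.get("schemes") or [{"scheme": "within", "model": "A"}]
    rows = []
    for i, sch in enumerate(schemes):
        name = sch["scheme"]
        model = sch.get("model", "A")
        spec = evaluate.SchemeSpec(
            scheme=name if name in ("within", "cv1", "cv2") else "within",
            model=model,
            k_folds=sch.get("k_folds", default_folds),
            n_repeats=sch.get("n_repeats", default_reps),
            seed=seed + i,
        )
        if name == "within":
            sel = sch.get("populations")
            ids = y_across.index if sel is None or pops is None else pops[pops.isin(sel)].index
            res = evaluate.run_within(y_across.loc[ids], Ka, Kd, model=model, spec=spec)
            label = "+".join(sel) if sel else "all"
            for _, r in res.per_repeat.iterrows():
                rows.append((name, model, label, "", r["repeat"], r["env"], r["pa"]))
        elif name in ("one_to_one", "three_to_one"):
            if pops is None:
                raise FileNotFoundError("population transfer schemes need line_populations.csv")
            pop_names = list(pd.unique(pops))
            combos = (
                [( [t], v) for t in pop_names for v in pop_names if t != v]
                if name == "one_to_one"
                else [([t for t in pop_names if t != v], v) for v in pop_names]
            )
            for train_pops, valid_pop in combos:
                pa = evaluate.run_transfer(
                    y_across,
                    pops[pops.isin(train_pops)].index,
                    pops[pops == valid_pop].index,
                    Ka,
                    Kd,
                    model=model,
                )
                rows.append((name, model, "+".join(train_pops), valid_pop, 0, "pooled", pa))
        elif name in ("cv1", "cv2"):
            res = evaluate.run_cv_multienv(
                stacked, Ka, model=model, scheme=name, spec=spec,
                target_env=sch.get("target_env"),
            )
            for _, r in res.per_repeat.iterrows():
                rows.append((name, model, "all", "", r["repeat"], r["env"], r["pa"]))
        else:
            raise ConfigError(f"unknown evaluation scheme {name!r}")
    result = pd.DataFrame(
        rows, columns=["scheme", "model", "train_set", "valid_set", "repeat", "env", "pa"]
    )
    result.to_csv(out / "evaluation.csv", index=False)
    summary = (
        result.groupby(["scheme", "model", "train_set", "valid_set", "env"])["pa"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary.to_csv(out / "evaluation_summary.csv", index=False)
    return ["evaluation.csv", "evaluation_summary.csv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "structure": _stage_structure,
    "trial": _stage_trial,
    "kinship": _stage_kinship,
    "evaluate": _stage_evaluate,
}


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the requested stages in dependency order; returns (and writes)
    the run manifest."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    requested = set(cfg.get("stages", list(STAGE_ORDER)))
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, seed=seed, version=__version__)
    for stage in STAGE_ORDER:
        if stage not in requested:
            manifest.stages[stage] = {"skipped": True}
            continue
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            files = _STAGE_FN[stage](cfg, out, seed)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {
            "skipped": False,
            "seconds": round(time.perf_counter() - t0, 3),
            "files": {f: _sha256(out / f) for f in files},
        }
        log.info("stage %s: done (%.1fs, %d files)", stage,
                 manifest.stages[stage]["seconds"], len(files))
    manifest.to_json(out / "manifest.json")
    return manifest
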