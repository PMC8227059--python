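"""Synthetic testcross study generator.

Builds fully homozygous founder inbreds on a centimorgan genome map, derives
structured line populations by explicit meiosis (backcross-derived, doubled
haploid, advanced selfing, and unrelated founder draws), testcrosses them to
a common tester, and simulates plot-level multi-environment yield trials with
controlled variance components.

Meiosis uses a no-interference (Haldane) model: crossover counts are Poisson
with mean equal to the chromosome length in Morgans, crossover positions
uniform on the genetic map.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix, HybridGenotypeSet, infer_hybrid_genotypes
from .trial import TrialRecords

__all__ = [
    "GenomeMap",
    "PedigreeSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_founders",
    "derive_population",
    "testcross",
    "simulate_phenotypes",
    "simulate_study",
    "draw_homozygous_lines",
    "default_config",
]

POPULATION_TYPES = ("bc1f3", "dh", "f45", "unrelated")


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation RNG derived from the study seed."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class GenomeMap:
    """Genetic map: marker positions in centimorgan per chromosome."""

    positions: tuple
    chrom_names: tuple

    def __post_init__(self):
        if len(self.positions) == 0:
            raise ValueError("genome map needs at least one chromosome")
        if len(self.positions) != len(self.chrom_names):
            raise ValueError("positions and chrom_names length mismatch")
        for pos in self.positions:
            p = np.asarray(pos)
            if p.ndim != 1 or p.size == 0:
                raise ValueError("each chromosome needs at least one marker position")
            if np.any(np.diff(p) <= 0):
                raise ValueError("marker positions must be strictly increasing")
            if np.any(p < 0):
                raise ValueError("marker positions must be non-negative")

    @classmethod
    def uniform(cls, n_chromosomes: int = 10, length_cm: float = 160.0, n_markers: int = 2000):
        """Evenly spaced markers over equally long chromosomes."""
        if n_markers < n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        per = np.full(n_chromosomes, n_markers // n_chromosomes)
        per[: n_markers % n_chromosomes] += 1
        positions = tuple(
            np.linspace(length_cm / (m + 1), length_cm * m / (m + 1), m) for m in per
        )
        names = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
        return cls(positions=positions, chrom_names=names)

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions))

    @property
    def chrom_lengths(self) -> np.ndarray:
        """Working chromosome lengths (cM): last marker position."""
        return np.array([float(np.asarray(p)[-1]) for p in self.positions])

    def chrom_slices(self) -> list[slice]:
        out, start = [], 0
        for p in self.positions:
            out.append(slice(start, start + len(p)))
            start += len(p)
        return out

    def marker_table(self) -> pd.DataFrame:
        chroms, pos = [], []
        for name, p in zip(self.chrom_names, self.positions):
            chroms.extend([name] * len(p))
            pos.extend(np.asarray(p, dtype=float))
        ids = [f"m{i + 1:05d}" for i in range(len(pos))]
        return pd.DataFrame(
            {"chrom": chroms, "pos_cM": pos}, index=pd.Index(ids, name="marker")
        )


@dataclass(frozen=True)
class PedigreeSpec:
    """How one line population is derived from named founder parents."""

    name: str
    population_type: str
    n_lines: int
    parents: tuple = ()
    tester: str | None = None

    def __post_init__(self):
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(
                f"unknown population_type {self.population_type!r}; "
                f"expected one of {POPULATION_TYPES}"
            )
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.population_type != "unrelated" and len(self.parents) != 2:
            raise ValueError(f"{self.population_type} populations need two parents")


@dataclass(frozen=True)
class SimulationConfig:
    genome: GenomeMap
    pedigrees: tuple
    tester: str = "T1"
    n_qtl: int = 200
    additive_effect_sd: float = 1.0
    dominance_effect_sd: float = 0.0
    mu: float = 700.0
    env_names: tuple = ("E1", "E2", "E3")
    env_means: tuple | None = None
    var_g: float = 1600.0
    var_ge: float = 700.0
    var_rep: float = 50.0
    var_error: float | tuple = 3300.0
    n_environments: int = 3
    n_replicates: int = 2
    maf_range: tuple = (0.05, 0.5)
    ge_structure: str = "iid"
    seed: int = 0

    def __post_init__(self):
        if self.n_qtl > self.genome.n_markers:
            raise ValueError("n_qtl exceeds marker count")
        errs = self.error_variances()
        for v in (self.var_g, self.var_ge, self.var_rep, *errs):
            if v < 0:
                raise ValueError("variance components must be non-negative")
        if len(self.env_names) != self.n_environments:
            raise ValueError("env_names length must equal n_environments")
        if self.env_means is not None and len(self.env_means) != self.n_environments:
            raise ValueError("env_means length must equal n_environments")
        if self.ge_structure not in ("iid", "genetic"):
            raise ValueError("ge_structure must be 'iid' or 'genetic'")

    def error_variances(self) -> np.ndarray:
        """Residual variance per environment (scalar configs are broadcast)."""
        v = np.atleast_1d(np.asarray(self.var_error, dtype=float))
        if v.size == 1:
            v = np.repeat(v, self.n_environments)
        if v.size != self.n_environments:
            raise ValueError("var_error must be scalar or one value per environment")
        return v


def default_config(
    n_markers: int = 2000,
    seed: int = 0,
    n_lines=(475, 72, 60, 68),
    **overrides,
) -> SimulationConfig:
    """Four-population testcross study: populations 1 and 2 derive from the
    same donor x recurrent cross (backcross-selfed and DH routes), population
    3 shares the donor parent in a biparental selfing series, population 4 is
    a set of unrelated homozygous materials."""
    genome = overrides.pop("genome", None) or GenomeMap.uniform(n_markers=n_markers)
    peds = (
        PedigreeSpec("pop1", "bc1f3", n_lines[0], parents=("P_donor", "P_recurrent")),
        PedigreeSpec("pop2", "dh", n_lines[1], parents=("P_donor", "P_recurrent")),
        PedigreeSpec("pop3", "f45", n_lines[2], parents=("P_donor", "P_third")),
        PedigreeSpec("pop4", "unrelated", n_lines[3]),
    )
    return SimulationConfig(genome=genome, pedigrees=peds, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# founders and meiosis


def draw_homozygous_lines(
    n_lines: int,
    freqs: np.ndarray,
    genome: GenomeMap,
    rng: np.random.Generator,
    prefix: str = "L",
) -> GenotypeMatrix:
    """Independent fully homozygous lines; each line carries allele 1 at a
    locus with probability ``freqs`` (both haplotypes identical)."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != genome.n_markers:
        raise ValueError("freqs length must equal marker count")
    alleles = (rng.random((n_lines, genome.n_markers)) < freqs).astype(np.int8)
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_lines)]
    return GenotypeMatrix(2 * alleles, ids, genome.marker_table())


def simulate_founders(config: SimulationConfig) -> GenotypeMatrix:
    """Homozygous founder parents (cross parents plus the tester) with
    population-level allele-1 frequencies uniform on ``maf_range``."""
    if config.genome.n_markers == 0:
        raise ValueError("genome has zero markers")
    names: list[str] = []
    for ped in config.pedigrees:
        for p in ped.parents:
            if p not in names:
                names.append(p)
    tester = config.tester
    if tester not in names:
        names.append(tester)
    rng = substream(config.seed, "founders")
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, config.genome.n_markers)
    alleles = (rng.random((len(names), config.genome.n_markers)) < freqs).astype(np.int8)
    return GenotypeMatrix(2 * alleles, names, config.genome.marker_table())


def _gamete(haps: np.ndarray, slices, lengths, rng) -> np.ndarray:
    """One recombinant gamete from a pair of haplotypes (Haldane model)."""
    out = np.empty(haps.shape[1], dtype=np.int8)
    for sl, length, pos in zip(slices, lengths[0], lengths[1]):
        n_xo = rng.poisson(length / 100.0)
        start = rng.integers(2)
        if n_xo == 0:
            out[sl] = haps[start, sl]
            continue
        xos = np.sort(rng.uniform(0.0, length, n_xo))
        which = (start + np.searchsorted(xos, pos)) % 2
        seg = haps[:, sl]
        out[sl] = np.where(which == 0, seg[0], seg[1])
    return out


class _Meiosis:
    """Caches per-chromosome geometry for repeated gamete sampling."""

    def __init__(self, genome: GenomeMap):
        self.slices = genome.chrom_slices()
        self.lengths = (
            genome.chrom_lengths,
            [np.asarray(p, dtype=float) for p in genome.positions],
        )

    def gamete(self, haps, rng):
        return _gamete(haps, self.slices, self.lengths, rng)

    def self_(self, haps, rng):
        return np.stack([self.gamete(haps, rng), self.gamete(haps, rng)])

    def cross(self, haps_a, haps_b, rng):
        return np.stack([self.gamete(haps_a, rng), self.gamete(haps_b, rng)])


def _founder_haplotype(founders: GenotypeMatrix, name: str) -> np.ndarray:
    if name not in founders.line_ids:
        raise ValueError(f"founder {name!r} not present in founder matrix")
    d = founders.line(name)
    if np.any(d == 1) or np.any(d == MISSING):
        raise ValueError(f"founder {name!r} is not fully homozygous")
    return (d // 2).astype(np.int8)


def derive_population(
    spec: PedigreeSpec,
    founders: GenotypeMatrix,
    genome: GenomeMap,
    seed: int,
) -> GenotypeMatrix:
    """Derive one line population from the founders by explicit meiosis.

    bc1f3: donor x recurrent F1, backcrossed to the recurrent parent; the
    bulked-pollen intercross step is approximated by crossing two independent
    BC1F1 plants, followed by one selfing.  dh: a doubled gamete from such a
    BC1F2 plant.  f45: biparental F1 selfed three times.  unrelated:
    independent homozygous founder draws.
    """
    rng = substream(seed, f"derive:{spec.name}")
    mei = _Meiosis(genome)
    ids = [f"{spec.name}_{i + 1:04d}" for i in range(spec.n_lines)]

    if spec.population_type == "unrelated":
        lo, hi = 0.05, 0.5
        freqs = rng.uniform(lo, hi, genome.n_markers)
        gm = draw_homozygous_lines(spec.n_lines, freqs, genome, rng, prefix=f"{spec.name}_")
        return GenotypeMatrix(gm.dosage, ids, genome.marker_table())

    donor, recurrent = spec.parents
    hd = _founder_haplotype(founders, donor)
    hr = _founder_haplotype(founders, recurrent)
    f1 = np.stack([hd, hr])

    def bc1f2_plant():
        bc1_a = np.stack([mei.gamete(f1, rng), hr])
        bc1_b = np.stack([mei.gamete(f1, rng), hr])
        return mei.cross(bc1_a, bc1_b, rng)

    rows = np.empty((spec.n_lines, genome.n_markers), dtype=np.int8)
    for i in range(spec.n_lines):
        if spec.population_type == "bc1f3":
            plant = mei.self_(bc1f2_plant(), rng)
        elif spec.population_type == "dh":
            gam = mei.gamete(bc1f2_plant(), rng)
            plant = np.stack([gam, gam])
        elif spec.population_type == "f45":
            plant = f1
            for _ in range(3):  # F1 -> F2 -> F3 -> F4
                plant = mei.self_(plant, rng)
        else:  # pragma: no cover - guarded by PedigreeSpec
            raise ValueError(f"unknown population_type {spec.population_type!r}")
        rows[i] = plant.sum(axis=0)
    return GenotypeMatrix(rows, ids, genome.marker_table())


def testcross(
    lines: GenotypeMatrix,
    founders: GenotypeMatrix,
    tester_id: str,
    seed: int | None = None,
) -> HybridGenotypeSet:
    """Expected additive/dominance codes of each line's hybrid with the
    tester (delegates to :func:`hybridgp.qc.infer_hybrid_genotypes`)."""
    if tester_id not in founders.line_ids:
        raise ValueError(f"tester {tester_id!r} not present in founders")
    return infer_hybrid_genotypes(lines, founders.line(tester_id))


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    hybrids: HybridGenotypeSet,
    config: SimulationConfig,
    populations: pd.Series | None = None,
    block_size: int = 60,
) -> TrialRecords:
    """Plot-level yields for every hybrid x environment x replicate.

    Genetic values are built from sampled QTL (additive plus optional
    dominance action on the hybrid codes) and rescaled to the configured
    genetic variance; environment offsets are fixed, while genotype-by-
    environment, replicate-within-environment, and residual terms are drawn
    with the configured variances.
    """
    rng = substream(config.seed, "phenotypes")
    Z = hybrids.Z.to_numpy(dtype=float)
    W = hybrids.W.to_numpy(dtype=float)
    n, m = Z.shape
    e, r = config.n_environments, config.n_replicates

    qtl = rng.choice(m, size=config.n_qtl, replace=False)
    a = rng.normal(0.0, config.additive_effect_sd, config.n_qtl)
    g = Z[:, qtl] @ a
    if config.dominance_effect_sd > 0:
        d = rng.normal(0.0, config.dominance_effect_sd, config.n_qtl)
        g = g + W[:, qtl] @ d
    g = g - g.mean()
    sd = g.std(ddof=1) if n > 1 else 0.0
    if config.var_g > 0:
        if sd == 0:
            warnings.warn("genetic values degenerate; var_g target not reachable")
        else:
            g = g * (np.sqrt(config.var_g) / sd)
    else:
        g = np.zeros(n)

    env_off = (
        np.zeros(e) if config.env_means is None else np.asarray(config.env_means, float)
    )
    if config.var_ge <= 0:
        ge = np.zeros((n, e))
    elif config.ge_structure == "iid":
        ge = rng.normal(0.0, np.sqrt(config.var_ge), (n, e))
    else:
        # genetically structured interaction: env-specific QTL effect
        # deviations, so the specific term is predictable through kinship
        ge = np.empty((n, e))
        for j in range(e):
            bj = rng.normal(0.0, config.additive_effect_sd, config.n_qtl)
            gj = Z[:, qtl] @ bj
            gj = gj - gj.mean()
            sdj = gj.std(ddof=1) if n > 1 else 0.0
            ge[:, j] = gj * (np.sqrt(config.var_ge) / sdj) if sdj > 0 else 0.0
    rep_eff = (
        rng.normal(0.0, np.sqrt(config.var_rep), (e, r)) if config.var_rep > 0 else np.zeros((e, r))
    )
    err_sd = np.sqrt(config.error_variances())

    line_ids = hybrids.line_ids
    if populations is None:
        populations = pd.Series("all", index=line_ids)
    blocks = {}
    for pop, grp in populations.groupby(populations, sort=False):
        for j, lid in enumerate(grp.index):
            blocks[lid] = f"{pop}_b{j // block_size + 1}"

    rows = []
    for j, env in enumerate(config.env_names):
        eps = rng.normal(0.0, err_sd[j], (n, r))
        for k in range(r):
            y = config.mu + g + env_off[j] + ge[:, j] + rep_eff[j, k] + eps[:, k]
            for i, lid in enumerate(line_ids):
                rows.append((lid, env, k + 1, blocks[lid], y[i]))
    data = pd.DataFrame(rows, columns=["line", "env", "rep", "block", "yield"])
    return TrialRecords(
        data=data,
        true_genetic=pd.Series(config.mu + g, index=pd.Index(line_ids, name="line")),
    )


# ---------------------------------------------------------------------------
# end-to-end study


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    founders: GenotypeMatrix
    populations: dict
    lines: GenotypeMatrix
    line_populations: pd.Series
    hybrids: HybridGenotypeSet
    records: TrialRecords


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generative chain: founders -> populations -> testcross
    hybrids -> multi-environment trial records."""
    founders = simulate_founders(config)
    pops: dict[str, GenotypeMatrix] = {}
    for ped in config.pedigrees:
        pops[ped.name] = derive_population(ped, founders, config.genome, config.seed)
    dosage = np.vstack([p.dosage for p in pops.values()])
    ids = [lid for p in pops.values() for lid in p.line_ids]
    lines = GenotypeMatrix(dosage, ids, config.genome.marker_table())
    line_pops = pd.Series(
        {lid: name for name, p in pops.items() for lid in p.line_ids}, name="population"
    ).loc[ids]
    hybrids = testcross(lines, founders, config.tester)
    records = simulate_phenotypes(hybrids, config, populations=line_pops)
    return SimulatedStudy(
        config=config,
        founders=founders,
        populations=pops,
        lines=lines,
        line_populations=line_pops,
        hybrids=hybrids,
        records=records,
    )
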