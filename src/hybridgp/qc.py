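"""SNP quality control, allele coding, and testcross hybrid genotype codes.

Genotype calls are held as dosages of a per-marker reference allele
(0, 1, 2; -1 for missing).  ``filter_snps`` applies the chip QC rules in a
fixed order, ``impute_missing`` provides simple stand-in imputers,
``code_alleles`` recodes every marker to count its minor allele, and
``infer_hybrid_genotypes`` produces the additive/dominance codes of
line-by-tester hybrids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "HybridGenotypeSet",
    "FilterReport",
    "filter_snps",
    "impute_missing",
    "code_alleles",
    "infer_hybrid_genotypes",
    "read_genotypes_tsv",
    "read_codes_tsv",
    "read_vcf",
]

MISSING = -1

_CALL_TO_DOSAGE = {"AA": 2, "Aa": 1, "aA": 1, "aa": 0, "NA": MISSING, "": MISSING}
_DOSAGE_TO_CALL = {2: "AA", 1: "Aa", 0: "aa", MISSING: "NA"}


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a set of lines.

    ``dosage[i, m]`` counts copies of marker *m*'s first allele carried by
    line *i* (-1 = missing).  ``markers`` is indexed by marker id and carries
    at least ``chrom`` and ``pos_cM`` columns (NaN position = unknown).
    """

    dosage: np.ndarray
    line_ids: list[str]
    markers: pd.DataFrame
    filter_report: "FilterReport | None" = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (lines x markers)")
        if self.dosage.shape[0] != len(self.line_ids):
            raise ValueError("dosage rows do not match line_ids")
        if self.dosage.shape[1] != len(self.markers):
            raise ValueError("dosage columns do not match marker table")
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage entries must be in {-1, 0, 1, 2}")
        if self.markers.index.has_duplicates:
            raise ValueError("duplicate marker ids")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")

    # -- basic properties -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def missing_rate(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def call_rate(self) -> np.ndarray:
        """Per-marker call rate: the assay-level ``call_rate`` metadata column
        when present, otherwise the observed fraction of non-missing calls."""
        if "call_rate" in self.markers.columns:
            return self.markers["call_rate"].to_numpy(dtype=float)
        return 1.0 - self.missing_rate()

    def allele_freq(self) -> np.ndarray:
        """Frequency of the first allele among non-missing calls."""
        d = np.where(self.dosage == MISSING, np.nan, self.dosage.astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def heterozygosity(self) -> np.ndarray:
        """Per-line fraction of heterozygous calls among non-missing ones."""
        obs = self.dosage != MISSING
        het = self.dosage == 1
        with np.errstate(invalid="ignore"):
            return het.sum(axis=1) / obs.sum(axis=1)

    # -- subsetting -------------------------------------------------------
    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(li, mi)].copy(),
            line_ids=[self.line_ids[i] for i in li],
            markers=self.markers.iloc[mi].copy(),
        )

    def line(self, line_id: str) -> np.ndarray:
        return self.dosage[self.line_ids.index(line_id)]

    # -- IO ---------------------------------------------------------------
    def calls_frame(self) -> pd.DataFrame:
        """Lines x markers string calls (AA/Aa/aa/NA)."""
        mapped = np.vectorize(_DOSAGE_TO_CALL.get)(self.dosage)
        return pd.DataFrame(mapped, index=self.line_ids, columns=self.markers.index)

    def to_tsv(self, genotype_path, marker_path=None) -> None:
        self.calls_frame().to_csv(genotype_path, sep="\t", index_label="line")
        if marker_path is not None:
            self.markers.to_csv(marker_path, sep="\t", index_label="marker")


@dataclass
class FilterReport:
    """Per-rule removal counts of :func:`filter_snps`, in application order."""

    n_input: int
    removed: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())


@dataclass
class HybridGenotypeSet:
    """Additive (Z) and dominance (W) codes of line-by-tester hybrids.

    Z entries live in [-1, 1] (half the sum of the parental additive codes);
    W entries in [0, 1] (expected heterozygosity of the hybrid at the locus).
    """

    Z: pd.DataFrame
    W: pd.DataFrame

    def __post_init__(self):
        if self.Z.shape != self.W.shape:
            raise ValueError("Z and W must have identical shape")
        if not (self.Z.index.equals(self.W.index) and self.Z.columns.equals(self.W.columns)):
            raise ValueError("Z and W must share index and columns")
        z = self.Z.to_numpy()
        w = self.W.to_numpy()
        if np.nanmin(z) < -1 - 1e-9 or np.nanmax(z) > 1 + 1e-9:
            raise ValueError("Z entries must lie in [-1, 1]")
        if np.nanmin(w) < -1e-9 or np.nanmax(w) > 1 + 1e-9:
            raise ValueError("W entries must lie in [0, 1]")

    @property
    def line_ids(self) -> list[str]:
        return list(self.Z.index)

    def to_tsv(self, z_path, w_path) -> None:
        self.Z.to_csv(z_path, sep="\t", index_label="line")
        self.W.to_csv(w_path, sep="\t", index_label="line")


# ---------------------------------------------------------------------------
# operations


def filter_snps(
    raw: GenotypeMatrix,
    call_rate_min: float = 0.97,
    missing_rate_max: float = 0.01,
    maf_min: float = 0.05,
    require_position: bool = True,
) -> GenotypeMatrix:
    """Apply the chip QC rules in order: call rate, position, missing rate,
    minor allele frequency.  A removal count per rule is attached to the
    result as ``filter_report``; raises if no marker survives."""
    if raw.n_markers == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(n_input=raw.n_markers)
    keep = np.ones(raw.n_markers, dtype=bool)

    bad = keep & (raw.call_rate() < call_rate_min)
    report.removed["call_rate"] = int(bad.sum())
    keep &= ~bad

    if require_position:
        pos = raw.markers.get("pos_cM")
        if pos is None:
            bad = keep.copy()
        else:
            has_chrom = raw.markers["chrom"].notna().to_numpy() if "chrom" in raw.markers else np.ones(raw.n_markers, bool)
            bad = keep & ~(pos.notna().to_numpy() & has_chrom)
        report.removed["no_position"] = int(bad.sum())
        keep &= ~bad
    else:
        report.removed["no_position"] = 0

    bad = keep & (raw.missing_rate() > missing_rate_max)
    report.removed["missing_rate"] = int(bad.sum())
    keep &= ~bad

    maf = raw.maf()
    with np.errstate(invalid="ignore"):
        bad = keep & (np.nan_to_num(maf, nan=0.0) < maf_min)
    report.removed["maf"] = int(bad.sum())
    keep &= ~bad

    if not keep.any():
        raise ValueError(f"no markers survive QC; removals per rule: {report.removed}")
    out = raw.subset(markers=np.flatnonzero(keep))
    out.filter_report = report
    return out


def impute_missing(
    g: GenotypeMatrix, method: str = "major_allele", seed: int | None = None
) -> GenotypeMatrix:
    """Fill residual missing calls.

    ``major_allele`` uses each marker's most frequent call; ``freq_sample``
    draws from the observed call frequencies (seed required for
    reproducibility).  This is a documented stand-in for haplotype-based
    imputation, adequate at post-QC missing rates of at most a few percent.
    """
    dosage = g.dosage.copy()
    miss_cols = np.flatnonzero((dosage == MISSING).any(axis=0))
    if miss_cols.size == 0:
        return GenotypeMatrix(dosage, list(g.line_ids), g.markers.copy())
    if method == "freq_sample":
        if seed is None:
            raise ValueError("freq_sample imputation requires a seed")
        rng = np.random.default_rng(seed)
    elif method != "major_allele":
        raise ValueError(f"unknown imputation method: {method!r}")
    for m in miss_cols:
        col = dosage[:, m]
        observed = col[col != MISSING]
        if observed.size == 0:
            raise ValueError(f"marker {g.markers.index[m]!r} has no observed calls")
        counts = np.bincount(observed, minlength=3)
        miss = col == MISSING
        if method == "major_allele":
            col[miss] = int(np.argmax(counts))
        else:
            col[miss] = rng.choice(3, size=int(miss.sum()), p=counts / counts.sum())
    return GenotypeMatrix(dosage, list(g.line_ids), g.markers.copy())


def code_alleles(g: GenotypeMatrix) -> GenotypeMatrix:
    """Recode every marker so its dosage counts the minor allele (labelled
    'A'); the major allele is labelled 'a'.  The line additive code is then
    dosage - 1: AA -> 1, Aa -> 0, aa -> -1.  Ties at MAF exactly 0.5 keep the
    lexicographically smaller allele label as minor."""
    dosage = g.dosage.copy()
    markers = g.markers.copy()
    a1 = markers["allele1"].astype(str).to_numpy() if "allele1" in markers else np.full(g.n_markers, "A")
    a2 = markers["allele2"].astype(str).to_numpy() if "allele2" in markers else np.full(g.n_markers, "a")
    p = g.allele_freq()

    mono = (p <= 0.0) | (p >= 1.0) | ~np.isfinite(p)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic marker(s) passed to code_alleles",
            stacklevel=2,
        )
    flip = p > 0.5
    tie = np.isclose(p, 0.5)
    flip[tie] = a2[tie] < a1[tie]

    miss = dosage == MISSING
    dosage[:, flip] = 2 - dosage[:, flip]
    dosage[miss] = MISSING
    minor = np.where(flip, a2, a1)
    major = np.where(flip, a1, a2)
    markers["minor_allele"] = minor
    markers["major_allele"] = major
    markers["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(dosage, list(g.line_ids), markers)


def additive_codes(g: GenotypeMatrix) -> pd.DataFrame:
    """Line additive codes (dosage - 1) as a lines x markers frame; missing
    calls become NaN."""
    x = g.dosage.astype(float) - 1.0
    x[g.dosage == MISSING] = np.nan
    return pd.DataFrame(x, index=g.line_ids, columns=g.markers.index)


def infer_hybrid_genotypes(lines: GenotypeMatrix, tester) -> HybridGenotypeSet:
    """Code hybrids of each line with a common homozygous tester.

    The additive code is the mean of the two parental additive codes
    (e.g. Aa x AA -> (0 + 1)/2 = 0.5, Aa x aa -> -0.5); the dominance code is
    the expected heterozygosity of the hybrid at the locus (both segregating
    mating types -> 0.5; AA x aa -> 1; matched homozygotes -> 0).
    """
    t = np.asarray(tester, dtype=float).ravel()
    if t.shape[0] != lines.n_markers:
        raise ValueError("tester genotype length does not match marker count")
    if np.any(t == MISSING) or np.any(~np.isin(t, [0.0, 2.0])):
        raise ValueError("tester must be homozygous and fully called at every locus")
    if (lines.dosage == MISSING).any():
        raise ValueError("impute missing calls before inferring hybrid genotypes")
    x_line = lines.dosage.astype(float) - 1.0
    x_tester = t - 1.0
    Z = (x_line + x_tester[None, :]) / 2.0
    p_line = lines.dosage.astype(float) / 2.0
    p_tester = t / 2.0
    W = p_line * (1.0 - p_tester[None, :]) + (1.0 - p_line) * p_tester[None, :]
    idx = pd.Index(lines.line_ids, name="line")
    cols = lines.markers.index
    return HybridGenotypeSet(
        Z=pd.DataFrame(Z, index=idx, columns=cols),
        W=pd.DataFrame(W, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# readers


def read_genotypes_tsv(genotype_path, marker_path=None) -> GenotypeMatrix:
    """Read a lines x markers call table (AA/Aa/aa/NA) with an optional
    marker metadata sidecar (marker, chrom, pos_cM, ...)."""
    calls = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
    calls = calls.fillna("NA")
    try:
        dosage = calls.map(lambda c: _CALL_TO_DOSAGE[c]).to_numpy(dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unrecognized genotype call {exc.args[0]!r}") from exc
    if marker_path is not None:
        markers = pd.read_csv(marker_path, sep="\t", index_col=0)
        markers = markers.reindex(calls.columns)
    else:
        markers = pd.DataFrame(
            {"chrom": pd.NA, "pos_cM": np.nan}, index=calls.columns
        )
    markers.index.name = "marker"
    return GenotypeMatrix(dosage, [str(s) for s in calls.index], markers)


def read_codes_tsv(path) -> pd.DataFrame:
    """Read a lines x markers numeric code table (Z or W)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (GT field, diploid).  The reference
    allele is allele 1 of the dosage."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, index, chroms, pos = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        dosage = np.select(
            [gt == 0, gt == 1, gt == 3], [2, 1, 0], default=MISSING
        ).astype(np.int8)
        rows.append(dosage)
        index.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(float(var.POS))
    if not rows:
        raise ValueError("no biallelic SNPs found in VCF")
    markers = pd.DataFrame({"chrom": chroms, "pos_cM": pos}, index=pd.Index(index, name="marker"))
    return GenotypeMatrix(np.vstack(rows).T, samples, markers)
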