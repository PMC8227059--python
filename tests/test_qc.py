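import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridgp import qc
from hybridgp.qc import (
    MISSING,
    GenotypeMatrix,
    code_alleles,
    filter_snps,
    impute_missing,
    infer_hybrid_genotypes,
    read_genotypes_tsv,
)


def matrix(dosages, chrom="chr1", pos=None, **marker_cols):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_markers = dosages.shape[1]
    if pos is None:
        pos = np.arange(1.0, n_markers + 1)
    markers = pd.DataFrame(
        {"chrom": chrom, "pos_cM": pos, **marker_cols},
        index=pd.Index([f"m{i}" for i in range(n_markers)], name="marker"),
    )
    ids = [f"l{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, ids, markers)


class TestFilterSnps:
    def test_low_maf_marker_removed(self):
        # 4 good markers, one with MAF 0.02 (1 minor allele in 25 lines)
        rng = np.random.default_rng(0)
        good = rng.choice([0, 2], size=(25, 4))
        bad = np.zeros((25, 1), dtype=np.int8)
        bad[0, 0] = 1  # MAF = 1/50 = 0.02
        g = matrix(np.hstack([good, bad]))
        out = filter_snps(g)
        assert out.n_markers == 4
        assert out.filter_report.removed["maf"] == 1

    def test_missing_rate_rule(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0, 2], size=(100, 2))
        d[:2, 1] = MISSING  # missing rate 0.02 > 0.01
        out = filter_snps(matrix(d), call_rate_min=0.0)
        assert out.n_markers == 1
        assert out.filter_report.removed["missing_rate"] == 1

    def test_call_rate_metadata_rule(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0, 2], size=(10, 3))
        g = matrix(d, call_rate=[0.99, 0.95, 0.98])
        out = filter_snps(g)
        assert out.filter_report.removed["call_rate"] == 1
        assert out.n_markers == 2

    def test_position_required(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0, 2], size=(10, 3))
        g = matrix(d, pos=[1.0, np.nan, 3.0])
        out = filter_snps(g)
        assert out.filter_report.removed["no_position"] == 1

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(4)
        d = rng.choice([0, 2], size=(40, 6))
        d[:15, :] = 2 - d[:15, :]  # guarantee polymorphism
        g = matrix(d)
        out = filter_snps(g)
        assert np.array_equal(out.dosage, g.dosage)
        assert list(out.markers.index) == list(g.markers.index)

    def test_nothing_survives_raises_with_counts(self):
        d = np.zeros((10, 2), dtype=np.int8)  # monomorphic: MAF 0
        with pytest.raises(ValueError, match="maf"):
            filter_snps(matrix(d))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.choice([0, 1, 2, MISSING], size=(30, 8), p=[0.4, 0.1, 0.4, 0.1]).astype(np.int8)
        g = matrix(d)
        try:
            once = filter_snps(g)
        except ValueError:
            return
        twice = filter_snps(once)
        assert np.array_equal(once.dosage, twice.dosage)
        assert list(once.markers.index) == list(twice.markers.index)


class TestImpute:
    def test_major_allele_fill(self):
        d = np.array([[2]] * 9 + [[0]] + [[MISSING]], dtype=np.int8)
        out = impute_missing(matrix(d))
        assert out.dosage[10, 0] == 2

    def test_no_missing_unchanged(self):
        d = np.array([[2, 0], [0, 2]], dtype=np.int8)
        out = impute_missing(matrix(d))
        assert np.array_equal(out.dosage, d)

    def test_freq_sample_reproducible(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0, 2, MISSING], size=(50, 4), p=[0.45, 0.45, 0.1]).astype(np.int8)
        a = impute_missing(matrix(d), method="freq_sample", seed=11)
        b = impute_missing(matrix(d), method="freq_sample", seed=11)
        assert np.array_equal(a.dosage, b.dosage)
        assert not np.any(a.dosage == MISSING)

    def test_freq_sample_requires_seed(self):
        d = np.array([[2], [MISSING]], dtype=np.int8)
        with pytest.raises(ValueError, match="seed"):
            impute_missing(matrix(d), method="freq_sample")

    def test_all_missing_marker_errors(self):
        d = np.full((4, 1), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="no observed calls"):
            impute_missing(matrix(d))


class TestCodeAlleles:
    def test_minor_allele_becomes_dosage_reference(self):
        # allele1 frequency 0.7 -> allele2 is minor, dosages flip
        d = np.array([[2]] * 7 + [[0]] * 3, dtype=np.int8)
        out = code_alleles(matrix(d))
        assert out.dosage[0, 0] == 0  # former major-hom becomes aa
        assert out.dosage[9, 0] == 2
        assert out.markers["maf"].iloc[0] == pytest.approx(0.3)

    def test_additive_codes_mapping(self):
        d = np.array([[2], [1], [0]], dtype=np.int8)
        g = matrix(d)
        # allele1 freq = 0.5: tie broken lexicographically ('A' < 'a' stays)
        out = code_alleles(g)
        codes = qc.additive_codes(out)
        assert list(codes.iloc[:, 0]) == [1.0, 0.0, -1.0]

    def test_tie_break_lexicographic(self):
        d = np.array([[2], [0]], dtype=np.int8)
        g = matrix(d, allele1="G", allele2="C")
        out = code_alleles(g)
        # freq 0.5 tie: 'C' < 'G' so allele2 is designated minor -> flip
        assert out.markers["minor_allele"].iloc[0] == "C"
        assert out.dosage[0, 0] == 0

    def test_monomorphic_warns(self):
        d = np.array([[2], [2]], dtype=np.int8)
        with pytest.warns(UserWarning, match="monomorphic"):
            code_alleles(matrix(d))


class TestHybridCodes:
    def test_segregating_line_codes(self):
        # Aa x AA -> additive (0+1)/2 = 0.5; Aa x aa -> (0-1)/2 = -0.5;
        # both give dominance 0.5
        lines = matrix(np.array([[1, 1]], dtype=np.int8))
        tester = np.array([2, 0])
        hyb = infer_hybrid_genotypes(lines, tester)
        assert hyb.Z.iloc[0, 0] == 0.5 and hyb.Z.iloc[0, 1] == -0.5
        assert hyb.W.iloc[0, 0] == 0.5 and hyb.W.iloc[0, 1] == 0.5

    def test_all_six_mating_types_match_mendelian_enumeration(self):
        # enumerate offspring of every parental gamete pair per mating type
        def enumerate_cross(line_dosage, tester_dosage):
            line_gametes = {0: [0], 1: [0, 1], 2: [1]}[line_dosage]
            tester_allele = tester_dosage // 2
            adds, hets = [], []
            for ga in line_gametes:
                off = ga + tester_allele
                adds.append(off - 1.0)
                hets.append(1.0 if off == 1 else 0.0)
            return np.mean(adds), np.mean(hets)

        for line_d in (0, 1, 2):
            for tester_d in (0, 2):
                lines = matrix(np.array([[line_d]], dtype=np.int8))
                hyb = infer_hybrid_genotypes(lines, np.array([tester_d]))
                exp_add, exp_het = enumerate_cross(line_d, tester_d)
                assert hyb.Z.iloc[0, 0] == pytest.approx(exp_add)
                assert hyb.W.iloc[0, 0] == pytest.approx(exp_het)

    def test_w_zero_for_matched_homozygotes(self):
        lines = matrix(np.array([[2, 0]], dtype=np.int8))
        hyb = infer_hybrid_genotypes(lines, np.array([2, 0]))
        assert (hyb.W.to_numpy() == 0).all()

    def test_heterozygous_tester_rejected(self):
        lines = matrix(np.array([[2]], dtype=np.int8))
        with pytest.raises(ValueError, match="homozygous"):
            infer_hybrid_genotypes(lines, np.array([1]))

    def test_missing_line_calls_rejected(self):
        lines = matrix(np.array([[MISSING]], dtype=np.int8))
        with pytest.raises(ValueError, match="impute"):
            infer_hybrid_genotypes(lines, np.array([2]))


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        d = rng.choice([0, 1, 2, MISSING], size=(5, 4)).astype(np.int8)
        g = matrix(d)
        g.to_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
        back = read_genotypes_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
        assert np.array_equal(back.dosage, g.dosage)
        assert back.line_ids == g.line_ids
        assert list(back.markers["chrom"]) == list(g.markers["chrom"])

    def test_codes_tsv_round_trip(self, tmp_path):
        lines = matrix(np.array([[1, 2], [0, 1]], dtype=np.int8))
        hyb = infer_hybrid_genotypes(lines, np.array([2, 2]))
        hyb.to_tsv(tmp_path / "Z.tsv", tmp_path / "W.tsv")
        Z = qc.read_codes_tsv(tmp_path / "Z.tsv")
        pd.testing.assert_frame_equal(Z, hyb.Z, check_names=False)

    def test_bad_call_string_rejected(self, tmp_path):
        (tmp_path / "g.tsv").write_text("line\tm0\nl0\tXX\n")
        with pytest.raises(ValueError, match="XX"):
            read_genotypes_tsv(tmp_path / "g.tsv")


class TestVCF:
    def test_read_biallelic_snps(self, tmp_path):
        pytest.importorskip("cyvcf2")
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t0/0\n"
        )
        g = qc.read_vcf(vcf)
        assert g.line_ids == ["s1", "s2", "s3"]
        assert list(g.dosage[:, 0]) == [2, 1, 0]
        assert list(g.dosage[:, 1]) == [2, MISSING, 2]
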