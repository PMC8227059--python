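import numpy as np
import pandas as pd
import pytest

from hybridgp import simulate, trial
from hybridgp.qc import GenotypeMatrix
from hybridgp.simulate import (
    GenomeMap,
    PedigreeSpec,
    SimulationConfig,
    derive_population,
    draw_homozygous_lines,
    simulate_founders,
    simulate_phenotypes,
    simulate_study,
    substream,
)
from hybridgp.simulate import testcross as make_testcross


def tiny_config(**overrides):
    return simulate.default_config(
        n_markers=200, seed=7, n_lines=(30, 20, 20, 20), n_qtl=50, **overrides
    )


class TestGenomeMap:
    def test_uniform_counts(self):
        g = GenomeMap.uniform(n_chromosomes=10, length_cm=160, n_markers=1003)
        assert g.n_chromosomes == 10
        assert g.n_markers == 1003
        assert len(g.marker_table()) == 1003

    def test_positions_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GenomeMap(positions=(np.array([1.0, 1.0, 2.0]),), chrom_names=("chr1",))

    def test_zero_marker_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeMap(positions=(np.array([]),), chrom_names=("chr1",))


class TestFounders:
    def test_founders_fully_homozygous(self):
        cfg = tiny_config()
        founders = simulate_founders(cfg)
        assert not np.any(founders.dosage == 1)
        assert not np.any(founders.dosage == -1)

    def test_same_seed_identical(self):
        cfg = tiny_config()
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        assert np.array_equal(a.dosage, b.dosage)
        assert a.line_ids == b.line_ids

    def test_realized_maf_binomial_oracle(self):
        # 10,000 independent homozygous lines at allele frequency 0.3: the
        # realized frequency is a binomial mean, so it must land within 3
        # standard errors of the target.
        genome = GenomeMap.uniform(n_chromosomes=2, length_cm=100, n_markers=4)
        target = 0.3
        n = 10_000
        lines = draw_homozygous_lines(
            n, np.full(4, target), genome, np.random.default_rng(42)
        )
        freq = lines.dosage.mean(axis=0) / 2.0
        se = np.sqrt(target * (1 - target) / n)
        assert np.all(np.abs(freq - target) < 3 * se)

    def test_zero_markers_error(self):
        with pytest.raises(ValueError):
            GenomeMap(positions=(), chrom_names=())


class TestDerivePopulation:
    def test_unknown_population_type(self):
        with pytest.raises(ValueError, match="population_type"):
            PedigreeSpec("x", "ssd", 5, parents=("a", "b"))

    def test_dh_lines_homozygous(self):
        cfg = tiny_config()
        founders = simulate_founders(cfg)
        spec = PedigreeSpec("dhpop", "dh", 30, parents=("P_donor", "P_recurrent"))
        pop = derive_population(spec, founders, cfg.genome, seed=3)
        assert not np.any(pop.dosage == 1)

    def test_bc1f3_recurrent_share(self):
        # one backcross leaves an expected 75% recurrent-parent allele share
        cfg = tiny_config()
        founders = simulate_founders(cfg)
        spec = PedigreeSpec("bc", "bc1f3", 2000, parents=("P_donor", "P_recurrent"))
        pop = derive_population(spec, founders, cfg.genome, seed=9)
        rec = founders.line("P_recurrent").astype(float) / 2.0
        don = founders.line("P_donor").astype(float) / 2.0
        seg = rec != don
        # share of the recurrent allele at loci where the parents differ
        dos_rec = np.where(rec[seg] == 1, pop.dosage[:, seg], 2 - pop.dosage[:, seg])
        share_per_line = dos_rec.mean(axis=1) / 2.0
        se = share_per_line.std(ddof=1) / np.sqrt(len(share_per_line))
        assert abs(share_per_line.mean() - 0.75) < 3 * se + 0.005

    def test_f4_heterozygosity_one_eighth(self):
        # brute-force selfing recursion: P(het) halves per generation, so an
        # initially segregating locus is heterozygous in F4 with prob (1/2)^3
        p_het = 1.0
        for _ in range(3):  # F1 -> F2 -> F3 -> F4
            p_het *= 0.5
        assert p_het == 0.125

        cfg = tiny_config()
        founders = simulate_founders(cfg)
        spec = PedigreeSpec("f4", "f45", 1500, parents=("P_donor", "P_third"))
        pop = derive_population(spec, founders, cfg.genome, seed=21)
        seg = founders.line("P_donor") != founders.line("P_third")
        het = (pop.dosage[:, seg] == 1).mean()
        se = np.sqrt(p_het * (1 - p_het) / (pop.n_lines * seg.sum()))
        # markers within a line are linked, so allow a generous multiple
        assert abs(het - p_het) < 10 * se

    def test_unrelated_lines_homozygous(self):
        cfg = tiny_config()
        founders = simulate_founders(cfg)
        spec = PedigreeSpec("u", "unrelated", 25)
        pop = derive_population(spec, founders, cfg.genome, seed=2)
        assert not np.any(pop.dosage == 1)
        assert pop.n_lines == 25

    def test_missing_founder_error(self):
        cfg = tiny_config()
        founders = simulate_founders(cfg)
        spec = PedigreeSpec("bad", "dh", 5, parents=("nobody", "P_recurrent"))
        with pytest.raises(ValueError, match="nobody"):
            derive_population(spec, founders, cfg.genome, seed=0)


class TestTestcross:
    def _matrix(self, dosages):
        dosages = np.asarray(dosages, dtype=np.int8)
        markers = pd.DataFrame(
            {"chrom": "chr1", "pos_cM": np.arange(1.0, dosages.shape[1] + 1)},
            index=pd.Index([f"m{i}" for i in range(dosages.shape[1])], name="marker"),
        )
        ids = [f"l{i}" for i in range(dosages.shape[0])]
        return GenotypeMatrix(dosages, ids, markers)

    def test_homozygous_mating_codes(self):
        lines = self._matrix([[2], [0]])
        founders = self._matrix([[2]])
        founders.line_ids[0] = "T"
        hyb = make_testcross(lines, founders, "T")
        # AA x AA -> all-AA hybrid; aa x AA -> all-Aa hybrid
        assert hyb.Z.iloc[0, 0] == 1.0 and hyb.W.iloc[0, 0] == 0.0
        assert hyb.Z.iloc[1, 0] == 0.0 and hyb.W.iloc[1, 0] == 1.0

    def test_het_line_expected_codes_match_mendelian_enumeration(self):
        # Aa x AA offspring are half AA, half Aa: additive mean
        # (1 + 0) / 2 = 0.5, heterozygote share 0.5
        offspring_additive = [1.0, 0.0]
        offspring_het = [0.0, 1.0]
        assert np.mean(offspring_additive) == 0.5
        assert np.mean(offspring_het) == 0.5
        lines = self._matrix([[1]])
        founders = self._matrix([[2]])
        founders.line_ids[0] = "T"
        hyb = make_testcross(lines, founders, "T")
        assert hyb.Z.iloc[0, 0] == 0.5
        assert hyb.W.iloc[0, 0] == 0.5

    def test_heterozygous_tester_rejected(self):
        lines = self._matrix([[2]])
        founders = self._matrix([[1]])
        founders.line_ids[0] = "T"
        with pytest.raises(ValueError, match="homozygous"):
            make_testcross(lines, founders, "T")


class TestPhenotypes:
    def test_noise_free_replicates_identical(self):
        cfg = tiny_config(var_ge=0.0, var_rep=0.0, var_error=0.0)
        study = simulate_study(cfg)
        wide = study.records.data.pivot_table(
            index="line", columns=["env", "rep"], values="yield"
        )
        per_env = wide.T.groupby(level="env").std()
        assert float(per_env.max().max()) < 1e-9

    def test_noise_free_heritability_is_one(self):
        cfg = tiny_config(var_ge=0.0, var_rep=0.0, var_error=0.0)
        study = simulate_study(cfg)
        a = trial.anova_ms(study.records, convention="classical")
        assert trial.heritability(a) == pytest.approx(1.0, abs=1e-9)

    def test_reference_population_sizes(self):
        cfg = simulate.default_config(
            n_markers=200, seed=1, n_lines=(475, 72, 60, 68), n_qtl=50
        )
        study = simulate_study(cfg)
        assert study.lines.n_lines == 675
        assert len(study.records.data) == 675 * 3 * 2

    def test_h2_converges_to_design_formula(self):
        # var_g=1, var_ge=0.5, var_err=1 with e=3, r=2 gives
        # H2 = 1 / (1 + 0.5/3 + 1/6) = 0.75
        genome = GenomeMap.uniform(n_chromosomes=5, length_cm=100, n_markers=200)
        cfg = SimulationConfig(
            genome=genome,
            pedigrees=(PedigreeSpec("u", "unrelated", 1000),),
            n_qtl=80,
            mu=700.0,
            var_g=1.0,
            var_ge=0.5,
            var_rep=0.1,
            var_error=1.0,
            seed=31,
        )
        study = simulate_study(cfg)
        a = trial.anova_ms(study.records, convention="classical")
        assert trial.heritability(a) == pytest.approx(0.75, abs=0.05)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tiny_config(var_ge=-1.0)

    def test_no_gxe_line_means_correlate_across_envs(self):
        cfg = tiny_config(var_ge=0.0, var_error=1.0, var_g=1600.0)
        study = simulate_study(cfg)
        means = study.records.data.groupby(["line", "env"])["yield"].mean().unstack()
        corr = means.corr().to_numpy()
        assert corr[np.triu_indices_from(corr, 1)].min() > 0.99


class TestDeterminism:
    def test_full_study_reproducible(self):
        cfg = tiny_config()
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert np.array_equal(a.lines.dosage, b.lines.dosage)
        assert a.hybrids.Z.equals(b.hybrids.Z)
        pd.testing.assert_frame_equal(a.records.data, b.records.data)

    def test_substreams_differ_by_label(self):
        a = substream(1, "x").integers(0, 1 << 30, 5)
        b = substream(1, "y").integers(0, 1 << 30, 5)
        assert not np.array_equal(a, b)
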