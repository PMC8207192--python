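import numpy as np
import pytest

from m2seq import (SimConfig, expected_bulk_freqs, make_bulks, simulate_m1,
                   simulate_m2, simulate_population, simulate_populations,
                   write_vcf)
from m2seq.simulate import recombination_fraction

ONE_CHROM = SimConfig(
    seed=1, n_chromosomes=1, chrom_length_bp=5_000_000, ems_rate_per_mb=4.0,
    background_shared_per_mb=0.0, background_private_per_mb=0.0, n_populations=1,
)


class TestDeterminism:
    def test_identical_config_identical_vcf_bytes(self, tmp_path, small_config):
        paths = []
        for tag in ("a", "b"):
            datasets, _ = simulate_populations(small_config)
            p = tmp_path / f"{tag}.vcf"
            write_vcf(datasets[0], p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seed_different_data(self, small_config):
        from dataclasses import replace

        d1, _ = simulate_population(small_config, seed=1)
        d2, _ = simulate_population(small_config, seed=2)
        assert not d1.frame.equals(d2.frame)


class TestM1:
    def test_ems_count_scales_with_rate_and_genome(self):
        cfg = SimConfig(seed=5, n_chromosomes=10, chrom_length_bp=20_000_000,
                        ems_rate_per_mb=5.0)
        m1 = simulate_m1(cfg)
        expected = 5.0 * 200  # rate * Mb
        assert abs(len(m1.cells[0].frame) - expected) < 4 * np.sqrt(expected)

    def test_causal_is_protein_changing_and_on_coupling_homolog(self):
        m1 = simulate_m1(ONE_CHROM)
        cell = m1.cells[0]
        row = cell.frame.iloc[cell.causal_index]
        assert row["functional_class"] in {"missense", "nonsense", "splice", "frameshift"}
        assert row["homolog"] == 0

    def test_causal_placement_honoured(self):
        from dataclasses import replace

        cfg = replace(ONE_CHROM, causal_chrom="Chr01", causal_pos=2_500_000)
        m1 = simulate_m1(cfg)
        assert (m1.causal.chrom, m1.causal.pos) == ("Chr01", 2_500_000)

    def test_extra_cells_for_chimera(self):
        from dataclasses import replace

        m1 = simulate_m1(replace(ONE_CHROM, chimera_fraction=0.5))
        assert len(m1.cells) == 2 and m1.cells[1].causal_index is None


class TestM2Segregation:
    def test_mutant_fraction_one_quarter_single_cell(self):
        rng = np.random.default_rng(7)
        m1 = simulate_m1(ONE_CHROM, rng=rng)
        m2 = simulate_m2(m1, ONE_CHROM, n_progeny=8000, rng=rng)
        frac = np.mean(m2.phenotype == "mutant")
        assert abs(frac - 0.25) < 2.58 * np.sqrt(0.25 * 0.75 / 8000)

    def test_two_initial_cells_approach_seven_to_one(self):
        from dataclasses import replace

        cfg = replace(ONE_CHROM, n_initial_cells=2)
        rng = np.random.default_rng(9)
        m1 = simulate_m1(cfg, rng=rng)
        m2 = simulate_m2(m1, cfg, n_progeny=8000, rng=rng)
        frac = np.mean(m2.phenotype == "mutant")
        assert abs(frac - 1 / 8) < 2.58 * np.sqrt((1 / 8) * (7 / 8) / 8000)

    def test_unlinked_sites_mendelian_half(self):
        """Pooled allele frequency at heterozygous M1 sites is ~0.5."""
        rng = np.random.default_rng(11)
        m1 = simulate_m1(ONE_CHROM, rng=rng)
        m2 = simulate_m2(m1, ONE_CHROM, n_progeny=4000, rng=rng)
        freqs = m2.dosages[0].mean(axis=0) / 2
        # average over sites; each site CI ~0.5 +/- 0.02
        assert abs(freqs.mean() - 0.5) < 0.01

    def test_lethality_reduces_mutant_fraction(self):
        from dataclasses import replace

        cfg = replace(ONE_CHROM, mutant_survival=0.5)
        rng = np.random.default_rng(13)
        m1 = simulate_m1(cfg, rng=rng)
        m2 = simulate_m2(m1, cfg, n_progeny=8000, rng=rng)
        expected = 0.125 / 0.875  # survivors: (1/4 * 1/2) / (3/4 + 1/8)
        frac = np.mean(m2.phenotype == "mutant")
        assert abs(frac - expected) < 0.02


class TestPhase:
    def test_expected_freqs_monotone_in_distance(self):
        rate = 2.5
        rs = [recombination_fraction(d, rate) for d in (0, 1e6, 5e6, 2e7)]
        assert rs == sorted(rs) and rs[-1] < 0.5
        coupling_mut = [expected_bulk_freqs(r, "coupling")[0] for r in rs]
        repulsion_mut = [expected_bulk_freqs(r, "repulsion")[0] for r in rs]
        assert coupling_mut == sorted(coupling_mut, reverse=True)
        assert repulsion_mut == sorted(repulsion_mut)
        assert expected_bulk_freqs(0.0, "coupling") == (1.0, pytest.approx(1 / 3))

    def test_simulated_bulk_freqs_match_expectation(self):
        """Pre-noise bulk frequencies of linked EMS variants track the
        Haldane-model expectation by phase."""
        from dataclasses import replace

        cfg = replace(ONE_CHROM, bulk_size=200, seed=21)
        rng = np.random.default_rng(cfg.seed)
        m1 = simulate_m1(cfg, rng=rng)
        m2 = simulate_m2(m1, cfg, n_progeny=2000, rng=rng)
        ds, truth = make_bulks(m2, cfg, rng)
        t = truth.truth
        causal_pos = truth.causal.pos
        for phase in ("coupling", "repulsion"):
            sub = t[(t["phase"] == phase) & ~t["is_causal"]]
            for row in sub.itertuples(index=False):
                r = recombination_fraction(abs(row.pos - causal_pos),
                                           cfg.recomb_rate_cm_per_mb)
                exp_mut, exp_wt = expected_bulk_freqs(r, phase)
                assert abs(row.exp_freq_mut - exp_mut) < 0.12
                assert abs(row.exp_freq_wt - exp_wt) < 0.12


class TestBulks:
    def test_causal_site_fixed_in_mutant_bulk(self, small_sim):
        _, truths = small_sim
        for truth in truths:
            causal = truth.truth[truth.truth["is_causal"]]
            assert len(causal) == 1
            assert causal["exp_freq_mut"].iloc[0] == 1.0

    def test_background_homozygous_in_both_bulks(self, small_sim):
        _, truths = small_sim
        t = truths[0].truth
        bg = t[t["origin"].str.startswith("background")]
        assert (bg["exp_freq_mut"] == 1.0).all() and (bg["exp_freq_wt"] == 1.0).all()

    def test_insufficient_mutants_is_explicit_error(self):
        rng = np.random.default_rng(3)
        m1 = simulate_m1(ONE_CHROM, rng=rng)
        m2 = simulate_m2(m1, ONE_CHROM, n_progeny=8, rng=rng)
        with pytest.raises(ValueError, match="larger M2 population"):
            make_bulks(m2, ONE_CHROM, rng)

    def test_chimera_scales_wildtype_bulk_frequency(self):
        """At contamination n, causal-cell variants' wild-type-bulk frequency
        scales to ~(1-n) of the uncontaminated value."""
        from dataclasses import replace

        base = replace(ONE_CHROM, chimera_fraction=0.9, seed=33)
        rng = np.random.default_rng(base.seed)
        m1 = simulate_m1(base, rng=rng)
        m2 = simulate_m2(m1, base, rng=rng)
        _, truth0 = make_bulks(m2, replace(base, chimera_fraction=0.0),
                               np.random.default_rng(1))
        _, truth9 = make_bulks(m2, base, np.random.default_rng(1))
        cell0 = truth0.truth["origin"] == "ems_cell0"
        mean0 = truth0.truth.loc[cell0, "exp_freq_wt"].mean()
        mean9 = truth9.truth.loc[truth9.truth["origin"] == "ems_cell0",
                                 "exp_freq_wt"].mean()
        scale = mean9 / mean0
        # 14 of 15 progenies replaced -> 1/15 plus progeny-sampling noise
        assert abs(scale - 0.1) < 0.1
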