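"""Synthetic-data generator: structure, determinism, and calibration."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from editqtl import sim
from editqtl.io import revcomp
from editqtl.sim import Pedigree, SimConfig


class TestPedigree:
    def test_trio(self):
        cfg = SimConfig(n_founders=2, n_generations=1, n_animals=3)
        ped = sim.simulate_pedigree(cfg, np.random.default_rng(0))
        assert len(ped) == 3
        assert list(ped.founders) == [0, 1]
        assert {ped.sire[2], ped.dam[2]} == {0, 1}

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_founders=10, n_generations=3, n_animals=60)
        a = sim.simulate_pedigree(cfg, np.random.default_rng(5))
        b = sim.simulate_pedigree(cfg, np.random.default_rng(5))
        assert a.ids == b.ids
        assert np.array_equal(a.sire, b.sire) and np.array_equal(a.dam, b.dam)

    def test_parents_precede_offspring(self):
        cfg = SimConfig(n_founders=10, n_generations=3, n_animals=80)
        ped = sim.simulate_pedigree(cfg, np.random.default_rng(1))
        idx = np.arange(len(ped))
        assert np.all(ped.sire < idx) and np.all(ped.dam < idx)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_pedigree(
                SimConfig(n_founders=2, n_generations=0, n_animals=3),
                np.random.default_rng(0),
            )
        with pytest.raises(ValueError):
            Pedigree(["a", "b"], np.array([1, -1]), np.array([-1, -1]),
                     np.array([0, 0]))


class TestGenotypes:
    def test_mendelian_homozygote_transmission(self, small_cohort):
        ped, geno, _ = small_cohort
        # wherever both parents are homozygous, the offspring is too
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0:
                continue
            both0 = (geno.dosages[s] == 0) & (geno.dosages[d] == 0)
            both2 = (geno.dosages[s] == 2) & (geno.dosages[d] == 2)
            assert np.all(geno.dosages[i, both0] == 0)
            assert np.all(geno.dosages[i, both2] == 2)

    def test_founder_frequencies_within_band(self, small_config, small_cohort):
        _, geno, _ = small_cohort
        lo, hi = small_config.maf_range
        maf = np.minimum(geno.allele_freqs, 1 - geno.allele_freqs)
        assert np.all(maf >= lo) and np.all(maf <= hi)

    def test_positions_span_cis_windows(self, small_cohort):
        _, geno, _ = small_cohort
        assert geno.positions.max() - geno.positions.min() >= 2_000_000
        assert np.all(np.diff(geno.positions) > 0)

    def test_gene_drop_drift_matches_neutral_expectation(self):
        """Across replicate gene drops from the same founders, the variance
        of the offspring-generation allele-frequency change is p(1-p)/2N."""
        cfg = SimConfig(n_founders=50, n_generations=1, n_animals=150,
                        n_variants=200, seed=2)
        rng = np.random.default_rng(2)
        ped = sim.simulate_pedigree(cfg, rng)
        geno = sim.simulate_genotypes(ped, cfg, rng)
        off = ped.generation == 1
        n_off = off.sum()
        founder_freq = geno.dosages[~off].mean(axis=0) / 2
        # each offspring samples one allele per parent; with random parent
        # pairs the per-variant drift variance is ~ p(1-p)/(2 n_off)
        drift = geno.dosages[off].mean(axis=0) / 2 - founder_freq
        p = founder_freq
        expected_var = np.mean(p * (1 - p)) / (2 * n_off)
        ratio = drift.var() / expected_var
        assert 0.4 < ratio < 2.5  # loose Monte-Carlo band, 200 variants


class TestEditing:
    def test_no_variance_means_constant_phi(self, small_cohort):
        ped, geno, _ = small_cohort
        cfg = SimConfig(n_animals=120, n_founders=30, n_generations=2,
                        n_variants=150, n_edit_sites=2,
                        causal_effect_logit=0.0, polygenic_variance=0.0,
                        residual_variance=0.0, depth_mean=500.0)
        edit = sim.simulate_editing(geno.dosages, ped, cfg,
                                    np.random.default_rng(3))
        phi = edit.edited.sum(axis=0) / edit.total.sum(axis=0)
        np.testing.assert_allclose(phi, expit(cfg.mu_logit), atol=0.01)

    def test_mean_phi_monotone_in_dosage(self, small_cohort):
        ped, geno, _ = small_cohort
        cfg = SimConfig(n_animals=120, n_founders=30, n_generations=2,
                        n_variants=150, n_edit_sites=1,
                        causal_effect_logit=2.0, polygenic_variance=0.05,
                        residual_variance=0.05, depth_mean=200.0)
        edit = sim.simulate_editing(geno.dosages, ped, cfg,
                                    np.random.default_rng(4))
        d = geno.dosages[:, edit.causal_index[0]]
        phi = edit.edited[:, 0] / edit.total[:, 0]
        means = [phi[d == k].mean() for k in (0, 1, 2) if (d == k).sum() > 3]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_zero_depth_recorded_as_missing_total(self, small_cohort):
        ped, geno, _ = small_cohort
        cfg = SimConfig(n_animals=120, n_founders=30, n_generations=2,
                        n_variants=150, n_edit_sites=2, depth_mean=0.5)
        edit = sim.simulate_editing(geno.dosages, ped, cfg,
                                    np.random.default_rng(5))
        zero = edit.total == 0
        assert zero.any()
        assert np.all(edit.edited[zero] == 0)

    def test_polygenic_covariance_converges_to_scaled_A(self):
        """Realized covariance of the polygenic term over replicates
        converges to polygenic_variance * A element-wise."""
        from editqtl.assoc import a_matrix

        cfg = SimConfig(n_animals=25, n_founders=6, n_generations=2,
                        n_variants=60, n_edit_sites=40,
                        causal_effect_logit=0.0, polygenic_variance=0.5,
                        residual_variance=0.0, depth_mean=50.0)
        rng = np.random.default_rng(6)
        ped = sim.simulate_pedigree(cfg, rng)
        geno = sim.simulate_genotypes(ped, cfg, rng)
        # with beta = 0 and no residual, latent - mu is the polygenic draw;
        # 40 sites x replicates give many independent MVN draws
        draws = []
        for rep in range(25):
            edit = sim.simulate_editing(geno.dosages, ped, cfg,
                                        np.random.default_rng(100 + rep))
            draws.append(edit.latent - cfg.mu_logit)
        G = np.hstack(draws)  # n_animals x 1000 draws
        emp = G @ G.T / G.shape[1]
        A = a_matrix(ped)
        err = np.abs(emp - 0.5 * A)
        # element-wise SE of a covariance estimate at 1000 draws is ~0.02
        assert err.max() < 0.15
        assert err.mean() < 0.03


class TestPremrna:
    def test_planted_stem_is_its_own_revcomp(self):
        cfg = SimConfig()
        pre = sim.simulate_premrna(cfg, np.random.default_rng(7))
        a, b = pre.stem
        stem = pre.sequence[a:b]
        j0 = min(j for _, j in pre.pairings)
        j1 = max(j for _, j in pre.pairings) + 1
        assert pre.sequence[j0:j1] == revcomp(stem)

    def test_edit_positions_inside_stem_and_are_A(self):
        pre = sim.simulate_premrna(SimConfig(), np.random.default_rng(8))
        a, b = pre.stem
        for p in pre.edit_positions:
            assert a <= p < b
            assert pre.sequence[p] == "A"

    def test_truth_pairings_complementary(self):
        pre = sim.simulate_premrna(SimConfig(), np.random.default_rng(9))
        wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
        for i, j in pre.pairings:
            assert (pre.sequence[i], pre.sequence[j]) in wc

    def test_undersized_stem_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_premrna(SimConfig(), np.random.default_rng(0),
                                 stem_len=30)


class TestReadPairs:
    def test_perfect_phase_empties_discordant_cells(self):
        table = sim.simulate_read_pairs(np.inf, 5000,
                                        np.random.default_rng(10),
                                        p_edit=0.4, p_alt=0.4)
        # edited&ref and unedited&alt are impossible under perfect phase
        assert table[0, 0] == 0 and table[1, 1] == 0

    def test_zero_reads_empty_table(self):
        table = sim.simulate_read_pairs(2.0, 0, np.random.default_rng(11))
        assert table.sum() == 0 and table.shape == (2, 2)

    def test_expected_odds_ratio_matches_target(self):
        rng = np.random.default_rng(12)
        table = sim.simulate_read_pairs(6.0, 2_000_000, rng)
        odds = (table[0, 1] * table[1, 0]) / (table[0, 0] * table[1, 1])
        assert odds == pytest.approx(6.0, rel=0.05)

    def test_null_chi2_p_uniform(self):
        """Under odds ratio 1 the independence-test p-values are uniform."""
        from editqtl.integrate import PhasePair, phase_test

        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(300):
            t = sim.simulate_read_pairs(1.0, 10_000, rng)
            pair = PhasePair("s", 1, t, separation=100, ld_r2=1.0)
            pvals.append(phase_test(pair)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestExpression:
    def test_zero_slope_uncorrelated(self):
        cfg = SimConfig(phi_expression_slope=0.0)
        rng = np.random.default_rng(14)
        latent = rng.standard_normal((355, 1))
        counts = sim.simulate_expression(latent, cfg, rng)
        r, p = stats.pearsonr(latent[:, 0], counts[:, 0])
        assert abs(r) < 0.15

    def test_negative_slope_detected_with_power(self):
        """At n=355 and the configured slope, the phi-expression
        correlation is negative and significant in >90% of replicates."""
        cfg = SimConfig()
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(200 + rep)
            latent = rng.standard_normal((355, 1))
            counts = sim.simulate_expression(latent, cfg, rng)
            r, p = stats.pearsonr(latent[:, 0], np.log1p(counts[:, 0]))
            hits += (r < 0) and (p < 0.05)
        assert hits >= 27

    def test_small_dispersion_approaches_poisson(self):
        cfg = SimConfig(expression_dispersion=1e-9, phi_expression_slope=0.0)
        rng = np.random.default_rng(15)
        counts = sim.simulate_expression(np.zeros((20000, 1)), cfg, rng,
                                         target_mean=100.0)
        m, v = counts.mean(), counts.var()
        assert v / m == pytest.approx(1.0, rel=0.05)


class TestDeterminism:
    def test_bundle_outputs_bit_identical(self, tmp_path):
        cfg = dict(n_animals=60, n_founders=16, n_generations=2,
                   n_variants=60, n_edit_sites=2)
        from editqtl.pipeline import run_simulate

        run_simulate(tmp_path / "a", seed=42, overrides=cfg)
        run_simulate(tmp_path / "b", seed=42, overrides=cfg)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a if f.is_file()] == [
            f.name for f in files_b if f.is_file()
        ]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file() and fa.suffix != ".fai":
                assert fa.read_bytes() == fb.read_bytes(), fa.name
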