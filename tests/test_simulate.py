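"""Generator correctness: genotype Markov structure, phenotype variance
components, expression latents, arm-entry sequences, and seeding."""

import numpy as np
import pandas as pd
import pytest

from cogpanel import (
    QTLSpec,
    SimulationConfig,
    simulate_arm_entries,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
)
from cogpanel.behavior import percent_spontaneous_alternation, summarize_by_strain
from cogpanel.simulate import stream_rngs


def _cfg(**kw):
    defaults = dict(n_strains=10, n_chromosomes=3, markers_per_chromosome=8,
                    seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenotypes:
    def test_zero_recombination_gives_constant_blocks(self):
        geno = simulate_genotypes(_cfg(adjacent_marker_recomb_fraction=0.0))
        for chrom, sub in geno.map.groupby("chromosome"):
            block = geno.calls.loc[sub["marker"]].to_numpy()
            assert (block == block[0]).all()

    def test_free_recombination_decorrelates_adjacent_markers(self):
        geno = simulate_genotypes(
            _cfg(n_strains=500, adjacent_marker_recomb_fraction=0.5))
        calls = geno.calls.to_numpy(dtype=float)
        corrs = [np.corrcoef(calls[m], calls[m + 1])[0, 1]
                 for m in range(7)]  # within first chromosome
        assert abs(np.mean(corrs)) < 0.05

    def test_switch_frequency_matches_recomb_fraction(self):
        geno = simulate_genotypes(
            _cfg(n_strains=500, adjacent_marker_recomb_fraction=0.1))
        switch_rates = []
        for _, sub in geno.map.groupby("chromosome"):
            block = geno.calls.loc[sub["marker"]].to_numpy()
            switch_rates.append(np.mean(block[1:] != block[:-1]))
        assert abs(np.mean(switch_rates) - 0.1) < 0.02

    def test_allele_frequency_near_half(self):
        geno = simulate_genotypes(_cfg(n_strains=500))
        assert abs(geno.calls.to_numpy().mean() - 0.5) < 0.05

    def test_invalid_map_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(markers_per_chromosome=0)
        with pytest.raises(ValueError):
            SimulationConfig(adjacent_marker_recomb_fraction=0.7)


class TestPhenotypes:
    def test_degenerate_noise_gives_identical_replicates(self):
        cfg = _cfg(ve=0.0, decline_sd=0.0, decline_mean=-4.0)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(cfg, geno)
        summ = summarize_by_strain(pheno)
        # all replicates within a strain identical
        spread = pheno.groupby(["strain", "trait", "age_months"])["value"].agg(
            lambda v: v.max() - v.min())
        assert (spread == 0).all()
        # strain difference between ages equals decline_mean exactly
        wide = summ.pivot_table(index=["strain", "trait"],
                                columns="age_months", values="mean")
        assert np.allclose(wide[14] - wide[6], -4.0)

    def test_no_variance_collapses_to_baseline(self):
        cfg = _cfg(va=0.0, ve=0.0, decline_mean=0.0, decline_sd=0.0,
                   baseline_mean=55.0)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(cfg, geno)
        assert np.allclose(pheno["value"], 55.0)

    def test_variance_components_recovered_at_scale(self):
        cfg = SimulationConfig(n_strains=500, reps_per_strain_age=20,
                               n_chromosomes=2, markers_per_chromosome=5,
                               traits=("ymaze_alt",), va=36.0, ve=96.0,
                               decline_sd=0.0, seed=11)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(cfg, geno)
        sub = pheno[(pheno.trait == "ymaze_alt") & (pheno.age_months == 6)]
        tv = truth.strain_values
        genetic = tv[(tv.trait == "ymaze_alt")
                     & (tv.age_months == 6)]["genetic_value"]
        assert abs(genetic.var(ddof=1) - 36.0) / 36.0 < 0.10
        within = sub.groupby("strain")["value"].var(ddof=1).mean()
        assert abs(within - 96.0) / 96.0 < 0.10

    def test_planted_qtl_r2_matches_requested_share(self):
        cfg = SimulationConfig(
            n_strains=200, reps_per_strain_age=4, traits=("ymaze_alt",),
            va=36.0, ve=4.0, n_chromosomes=3, markers_per_chromosome=10,
            qtl_spec=QTLSpec(chromosome=1, marker_index=4, pve=0.5),
            seed=5)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(cfg, geno)
        summ = summarize_by_strain(pheno)
        means = summ[(summ.trait == "ymaze_alt")
                     & (summ.age_months == 6)].set_index("strain")["mean"]
        g = geno.calls.loc[truth.qtl_marker, means.index].to_numpy(dtype=float)
        r2 = np.corrcoef(g, means.to_numpy())[0, 1] ** 2
        assert abs(r2 - 0.5) < 0.1

    def test_qtl_outside_map_rejected(self):
        with pytest.raises(ValueError):
            _cfg(qtl_spec=QTLSpec(chromosome=99, marker_index=0, pve=0.5))
        with pytest.raises(ValueError):
            _cfg(qtl_spec=QTLSpec(chromosome=0, marker_index=99, pve=0.5))

    def test_values_bounded_and_longitudinal_design(self):
        cfg = _cfg(ve=400.0)  # large noise forces truncation
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(cfg, geno)
        assert pheno["value"].between(0, 100).all()
        assert truth.truncation_events > 0
        # y-maze animals appear at both ages; fear-conditioning animals at one
        ymaze = pheno[pheno.trait == "ymaze_alt"]
        ages_per_animal = ymaze.groupby("animal_id")["age_months"].nunique()
        assert (ages_per_animal == 2).all()
        cfa = pheno[pheno.trait == "cfa"]
        assert (cfa.groupby("animal_id")["age_months"].nunique() == 1).all()

    def test_unbalanced_replicates(self):
        reps = [1, 2, 3, 4, 5, 6, 7, 8, 2, 3]
        cfg = _cfg(reps_per_strain_age=reps)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(cfg, geno)
        counts = (pheno[(pheno.trait == "ymaze_alt") & (pheno.age_months == 6)]
                  .groupby("strain")["value"].count())
        assert sorted(counts) == sorted(reps)


class TestSeeding:
    def test_same_seed_bit_identical(self):
        cfg = _cfg(seed=123)
        g1, g2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
        pd.testing.assert_frame_equal(g1.calls, g2.calls)
        p1, _ = simulate_phenotypes(cfg, g1)
        p2, _ = simulate_phenotypes(cfg, g2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_different_seeds_differ(self):
        a = simulate_genotypes(_cfg(seed=1))
        b = simulate_genotypes(_cfg(seed=2))
        assert not a.calls.equals(b.calls)

    def test_streams_are_independent(self):
        """Phenotype draws must not depend on the expression stream."""
        cfg1 = _cfg(seed=99, n_background_genes=10)
        cfg2 = _cfg(seed=99, n_background_genes=500)
        for cfg in (cfg1, cfg2):
            rngs = stream_rngs(cfg.seed)
            geno = simulate_genotypes(cfg, rngs["genotypes"])
            pheno, _ = simulate_phenotypes(cfg, geno, rngs["phenotypes"])
            summ = summarize_by_strain(pheno)
            simulate_expression(cfg, summ, rngs["expression"])
            if cfg is cfg1:
                first = pheno
        pd.testing.assert_frame_equal(first, pheno)


class TestExpression:
    def _panel_summary(self, cfg):
        rngs = stream_rngs(cfg.seed)
        geno = simulate_genotypes(cfg, rngs["genotypes"])
        pheno, _ = simulate_phenotypes(cfg, geno, rngs["phenotypes"])
        return summarize_by_strain(pheno), rngs["expression"]

    def test_perfect_module_is_affine_in_trait(self):
        cfg = _cfg(n_modules=1, module_trait_r=(1.0,),
                   module_loading_range=(1.0, 1.0), n_background_genes=0)
        summ, rng = self._panel_summary(cfg)
        expr, assign, latents = simulate_expression(cfg, summ, rng)
        target = summ[(summ.trait == "ymaze_alt")
                      & (summ.age_months == 6)].set_index("strain")["mean"]
        for gene in expr.index:
            r = np.corrcoef(expr.loc[gene, target.index], target)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_latent_correlation_is_exact(self):
        cfg = _cfg(n_strains=30, n_modules=2, module_trait_r=(0.6, 0.0))
        summ, rng = self._panel_summary(cfg)
        _, _, latents = simulate_expression(cfg, summ, rng)
        target = summ[(summ.trait == "ymaze_alt")
                      & (summ.age_months == 6)].set_index("strain")["mean"]
        r1 = np.corrcoef(latents.loc["module01", target.index], target)[0, 1]
        assert r1 == pytest.approx(0.6, abs=1e-9)

    def test_null_modules_uncorrelated_on_average(self):
        rs = []
        for seed in range(40):
            cfg = _cfg(n_strains=30, n_modules=1, module_trait_r=(0.0,),
                       n_background_genes=0, seed=3000 + seed)
            summ, rng = self._panel_summary(cfg)
            _, _, latents = simulate_expression(cfg, summ, rng)
            target = summ[(summ.trait == "ymaze_alt")
                          & (summ.age_months == 6)].set_index("strain")["mean"]
            rs.append(np.corrcoef(latents.iloc[0][target.index], target)[0, 1])
        assert abs(np.mean(rs)) < 0.05  # centred on zero by construction
        assert np.mean(np.abs(rs)) < 0.05  # sample r is exactly 0 here

    def test_nonnegative_tpm_scale(self):
        cfg = _cfg()
        summ, rng = self._panel_summary(cfg)
        expr, _, _ = simulate_expression(cfg, summ, rng)
        assert (expr.to_numpy() >= 0).all()

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            _cfg(module_trait_r=(1.5,))


class TestArmEntries:
    def test_perfect_alternator_scores_100(self):
        seq = simulate_arm_entries(1.0, 50, seed=3)
        assert percent_spontaneous_alternation(seq) == 100.0

    def test_never_alternates_scores_0(self):
        seq = simulate_arm_entries(0.0, 50, seed=3)
        assert percent_spontaneous_alternation(seq) == 0.0

    def test_rate_recovered_at_large_n(self):
        seq = simulate_arm_entries(0.6, 2000, seed=3)
        assert abs(percent_spontaneous_alternation(seq) - 60.0) < 3.0

    def test_no_consecutive_repeats(self):
        seq = simulate_arm_entries(0.5, 200, seed=4)
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_arm_entries(0.5, 2)
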