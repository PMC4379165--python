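import numpy as np
import pandas as pd
import pytest

from ncqtl import (
    EffectDescriptor,
    EffectEncoding,
    ScanConfig,
    SimulationSpec,
    allele_frequencies,
    calibrate_qtl_effects,
    default_qtl_architecture,
    f1_only,
    parents_only,
    parents_plus_f1,
    run_experiment,
    sample_size_structure,
    simulate_dataset,
    simulate_ncii_population,
    simulate_phenotypes,
)
from ncqtl.simulate import QTLSpec, breeding_scale_structure


class TestStructures:
    def test_parents_only_preset(self):
        spec = SimulationSpec(n_markers=10, structure=parents_only(300), qtl=[])
        pop = simulate_ncii_population(spec, seed=0)
        assert len(pop.individuals) == 600
        assert len(pop.pedigree) == 0

    @pytest.mark.parametrize("n,expected", [(400, (160, 80, 160)),
                                            (500, (200, 100, 200)),
                                            (600, (240, 120, 240))])
    def test_sample_size_presets(self, n, expected):
        st = sample_size_structure(n)
        assert (st.n_parent_a, st.n_parent_b, st.n_f1) == expected
        spec = SimulationSpec(n_markers=8, structure=st, qtl=[])
        pop = simulate_ncii_population(spec, seed=1)
        assert len(pop.individuals) == n
        assert len(pop.pedigree) == st.n_f1

    def test_breeding_scale_structure_totals_725(self):
        st = breeding_scale_structure()
        assert st.n_parent_a + st.n_parent_b + st.n_f1 == 725
        spec = SimulationSpec(n_markers=8, structure=st, qtl=[])
        pop = simulate_ncii_population(spec, seed=2)
        assert len(pop.mapped_ids()) == 0  # no phenotypes yet
        assert len(pop.individuals) == 725

    def test_f1_only_leaves_parents_unphenotyped(self):
        spec = SimulationSpec(n_markers=8, structure=f1_only(100),
                              qtl=[QTLSpec(EffectDescriptor("a", 0), h2=0.1)])
        pop, _ = simulate_dataset(spec, seed=3)
        mapped = pop.mapped_ids()
        assert len(mapped) == 100
        assert set(pop.roles.loc[mapped]) == {"F1"}

    def test_partial_pedigree_crosses_two_a_parents_per_b(self):
        spec = SimulationSpec(n_markers=5, structure=parents_plus_f1(50, 25, 50),
                              qtl=[])
        pop = simulate_ncii_population(spec, seed=4)
        per_b = pop.pedigree.groupby("parent_b").size()
        assert (per_b == 2).all()
        # partial design: far fewer crosses than the full factorial
        assert len(pop.pedigree) < 50 * 25

    def test_f1_genotypes_are_parental_means(self):
        spec = SimulationSpec(n_markers=6, structure=parents_plus_f1(20, 10, 20),
                              qtl=[])
        pop = simulate_ncii_population(spec, seed=5)
        for _, row in pop.pedigree.head(5).iterrows():
            expected = (pop.genotypes.loc[row["parent_a"]]
                        + pop.genotypes.loc[row["parent_b"]]) / 2.0
            pd.testing.assert_series_equal(pop.genotypes.loc[row["f1_id"]],
                                           expected, check_names=False)

    def test_same_seed_is_bit_identical(self):
        spec = SimulationSpec(n_markers=12, structure=parents_plus_f1(30, 15, 30),
                              qtl=default_qtl_architecture(0.05, m=12))
        pop1, truth1 = simulate_dataset(spec, seed=99)
        pop2, truth2 = simulate_dataset(spec, seed=99)
        pd.testing.assert_frame_equal(pop1.genotypes, pop2.genotypes)
        pd.testing.assert_series_equal(pop1.phenotypes, pop2.phenotypes)
        assert truth1["qtl"] == truth2["qtl"]

    def test_realized_allele_frequency_close_to_target(self):
        spec = SimulationSpec(n_markers=20, structure=parents_only(300), qtl=[])
        hits = 0
        for seed in range(5):
            pop = simulate_ncii_population(spec, seed=seed)
            freq = allele_frequencies(pop)
            hits += int(((freq > 0.4) & (freq < 0.6)).all())
        assert hits >= 4  # binomial bound at n = 600 parents


class TestEffectCalibration:
    def test_genetic_variance_closed_form(self):
        # 8 QTL at h2 = 0.05 -> sigma_G^2 = 0.05 / 0.60 each
        spec = SimulationSpec(n_markers=20, structure=parents_plus_f1(60, 30, 60),
                              qtl=default_qtl_architecture(0.05, m=20))
        pop = simulate_ncii_population(spec, seed=6)
        _ = calibrate_qtl_effects(pop, spec)
        total_h2 = 8 * 0.05
        assert 0.05 / (1 - total_h2) == pytest.approx(0.0833333, abs=1e-6)
        assert 0.02 / (1 - 8 * 0.02) == pytest.approx(0.0238095, abs=1e-6)

    def test_realized_column_variance_hits_target_exactly(self):
        spec = SimulationSpec(n_markers=20, structure=parents_plus_f1(60, 30, 60),
                              qtl=default_qtl_architecture(0.05, m=20))
        pop = simulate_ncii_population(spec, seed=7)
        effects = calibrate_qtl_effects(pop, spec)
        enc = EffectEncoding.from_population(pop)
        sigma_g2 = 0.05 / (1 - 0.4)
        for e, q in zip(effects, spec.qtl):
            w = enc.column(q.descriptor)
            assert (e * w).var() == pytest.approx(sigma_g2, abs=1e-12)

    def test_fixed_effect_sizes_pass_through(self):
        spec = SimulationSpec(n_markers=5, structure=parents_plus_f1(20, 10, 20),
                              qtl=[QTLSpec(EffectDescriptor("a", 1), effect=1.0)])
        pop = simulate_ncii_population(spec, seed=8)
        effects = calibrate_qtl_effects(pop, spec)
        assert effects[0] == 1.0

    def test_non_segregating_qtl_is_an_error(self):
        spec = SimulationSpec(n_markers=5, structure=parents_only(50),
                              qtl=[QTLSpec(EffectDescriptor("dd", 0, 1), h2=0.1)])
        pop = simulate_ncii_population(spec, seed=9)
        with pytest.raises(ValueError, match="zero variance"):
            calibrate_qtl_effects(pop, spec)


class TestPhenotypes:
    def test_noiseless_phenotype_equals_genotypic_value(self):
        spec = SimulationSpec(n_markers=10, structure=parents_plus_f1(30, 15, 30),
                              qtl=default_qtl_architecture(0.05, m=10),
                              residual_var=0.0)
        pop = simulate_ncii_population(spec, seed=10)
        effects = calibrate_qtl_effects(pop, spec)
        y, g = simulate_phenotypes(pop, effects, spec, seed=11)
        pd.testing.assert_series_equal(y, g, check_names=False)

    def test_phenotypic_variance_matches_decomposition(self):
        # Var(y) ~= Var(g) + sigma^2 at the 725-individual scale, and the
        # genetic variance is at least the sum of the per-QTL targets
        # (dominance-related columns are positively correlated in a mixed
        # parents+F1 population, so Var(g) can exceed the orthogonal sum)
        spec = SimulationSpec(n_markers=30, structure=breeding_scale_structure(),
                              qtl=default_qtl_architecture(0.05, m=30))
        pop, truth = simulate_dataset(spec, seed=12)
        y = pop.phenotypes.dropna()
        g = truth["genotypic_values"]
        expected = g.var() + 1.0
        assert abs(y.var() - expected) / expected < 0.10
        orthogonal_sum = 8 * 0.05 / (1 - 0.4)
        assert g.var() >= orthogonal_sum - 0.02

    def test_pure_noise_phenotype_moments(self):
        spec = SimulationSpec(n_markers=5, structure=parents_only(300),
                              qtl=[], mu=3.0)
        pop, _ = simulate_dataset(spec, seed=13)
        y = pop.phenotypes.dropna()
        assert y.mean() == pytest.approx(3.0, abs=0.15)
        assert y.var() == pytest.approx(1.0, abs=0.15)


class TestExperimentHarness:
    def test_power_and_fpr_bookkeeping(self):
        spec = SimulationSpec(
            n_markers=15, structure=parents_plus_f1(60, 30, 60),
            qtl=[QTLSpec(EffectDescriptor("a", 3), h2=0.25),
                 QTLSpec(EffectDescriptor("a", 9), h2=0.25)])
        res = run_experiment(spec, ScanConfig(cap=20), replicates=3, base_seed=50)
        assert res.n_replicates == 3
        assert res.n_zero_effects == 2 * 15 + 2 * 15 * 14 - 2
        assert set(res.per_qtl["power"]).issubset({0.0, 1 / 3, 2 / 3, 1.0})
        # two very strong QTL: both detected in every replicate
        assert (res.per_qtl["power"] == 1.0).all()
        assert (res.per_qtl["bias_mean"] >= 0).all()
        assert 0 <= res.fpr <= 1

    def test_replicate_seeds_derive_from_base_seed(self):
        spec = SimulationSpec(
            n_markers=10, structure=parents_plus_f1(40, 20, 40),
            qtl=[QTLSpec(EffectDescriptor("a", 2), h2=0.3)])
        r1 = run_experiment(spec, ScanConfig(cap=10), replicates=2, base_seed=7)
        r2 = run_experiment(spec, ScanConfig(cap=10), replicates=2, base_seed=7)
        pd.testing.assert_frame_equal(
            r1.per_qtl.drop(columns="descriptor"),
            r2.per_qtl.drop(columns="descriptor"))
        assert r1.fpr == r2.fpr
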