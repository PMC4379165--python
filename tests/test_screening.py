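import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncqtl import (
    EffectDescriptor,
    EffectEncoding,
    chi2_independence,
    screen_all_effects,
    screen_top_effects,
    select_extremes,
)
from ncqtl.screening import ScreeningError, screening_report

from conftest import make_population


class TestSelectExtremes:
    def test_tail_sizes(self):
        y = pd.Series(np.arange(725, dtype=float),
                      index=[f"I{i:04d}" for i in range(725)])
        high, low = select_extremes(y, 0.10)
        assert len(high) == len(low) == 72
        assert set(high).isdisjoint(low)

    def test_small_population_single_individual_tails(self):
        y = pd.Series(np.arange(10, dtype=float), index=list("abcdefghij"))
        high, low = select_extremes(y, 0.10)
        assert low == ["a"] and high == ["j"]

    def test_all_equal_phenotypes_fill_tails_by_id_order(self):
        y = pd.Series(1.0, index=[f"I{i:02d}" for i in range(20)])
        high, low = select_extremes(y, 0.10)
        assert low == ["I00", "I01"]
        assert set(high).isdisjoint(low)
        assert len(high) == 2

    def test_tails_never_overlap_at_the_maximum_fraction(self):
        # floor(0.5 n) per tail can never overlap; above 0.5 is rejected
        y = pd.Series(np.arange(5, dtype=float), index=list("abcde"))
        high, low = select_extremes(y, 0.5)
        assert set(high).isdisjoint(low)
        with pytest.raises(ScreeningError):
            select_extremes(y, 0.6)

    def test_fraction_out_of_range(self):
        y = pd.Series(np.arange(10, dtype=float), index=list("abcdefghij"))
        with pytest.raises(ScreeningError):
            select_extremes(y, 0.0)


class TestChi2Independence:
    def test_hand_computed_2x2_table(self):
        # [[30,10],[10,30]]: expected counts all 20 -> chi2 = 4*100/20 = 20
        column = np.array([1.0] * 40 + [0.0] * 40)
        in_high = np.array([True] * 30 + [False] * 10 + [True] * 10 + [False] * 30)
        res = chi2_independence(column, in_high)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_identical_distributions_give_zero(self):
        column = np.array([1.0, 0.0, -1.0] * 10)
        in_high = np.array([True, False] * 15)
        res = chi2_independence(column, in_high)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_single_level_is_untestable(self):
        res = chi2_independence(np.ones(20), np.arange(20) < 10)
        assert res.untestable and res.p == 1.0

    def test_missing_individuals_are_excluded(self):
        column = np.array([1.0] * 5 + [0.0] * 5 + [np.nan] * 5)
        in_high = np.array([True] * 5 + [False] * 5 + [True] * 5)
        res = chi2_independence(column, in_high)
        # perfect separation of the 10 informative individuals
        assert res.df == 1 and res.chi2 == pytest.approx(10.0)

    def test_df_follows_observed_levels(self):
        rng = np.random.default_rng(0)
        col3 = rng.choice([-1.0, 0.0, 1.0], size=100)
        col2 = rng.choice([0.0, 1.0], size=100)
        labels = rng.random(100) < 0.5
        assert chi2_independence(col3, labels).df == 2
        assert chi2_independence(col2, labels).df == 1


class TestVectorizedScreen:
    def test_matches_per_effect_reference_on_missing_data(self, random_population):
        """The batched indicator-product screen must agree with the scalar
        scipy-based test for every effect, including markers with missing
        genotypes."""
        enc = EffectEncoding.from_population(random_population)
        y = random_population.phenotypes
        high, low = select_extremes(y, 0.15)
        table = screen_all_effects(enc, high, low)
        id_pos = {i: k for k, i in enumerate(enc.ids)}
        rows = np.array([id_pos[i] for i in high] + [id_pos[i] for i in low])
        in_high = np.array([True] * len(high) + [False] * len(low))
        for row in table.sample(n=200, random_state=1).itertuples():
            locus2 = None if row.locus2 < 0 else int(row.locus2)
            desc = EffectDescriptor(row.kind, int(row.locus1), locus2)
            sub = enc.subset(rows)
            # rebuild the raw (non-imputed) column for the extreme subset
            j = desc.locus1
            left = sub.X_raw[:, j] if desc.kind[0] == "a" else sub.Z_raw[:, j]
            if desc.is_main:
                col = left
            else:
                k = desc.locus2
                right = sub.X_raw[:, k] if desc.kind[1] == "a" else sub.Z_raw[:, k]
                col = left * right
            ref = chi2_independence(col, in_high)
            assert row.untestable == ref.untestable
            if not ref.untestable:
                assert row.chi2 == pytest.approx(ref.chi2, abs=1e-10)
                assert row.df == ref.df
                assert row.p == pytest.approx(ref.p, abs=1e-12)

    def test_df_pattern_by_effect_kind(self):
        rng = np.random.default_rng(3)
        pa = 2.0 * (rng.random((60, 10)) < 0.5)
        pb = 2.0 * (rng.random((30, 10)) < 0.5)
        pop = make_population(pa, pb, seed=5)
        y = pd.Series(np.random.default_rng(9).normal(size=len(pop.individuals)),
                      index=pop.individuals)
        enc = EffectEncoding.from_population(pop)
        high, low = select_extremes(y, 0.2)
        table = screen_all_effects(enc, high, low)
        testable = table[~table["untestable"]]
        assert (testable[testable["kind"].isin(["d", "dd"])]["df"] == 1).all()
        assert (testable[~testable["kind"].isin(["d", "dd"])]["df"] <= 2).all()


class TestTopEffects:
    def _noise_setup(self, seed=0, m=8, with_f1=True):
        rng = np.random.default_rng(seed)
        pa = 2.0 * (rng.random((40, m)) < 0.5)
        pb = 2.0 * (rng.random((20, m)) < 0.5)
        pop = make_population(pa, pb, seed=seed,
                              n_f1_per_b=2 if with_f1 else 0)
        y = pd.Series(rng.normal(size=len(pop.individuals)), index=pop.individuals)
        return EffectEncoding.from_population(pop), y

    def test_cap_behavior_under_pure_noise(self):
        enc, y = self._noise_setup()
        results = screen_top_effects(enc, y, cap=5, alpha=1.0)
        main = [r for r in results if r.descriptor.is_main]
        inter = [r for r in results if not r.descriptor.is_main]
        assert len(main) == 5 and len(inter) == 5
        assert all(main[i].p <= main[i + 1].p for i in range(len(main) - 1))
        assert all(inter[i].p <= inter[i + 1].p for i in range(len(inter) - 1))

    def test_already_selected_effects_are_skipped(self):
        enc, y = self._noise_setup()
        first = screen_top_effects(enc, y, cap=3, alpha=1.0)
        chosen = {r.descriptor for r in first}
        second = screen_top_effects(enc, y, already_selected=chosen, cap=3, alpha=1.0)
        assert chosen.isdisjoint({r.descriptor for r in second})

    def test_output_invariant_to_row_order(self):
        enc, y = self._noise_setup(seed=4)
        shuffled = y.sample(frac=1.0, random_state=8)
        a = screen_top_effects(enc, y, cap=10, alpha=1.0)
        b = screen_top_effects(enc, shuffled, cap=10, alpha=1.0)
        assert [r.descriptor for r in a] == [r.descriptor for r in b]

    def test_strong_additive_qtl_ranks_first(self):
        rng = np.random.default_rng(12)
        m = 20
        pa = 2.0 * (rng.random((100, m)) < 0.5)
        pb = 2.0 * (rng.random((50, m)) < 0.5)
        pop = make_population(pa, pb, seed=12)
        enc = EffectEncoding.from_population(pop)
        target = EffectDescriptor("a", 7)
        y_vals = 1.2 * enc.column(target) + rng.normal(size=enc.n)
        y = pd.Series(y_vals, index=pop.individuals)
        results = screen_top_effects(enc, y, cap=10)
        main = [r for r in results if r.descriptor.is_main]
        assert main[0].descriptor == target

    def test_null_p_values_are_calibrated(self):
        """Permuting the phenotype should leave about alpha of the candidate
        effects below alpha (chi-square calibration under independence)."""
        rng = np.random.default_rng(42)
        m = 20
        pa = 2.0 * (rng.random((150, m)) < 0.5)
        pb = 2.0 * (rng.random((75, m)) < 0.5)
        pop = make_population(pa, pb, seed=21)
        enc = EffectEncoding.from_population(pop)
        base = rng.normal(size=enc.n)
        props = []
        for perm_seed in range(4):
            y = pd.Series(np.random.default_rng(perm_seed).permutation(base),
                          index=pop.individuals)
            high, low = select_extremes(y, 0.10)
            table = screen_all_effects(enc, high, low)
            testable = table[~table["untestable"]]
            props.append((testable["p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 500)  # reference scale at 500 effects
        assert abs(np.mean(props) - 0.05) < 3 * se

    def test_report_columns(self):
        enc, y = self._noise_setup(seed=6)
        results = screen_top_effects(enc, y, cap=3, alpha=1.0)
        report = screening_report(results, enc.markers)
        assert list(report.columns) == ["effect", "kind", "locus1", "locus2",
                                        "chi2", "df", "p"]
        assert len(report) == len(results)
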