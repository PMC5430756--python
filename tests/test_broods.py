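"""Classifier tests: chi-square machinery, filters, decision tree, power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from isosex.broods import (
    BroodRecord,
    DegenerateExpectationError,
    DegenerateTableError,
    NoDataError,
    chisq_gof,
    classify_species,
    exact_zero_male_test,
    filter_broods,
    heterogeneity_test,
    viability_power,
)


def b(m, f, wolb="negative", species="sp", bid="b"):
    return BroodRecord(species, bid, m, f, wolb)


class TestChisqGof:
    def test_perfect_fit(self):
        stat, p = chisq_gof(15, 15, 0.5)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_unbalanced(self):
        # (O-E)^2/E with E=(15,15): 25/15 + 25/15 = 10/3
        stat, p = chisq_gof(10, 20, 0.5)
        assert stat == pytest.approx(10.0 / 3.0, abs=1e-12)
        assert p == pytest.approx(0.06788915, abs=1e-6)

    def test_observed_equals_expected_quarter(self):
        stat, p = chisq_gof(10, 30, 0.25)
        assert stat == 0.0 and p == 1.0

    def test_degenerate_expectation(self):
        with pytest.raises(DegenerateExpectationError):
            chisq_gof(0, 10, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        m=st.integers(0, 500),
        f=st.integers(0, 500),
        prop=st.floats(0.05, 0.95),
    )
    def test_agrees_with_textbook_implementation(self, m, f, prop):
        """Sum((O-E)^2/E) with a chi2(1) upper tail, written independently."""
        if m + f == 0:
            return
        n = m + f
        e_m, e_f = n * prop, n * (1 - prop)
        stat_ref = (m - e_m) ** 2 / e_m + (f - e_f) ** 2 / e_f
        p_ref = stats.chi2.sf(stat_ref, 1)
        stat, p = chisq_gof(m, f, prop)
        assert stat == pytest.approx(stat_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestExactZeroMaleTest:
    def test_no_males_consistent(self):
        assert exact_zero_male_test(0, 40, 0.0) == 1.0

    def test_any_male_falsifies_strict_xy(self):
        assert exact_zero_male_test(1, 40, 0.0) == 0.0

    def test_binomial_tail_with_leak(self):
        # P(X >= 2), X ~ Binomial(40, 0.02) = 1 - 0.98^40 - 40*0.02*0.98^39
        assert exact_zero_male_test(2, 38, 0.02) == pytest.approx(0.19046, abs=1e-4)


class TestFilterBroods:
    def test_balanced_discarded(self):
        rep = filter_broods([b(10, 10)])
        assert rep.kept == [] and rep.discarded[0][1] == "balanced_sex_ratio"

    def test_wolbachia_precedence(self):
        # Even an extreme sex ratio is discarded first on infection status.
        rep = filter_broods([b(0, 30, "positive")])
        assert rep.discarded[0][1] == "wolbachia"

    def test_biased_kept(self):
        rep = filter_broods([b(5, 35)])  # chi2 = 22.5, p < 1e-5
        assert len(rep.kept) == 1

    def test_partition_and_idempotence(self, rng):
        broods = [
            b(int(m), int(f), w, bid=str(i))
            for i, (m, f, w) in enumerate(
                zip(
                    rng.integers(0, 40, 50),
                    rng.integers(1, 40, 50),
                    rng.choice(["positive", "negative"], 50),
                )
            )
        ]
        rep = filter_broods(broods)
        assert sorted(
            [x.brood_id for x in rep.kept] + [x.brood_id for x, _ in rep.discarded]
        ) == sorted(x.brood_id for x in broods)
        rerun = filter_broods(rep.kept) if rep.kept else None
        if rerun is not None:
            assert rerun.discarded == []

    def test_untested_warns(self):
        with pytest.warns(UserWarning):
            rep = filter_broods([b(5, 35, "untested")])
        assert len(rep.kept) == 1
        with pytest.warns(UserWarning):
            rep = filter_broods([b(5, 35, "untested")], untested_policy="discard")
        assert rep.discarded[0][1] == "wolbachia"


class TestHeterogeneity:
    def test_identical_broods(self):
        assert heterogeneity_test([b(5, 15), b(5, 15)]) == 1.0

    def test_opposite_broods_closed_form(self):
        # 2x2 table: n(ad-bc)^2/(r1*r2*c1*c2) = 40; p = chi2.sf(40, 1)
        p = heterogeneity_test([b(20, 0), b(0, 20)])
        assert p == pytest.approx(2.54e-10, rel=0.01)

    def test_equal_proportions(self):
        assert heterogeneity_test([b(6, 18), b(7, 21), b(5, 15)]) == 1.0

    def test_degenerate_table(self):
        with pytest.raises(DegenerateTableError):
            heterogeneity_test([b(0, 20), b(0, 30)])


class TestClassifySpecies:
    def test_exact_three_to_one_is_indeterminate_at_n100(self):
        """(25,75) cannot reject the 1/3 ratio (chi2=3.125, p~0.077)."""
        call = classify_species([b(25, 75)])
        assert call.system == "ZW"
        assert call.ww_viability == "indeterminate"
        assert call.p_onequarter == 1.0
        assert call.p_onethird == pytest.approx(0.0771, abs=1e-3)

    def test_large_quarter_ratio_is_viable(self):
        call = classify_species([b(100, 300)])
        assert call.system == "ZW" and call.ww_viability == "viable"

    def test_large_third_ratio_is_inviable(self):
        call = classify_species([b(200, 400)])
        assert call.system == "ZW" and call.ww_viability == "inviable"

    def test_all_female_is_xy(self):
        # (0,60): both ZW ratios rejected (chi2 20 and 30), zero males.
        call = classify_species([b(0, 60)])
        assert call.system == "XY"
        assert call.ww_viability == "not_applicable"

    def test_all_male_is_undetermined(self):
        call = classify_species([b(30, 0)])
        assert call.system == "UNDETERMINED"
        assert "male_excess" in call.flags

    def test_small_all_female_is_low_power_xy_candidate(self):
        call = classify_species([b(0, 8)])
        assert call.system == "XY"
        assert "low_power" in call.flags

    def test_heterogeneous_block_policy(self):
        broods = [b(5, 35, bid="1"), b(35, 5, bid="2"), b(6, 34, bid="3")]
        call = classify_species(broods, heterogeneity_policy="block")
        assert call.system == "UNDETERMINED"
        assert "heterogeneous" in call.flags

    def test_trim_recovers_contaminated_set(self):
        """One stray near-1:1 brood is trimmed; the rest classify as ZW."""
        broods = [b(12, 38, bid=str(i)) for i in range(6)] + [b(33, 13, bid="gm")]
        call = classify_species(broods, heterogeneity_policy="trim")
        assert call.system == "ZW"
        assert any(f == "trimmed:gm" for f in call.flags)

    def test_empty_raises(self):
        with pytest.raises(NoDataError):
            classify_species([])


class TestViabilityPower:
    def test_underpowered_at_n30(self):
        """30 offspring cannot separate 1/4 from 1/3 (exact power < 0.30)."""
        # Exact oracle: sum Binomial(30, 0.25) pmf over the rejection region
        # of the 1/3-male null.
        n = 30
        males = np.arange(n + 1)
        e_m, e_f = n / 3.0, 2.0 * n / 3.0
        statv = (males - e_m) ** 2 / e_m + ((n - males) - e_f) ** 2 / e_f
        reject = stats.chi2.sf(statv, 1) < 0.05
        exact = float(stats.binom.pmf(males, n, 0.25)[reject].sum())
        assert exact < 0.30
        mc = viability_power(30, 0.25, 1.0 / 3.0, n_sim=10_000, seed=3)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_consistency_at_large_n(self):
        assert viability_power(10_000, 0.25, 1.0 / 3.0, n_sim=2_000, seed=3) > 0.99

    def test_size_equals_level(self):
        power = viability_power(500, 1.0 / 3.0, 1.0 / 3.0, n_sim=10_000, seed=3)
        assert 0.03 <= power <= 0.07

    def test_monotone_in_brood_total(self):
        grid = [30, 100, 300, 1000]
        powers = [
            viability_power(n, 0.25, 1.0 / 3.0, n_sim=4_000, seed=9) for n in grid
        ]
        # Non-decreasing within Monte-Carlo tolerance.
        for lo, hi in zip(powers, powers[1:]):
            assert hi >= lo - 0.02

    def test_reproducible(self):
        a = viability_power(100, 0.25, 1.0 / 3.0, n_sim=500, seed=7)
        assert a == viability_power(100, 0.25, 1.0 / 3.0, n_sim=500, seed=7)
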