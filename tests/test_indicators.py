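"""Lifetime-risk estimators: worked-example values, identities, errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltrmnm import (
    AbridgedLifeTable,
    AgeGrid,
    FertilitySchedule,
    GridAlignmentError,
    InputError,
    LifetimeRisk,
    MorbiditySchedule,
    SummaryInputs,
    UsageError,
    ltr_age_specific,
    ltr_from_rate,
    ltr_smo,
    ltr_summary,
    ltr_summary_nrr,
    morbidity_share,
    one_in_n,
    srb_scaling_factor,
)

REPRO = AgeGrid.reproductive()


def random_inputs(rng):
    q = rng.uniform(0, 0.15, 7)
    lx = 95_000 * np.concatenate([[1.0], np.cumprod(1 - q)])
    lt = AbridgedLifeTable(REPRO, lx[:-1], 2.5 * (lx[:-1] + lx[1:]), lx_end=lx[-1])
    fert = FertilitySchedule(REPRO, rng.uniform(0, 0.25, 7))
    morb = MorbiditySchedule.from_ratios(rng.uniform(0, 0.03, 7))
    return lt, fert, morb


class TestAgeSpecific:
    def test_namibia_contribution_30_34(self, namibia):
        # 11.19/1000 * 140.9/1000 * 455466.6/95283
        ltr = ltr_age_specific(namibia.morbidity, namibia.fertility, namibia.life_table)
        assert round(float(ltr.per_age_contributions[3]), 4) == 0.0075

    def test_namibia_total_renders_one_in_35(self, namibia):
        ltr = ltr_age_specific(namibia.morbidity, namibia.fertility, namibia.life_table)
        assert 0.0282 <= ltr.value <= 0.0284
        assert ltr.render() == "1 in 35"

    def test_zero_ratios_give_zero_everywhere(self, namibia):
        morb = MorbiditySchedule.from_ratios(np.zeros(7))
        ltr = ltr_age_specific(morb, namibia.fertility, namibia.life_table)
        assert ltr.value == 0.0
        assert np.all(ltr.per_age_contributions == 0)

    def test_constant_ratio_collapses_to_summary_route(self, namibia):
        r = 0.00803
        morb = MorbiditySchedule.from_ratios(np.full(7, r))
        a = ltr_age_specific(morb, namibia.fertility, namibia.life_table)
        s = ltr_summary(r, namibia.fertility, namibia.life_table)
        assert a.value == pytest.approx(s.value, rel=1e-14)

    def test_grid_mismatch_is_a_distinct_error(self, namibia):
        morb = MorbiditySchedule.from_ratios([0.01, 0.01], AgeGrid((15, 20), (5, 5)))
        with pytest.raises(GridAlignmentError):
            ltr_age_specific(morb, namibia.fertility, namibia.life_table)

    def test_event_kind_follows_schedule_label(self, namibia):
        morb = MorbiditySchedule.from_ratios(
            np.full(7, 0.00223), event_kind="maternal_death"
        )
        ltr = ltr_age_specific(morb, namibia.fertility, namibia.life_table)
        assert ltr.event_kind == "maternal_death"


class TestRateRoute:
    def test_single_group_closed_form(self):
        lx = np.full(7, 100_000.0)
        lt = AbridgedLifeTable(REPRO, lx, 5 * lx, lx_end=lx[0])
        rates = np.zeros(7)
        rates[0] = 0.001
        assert ltr_from_rate(rates, lt).value == pytest.approx(0.005)

    def test_equals_ratio_route_under_rate_substitution(self, namibia):
        rates = namibia.morbidity.ratio * namibia.fertility.rates
        a = ltr_from_rate(rates, namibia.life_table)
        b = ltr_age_specific(namibia.morbidity, namibia.fertility, namibia.life_table)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_equality_over_1000_random_schedules(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            lt, fert, morb = random_inputs(rng)
            a = ltr_from_rate(morb.ratio * fert.rates, lt)
            b = ltr_age_specific(morb, fert, lt)
            assert a.value == pytest.approx(b.value, rel=1e-12)


class TestSummaryRoutes:
    def test_zero_ratio_gives_zero(self, namibia):
        assert ltr_summary(0.0, namibia.fertility, namibia.life_table).value == 0.0

    def test_namibia_summary_renders_one_in_38(self, namibia):
        ltr = ltr_summary(0.00803, namibia.fertility, namibia.life_table)
        assert ltr.render() == "1 in 38"
        assert ltr.value == pytest.approx(0.0264, abs=5e-4)

    def test_linearity_in_aggregate_ratio(self, namibia):
        one = ltr_summary(0.004, namibia.fertility, namibia.life_table)
        two = ltr_summary(0.008, namibia.fertility, namibia.life_table)
        assert two.value == pytest.approx(2 * one.value, rel=1e-14)

    def test_namibia_nrr_shortcut_published_inputs(self):
        ltr = ltr_summary_nrr(SummaryInputs(0.00803, 1.554, 101, 100_000, 95_283))
        assert round(ltr.value, 4) == 0.0263
        assert ltr.render() == "1 in 38"

    def test_nrr_shortcut_one_step_arithmetic(self):
        ltr = ltr_summary_nrr(SummaryInputs(0.001, 1.0, 105, 100_000, 100_000))
        assert ltr.value == pytest.approx(0.00205)

    def test_zero_ratio_shortcut(self):
        assert ltr_summary_nrr(SummaryInputs(0.0, 1.554, 101)).value == 0.0


class TestSRBScaling:
    @pytest.mark.parametrize("srb,expected", [(101, 2.01), (105, 2.05), (100, 2.00)])
    def test_values(self, srb, expected):
        assert srb_scaling_factor(srb) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(InputError):
            srb_scaling_factor(0)


class TestSevereMaternalOutcome:
    def test_printed_components_sum(self):
        md = LifetimeRisk(0.00702, "summary_nrr", "maternal_death")
        nm = LifetimeRisk(0.0263, "summary_nrr", "mnm")
        smo = ltr_smo(md, nm)
        assert round(smo.value, 4) == 0.0333
        assert smo.render() == "1 in 30"
        assert smo.event_kind == "smo"

    def test_zero_morbidity_leaves_mortality_risk(self):
        md = LifetimeRisk(0.007, "summary", "maternal_death")
        nm = LifetimeRisk(0.0, "summary", "mnm")
        assert ltr_smo(md, nm).value == pytest.approx(0.007)

    def test_commutative_in_arguments(self):
        md = LifetimeRisk(0.007, "summary", "maternal_death")
        nm = LifetimeRisk(0.026, "summary", "mnm")
        assert ltr_smo(md, nm).value == ltr_smo(nm, md).value

    def test_mismatched_event_kinds_rejected(self):
        nm = LifetimeRisk(0.02, "summary", "mnm")
        with pytest.raises(UsageError):
            ltr_smo(nm, nm)

    def test_additivity_of_count_schedules(self, namibia):
        # summing MNM and death counts over the same births equals summing risks
        births = namibia.morbidity.live_births
        deaths = np.round(births * 0.00223)
        md_sched = MorbiditySchedule.from_counts(deaths, births, event_kind="maternal_death")
        nm_sched = MorbiditySchedule.from_counts(namibia.morbidity.cases, births)
        both = MorbiditySchedule.from_counts(namibia.morbidity.cases + deaths, births)
        md = ltr_age_specific(md_sched, namibia.fertility, namibia.life_table)
        nm = ltr_age_specific(nm_sched, namibia.fertility, namibia.life_table)
        combined = ltr_age_specific(both, namibia.fertility, namibia.life_table)
        assert ltr_smo(md, nm).value == pytest.approx(combined.value, rel=1e-12)


class TestMorbidityShare:
    def test_printed_share(self):
        nm = LifetimeRisk(0.0263, "summary_nrr", "mnm")
        smo = LifetimeRisk(0.0333, "summary_nrr", "smo")
        assert round(morbidity_share(nm, smo)) == 79

    def test_equal_risks_give_100(self):
        nm = LifetimeRisk(0.02, "summary", "mnm")
        smo = LifetimeRisk(0.02, "summary", "smo")
        assert morbidity_share(nm, smo) == pytest.approx(100.0)

    def test_zero_morbidity_gives_0(self):
        nm = LifetimeRisk(0.0, "summary", "mnm")
        smo = LifetimeRisk(0.02, "summary", "smo")
        assert morbidity_share(nm, smo) == 0.0

    def test_zero_smo_rejected(self):
        nm = LifetimeRisk(0.0, "summary", "mnm")
        smo = LifetimeRisk(0.0, "summary", "smo")
        with pytest.raises(InputError):
            morbidity_share(nm, smo)


class TestOneInN:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0263, 38), (0.0282, 35), (0.0333, 30), (0.00702, 142), (0.5, 2)],
    )
    def test_nearest_integer_reciprocal(self, value, expected):
        n, rendered = one_in_n(value)
        assert n == expected
        assert rendered == f"1 in {expected}"

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0, 1.5])
    def test_rejects_non_probabilities(self, bad):
        with pytest.raises(InputError):
            one_in_n(bad)


class TestEstimatorProperties:
    @settings(derandomize=True, max_examples=50)
    @given(k=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
    def test_linearity_and_monotonicity_in_ratios(self, k, seed):
        rng = np.random.default_rng(seed)
        lt, fert, morb = random_inputs(rng)
        base = ltr_age_specific(morb, fert, lt).value
        scaled_sched = MorbiditySchedule(morb.grid, morb.ratio * k)
        if k * base < 1:
            scaled = ltr_age_specific(scaled_sched, fert, lt).value
            assert scaled == pytest.approx(k * base, rel=1e-10)
            if k >= 1:
                assert scaled >= base

    def test_monotone_in_fertility_and_person_years(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            lt, fert, morb = random_inputs(rng)
            base = ltr_age_specific(morb, fert, lt).value
            more_fert = FertilitySchedule(fert.grid, fert.rates * 1.1)
            assert ltr_age_specific(morb, more_fert, lt).value >= base
            # smallest admissible person-years: everyone dies at interval start
            low_Lx = 5.0 * np.append(lt.lx[1:], lt.lx_end)
            slimmer = AbridgedLifeTable(lt.grid, lt.lx, low_Lx, lt.radix, lt.lx_end)
            assert ltr_age_specific(morb, fert, slimmer).value <= base
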