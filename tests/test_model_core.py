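"""Decision-tree pathways, cohort engine accounting and incremental analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sahcea as s
from sahcea.model_core import (
    EntryProfile,
    HealthState,
    combine_hazards,
    discount_factor,
    elective_treatment_cost,
    rebleed_resolution,
    run_cohort,
    short_term_pathway,
)
from sahcea.parameters import LifeTable, RebleedSchedule


def _entry(at_risk=0.0, favorable=0.0, unfavorable=0.0, dead=0.0, cost=0.0):
    return EntryProfile(upfront_cost=cost, entry_mass=np.array([at_risk, favorable, unfavorable, dead]))


class TestPathways:
    def test_no_repeat_entry(self, params):
        e = short_term_pathway("no_repeat", params)
        assert e.upfront_cost == 0.0
        assert e.entry_mass[HealthState.AT_RISK] == pytest.approx(0.173)

    def test_perfect_test_leaves_nobody_at_risk(self, params):
        p = dataclasses.replace(params, cta_sensitivity=1.0)
        e = short_term_pathway("repeat_cta", p)
        assert e.entry_mass[HealthState.AT_RISK] == 0.0

    def test_repeat_arm_false_negatives_and_stay_cost(self, params):
        e = short_term_pathway("repeat_cta", params)
        assert e.entry_mass[HealthState.AT_RISK] == pytest.approx(0.173 * 0.02)
        # with nobody harboring an aneurysm the upfront cost reduces to
        # the 7-day stay plus the CTA: 7 x 380.75 + 331
        none = dataclasses.replace(params, prevalence_aneurysm=0.0)
        assert short_term_pathway("repeat_cta", none).upfront_cost == pytest.approx(2_996.25)

    def test_false_positives_pay_dsa_only(self, params):
        p = dataclasses.replace(params, prevalence_aneurysm=0.0, cta_specificity=0.9)
        e = short_term_pathway("repeat_cta", p)
        assert e.branch_log["false_positive"] == pytest.approx(0.1)
        assert e.upfront_cost == pytest.approx(2_996.25 + 0.1 * 1_919.00)

    def test_entry_mass_sums_to_one(self, params):
        for arm in s.ARMS:
            assert short_term_pathway(arm, params).entry_mass.sum() == pytest.approx(1.0)

    def test_unknown_arm_rejected(self, params):
        with pytest.raises(ValueError, match="unknown arm"):
            short_term_pathway("watchful_waiting", params)


class TestRebleedResolution:
    def test_even_coiling_mix(self, params):
        cost, outcome = rebleed_resolution(params)
        assert cost == pytest.approx((19_983.87 + 20_275.02) / 2)
        assert outcome[:2] == pytest.approx([0.0752, 0.3948])
        assert outcome.sum() == pytest.approx(1.0)

    def test_pure_coiling(self, params):
        p = dataclasses.replace(params, coiling_fraction=1.0)
        assert rebleed_resolution(p)[0] == pytest.approx(19_983.87)
        assert elective_treatment_cost(p) == pytest.approx(14_030.80)


class TestElementalOps:
    @pytest.mark.parametrize(
        "p_state,q_age,expected", [(0.0, 0.3, 0.3), (1.0, 0.3, 1.0), (0.1, 0.2, 0.28)]
    )
    def test_combine_hazards_examples(self, p_state, q_age, expected):
        assert combine_hazards(p_state, q_age) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_combine_hazards_properties(self, a, b):
        c = combine_hazards(a, b)
        assert combine_hazards(b, a) == c
        assert max(a, b) <= c <= 1.0

    def test_combine_hazards_domain(self):
        with pytest.raises(ValueError):
            combine_hazards(-0.1, 0.5)

    def test_discount_factor(self):
        assert discount_factor(0, 0.035) == 1.0
        assert discount_factor(7, 0.0) == 1.0
        assert discount_factor(2, 0.035) == pytest.approx(0.93351, abs=1e-5)
        with pytest.raises(ValueError):
            discount_factor(1, -1.5)


class TestCohortEngine:
    def test_all_dead_entry_is_inert(self, params, tm):
        trace = run_cohort(_entry(dead=1.0), tm, params)
        assert trace.total_cost == 0.0
        assert trace.total_qaly == 0.0

    def test_geometric_series_limit(self, params, immortal_life_table, no_rebleed_schedule):
        # single living state, constant annual death p, constant reward
        p_die, rate, horizon = 0.2, 0.035, 30
        p = dataclasses.replace(
            params,
            state_mortality=(p_die, 0.5, 0.5 - p_die),
            start_age=0,
            stop_age=horizon + 1,  # keep the forced-terminal cycle out of scope
        )
        tm = s.TransitionModel(immortal_life_table, no_rebleed_schedule)
        trace = run_cohort(_entry(favorable=1.0), tm, p)
        expected = p.utility_favorable * sum(
            ((1 - p_die) / (1 + rate)) ** t for t in range(1, horizon + 1)
        )
        partial = trace.qaly_accrual[:horizon].sum()
        assert partial == pytest.approx(expected, rel=1e-9)

    def test_single_cycle_nursing_cost(self, params, immortal_life_table, no_rebleed_schedule):
        # an unfavorable cohort with no mortality accrues one discounted
        # year of nursing per cycle
        p = dataclasses.replace(params, state_mortality=(0.0, 0.0, 1.0), start_age=0, stop_age=5)
        tm = s.TransitionModel(immortal_life_table, no_rebleed_schedule)
        trace = run_cohort(_entry(unfavorable=1.0), tm, p)
        assert trace.cost_accrual[0] == pytest.approx(84_346.39 / 1.035)

    def test_mass_conserved_and_dead_monotone(self, params, tm):
        for arm in s.ARMS:
            trace = s.evaluate_strategy(arm, params, tm).trace
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = trace.occupancy[:, HealthState.DEAD]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_discount_monotonicity(self, params, tm):
        def totals(rate):
            p = dataclasses.replace(params, discount_qaly=rate, discount_cost=rate)
            res = s.evaluate_strategy("no_repeat", p, tm)
            return res.expected_cost, res.expected_qaly

        c_hi, q_hi = totals(0.07)
        c_lo, q_lo = totals(0.0)
        assert c_hi <= c_lo and q_hi <= q_lo

    def test_qaly_monotone_in_sensitivity(self, params, tm):
        qalys = [
            s.evaluate_strategy(
                "repeat_cta", dataclasses.replace(params, cta_sensitivity=sens), tm
            ).expected_qaly
            for sens in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(qalys) >= -1e-12)

    def test_degenerate_test_equivalence(self, params, tm):
        # an uninformative repeat test (sens 0, spec 1) changes nothing
        # but the upfront stay + CTA cost
        p = dataclasses.replace(params, cta_sensitivity=0.0, cta_specificity=1.0)
        ref = s.evaluate_strategy("no_repeat", p, tm)
        comp = s.evaluate_strategy("repeat_cta", p, tm)
        stay_and_cta = p.los_days * p.cost_hospital_day + p.cost_cta
        assert comp.expected_cost - ref.expected_cost == pytest.approx(stay_and_cta, abs=1e-9)
        assert comp.expected_qaly == pytest.approx(ref.expected_qaly, abs=1e-9)

    def test_half_cycle_correction_adds_first_half_cycle(self, params, tm):
        hcc = dataclasses.replace(params, half_cycle_correction=True)
        plain = s.evaluate_strategy("no_repeat", params, tm)
        corrected = s.evaluate_strategy("no_repeat", hcc, tm)
        assert corrected.expected_qaly > plain.expected_qaly

    def test_matrix_mode_allows_recovery_moves(self, params, tm):
        m = np.array([[0.85, 0.05, 0.10], [0.10, 0.60, 0.30], [0.0, 0.0, 1.0]])
        tm2 = s.TransitionModel(tm.life_table, tm.rebleed_schedule, outcome_matrix=m)
        trace = run_cohort(_entry(favorable=1.0), tm2, params)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert trace.occupancy[0, HealthState.UNFAVORABLE] > 0

    def test_bad_matrix_rejected(self, tm):
        m = np.array([[0.9, 0.2, 0.1], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="favorable"):
            s.TransitionModel(tm.life_table, tm.rebleed_schedule, outcome_matrix=m)


class TestIncrementalAnalysis:
    @staticmethod
    def _result(cost, qaly, label="x"):
        entry = _entry(favorable=1.0)
        trace = run_cohort(entry, s.default_transition_fixture(), s.default_parameters())
        return s.StrategyResult(label, cost, qaly, entry, trace)

    def test_published_table_identity(self):
        ref = self._result(7_430.0, 4.656)
        comp = self._result(7_430.0 + 2_635.29, 4.656 + 0.283)
        cmp_ = s.incremental_analysis(ref, comp, wtp=20_000.0)
        assert cmp_.label == "icer"
        assert 9_300 <= cmp_.icer <= 9_325
        assert cmp_.nmb == pytest.approx(20_000 * 0.283 - 2_635.29)

    def test_dominance(self):
        cmp_ = s.incremental_analysis(self._result(100.0, 1.0), self._result(50.0, 2.0))
        assert cmp_.label == "dominant"
        cmp_ = s.incremental_analysis(self._result(50.0, 2.0), self._result(100.0, 1.0))
        assert cmp_.label == "dominated"

    def test_identical_results(self):
        cmp_ = s.incremental_analysis(self._result(10.0, 1.0), self._result(10.0, 1.0))
        assert cmp_.icer is None
        assert cmp_.label == "undefined"
        assert cmp_.nmb == 0.0
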