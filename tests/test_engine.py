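"""Cohort engine: conversions, matrices, rewards, propagation invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdpp_cea import (
    HealthState,
    ModelConfig,
    MortalityModel,
    ScenarioFlags,
    StrategyArm,
    annual_to_monthly_prob,
    build_transition_matrix,
    cycle_rewards,
    expected_multiplier,
    generate_synthetic_life_table,
    initial_distribution,
    run_cohort,
    summarize,
)

S = HealthState


def tiny_mortality_model():
    """Effectively immortal cohort (q ~ 1e-13) for closed-form checks."""
    return MortalityModel(generate_synthetic_life_table(a=1e-13, b=0.0), 0.75)


class TestAnnualToMonthly:
    @pytest.mark.parametrize("p", [0.0, 0.004, 0.108, 0.121, 0.162, 0.9])
    def test_twelvefold_compounding_recovers_annual(self, p):
        q = annual_to_monthly_prob(p)
        assert 1 - (1 - q) ** 12 == pytest.approx(p, abs=1e-12)

    def test_preserves_strict_ordering(self):
        assert annual_to_monthly_prob(0.121) < annual_to_monthly_prob(0.162)

    @pytest.mark.parametrize("p", [1.0, 1.5, -0.1])
    def test_rejects_out_of_range(self, p):
        with pytest.raises(ValueError):
            annual_to_monthly_prob(p)


class TestInitialDistribution:
    def test_base_case_split(self, params):
        occ = initial_distribution(StrategyArm.MDPP, params)
        assert occ[S.RF_NEG] == pytest.approx(0.690)
        assert occ[S.RF_POS_ENROLLED] == pytest.approx(0.31 * 0.47)
        assert occ[S.RF_POS_NOT_ENROLLED] == pytest.approx(0.31 * 0.53)
        assert occ[S.STABLE_DM] == occ[S.COMPLICATED_DM] == occ[S.DEAD] == 0.0
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)

    def test_usual_care_has_no_enrollment(self, params):
        occ = initial_distribution(StrategyArm.USUAL_CARE, params)
        assert occ[S.RF_POS_ENROLLED] == 0.0
        assert occ[S.RF_POS_NOT_ENROLLED] == pytest.approx(0.31)

    def test_no_positive_screens_all_risk_factor_negative(self, params):
        p0 = params.with_values({"p_screen_positive": 0.0})
        for arm in StrategyArm:
            occ = initial_distribution(arm, p0)
            assert occ[S.RF_NEG] == 1.0

    def test_enrollment_does_not_touch_usual_care(self, params):
        p1 = params.with_values({"p_enroll": 1.0})
        occ = initial_distribution(StrategyArm.USUAL_CARE, p1)
        assert np.array_equal(occ, initial_distribution(StrategyArm.USUAL_CARE, params))


class TestExpectedMultiplier:
    def test_unit_multipliers_are_neutral(self):
        assert expected_multiplier([0.3, 0.9], [1.0, 1.0]) == 1.0

    def test_single_condition(self):
        assert expected_multiplier([0.75], [1.14]) == pytest.approx(1.105)

    def test_product_form(self):
        got = expected_multiplier([0.75, 0.271], [1.14, 0.82])
        assert got == pytest.approx((1 + 0.75 * 0.14) * (1 - 0.271 * 0.18))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            expected_multiplier([1.5], [1.1])
        with pytest.raises(ValueError):
            expected_multiplier([0.5], [-1.0])


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", list(StrategyArm))
    @pytest.mark.parametrize("year", [1, 2, 3])
    def test_rows_stochastic_dead_absorbing(self, params, mortality, arm, year):
        P = build_transition_matrix(arm, year, 54 + year, params, mortality)
        assert np.abs(P.sum(axis=1) - 1.0).max() <= 1e-12
        assert np.all((P >= 0.0) & (P <= 1.0))
        expected_dead = np.zeros(len(S))
        expected_dead[S.DEAD] = 1.0
        assert np.array_equal(P[S.DEAD], expected_dead)

    def test_no_resolution_after_year1_both_zeroes_both_rates(self, params, mortality):
        flags = ScenarioFlags(mets_resolution_mode="none_after_year1_both")
        P = build_transition_matrix(StrategyArm.MDPP, 2, 56, params, mortality, flags)
        assert P[S.RF_POS_ENROLLED, S.RF_NEG] == 0.0
        assert P[S.RF_POS_NOT_ENROLLED, S.RF_NEG] == 0.0

    def test_enrolled_resolution_reverts_to_no_program_rate_after_year1(self, params, mortality):
        P2 = build_transition_matrix(StrategyArm.MDPP, 2, 56, params, mortality)
        d = mortality.monthly_death_prob(56, params.rr_death_rfpos.base)
        expect = (1 - d) * annual_to_monthly_prob(0.121)
        assert P2[S.RF_POS_ENROLLED, S.RF_NEG] == pytest.approx(expect, rel=1e-12)
        assert P2[S.RF_POS_ENROLLED, S.RF_NEG] == pytest.approx(
            P2[S.RF_POS_NOT_ENROLLED, S.RF_NEG], rel=1e-12
        )
        P1 = build_transition_matrix(StrategyArm.MDPP, 1, 55, params, mortality)
        d1 = mortality.monthly_death_prob(55, params.rr_death_rfpos.base)
        assert P1[S.RF_POS_ENROLLED, S.RF_NEG] == pytest.approx(
            (1 - d1) * annual_to_monthly_prob(0.162), rel=1e-12
        )

    def test_year1_nonenrolled_keeps_resolving_in_enrolled_only_scenario(self, params, mortality):
        flags = ScenarioFlags(mets_resolution_mode="none_after_year1_enrolled_only")
        P = build_transition_matrix(StrategyArm.MDPP, 3, 57, params, mortality, flags)
        assert P[S.RF_POS_ENROLLED, S.RF_NEG] == 0.0
        assert P[S.RF_POS_NOT_ENROLLED, S.RF_NEG] > 0.0

    def test_excess_exit_probability_guarded(self, params, mortality):
        bad = params.with_values(
            {"p_dm_rfpos_no_program_yr": 0.9999999999, "p_resolve_no_program_yr": 0.9999999999}
        )
        with pytest.raises(ValueError, match="exceeds 1"):
            build_transition_matrix(StrategyArm.USUAL_CARE, 1, 55, bad, mortality)


class TestCycleRewards:
    def test_dead_state_accrues_nothing(self, params):
        for cycle in (0, 1, 35):
            cost, util = cycle_rewards(StrategyArm.MDPP, params, None, cycle)
            assert cost[S.DEAD] == util[S.DEAD] == 0.0

    def test_usual_care_has_no_one_time_costs(self, params):
        c0, _ = cycle_rewards(StrategyArm.USUAL_CARE, params, None, 0)
        c1, _ = cycle_rewards(StrategyArm.USUAL_CARE, params, None, 1)
        assert np.array_equal(c0, c1)

    def test_mdpp_cycle0_lump_per_starting_member(self, params):
        c0, _ = cycle_rewards(StrategyArm.MDPP, params, None, 0)
        c1, _ = cycle_rewards(StrategyArm.MDPP, params, None, 1)
        occ0 = initial_distribution(StrategyArm.MDPP, params)
        lump = occ0 @ (c0 - c1)
        assert lump == pytest.approx(0.31 * 35 + 0.69 * 32 + 0.31 * 0.47 * 219, rel=1e-12)

    def test_equalized_utilities_use_program_value(self, params):
        flags = ScenarioFlags(equalize_rfpos_utilities=True)
        _, util = cycle_rewards(StrategyArm.USUAL_CARE, params, flags, 1)
        assert util[S.RF_POS_NOT_ENROLLED] == pytest.approx(0.75 / 12)

    def test_demographic_multipliers_enter_state_costs(self, params):
        c1, _ = cycle_rewards(StrategyArm.USUAL_CARE, params, None, 1)
        assert c1[S.RF_NEG] == pytest.approx(616 / 12)  # no multiplier on RF- cost
        rf_mult = (1 + 0.75 * 0.14) * (1 - 0.271 * 0.18)
        assert c1[S.RF_POS_NOT_ENROLLED] == pytest.approx(1296 * rf_mult / 12)
        assert c1[S.COMPLICATED_DM] > c1[S.STABLE_DM]  # comorbidity load


class TestRunCohort:
    @pytest.mark.parametrize("arm", list(StrategyArm))
    def test_mass_conserved_and_dead_monotone(self, config, params, mortality, arm):
        trace = run_cohort(arm, config, params, mortality)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() <= 1e-12
        dead = trace.occupancy[:, S.DEAD]
        assert np.all(np.diff(dead) >= 0.0)

    def test_zero_mortality_empties_dead_state(self, config, params):
        trace = run_cohort(StrategyArm.MDPP, config, params, tiny_mortality_model())
        assert trace.occupancy[:, S.DEAD].max() < 1e-12

    def test_single_state_closed_form_qalys(self, params):
        # whole cohort risk-factor-negative, no transitions, no discounting:
        # 36 months at utility 0.88 is exactly 2.64 QALYs
        p = params.with_values(
            {"p_screen_positive": 0.0, "p_dm_rfneg_yr": 0.0, "p_become_rfpos_yr": 0.0}
        )
        cfg = ModelConfig(annual_discount_rate=0.0)
        trace = run_cohort(StrategyArm.USUAL_CARE, cfg, p, tiny_mortality_model())
        total = trace.discounted_qaly_per_cycle.sum()
        assert total == pytest.approx(3 * 0.88, abs=1e-9)

    def test_discounting_strictly_shrinks_totals(self, config, params, mortality):
        t3 = run_cohort(StrategyArm.USUAL_CARE, config, params, mortality)
        t0 = run_cohort(
            StrategyArm.USUAL_CARE,
            dataclasses.replace(config, annual_discount_rate=0.0),
            params,
            mortality,
        )
        assert t3.discounted_cost_per_cycle.sum() < t0.discounted_cost_per_cycle.sum()
        assert t3.discounted_qaly_per_cycle.sum() < t0.discounted_qaly_per_cycle.sum()

    def test_strategy_ordering_base_case(self, config, params, mortality):
        out_m = summarize(run_cohort(StrategyArm.MDPP, config, params, mortality))
        out_u = summarize(run_cohort(StrategyArm.USUAL_CARE, config, params, mortality))
        assert out_m.total_discounted_cost > out_u.total_discounted_cost
        assert out_m.total_discounted_qaly > out_u.total_discounted_qaly

    def test_incidence_flow_accounting(self, config, params, mortality):
        for arm in StrategyArm:
            out = summarize(run_cohort(arm, config, params, mortality))
            assert 0.0 <= out.cum_complication_incidence <= out.cum_diabetes_incidence <= 1.0
        p_nodm = params.with_values(
            {"p_dm_rfpos_no_program_yr": 0.0, "p_dm_in_program_yr": 0.0, "p_dm_rfneg_yr": 0.0}
        )
        out = summarize(run_cohort(StrategyArm.MDPP, config, p_nodm, mortality))
        assert out.cum_diabetes_incidence == 0.0
        assert out.cum_complication_incidence == 0.0

    def test_trace_exports_tidy_frame(self, config, params, mortality):
        trace = run_cohort(StrategyArm.MDPP, config, params, mortality)
        df = trace.to_frame()
        assert list(df.columns) == [
            "cycle", "state", "occupancy", "discounted_cost", "discounted_qaly", "arm",
        ]
        assert len(df) == (config.horizon_cycles + 1) * len(S)
        assert set(df["arm"]) == {"MDPP"}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    p_dm_pos=st.floats(0.029, 0.233),
    p_dm_in=st.floats(0.013, 0.105),
    p_res_no=st.floats(0.032, 0.259),
    p_res_in=st.floats(0.042, 0.344),
    p_screen=st.floats(0.072, 0.635),
    p_enroll=st.floats(0.092, 0.867),
    rr_comp=st.floats(1.0, 5.0),
    arm=st.sampled_from(list(StrategyArm)),
)
def test_propagation_invariants_hold_across_parameter_space(
    p_dm_pos, p_dm_in, p_res_no, p_res_in, p_screen, p_enroll, rr_comp, arm
):
    """Row-stochasticity, mass conservation and dead-state monotonicity are
    structural: they hold for any admissible parameter draw."""
    from mdpp_cea import default_life_table, default_parameter_set

    p = default_parameter_set().with_values(
        {
            "p_dm_rfpos_no_program_yr": p_dm_pos,
            "p_dm_in_program_yr": p_dm_in,
            "p_resolve_no_program_yr": p_res_no,
            "p_resolve_in_program_yr": p_res_in,
            "p_screen_positive": p_screen,
            "p_enroll": p_enroll,
            "rr_death_complicated_dm": rr_comp,
        }
    )
    m = MortalityModel(default_life_table(), 0.75)
    trace = run_cohort(arm, ModelConfig(), p, m)
    assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() <= 1e-12
    assert np.all(np.diff(trace.occupancy[:, S.DEAD]) >= -1e-15)
    assert np.all(trace.occupancy >= -1e-15)
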