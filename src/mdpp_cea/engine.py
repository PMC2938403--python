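"""Markov cohort engine: transition matrices, cohort propagation, accrual.

The model follows a screened adult cohort through six health states —
risk-factor-negative (RF-), risk-factor-positive enrolled in the lifestyle
program, risk-factor-positive not enrolled, stable diabetes, complicated
diabetes, and dead — in monthly cycles over a 3-year horizon. Screening and
(for the intervention arm) program enrollment happen once, at model start.

Conventions (each is a deliberate modelling choice, see the methods note):

* annual probabilities convert to monthly via the constant-hazard rule
  ``1 - (1 - p) ** (1/12)``, so twelve-cycle compounding is exact;
* within a cycle, death (baseline mortality times the state's hazard-ratio
  relative risk) is applied first, and the remaining transitions are
  conditional on survival with the stay-probability as residual;
* rewards accrue at cycle start (no half-cycle correction) and are
  discounted with the compound-equivalent monthly factor
  ``(1 + r) ** (-t/12)``;
* cohort age advances one year every 12 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mortality import MortalityModel
from .params import CohortProfile, ModelConfig, ParameterSet, ScenarioFlags

__all__ = [
    "HealthState",
    "StrategyArm",
    "N_STATES",
    "annual_to_monthly_prob",
    "expected_multiplier",
    "rfpos_cost_multiplier",
    "stable_dm_cost_multiplier",
    "complicated_dm_cost_multiplier",
    "initial_distribution",
    "build_transition_matrix",
    "cycle_rewards",
    "run_cohort",
    "summarize",
    "CohortTrace",
    "ArmOutcome",
]

ROW_TOL = 1e-12


class HealthState(IntEnum):
    RF_NEG = 0
    RF_POS_ENROLLED = 1
    RF_POS_NOT_ENROLLED = 2
    STABLE_DM = 3
    COMPLICATED_DM = 4
    DEAD = 5


class StrategyArm(IntEnum):
    MDPP = 0
    USUAL_CARE = 1


N_STATES = len(HealthState)


def annual_to_monthly_prob(p_annual: float) -> float:
    """Constant-hazard conversion of an annual probability to monthly."""
    if not (0.0 <= p_annual < 1.0):
        raise ValueError(f"annual probability must lie in [0, 1), got {p_annual}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def expected_multiplier(prevalences: Sequence[float], multipliers: Sequence[float]) -> float:
    """Cohort-expected cost multiplier under independent binary conditions.

    Each condition with prevalence ``prev`` and multiplier ``mult``
    contributes a factor ``1 + prev * (mult - 1)``, the expectation of
    ``mult ** flag`` for a Bernoulli flag; factors multiply because the
    condition flags are independent.
    """
    if len(prevalences) != len(multipliers):
        raise ValueError("prevalences and multipliers must align")
    out = 1.0
    for prev, mult in zip(prevalences, multipliers):
        if not (0.0 <= prev <= 1.0):
            raise ValueError(f"prevalence {prev} outside [0, 1]")
        if mult <= 0.0:
            raise ValueError(f"multiplier {mult} must be positive")
        out *= 1.0 + prev * (mult - 1.0)
    return out


def rfpos_cost_multiplier(v: Mapping[str, float], cohort: CohortProfile) -> float:
    return expected_multiplier(
        [cohort.fraction_female, cohort.fraction_african_american],
        [v["mult_rfpos_female"], v["mult_rfpos_aa"]],
    )


def stable_dm_cost_multiplier(v: Mapping[str, float], cohort: CohortProfile) -> float:
    return expected_multiplier(
        [cohort.fraction_female, cohort.fraction_african_american],
        [v["mult_dm_female"], v["mult_dm_aa"]],
    )


def complicated_dm_cost_multiplier(v: Mapping[str, float], cohort: CohortProfile) -> float:
    """Female/African-American plus the five comorbidity multipliers."""
    return expected_multiplier(
        [
            cohort.fraction_female,
            cohort.fraction_african_american,
            cohort.prev_angina,
            cohort.prev_htn_treated,
            cohort.prev_mi,
            cohort.prev_stroke,
            cohort.prev_pvd,
        ],
        [
            v["mult_comp_female"],
            v["mult_comp_aa"],
            v["mult_comp_angina"],
            v["mult_comp_htn"],
            v["mult_comp_mi"],
            v["mult_comp_stroke"],
            v["mult_comp_pvd"],
        ],
    )


def initial_distribution(arm: StrategyArm, p: ParameterSet) -> np.ndarray:
    """Cycle-0 state occupancy after the one-time screening evaluation.

    In the intervention arm, screened risk-factor-positive subjects enroll
    with probability ``p_enroll``; usual care has no program, so all
    risk-factor-positive mass starts non-enrolled.
    """
    v = p.values()
    pos, enr = v["p_screen_positive"], v["p_enroll"]
    occ = np.zeros(N_STATES)
    occ[HealthState.RF_NEG] = 1.0 - pos
    if arm == StrategyArm.MDPP:
        occ[HealthState.RF_POS_ENROLLED] = pos * enr
        occ[HealthState.RF_POS_NOT_ENROLLED] = pos * (1.0 - enr)
    else:
        occ[HealthState.RF_POS_NOT_ENROLLED] = pos
    return occ


def _resolution_rates(v: Mapping[str, float], model_year: int, flags: ScenarioFlags) -> tuple[float, float]:
    """(annual resolution for enrolled, for non-enrolled) in ``model_year``."""
    mode = flags.mets_resolution_mode
    if model_year == 1:
        enrolled = v["p_resolve_in_program_yr"]
        nonenrolled = v["p_resolve_no_program_yr"]
    else:
        enrolled = 0.0 if mode != "base" else v["p_resolve_no_program_yr"]
        nonenrolled = 0.0 if mode == "none_after_year1_both" else v["p_resolve_no_program_yr"]
    return enrolled, nonenrolled


def build_transition_matrix(
    arm: StrategyArm,
    model_year: int,
    age: int,
    p: ParameterSet,
    m: MortalityModel,
    flags: ScenarioFlags | None = None,
) -> np.ndarray:
    """Monthly transition matrix for one strategy arm, model year and age.

    Rows index the origin state, columns the destination; each row sums to
    one. Death is applied first from baseline mortality times the state's
    relative risk; all other exits are survival-conditional.
    """
    flags = flags or ScenarioFlags()
    if model_year < 1:
        raise ValueError("model_year counts from 1")
    v = p.values()
    res_enr, res_non = _resolution_rates(v, model_year, flags)

    P = np.zeros((N_STATES, N_STATES))

    def fill_row(state: HealthState, rr: float, exits: Mapping[HealthState, float]) -> None:
        d = m.monthly_death_prob(age, rr)
        s = 1.0 - d
        total_exit = sum(exits.values())
        if total_exit > 1.0:
            raise ValueError(
                f"combined monthly exit probability {total_exit:.4f} from "
                f"{state.name} exceeds 1"
            )
        for to, prob in exits.items():
            P[state, to] = s * prob
        P[state, state] = s * (1.0 - total_exit)
        P[state, HealthState.DEAD] = d

    fill_row(
        HealthState.RF_NEG,
        v["rr_death_rfneg"],
        {
            HealthState.STABLE_DM: annual_to_monthly_prob(v["p_dm_rfneg_yr"]),
            HealthState.RF_POS_NOT_ENROLLED: annual_to_monthly_prob(v["p_become_rfpos_yr"]),
        },
    )
    fill_row(
        HealthState.RF_POS_ENROLLED,
        v["rr_death_rfpos"],
        {
            HealthState.STABLE_DM: annual_to_monthly_prob(v["p_dm_in_program_yr"]),
            HealthState.RF_NEG: annual_to_monthly_prob(res_enr),
        },
    )
    fill_row(
        HealthState.RF_POS_NOT_ENROLLED,
        v["rr_death_rfpos"],
        {
            HealthState.STABLE_DM: annual_to_monthly_prob(v["p_dm_rfpos_no_program_yr"]),
            HealthState.RF_NEG: annual_to_monthly_prob(res_non),
        },
    )
    fill_row(
        HealthState.STABLE_DM,
        v["rr_death_stable_dm"],
        {HealthState.COMPLICATED_DM: annual_to_monthly_prob(v["p_progress_complicated_yr"])},
    )
    fill_row(HealthState.COMPLICATED_DM, v["rr_death_complicated_dm"], {})
    P[HealthState.DEAD, HealthState.DEAD] = 1.0

    row_err = np.abs(P.sum(axis=1) - 1.0).max()
    if row_err > ROW_TOL:
        raise AssertionError(f"transition rows not stochastic (max error {row_err})")
    return P


def cycle_rewards(
    arm: StrategyArm,
    p: ParameterSet,
    flags: ScenarioFlags | None = None,
    cycle_index: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state (cost, utility) accrued in one monthly cycle.

    Annual state costs and utilities are divided by 12. The risk-factor-
    positive and diabetes costs carry the cohort-expected demographic
    multipliers (comorbidity multipliers apply to complicated diabetes
    only); the RF- cost carries none. When ``equalize_rfpos_utilities`` is
    set, both risk-factor-positive states use the in-program utility.

    At cycle 0 of the intervention arm the one-time costs are added per
    starting state: the screening cost appropriate to the screening result,
    plus the program cost for the enrolled.
    """
    flags = flags or ScenarioFlags()
    v = p.values()
    cohort = p.base_cohort()

    util = np.zeros(N_STATES)
    util[HealthState.RF_NEG] = v["u_rfneg"]
    util[HealthState.RF_POS_ENROLLED] = v["u_rfpos_program"]
    util[HealthState.RF_POS_NOT_ENROLLED] = (
        v["u_rfpos_program"] if flags.equalize_rfpos_utilities else v["u_rfpos_usual"]
    )
    util[HealthState.STABLE_DM] = v["u_stable_dm"]
    util[HealthState.COMPLICATED_DM] = v["u_complicated_dm"]
    util /= 12.0

    cost = np.zeros(N_STATES)
    c_rfpos = v["c_rfpos_yr"] * rfpos_cost_multiplier(v, cohort)
    cost[HealthState.RF_NEG] = v["c_rfneg_yr"]
    cost[HealthState.RF_POS_ENROLLED] = c_rfpos
    cost[HealthState.RF_POS_NOT_ENROLLED] = c_rfpos
    cost[HealthState.STABLE_DM] = v["c_dm_base_yr"] * stable_dm_cost_multiplier(v, cohort)
    cost[HealthState.COMPLICATED_DM] = v["c_complicated_dm_base_yr"] * complicated_dm_cost_multiplier(v, cohort)
    cost /= 12.0

    if cycle_index == 0 and arm == StrategyArm.MDPP:
        cost[HealthState.RF_NEG] += v["c_screen_negative"]
        cost[HealthState.RF_POS_ENROLLED] += v["c_screen_positive"] + v["c_program"]
        cost[HealthState.RF_POS_NOT_ENROLLED] += v["c_screen_positive"]
    return cost, util


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and discounted accruals for one arm."""

    arm: StrategyArm
    occupancy: np.ndarray  # (horizon + 1, N_STATES)
    discounted_cost_per_cycle: np.ndarray  # (horizon,)
    discounted_qaly_per_cycle: np.ndarray  # (horizon,)
    dm_inflow_per_cycle: np.ndarray  # mass newly entering stable diabetes
    comp_inflow_per_cycle: np.ndarray  # mass newly entering complicated diabetes

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, state)."""
        horizon = self.discounted_cost_per_cycle.size
        rows = []
        for t in range(horizon + 1):
            for s in HealthState:
                rows.append(
                    {
                        "cycle": t,
                        "state": s.name,
                        "occupancy": float(self.occupancy[t, s]),
                        "discounted_cost": (
                            float(self.discounted_cost_per_cycle[t]) if t < horizon else np.nan
                        ),
                        "discounted_qaly": (
                            float(self.discounted_qaly_per_cycle[t]) if t < horizon else np.nan
                        ),
                        "arm": StrategyArm(self.arm).name,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals and cumulative incidences for one strategy arm."""

    total_discounted_cost: float
    total_discounted_qaly: float
    cum_diabetes_incidence: float
    cum_complication_incidence: float


def run_cohort(
    arm: StrategyArm,
    config: ModelConfig,
    p: ParameterSet,
    m: MortalityModel,
    flags: ScenarioFlags | None = None,
) -> CohortTrace:
    """Propagate the cohort over the horizon, accruing discounted rewards.

    Scenario parameter overrides in ``flags.parameter_overrides`` are
    applied before anything is computed.
    """
    flags = flags if flags is not None else config.scenario
    if flags.parameter_overrides:
        p = p.with_values(flags.parameter_overrides)

    horizon = config.horizon_cycles
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = initial_distribution(arm, p)
    cost_t = np.zeros(horizon)
    qaly_t = np.zeros(horizon)
    dm_in = np.zeros(horizon)
    comp_in = np.zeros(horizon)

    matrices: dict[int, np.ndarray] = {}
    r = config.annual_discount_rate
    for t in range(horizon):
        year = t // 12 + 1
        age = config.starting_age + t // 12
        if year not in matrices:
            matrices[year] = build_transition_matrix(arm, year, age, p, m, flags)
        P = matrices[year]
        cost_vec, util_vec = cycle_rewards(arm, p, flags, cycle_index=t)
        disc = (1.0 + r) ** (-t / 12.0)
        cost_t[t] = occ[t] @ cost_vec * disc
        qaly_t[t] = occ[t] @ util_vec * disc
        # inflow accounting: mass arriving from a *different* state
        nxt = occ[t] @ P
        dm_in[t] = nxt[HealthState.STABLE_DM] - occ[t, HealthState.STABLE_DM] * P[
            HealthState.STABLE_DM, HealthState.STABLE_DM
        ]
        comp_in[t] = nxt[HealthState.COMPLICATED_DM] - occ[t, HealthState.COMPLICATED_DM] * P[
            HealthState.COMPLICATED_DM, HealthState.COMPLICATED_DM
        ]
        occ[t + 1] = nxt

    mass_err = np.abs(occ.sum(axis=1) - 1.0).max()
    if mass_err > 1e-9:
        raise AssertionError(f"cohort mass not conserved (max error {mass_err})")
    return CohortTrace(
        arm=arm,
        occupancy=occ,
        discounted_cost_per_cycle=cost_t,
        discounted_qaly_per_cycle=qaly_t,
        dm_inflow_per_cycle=dm_in,
        comp_inflow_per_cycle=comp_in,
    )


def summarize(trace: CohortTrace) -> ArmOutcome:
    """Totals and cumulative incidences from a cohort trace.

    Cumulative incidence is the total probability mass that ever flowed
    into the state (inflow accounting), not the point occupancy at the end
    of the horizon.
    """
    return ArmOutcome(
        total_discounted_cost=float(trace.discounted_cost_per_cycle.sum()),
        total_discounted_qaly=float(trace.discounted_qaly_per_cycle.sum()),
        cum_diabetes_incidence=float(trace.dm_inflow_per_cycle.sum()),
        cum_complication_incidence=float(trace.comp_inflow_per_cycle.sum()),
    )
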