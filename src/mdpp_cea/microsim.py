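"""Individual-level Monte-Carlo simulator of the same natural history.

Walks ``n`` independent individuals through the identical per-cycle
transition probabilities used by the cohort engine, so its sample means are
unbiased estimators of the cohort expectations — it serves as a brute-force
validation oracle and as a synthetic-cohort generator.

Two deliberate differences from the cohort engine:

* demographic and comorbidity *cost multipliers* are applied per individual
  from sampled Bernoulli flags (female, African American, angina, treated
  hypertension, MI history, stroke history, PVD) rather than as the
  prevalence-weighted expectation — because the flags are independent, the
  expectations coincide exactly, and the simulator measures the sampling
  error around that identity;
* mortality uses the same sex-mixture monthly probabilities as the cohort
  engine (sampled sex drives only costs), which is what makes the oracle
  exact for the engine's pooled-cohort design.

Draw order is fixed and documented for reproducibility: sex, race, the five
comorbidity flags, screening result, enrollment, then one uniform per
individual per cycle (cycle-major).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import HealthState, N_STATES, StrategyArm, build_transition_matrix, cycle_rewards
from .mortality import MortalityModel
from .params import ModelConfig, ParameterSet, ScenarioFlags

__all__ = ["MicrosimResult", "simulate_individuals", "export_synthetic_cohort", "load_synthetic_cohort"]


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimates (means and standard errors) for one arm."""

    arm: StrategyArm
    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    cum_diabetes_incidence: float
    se_diabetes_incidence: float
    cum_complication_incidence: float
    se_complication_incidence: float
    # per-individual paths, retained only when requested
    states: np.ndarray | None = None  # (n, horizon + 1) int8
    cost_cum: np.ndarray | None = None  # (n, horizon + 1) discounted
    qaly_cum: np.ndarray | None = None


def _se(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def simulate_individuals(
    arm: StrategyArm,
    config: ModelConfig,
    p: ParameterSet,
    m: MortalityModel,
    n: int,
    seed: int,
    flags: ScenarioFlags | None = None,
    keep_paths: bool = False,
) -> MicrosimResult:
    """Simulate ``n`` individual trajectories through one strategy arm."""
    if n < 1:
        raise ValueError("n must be >= 1")
    flags = flags if flags is not None else config.scenario
    if flags.parameter_overrides:
        p = p.with_values(flags.parameter_overrides)
    v = p.values()
    rng = np.random.default_rng(seed)

    # baseline characteristics, fixed for life
    female = rng.random(n) < v["fraction_female"]
    aa = rng.random(n) < v["fraction_african_american"]
    angina = rng.random(n) < v["prev_angina"]
    htn = rng.random(n) < v["prev_htn_treated"]
    mi = rng.random(n) < v["prev_mi"]
    stroke = rng.random(n) < v["prev_stroke"]
    pvd = rng.random(n) < v["prev_pvd"]

    def flag_mult(mult: float, flag: np.ndarray) -> np.ndarray:
        return np.where(flag, mult, 1.0)

    mult_rfpos = flag_mult(v["mult_rfpos_female"], female) * flag_mult(v["mult_rfpos_aa"], aa)
    mult_dm = flag_mult(v["mult_dm_female"], female) * flag_mult(v["mult_dm_aa"], aa)
    mult_comp = (
        flag_mult(v["mult_comp_female"], female)
        * flag_mult(v["mult_comp_aa"], aa)
        * flag_mult(v["mult_comp_angina"], angina)
        * flag_mult(v["mult_comp_htn"], htn)
        * flag_mult(v["mult_comp_mi"], mi)
        * flag_mult(v["mult_comp_stroke"], stroke)
        * flag_mult(v["mult_comp_pvd"], pvd)
    )

    # screening and (intervention arm) enrollment, once at model start
    rfpos = rng.random(n) < v["p_screen_positive"]
    enroll_u = rng.random(n)  # drawn for everyone to keep the stream aligned
    state = np.full(n, HealthState.RF_NEG, dtype=np.int8)
    if arm == StrategyArm.MDPP:
        enrolled = rfpos & (enroll_u < v["p_enroll"])
        state[enrolled] = HealthState.RF_POS_ENROLLED
        state[rfpos & ~enrolled] = HealthState.RF_POS_NOT_ENROLLED
    else:
        state[rfpos] = HealthState.RF_POS_NOT_ENROLLED

    # per-state annual cost bases (multiplier applied per individual) and
    # per-cycle utilities, matching the cohort engine's reward convention
    cost_base = np.zeros(N_STATES)
    cost_base[HealthState.RF_NEG] = v["c_rfneg_yr"]
    cost_base[HealthState.RF_POS_ENROLLED] = v["c_rfpos_yr"]
    cost_base[HealthState.RF_POS_NOT_ENROLLED] = v["c_rfpos_yr"]
    cost_base[HealthState.STABLE_DM] = v["c_dm_base_yr"]
    cost_base[HealthState.COMPLICATED_DM] = v["c_complicated_dm_base_yr"]
    cost_base /= 12.0
    _, util_vec = cycle_rewards(arm, p, flags, cycle_index=1)

    horizon = config.horizon_cycles
    r = config.annual_discount_rate
    cost_tot = np.zeros(n)
    qaly_tot = np.zeros(n)
    ever_dm = np.zeros(n, dtype=bool)
    ever_comp = np.zeros(n, dtype=bool)
    if keep_paths:
        states_path = np.empty((n, horizon + 1), dtype=np.int8)
        cost_path = np.zeros((n, horizon + 1))
        qaly_path = np.zeros((n, horizon + 1))
        states_path[:, 0] = state

    # cycle-0 one-time costs in the intervention arm
    if arm == StrategyArm.MDPP:
        cost_tot += np.where(rfpos, v["c_screen_positive"], v["c_screen_negative"])
        cost_tot += np.where(state == HealthState.RF_POS_ENROLLED, v["c_program"], 0.0)

    matrices: dict[int, np.ndarray] = {}
    for t in range(horizon):
        year = t // 12 + 1
        if year not in matrices:
            age = config.starting_age + t // 12
            matrices[year] = build_transition_matrix(arm, year, age, p, m, flags)
        cum = matrices[year].cumsum(axis=1)

        disc = (1.0 + r) ** (-t / 12.0)
        ind_mult = np.ones(n)
        is_rfpos = (state == HealthState.RF_POS_ENROLLED) | (state == HealthState.RF_POS_NOT_ENROLLED)
        ind_mult[is_rfpos] = mult_rfpos[is_rfpos]
        ind_mult[state == HealthState.STABLE_DM] = mult_dm[state == HealthState.STABLE_DM]
        ind_mult[state == HealthState.COMPLICATED_DM] = mult_comp[state == HealthState.COMPLICATED_DM]
        cost_tot += cost_base[state] * ind_mult * disc
        qaly_tot += util_vec[state] * disc
        if keep_paths:
            cost_path[:, t] = cost_tot
            qaly_path[:, t] = qaly_tot

        u = rng.random(n)
        new_state = np.empty(n, dtype=np.int8)
        for s in range(N_STATES):
            mask = state == s
            if mask.any():
                nxt = np.searchsorted(cum[s], u[mask], side="right")
                new_state[mask] = np.minimum(nxt, N_STATES - 1)
        ever_dm |= new_state == HealthState.STABLE_DM
        ever_comp |= new_state == HealthState.COMPLICATED_DM
        state = new_state
        if keep_paths:
            states_path[:, t + 1] = state
    if keep_paths:
        # final column: totals after the last accrual (no reward at the
        # terminal occupancy, matching the cohort engine)
        cost_path[:, horizon] = cost_tot
        qaly_path[:, horizon] = qaly_tot

    dm = ever_dm.astype(float)
    comp = ever_comp.astype(float)
    return MicrosimResult(
        arm=arm,
        n=n,
        mean_cost=float(cost_tot.mean()),
        se_cost=_se(cost_tot),
        mean_qaly=float(qaly_tot.mean()),
        se_qaly=_se(qaly_tot),
        cum_diabetes_incidence=float(dm.mean()),
        se_diabetes_incidence=_se(dm),
        cum_complication_incidence=float(comp.mean()),
        se_complication_incidence=_se(comp),
        states=states_path if keep_paths else None,
        cost_cum=cost_path if keep_paths else None,
        qaly_cum=qaly_path if keep_paths else None,
    )


def export_synthetic_cohort(result: MicrosimResult, path) -> pd.DataFrame:
    """Write per-individual state paths and accumulators as tidy CSV.

    One row per (individual, cycle): ``id, cycle, state, cost_cum,
    qaly_cum``. Requires a simulation run with ``keep_paths=True``.
    """
    if result.states is None:
        raise ValueError("simulation was run without keep_paths=True; nothing to export")
    n, ncyc = result.states.shape
    ids = np.repeat(np.arange(n), ncyc)
    cycles = np.tile(np.arange(ncyc), n)
    df = pd.DataFrame(
        {
            "id": ids,
            "cycle": cycles,
            "state": [HealthState(s).name for s in result.states.ravel()],
            "cost_cum": result.cost_cum.ravel(),
            "qaly_cum": result.qaly_cum.ravel(),
        }
    )
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing synthetic cohort to {path}: {exc}") from exc
    return df


def load_synthetic_cohort(path) -> pd.DataFrame:
    """Re-import a cohort CSV written by :func:`export_synthetic_cohort`."""
    df = pd.read_csv(path)
    missing = {"id", "cycle", "state", "cost_cum", "qaly_cum"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    return df
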