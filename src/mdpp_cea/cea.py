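"""Cost-effectiveness analyses on top of the cohort engine.

Covers the deterministic base case (incremental cost, incremental QALYs,
ICER), one-way (tornado) sensitivity analysis over the documented parameter
ranges, probabilistic sensitivity analysis with per-family distributions
fitted from (base, low, high), the cost-effectiveness acceptability curve,
and the named structural scenarios.

Distribution calibration from the printed ranges: uniform ranges are hard
support; beta, log-normal and normal ranges are read as central 95%
intervals (for beta the mean is pinned to the base value and the
concentration fitted to the interval, with a method-of-moments fallback
``sd = (high - low) / 3.92``).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .engine import ArmOutcome, StrategyArm, run_cohort, summarize
from .mortality import MortalityModel
from .params import (
    DistributionSpec,
    ModelConfig,
    ParameterSet,
    ScenarioFlags,
    validate_parameters,
)

__all__ = [
    "CEAResult",
    "TornadoEntry",
    "PSASample",
    "CEACPoint",
    "compute_icer",
    "evaluate_strategies",
    "one_way_sensitivity",
    "tornado",
    "discount_rate_sweep",
    "fit_distribution",
    "run_psa",
    "ceac",
    "run_scenario",
    "SCENARIO_NAMES",
    "DEFAULT_CEAC_THRESHOLDS",
]

logger = logging.getLogger(__name__)

DEFAULT_CEAC_THRESHOLDS = tuple(range(0, 100_001, 5_000))
TORNADO_FLAG_SWING = 7_000.0  # $/QALY; entries below this swing are flagged minor


@dataclass(frozen=True)
class CEAResult:
    """Two-arm incremental cost-effectiveness comparison."""

    cost_mdpp: float
    cost_usual: float
    qaly_mdpp: float
    qaly_usual: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # none | mdpp_dominant | mdpp_dominated

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low_input: float
    high_input: float
    icer_at_low: float | None
    icer_at_high: float | None
    dominance_at_low: str
    dominance_at_high: str
    swing: float
    minor: bool = False  # swing stays under the reporting threshold


@dataclass(frozen=True)
class PSASample:
    """One probabilistic draw and its incremental outcomes."""

    index: int
    values: Mapping[str, float]
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class CEACPoint:
    threshold: float
    probability_mdpp_preferred: float


def compute_icer(outcome_mdpp: ArmOutcome, outcome_usual: ArmOutcome) -> CEAResult:
    """Incremental comparison of the intervention against usual care.

    The ICER is defined only when neither strategy dominates and the QALY
    difference is nonzero; a cheaper-and-better intervention is tagged
    ``mdpp_dominant``, a costlier-and-worse one ``mdpp_dominated`` (the
    zero-benefit, positive-cost edge collapses to ``mdpp_dominated``).
    """
    dc = outcome_mdpp.total_discounted_cost - outcome_usual.total_discounted_cost
    de = outcome_mdpp.total_discounted_qaly - outcome_usual.total_discounted_qaly
    dominance = "none"
    icer: float | None
    if de > 0.0 and dc <= 0.0:
        dominance, icer = "mdpp_dominant", None
    elif de < 0.0 and dc >= 0.0:
        dominance, icer = "mdpp_dominated", None
    elif de == 0.0:
        dominance = "none" if dc == 0.0 else ("mdpp_dominated" if dc > 0 else "mdpp_dominant")
        icer = None
    else:
        icer = dc / de
    return CEAResult(
        cost_mdpp=outcome_mdpp.total_discounted_cost,
        cost_usual=outcome_usual.total_discounted_cost,
        qaly_mdpp=outcome_mdpp.total_discounted_qaly,
        qaly_usual=outcome_usual.total_discounted_qaly,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        dominance=dominance,
    )


def _mortality_for(p: ParameterSet, m: MortalityModel) -> MortalityModel:
    """Rebind the mortality mixture weight to the (possibly varied) cohort."""
    w = p.fraction_female.base
    if abs(w - m.fraction_female) < 1e-15:
        return m
    return replace(m, fraction_female=w)


def evaluate_strategies(
    config: ModelConfig,
    p: ParameterSet,
    m: MortalityModel,
    flags: ScenarioFlags | None = None,
) -> tuple[CEAResult, ArmOutcome, ArmOutcome]:
    """Run both arms under one parameterization and compare them."""
    flags = flags if flags is not None else config.scenario
    if flags.parameter_overrides:
        p = p.with_values(flags.parameter_overrides)
        flags = replace(flags, parameter_overrides={})
    m = _mortality_for(p, m)
    out_mdpp = summarize(run_cohort(StrategyArm.MDPP, config, p, m, flags))
    out_usual = summarize(run_cohort(StrategyArm.USUAL_CARE, config, p, m, flags))
    return compute_icer(out_mdpp, out_usual), out_mdpp, out_usual


def _icer_value(res: CEAResult) -> float:
    """Numeric ICER for ranking: dominant draws count as 0 net cost per QALY."""
    if res.icer is not None:
        return res.icer
    return 0.0 if res.dominance == "mdpp_dominant" else math.inf


def _evaluate_with_value(
    config: ModelConfig, p: ParameterSet, m: MortalityModel, name: str, value: float
) -> CEAResult:
    if name == "starting_age":
        cfg = replace(config, starting_age=int(round(value)))
        res, _, _ = evaluate_strategies(cfg, p, m)
    else:
        res, _, _ = evaluate_strategies(config, p.with_values({name: value}), m)
    return res


def one_way_sensitivity(
    config: ModelConfig, p: ParameterSet, m: MortalityModel, parameter: str
) -> TornadoEntry:
    """Rerun both arms with one parameter at each end of its range."""
    spec: DistributionSpec = getattr(p, parameter)
    if spec.is_fixed:
        raise ValueError(
            f"parameter {parameter!r} is fixed and not varied; variable "
            f"parameters: {', '.join(p.varied_names())}"
        )
    res_low = _evaluate_with_value(config, p, m, parameter, spec.low)
    res_high = _evaluate_with_value(config, p, m, parameter, spec.high)
    lo_v, hi_v = _icer_value(res_low), _icer_value(res_high)
    swing = abs(hi_v - lo_v)
    return TornadoEntry(
        parameter=parameter,
        low_input=spec.low,
        high_input=spec.high,
        icer_at_low=res_low.icer,
        icer_at_high=res_high.icer,
        dominance_at_low=res_low.dominance,
        dominance_at_high=res_high.dominance,
        swing=swing,
        minor=swing < TORNADO_FLAG_SWING,
    )


def tornado(config: ModelConfig, p: ParameterSet, m: MortalityModel) -> list[TornadoEntry]:
    """One-way sensitivity over every varied parameter, ranked by swing."""
    entries = [one_way_sensitivity(config, p, m, name) for name in p.varied_names()]
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def discount_rate_sweep(
    config: ModelConfig,
    p: ParameterSet,
    m: MortalityModel,
    rates: Iterable[float] = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05),
) -> dict[float, float]:
    """Base-case ICER at each annual discount rate."""
    out = {}
    for r in rates:
        cfg = replace(config, annual_discount_rate=r)
        res, _, _ = evaluate_strategies(cfg, p, m)
        out[float(r)] = _icer_value(res)
    return out


# -- distribution fitting / sampling -------------------------------------


def _fit_beta(spec: DistributionSpec) -> tuple[float, float]:
    """Beta (alpha, beta) with mean at base and 95% interval near (low, high)."""
    mean = spec.base
    sd_moment = (spec.high - spec.low) / 3.92
    var_max = mean * (1.0 - mean)

    def moments() -> tuple[float, float]:
        var = min(sd_moment**2, 0.99 * var_max)
        kappa = var_max / var - 1.0
        if kappa <= 0:  # pragma: no cover - guarded by the min above
            kappa = 2.0
        return mean * kappa, (1.0 - mean) * kappa

    def err(log_kappa: float) -> float:
        kappa = math.exp(log_kappa)
        a, b = mean * kappa, (1.0 - mean) * kappa
        lo = stats.beta.ppf(0.025, a, b)
        hi = stats.beta.ppf(0.975, a, b)
        return (lo - spec.low) ** 2 + (hi - spec.high) ** 2

    try:
        res = optimize.minimize_scalar(err, bounds=(math.log(0.5), math.log(1e6)), method="bounded")
        if not res.success or not np.isfinite(res.x):
            raise RuntimeError("beta interval fit did not converge")
        kappa = math.exp(res.x)
        return mean * kappa, (1.0 - mean) * kappa
    except Exception:
        logger.warning("beta interval fit failed for %s; falling back to moments", spec)
        return moments()


def fit_distribution(spec: DistributionSpec) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Build a sampler ``draw(rng, size)`` for one parameter's family.

    * fixed: point mass at base;
    * uniform: support exactly [low, high];
    * normal: mean base, sd (high - low)/3.92;
    * log-normal: log-mean ln(base) (median = base), log-sd
      (ln high - ln low)/3.92;
    * beta: mean base, concentration fitted so the central 95% interval
      matches (low, high) as closely as possible, truncated to (0, 1) by
      construction.
    """
    if spec.is_fixed:
        base = spec.base
        return lambda rng, size: np.full(size, base)
    if spec.family == "uniform":
        lo, hi = spec.low, spec.high
        return lambda rng, size: rng.uniform(lo, hi, size)
    if spec.family == "normal":
        mu, sd = spec.base, (spec.high - spec.low) / 3.92
        return lambda rng, size: rng.normal(mu, sd, size)
    if spec.family == "log-normal":
        mu, sd = math.log(spec.base), (math.log(spec.high) - math.log(spec.low)) / 3.92
        return lambda rng, size: rng.lognormal(mu, sd, size)
    if spec.family == "beta":
        a, b = _fit_beta(spec)
        return lambda rng, size: rng.beta(a, b, size)
    raise ValueError(f"no sampler for family {spec.family!r}")


def _sampled_values_valid(p: ParameterSet, values: Mapping[str, float], m: MortalityModel, config: ModelConfig) -> bool:
    candidate = p.with_values(values)
    if validate_parameters(candidate):
        return False
    age = int(round(values.get("starting_age", config.starting_age)))
    max_age = age + config.horizon_years - 1
    return m.life_table.covers(age) and m.life_table.covers(max_age)


def run_psa(
    config: ModelConfig,
    p: ParameterSet,
    m: MortalityModel,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> list[PSASample]:
    """Probabilistic sensitivity analysis: joint independent parameter draws.

    Each iteration draws every non-fixed parameter from its fitted
    distribution (independently, with no covariance), rounds the starting
    age to integer years, and evaluates both strategy arms. Draws failing
    parameter validation are redrawn, with the redraw count logged. Fully
    reproducible for a given seed.
    """
    n = n_iterations if n_iterations is not None else config.psa_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    varied = p.varied_names()
    samplers = {name: fit_distribution(getattr(p, name)) for name in varied}

    samples: list[PSASample] = []
    redraws = 0
    for i in range(n):
        while True:
            values = {name: float(samplers[name](rng, 1)[0]) for name in varied}
            if _sampled_values_valid(p, values, m, config):
                break
            redraws += 1
            if redraws > 100 * n:
                raise RuntimeError("PSA rejected too many invalid draws; check specs")
        age = int(round(values.pop("starting_age"))) if "starting_age" in values else config.starting_age
        cfg = replace(config, starting_age=age)
        draw = p.with_values(values)
        res, _, _ = evaluate_strategies(cfg, draw, m)
        samples.append(
            PSASample(
                index=i,
                values={**values, "starting_age": age},
                delta_cost=res.delta_cost,
                delta_qaly=res.delta_qaly,
            )
        )
    if redraws:
        logger.info("PSA redrew %d invalid parameter vectors", redraws)
    return samples


def ceac(samples: Sequence[PSASample], thresholds: Iterable[float] = DEFAULT_CEAC_THRESHOLDS) -> list[CEACPoint]:
    """Acceptability curve: P(positive net monetary benefit) per threshold.

    At willingness-to-pay ``lam`` the intervention is preferred in a draw
    iff ``lam * delta_qaly - delta_cost > 0``; this handles dominant and
    dominated draws without per-draw ICER sign gymnastics.
    """
    if not samples:
        raise ValueError("ceac requires at least one PSA sample")
    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_qaly for s in samples])
    return [
        CEACPoint(threshold=float(lam), probability_mdpp_preferred=float(np.mean(lam * de - dc > 0.0)))
        for lam in thresholds
    ]


# -- named scenarios ------------------------------------------------------

_SCENARIOS: dict[str, dict] = {
    "base": {},
    "no_resolution_after_y1_both": {"mets_resolution_mode": "none_after_year1_both"},
    "no_resolution_after_y1_enrolled_only": {
        "mets_resolution_mode": "none_after_year1_enrolled_only"
    },
    "equal_rfpos_utilities": {"equalize_rfpos_utilities": True},
    # joint pessimistic bundles: equalized RF+ utilities, near-null program
    # effect on diabetes risk, low RF- utility; the second adds a program
    # resolution benefit shrunk to two percentage points
    "worst_case_3": {
        "equalize_rfpos_utilities": True,
        "parameter_overrides": {"p_dm_in_program_yr": 0.098, "u_rfneg": 0.77},
    },
    "worst_case_4": {
        "equalize_rfpos_utilities": True,
        "parameter_overrides": {
            "p_dm_in_program_yr": 0.098,
            "u_rfneg": 0.77,
            "p_resolve_in_program_yr": 0.141,
        },
    },
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def scenario_flags(name: str) -> ScenarioFlags:
    if name not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIO_NAMES)}"
        )
    return ScenarioFlags(**_SCENARIOS[name])


def run_scenario(
    name: str, config: ModelConfig, p: ParameterSet, m: MortalityModel
) -> CEAResult:
    """Evaluate one named structural scenario and return its comparison."""
    res, _, _ = evaluate_strategies(config, p, m, scenario_flags(name))
    return res
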