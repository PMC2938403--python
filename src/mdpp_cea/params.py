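"""Model parameterization: distributions, cohort profile, run configuration.

Every model input is stored as a :class:`DistributionSpec` carrying its
base-case value on the natural scale (proportions, not percentages), the
range examined in sensitivity analyses, and the distribution family used for
probabilistic draws (beta for probabilities and prevalences, uniform for
costs and utilities, log-normal for relative risks of death, normal for cost
multipliers, ``fixed`` for inputs that are never varied).

The full parameter set covers, for a cohort screened once at model start:

* cohort characteristics (starting age, sex/race mix, comorbidity
  prevalences that drive cost multipliers),
* screening and enrollment probabilities,
* annual probabilities of acquiring diabetes, of metabolic-syndrome
  resolution with and without the lifestyle program, of becoming
  risk-factor-positive, and of progressing to complicated diabetes,
* relative risks of death by health state,
* health-state utilities, and
* screening/program costs, annual state costs and their demographic and
  comorbidity cost multipliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "DistributionSpec",
    "CohortProfile",
    "ScenarioFlags",
    "ModelConfig",
    "ParameterSet",
    "default_parameter_set",
    "validate_parameters",
    "read_config",
    "write_config",
    "default_config_path",
]

FAMILIES = ("beta", "uniform", "log-normal", "normal", "fixed")

RESOLUTION_MODES = (
    "base",
    "none_after_year1_both",
    "none_after_year1_enrolled_only",
)


@dataclass(frozen=True)
class DistributionSpec:
    """One model input: family, base-case value and range examined.

    ``low``/``high`` are the endpoints of the range examined in one-way and
    probabilistic sensitivity analyses; they are ``None`` for ``fixed``
    inputs, which are excluded from both.
    """

    family: str
    base: float
    low: float | None = None
    high: float | None = None

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    def violations(self, name: str = "spec") -> list[str]:
        out: list[str] = []
        if self.family not in FAMILIES:
            out.append(f"{name}: unknown distribution family {self.family!r}")
            return out
        if self.is_fixed:
            if self.low is not None or self.high is not None:
                out.append(f"{name}: fixed parameters carry no range")
            return out
        if self.low is None or self.high is None:
            out.append(f"{name}: {self.family} requires low and high")
            return out
        if not (self.low <= self.base <= self.high):
            out.append(
                f"{name}: requires low <= base <= high, got "
                f"{self.low} / {self.base} / {self.high}"
            )
        if self.family == "beta":
            # closed upper endpoint allowed: one prevalence range reaches 100%
            if not (0.0 < self.low and self.base < 1.0 and self.high <= 1.0):
                out.append(f"{name}: beta requires values inside (0, 1]")
        if self.family == "log-normal" and self.low <= 0.0:
            out.append(f"{name}: log-normal requires positive values")
        return out


def _fixed(base: float) -> DistributionSpec:
    return DistributionSpec("fixed", base)


def _beta(base: float, low: float, high: float) -> DistributionSpec:
    return DistributionSpec("beta", base, low, high)


def _unif(base: float, low: float, high: float) -> DistributionSpec:
    return DistributionSpec("uniform", base, low, high)


def _lnorm(base: float, low: float, high: float) -> DistributionSpec:
    return DistributionSpec("log-normal", base, low, high)


def _norm(base: float, low: float, high: float) -> DistributionSpec:
    return DistributionSpec("normal", base, low, high)


@dataclass(frozen=True)
class CohortProfile:
    """Realized demographic/comorbidity mix of the modelled cohort."""

    fraction_female: float
    fraction_african_american: float
    prev_angina: float
    prev_htn_treated: float
    prev_mi: float
    prev_stroke: float
    prev_pvd: float

    def violations(self) -> list[str]:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                out.append(f"cohort.{f.name}: proportion {v} outside [0, 1]")
        return out


@dataclass(frozen=True)
class ScenarioFlags:
    """Structural scenario switches.

    ``mets_resolution_mode`` selects how metabolic-syndrome resolution
    behaves after model year 1:

    * ``base`` — enrolled resolve at the program rate in year 1 and at the
      no-program rate in years 2-3; non-enrolled resolve at the no-program
      rate in all years;
    * ``none_after_year1_both`` — no resolution after year 1 for anyone;
    * ``none_after_year1_enrolled_only`` — no resolution after year 1 for
      the enrolled, non-enrolled keep resolving in all years.

    ``equalize_rfpos_utilities`` sets the non-enrolled risk-factor-positive
    utility equal to the enrolled (in-program) value.
    """

    mets_resolution_mode: str = "base"
    equalize_rfpos_utilities: bool = False
    parameter_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mets_resolution_mode not in RESOLUTION_MODES:
            raise ValueError(
                f"unknown mets_resolution_mode {self.mets_resolution_mode!r}; "
                f"valid: {', '.join(RESOLUTION_MODES)}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: cohort age, horizon, discounting, PSA size."""

    starting_age: int = 55
    horizon_cycles: int = 36
    cycle_length: float = 1.0 / 12.0
    annual_discount_rate: float = 0.03
    psa_iterations: int = 1000
    rng_seed: int = 12345
    scenario: ScenarioFlags = field(default_factory=ScenarioFlags)

    def __post_init__(self) -> None:
        if self.horizon_cycles <= 0 or self.horizon_cycles % 12 != 0:
            raise ValueError(
                f"horizon_cycles must be a positive multiple of 12, got "
                f"{self.horizon_cycles}"
            )
        if not (0.0 <= self.annual_discount_rate <= 1.0):
            raise ValueError(
                f"annual_discount_rate must lie in [0, 1], got "
                f"{self.annual_discount_rate}"
            )
        if abs(self.cycle_length - 1.0 / 12.0) > 1e-12:
            raise ValueError("cycle_length is fixed at one month (1/12 year)")

    @property
    def horizon_years(self) -> int:
        return self.horizon_cycles // 12


# field name -> semantic category, used for validation and unit handling
PROBABILITY_FIELDS = frozenset(
    {
        "fraction_female",
        "fraction_african_american",
        "prev_angina",
        "prev_htn_treated",
        "prev_mi",
        "prev_stroke",
        "prev_pvd",
        "p_screen_positive",
        "p_enroll",
        "p_dm_rfpos_no_program_yr",
        "p_dm_rfneg_yr",
        "p_dm_in_program_yr",
        "p_become_rfpos_yr",
        "p_progress_complicated_yr",
        "p_resolve_no_program_yr",
        "p_resolve_in_program_yr",
    }
)
UTILITY_FIELDS = frozenset(
    {"u_rfpos_usual", "u_rfpos_program", "u_rfneg", "u_stable_dm", "u_complicated_dm"}
)
COST_FIELDS = frozenset(
    {
        "c_screen_positive",
        "c_screen_negative",
        "c_program",
        "c_rfpos_yr",
        "c_rfneg_yr",
        "c_dm_base_yr",
        "c_complicated_dm_base_yr",
    }
)
RELATIVE_RISK_FIELDS = frozenset(
    {"rr_death_rfpos", "rr_death_rfneg", "rr_death_stable_dm", "rr_death_complicated_dm"}
)
MULTIPLIER_FIELDS = frozenset(
    {
        "mult_rfpos_female",
        "mult_rfpos_aa",
        "mult_dm_female",
        "mult_dm_aa",
        "mult_comp_female",
        "mult_comp_aa",
        "mult_comp_angina",
        "mult_comp_htn",
        "mult_comp_mi",
        "mult_comp_stroke",
        "mult_comp_pvd",
    }
)

# fields printed as percentages in the source table; a config file declaring
# units: percent divides these by 100 on read
PERCENT_SCALED_FIELDS = PROBABILITY_FIELDS


@dataclass(frozen=True)
class ParameterSet:
    """Complete model parameterization, one :class:`DistributionSpec` each."""

    # cohort characteristics
    starting_age: DistributionSpec
    fraction_female: DistributionSpec
    fraction_african_american: DistributionSpec
    prev_angina: DistributionSpec
    prev_htn_treated: DistributionSpec
    prev_mi: DistributionSpec
    prev_stroke: DistributionSpec
    prev_pvd: DistributionSpec
    # screening / enrollment
    p_screen_positive: DistributionSpec
    p_enroll: DistributionSpec
    # annual transition probabilities
    p_dm_rfpos_no_program_yr: DistributionSpec
    p_dm_rfneg_yr: DistributionSpec
    p_dm_in_program_yr: DistributionSpec
    p_become_rfpos_yr: DistributionSpec
    p_progress_complicated_yr: DistributionSpec
    p_resolve_no_program_yr: DistributionSpec
    p_resolve_in_program_yr: DistributionSpec
    # relative risks of death
    rr_death_rfpos: DistributionSpec
    rr_death_rfneg: DistributionSpec
    rr_death_stable_dm: DistributionSpec
    rr_death_complicated_dm: DistributionSpec
    # utilities
    u_rfpos_usual: DistributionSpec
    u_rfpos_program: DistributionSpec
    u_rfneg: DistributionSpec
    u_stable_dm: DistributionSpec
    u_complicated_dm: DistributionSpec
    # costs
    c_screen_positive: DistributionSpec
    c_screen_negative: DistributionSpec
    c_program: DistributionSpec
    c_rfpos_yr: DistributionSpec
    c_rfneg_yr: DistributionSpec
    c_dm_base_yr: DistributionSpec
    c_complicated_dm_base_yr: DistributionSpec
    # cost multipliers
    mult_rfpos_female: DistributionSpec
    mult_rfpos_aa: DistributionSpec
    mult_dm_female: DistributionSpec
    mult_dm_aa: DistributionSpec
    mult_comp_female: DistributionSpec
    mult_comp_aa: DistributionSpec
    mult_comp_angina: DistributionSpec
    mult_comp_htn: DistributionSpec
    mult_comp_mi: DistributionSpec
    mult_comp_stroke: DistributionSpec
    mult_comp_pvd: DistributionSpec

    # -- access helpers -------------------------------------------------

    def names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def items(self) -> Iterator[tuple[str, DistributionSpec]]:
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def values(self) -> dict[str, float]:
        """Base-case value of every parameter."""
        return {name: spec.base for name, spec in self.items()}

    def varied_names(self) -> list[str]:
        """Parameters with a non-fixed family (enter tornado and PSA)."""
        return [name for name, spec in self.items() if not spec.is_fixed]

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the named parameters pinned to given values.

        Overridden parameters become ``fixed`` specs: scenario overrides may
        fall outside the sensitivity range, so the original range is dropped
        rather than invalidated.
        """
        known = set(self.names())
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {', '.join(unknown)}; valid names: "
                f"{', '.join(sorted(known))}"
            )
        changes = {name: _fixed(float(v)) for name, v in overrides.items()}
        return replace(self, **changes)

    def as_fixed(self) -> "ParameterSet":
        """Collapse every distribution to a point mass at its base value."""
        return replace(self, **{n: _fixed(s.base) for n, s in self.items()})

    def base_cohort(self) -> CohortProfile:
        return CohortProfile(
            fraction_female=self.fraction_female.base,
            fraction_african_american=self.fraction_african_american.base,
            prev_angina=self.prev_angina.base,
            prev_htn_treated=self.prev_htn_treated.base,
            prev_mi=self.prev_mi.base,
            prev_stroke=self.prev_stroke.base,
            prev_pvd=self.prev_pvd.base,
        )


def default_parameter_set() -> ParameterSet:
    """Base-case parameterization of the model.

    Probabilities and prevalences are proportions; costs are USD (2000);
    utilities are on the 0 (death) to 1 (perfect health) scale.
    """
    return ParameterSet(
        starting_age=_unif(55, 45, 65),
        fraction_female=_beta(0.75, 0.482, 0.940),
        fraction_african_american=_beta(0.271, 0.065, 0.558),
        prev_angina=_beta(0.038, 0.010, 0.083),
        prev_htn_treated=_beta(0.849, 0.045, 1.000),
        prev_mi=_beta(0.019, 0.005, 0.042),
        prev_stroke=_beta(0.019, 0.005, 0.042),
        prev_pvd=_beta(0.047, 0.013, 0.102),
        p_screen_positive=_beta(0.310, 0.072, 0.635),
        p_enroll=_beta(0.470, 0.092, 0.867),
        p_dm_rfpos_no_program_yr=_beta(0.108, 0.029, 0.233),
        p_dm_rfneg_yr=_beta(0.004, 0.0005, 0.0075),
        p_dm_in_program_yr=_beta(0.048, 0.013, 0.105),
        p_become_rfpos_yr=_beta(0.040, 0.010, 0.087),
        p_progress_complicated_yr=_beta(0.075, 0.020, 0.163),
        p_resolve_no_program_yr=_beta(0.121, 0.032, 0.259),
        p_resolve_in_program_yr=_beta(0.162, 0.042, 0.344),
        rr_death_rfpos=_lnorm(1.7, 1.5, 1.8),
        rr_death_rfneg=_fixed(1.0),
        rr_death_stable_dm=_lnorm(2.0, 1.8, 2.2),
        rr_death_complicated_dm=_lnorm(2.4, 2.2, 2.6),
        u_rfpos_usual=_unif(0.73, 0.71, 0.75),
        u_rfpos_program=_unif(0.75, 0.73, 0.77),
        u_rfneg=_unif(0.88, 0.84, 0.92),
        u_stable_dm=_unif(0.69, 0.66, 0.72),
        u_complicated_dm=_unif(0.59, 0.51, 0.68),
        c_screen_positive=_unif(35, 18, 53),
        c_screen_negative=_unif(32, 16, 48),
        c_program=_unif(219, 110, 329),
        c_rfpos_yr=_fixed(1296),
        c_rfneg_yr=_fixed(616),
        c_dm_base_yr=_fixed(1684),
        c_complicated_dm_base_yr=_fixed(1684),
        mult_rfpos_female=_norm(1.14, 1.05, 1.25),
        mult_rfpos_aa=_norm(0.82, 0.70, 0.95),
        mult_dm_female=_norm(1.25, 1.14, 1.35),
        mult_dm_aa=_norm(0.82, 0.70, 0.95),
        mult_comp_female=_norm(1.25, 1.14, 1.35),
        mult_comp_aa=_norm(0.82, 0.70, 0.95),
        mult_comp_angina=_norm(1.73, 1.31, 2.14),
        mult_comp_htn=_norm(1.24, 1.10, 1.37),
        mult_comp_mi=_norm(1.90, 1.64, 2.17),
        mult_comp_stroke=_norm(1.30, 1.20, 1.40),
        mult_comp_pvd=_norm(1.31, 1.10, 1.53),
    )


def validate_parameters(p: ParameterSet) -> list[str]:
    """Check every type invariant; returns violations instead of raising."""
    out: list[str] = []
    for name, spec in p.items():
        out.extend(spec.violations(name))
        check = [spec.base]
        if not spec.is_fixed and spec.low is not None and spec.high is not None:
            check += [spec.low, spec.high]
        if name in PROBABILITY_FIELDS:
            for v in check:
                if not (0.0 <= v <= 1.0):
                    out.append(f"{name}: probability {v} outside [0, 1]")
        elif name in UTILITY_FIELDS:
            for v in check:
                if not (0.0 <= v <= 1.0):
                    out.append(f"{name}: utility {v} outside [0, 1]")
        elif name in COST_FIELDS:
            for v in check:
                if v < 0.0:
                    out.append(f"{name}: cost {v} is negative")
        elif name in RELATIVE_RISK_FIELDS or name in MULTIPLIER_FIELDS:
            for v in check:
                if v <= 0.0:
                    out.append(f"{name}: must be positive, got {v}")
        elif name == "starting_age":
            for v in check:
                if not (18 <= v <= 100):
                    out.append(f"{name}: implausible adult age {v}")
    return out


# -- config file I/O -----------------------------------------------------


def _spec_to_dict(spec: DistributionSpec) -> dict:
    d: dict = {"family": spec.family, "base": spec.base}
    if not spec.is_fixed:
        d["low"] = spec.low
        d["high"] = spec.high
    return d


def _spec_from_dict(name: str, d: object) -> DistributionSpec:
    if not isinstance(d, Mapping) or "family" not in d or "base" not in d:
        raise ValueError(
            f"parameter {name!r}: expected a mapping with family and base, got {d!r}"
        )
    return DistributionSpec(
        family=str(d["family"]),
        base=float(d["base"]),
        low=None if d.get("low") is None else float(d["low"]),
        high=None if d.get("high") is None else float(d["high"]),
    )


def _rescale_percent(spec: DistributionSpec) -> DistributionSpec:
    return DistributionSpec(
        spec.family,
        spec.base / 100.0,
        None if spec.low is None else spec.low / 100.0,
        None if spec.high is None else spec.high / 100.0,
    )


def write_config(config: ModelConfig, params: ParameterSet, path: str | Path) -> None:
    """Serialize a config + parameter set to a YAML file (proportion units)."""
    doc = {
        "model": {
            "starting_age": config.starting_age,
            "horizon_cycles": config.horizon_cycles,
            "annual_discount_rate": config.annual_discount_rate,
            "psa_iterations": config.psa_iterations,
            "rng_seed": config.rng_seed,
            "scenario": {
                "mets_resolution_mode": config.scenario.mets_resolution_mode,
                "equalize_rfpos_utilities": config.scenario.equalize_rfpos_utilities,
                "parameter_overrides": dict(config.scenario.parameter_overrides),
            },
        },
        "parameters": {"units": "proportion"}
        | {name: _spec_to_dict(spec) for name, spec in params.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path: str | Path) -> tuple[ModelConfig, ParameterSet]:
    """Read a YAML config written by :func:`write_config` (or hand-edited).

    The ``units`` key under ``parameters`` may be ``proportion`` (default) or
    ``percent``; with ``percent``, probability and prevalence entries are
    divided by 100 on read.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ValueError(f"malformed config file {path}: top level must be a mapping")

    model = dict(doc.get("model", {}))
    scen = dict(model.pop("scenario", {}) or {})
    flags = ScenarioFlags(
        mets_resolution_mode=scen.get("mets_resolution_mode", "base"),
        equalize_rfpos_utilities=bool(scen.get("equalize_rfpos_utilities", False)),
        parameter_overrides=dict(scen.get("parameter_overrides", {}) or {}),
    )
    config = ModelConfig(
        starting_age=int(model.get("starting_age", 55)),
        horizon_cycles=int(model.get("horizon_cycles", 36)),
        annual_discount_rate=float(model.get("annual_discount_rate", 0.03)),
        psa_iterations=int(model.get("psa_iterations", 1000)),
        rng_seed=int(model.get("rng_seed", 12345)),
        scenario=flags,
    )

    raw = dict(doc.get("parameters", {}))
    units = str(raw.pop("units", "proportion"))
    if units not in ("proportion", "percent"):
        raise ValueError(f"units must be 'proportion' or 'percent', got {units!r}")
    expected = [f.name for f in fields(ParameterSet)]
    unknown = sorted(set(raw) - set(expected))
    if unknown:
        raise ValueError(
            f"unknown parameter(s) {', '.join(unknown)}; valid names: "
            f"{', '.join(expected)}"
        )
    missing = sorted(set(expected) - set(raw))
    if missing:
        raise ValueError(f"config file {path} missing parameter(s): {', '.join(missing)}")
    specs = {name: _spec_from_dict(name, raw[name]) for name in expected}
    if units == "percent":
        specs = {
            name: (_rescale_percent(s) if name in PERCENT_SCALED_FIELDS else s)
            for name, s in specs.items()
        }
    return config, ParameterSet(**specs)


def default_config_path() -> Path:
    """Path of the bundled base-case config file."""
    from importlib.resources import files

    return Path(str(files("mdpp_cea").joinpath("data/table1_base.yaml")))
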