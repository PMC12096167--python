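"""Model parameters: the single source of truth for a scenario.

Four blocks mirror the structure of the model's input table: demographics of
the annual cohort, clinical probabilities and timings, monthly formula costs
by age band, and calendar conventions.  Every block is validated on
construction; a scenario round-trips losslessly through YAML.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

Formula = Literal["AAF", "eHF"]
AgeBand = Literal["young", "old"]

_PROPORTION_FIELDS = (
    "ebf_fraction",
    "mixed_fraction",
    "suspected_incidence",
    "confirmed_incidence",
    "mixed_formula_share",
)


class ParameterError(ValueError):
    """A scenario value violates the model's contract; message names the key."""


class Demographics(BaseModel):
    """Annual cohort of infants under 6 months and its CMPA epidemiology.

    ``suspected_count_override`` bypasses the derived suspected-cohort size;
    it exists for the one-way sensitivity row that varies the cohort directly.
    ``mixed_formula_share`` is the fraction of formula cost attributed to
    mixed-fed (breast + formula) infants; only exclusive breastfeeding
    excludes a child from the model, and mixed-fed children are costed as
    fully formula-fed by default (share 1.0).
    """

    model_config = ConfigDict(extra="forbid")

    population_under_6mo: int = Field(gt=0)
    ebf_fraction: float
    mixed_fraction: float
    suspected_incidence: float
    confirmed_incidence: float
    mixed_formula_share: float = 1.0
    suspected_count_override: int | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "Demographics":
        for name in _PROPORTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"proportion out of range: {name}={v}")
        if self.ebf_fraction + self.mixed_fraction > 1.0 + 1e-12:
            raise ValueError(
                "ebf_fraction + mixed_fraction exceeds 1 "
                f"({self.ebf_fraction} + {self.mixed_fraction})"
            )
        if self.confirmed_incidence > self.suspected_incidence + 1e-12:
            raise ValueError(
                "confirmed_incidence exceeds suspected_incidence "
                "(a confirmed case must first be suspected)"
            )
        return self


class ClinicalParams(BaseModel):
    """Effectiveness, tolerance acquisition and diagnostic timings.

    ``tolerance_cumulative`` maps age in months to the cumulative probability
    that a true-CMPA child has acquired oral tolerance by that age; it must be
    non-decreasing.  ``tolerance_exit`` selects what happens after a positive
    tolerance challenge: ``exit_model`` (default) stops both cost and effect
    accrual; ``keep_effect`` stops cost but counts the remaining horizon as
    symptom-free.
    """

    model_config = ConfigDict(extra="forbid")

    ehf_effectiveness: float
    aaf_effectiveness: float
    tolerance_cumulative: dict[int, float]
    diagnostic_duration_weeks: float = Field(ge=0)
    challenge_interval_months: float = Field(gt=0)
    tolerance_exit: Literal["exit_model", "keep_effect"] = "exit_model"

    @model_validator(mode="after")
    def _check(self) -> "ClinicalParams":
        for name in ("ehf_effectiveness", "aaf_effectiveness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"proportion out of range: {name}={v}")
        prev_age, prev_p = None, -1.0
        for age in sorted(self.tolerance_cumulative):
            p = self.tolerance_cumulative[age]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion out of range: tolerance_cumulative[{age}]={p}")
            if p < prev_p:
                raise ValueError(
                    f"non-monotone tolerance: tolerance_cumulative[{age}]={p} "
                    f"< tolerance_cumulative[{prev_age}]={prev_p}"
                )
            prev_age, prev_p = age, p
        return self


class CostTable(BaseModel):
    """Monthly formula cost in USD by formula and age band.

    The ``young`` band applies before ``age_band_switch_months`` (default 9
    months, when complementary feeding halves the formula share) and ``old``
    after.  In the base case AAF is pricier than eHF within each band; this is
    a base-case expectation, not a validated constraint, because one-way
    sensitivity ranges legitimately cross the two prices.

    ``diagnostic_pricing`` selects how the 4-week diagnostic window is costed:

    * ``published`` (default): the standard-of-care (eHF-first) arm carries
      the AAF-priced diagnostic exposure and the AAF-first arm's window is
      costed at the eHF price — the accounting under which the strategy that
      delays definitive therapy bears the premium-formula diagnostic cost.
    * ``as_fed``: each arm pays for the formula actually dispensed during its
      own diagnostic window.
    """

    model_config = ConfigDict(extra="forbid")

    monthly_cost: dict[Formula, dict[AgeBand, float]]
    age_band_switch_months: float = Field(default=9.0, gt=0)
    diagnostic_pricing: Literal["published", "as_fed"] = "published"

    @model_validator(mode="after")
    def _check(self) -> "CostTable":
        for formula in ("AAF", "eHF"):
            bands = self.monthly_cost.get(formula)
            if bands is None:
                raise ValueError(f"missing monthly_cost entry for formula {formula!r}")
            for band in ("young", "old"):
                if band not in bands:
                    raise ValueError(f"missing monthly_cost[{formula}] entry for band {band!r}")
                if bands[band] <= 0:
                    raise ValueError(f"cost not positive: monthly_cost[{formula}][{band}]")
        return self

    def price(self, formula: Formula, band: AgeBand) -> float:
        return self.monthly_cost[formula][band]


class TimeConventions(BaseModel):
    """Model entry age, follow-up horizon and the week-to-month convention."""

    model_config = ConfigDict(extra="forbid")

    entry_age_months: float = 3.0
    horizon_age_months: float = 24.0
    days_per_month: float = 30.4375

    @model_validator(mode="after")
    def _check(self) -> "TimeConventions":
        if not 0 < self.entry_age_months < self.horizon_age_months:
            raise ValueError(
                "entry_age_months must lie strictly between 0 and horizon_age_months"
            )
        if not 28.0 <= self.days_per_month <= 31.0:
            raise ValueError(f"days_per_month out of range: {self.days_per_month}")
        return self


class ModelParameters(BaseModel):
    model_config = ConfigDict(extra="forbid")

    demographics: Demographics
    clinical: ClinicalParams
    costs: CostTable
    time: TimeConventions

    def to_plain(self) -> dict:
        """JSON/YAML-ready nested dict (mode='json' keeps keys primitive)."""
        return self.model_dump(mode="json")


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def parameters_from_dict(data: dict) -> ModelParameters:
    try:
        return ModelParameters.model_validate(data)
    except ValidationError as exc:
        raise ParameterError(_format_validation_error(exc)) from exc


def load_parameters(path: str | Path) -> ModelParameters:
    """Read and validate a scenario from a YAML (or JSON) config file."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    return parameters_from_dict(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a scenario so that load_parameters() restores it exactly."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(params.to_plain(), fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """The base-case scenario shipped with the package."""
    text = resources.files("cmpa_cea.data").joinpath("base_case.yaml").read_text()
    return parameters_from_dict(yaml.safe_load(text))
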