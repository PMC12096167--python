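"""Seeded synthetic parameter scenarios with the base case's structure.

Probabilities are drawn from beta distributions and monthly costs from gamma
distributions, both parameterized so that the base-case value is the mean —
the conventional shapes for second-order uncertainty in health-economic
models.  Draws always pass full parameter validation, so any scenario can be
pushed through the model and the CEA without special-casing.
"""
from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .parameters import ModelParameters, default_parameters, parameters_from_dict


class ScenarioSpec(BaseModel):
    """Sampling plan: ``prob_concentration`` is the beta pseudo-sample size
    (larger = tighter around the base), ``cost_cv`` the gamma coefficient of
    variation."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    seed: int
    n_draws: int = Field(gt=0)
    prob_concentration: float = Field(default=100.0, gt=0)
    cost_cv: float = Field(default=0.10, gt=0)
    base: ModelParameters = Field(default_factory=default_parameters)


def _beta_mean(rng: np.random.Generator, mean: float, kappa: float) -> float:
    """Beta draw with the given mean; degenerate at the endpoints."""
    if mean <= 0.0 or mean >= 1.0:
        return mean
    return float(rng.beta(mean * kappa, (1.0 - mean) * kappa))


def _gamma_mean(rng: np.random.Generator, mean: float, cv: float) -> float:
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def draw_one(spec: ScenarioSpec, rng: np.random.Generator) -> ModelParameters:
    base = spec.base
    k, cv = spec.prob_concentration, spec.cost_cv
    d, c = base.demographics, base.clinical

    # Feeding-mode proportions must leave room for each other; rejection is
    # cheap at realistic concentrations.
    for _ in range(1000):
        ebf = _beta_mean(rng, d.ebf_fraction, k)
        mixed = _beta_mean(rng, d.mixed_fraction, k)
        if ebf + mixed <= 1.0:
            break
    else:
        total = ebf + mixed
        ebf, mixed = ebf / total, mixed / total

    suspected = _beta_mean(rng, d.suspected_incidence, k)
    # Drawing the confirmation probability (confirmed | suspected) keeps the
    # confirmed incidence below the suspected one by construction.
    base_ratio = (
        d.confirmed_incidence / d.suspected_incidence if d.suspected_incidence > 0 else 0.0
    )
    confirmed = suspected * _beta_mean(rng, base_ratio, k)

    tol_ages = sorted(c.tolerance_cumulative)
    tol_draws = sorted(_beta_mean(rng, c.tolerance_cumulative[a], k) for a in tol_ages)

    data = base.model_dump()
    data["demographics"].update(
        ebf_fraction=ebf,
        mixed_fraction=mixed,
        suspected_incidence=suspected,
        confirmed_incidence=confirmed,
    )
    data["clinical"].update(
        ehf_effectiveness=_beta_mean(rng, c.ehf_effectiveness, k),
        aaf_effectiveness=_beta_mean(rng, c.aaf_effectiveness, k),
        tolerance_cumulative=dict(zip(tol_ages, tol_draws)),
    )
    data["costs"]["monthly_cost"] = {
        formula: {
            band: _gamma_mean(rng, price, cv)
            for band, price in bands.items()
        }
        for formula, bands in base.costs.monthly_cost.items()
    }
    return parameters_from_dict(data)


def draw(spec: ScenarioSpec) -> list[ModelParameters]:
    """``n_draws`` validated scenarios, reproducible under ``seed``."""
    rng = np.random.default_rng(spec.seed)
    return [draw_one(spec, rng) for _ in range(spec.n_draws)]
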