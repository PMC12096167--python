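"""Monthly formula consumption: energy requirement to whole-can counts.

These equations document where the monthly formula budget comes from — a
50th-percentile-weight male infant's energy requirement, converted to whole
cans per month.  The cost-effectiveness model itself consumes monthly USD
prices directly; this module exists so that those prices can be audited
against consumption arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass

from .cohort import round_half_up


@dataclass(frozen=True)
class ConsumptionProfile:
    """Inputs for one age point.

    weight_kg: 50th-percentile weight for age (male reference).
    kcal_per_kg_day: age-specific energy requirement.
    days: days per consumption month (30 by convention here).
    kcal_per_can: energy content of one can (1,864 kcal for the reference can).
    formula_share: fraction of energy supplied by formula — 1.0 for an
        exclusively formula-fed 6-month-old, 0.5 at 9 months once
        complementary feeding covers half the requirement.
    """

    weight_kg: float
    kcal_per_kg_day: float
    days: float = 30.0
    kcal_per_can: float = 1864.0
    formula_share: float = 1.0

    def __post_init__(self) -> None:
        for name in ("weight_kg", "kcal_per_kg_day", "days", "kcal_per_can"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.formula_share <= 1.0:
            raise ValueError("formula_share must be in (0, 1]")


def monthly_energy(p: ConsumptionProfile) -> float:
    """kcal consumed per month: weight x requirement x days."""
    return p.weight_kg * p.kcal_per_kg_day * p.days


def cans_per_month(energy: float, kcal_per_can: float, formula_share: float = 1.0) -> int:
    """Whole cans per month, rounded half-up.

    Half-up is the only simple rule consistent with both reference age
    points (10.04 -> 10 cans and 5.58 -> 6 cans; floor fails the second,
    ceiling the first).
    """
    if kcal_per_can <= 0:
        raise ValueError("kcal_per_can must be positive")
    return round_half_up(energy * formula_share / kcal_per_can)


def profile_cans(p: ConsumptionProfile) -> int:
    return cans_per_month(monthly_energy(p), p.kcal_per_can, p.formula_share)
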