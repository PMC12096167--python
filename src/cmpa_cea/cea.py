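"""Incremental cost-effectiveness comparison and dominance classification."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import StrategyResult

DOMINANT = "dominant"
DOMINATED = "dominated"
ICER = "icer"
EQUIVALENT = "equivalent"
COST_ONLY = "cost-difference only, ICER undefined"


@dataclass(frozen=True)
class CEAResult:
    """Comparator vs reference: positive delta_cost means b costs more.

    ``label`` is ``dominated`` when the comparator is costlier *and* less
    effective, ``dominant`` on the mirror signs (an ICER is meaningless in
    both cases), ``icer`` when the ratio is informative, and degenerate
    labels when an effect or both deltas vanish.
    """

    reference: str
    comparator: str
    reference_cost: float
    comparator_cost: float
    reference_effect: float
    comparator_effect: float
    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str

    def to_plain(self) -> dict:
        return {
            "reference": self.reference,
            "comparator": self.comparator,
            "reference_cost": self.reference_cost,
            "comparator_cost": self.comparator_cost,
            "reference_effect": self.reference_effect,
            "comparator_effect": self.comparator_effect,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "label": self.label,
        }


def classify(delta_cost: float, delta_effect: float) -> tuple[float | None, str]:
    if delta_cost == 0.0 and delta_effect == 0.0:
        return None, EQUIVALENT
    if delta_effect == 0.0:
        return None, COST_ONLY
    if delta_cost > 0.0 and delta_effect < 0.0:
        return None, DOMINATED
    if delta_cost < 0.0 and delta_effect > 0.0:
        return None, DOMINANT
    return delta_cost / delta_effect, ICER


def compare(a: StrategyResult, b: StrategyResult) -> CEAResult:
    """Incremental comparison of comparator ``b`` against reference ``a``."""
    delta_cost = b.total_cost - a.total_cost
    delta_effect = b.total_symptom_free_months - a.total_symptom_free_months
    icer, label = classify(delta_cost, delta_effect)
    return CEAResult(
        reference=a.arm,
        comparator=b.arm,
        reference_cost=a.total_cost,
        comparator_cost=b.total_cost,
        reference_effect=a.total_symptom_free_months,
        comparator_effect=b.total_symptom_free_months,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        label=label,
    )


def summary_table(a: StrategyResult, b: StrategyResult) -> pd.DataFrame:
    """Two-row incremental table (reference first, comparator second).

    ``Avoided cost`` on the comparator row is the extra spend of the costlier
    strategy, i.e. what choosing the cheaper one avoids.
    """
    res = compare(a, b)
    min_cost = min(a.total_cost, b.total_cost)
    rows = []
    for r in (a, b):
        rows.append(
            {
                "Formula": r.arm,
                "Cost USD": r.total_cost,
                "Avoided cost": r.total_cost - min_cost,
                "Months without symptoms": r.total_symptom_free_months,
                "Months gained": r.total_symptom_free_months
                - a.total_symptom_free_months
                if r.arm != a.arm
                else 0.0,
                "ICER": "" if r.arm == a.arm else (res.label if res.icer is None else res.icer),
            }
        )
    return pd.DataFrame(rows)
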