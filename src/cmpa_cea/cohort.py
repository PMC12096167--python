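"""Derivation of the analysis cohort from national demographics.

Exclusively breastfed infants never enter the formula-based pathway; among
the rest, the suspected-CMPA fraction enters the model and the confirmed
fraction is carried as a continuous expectation (integers only at report
time).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import Demographics


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero for positive x."""
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class CohortBreakdown:
    total: int
    exclusively_breastfed: int
    eligible: int
    suspected: int
    confirmed_expected: float  # kept fractional; rounded only for display
    confirmation_ratio: float  # P(true CMPA | suspected)

    def to_plain(self) -> dict:
        return {
            "total": self.total,
            "exclusively_breastfed": self.exclusively_breastfed,
            "eligible": self.eligible,
            "suspected": self.suspected,
            "confirmed_expected": self.confirmed_expected,
            "confirmation_ratio": self.confirmation_ratio,
        }


def breakdown(d: Demographics) -> CohortBreakdown:
    """Cohort arithmetic: EBF exclusion, suspected entry, expected confirmed.

    Rounding conventions: the EBF count is truncated toward zero and the
    suspected count rounded half-up — the pair of rules that reproduces the
    published head-counts from the published proportions.
    """
    ebf = math.trunc(d.population_under_6mo * d.ebf_fraction)
    eligible = d.population_under_6mo - ebf
    if d.suspected_count_override is not None:
        suspected = d.suspected_count_override
    else:
        suspected = round_half_up(eligible * d.suspected_incidence)
    if d.suspected_incidence == 0:
        if d.confirmed_incidence > 0:
            raise ValueError(
                "confirmed_incidence > 0 with suspected_incidence = 0: "
                "confirmation probability undefined"
            )
        ratio = 0.0
    else:
        ratio = d.confirmed_incidence / d.suspected_incidence
    return CohortBreakdown(
        total=d.population_under_6mo,
        exclusively_breastfed=ebf,
        eligible=eligible,
        suspected=suspected,
        confirmed_expected=suspected * ratio,
        confirmation_ratio=ratio,
    )
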