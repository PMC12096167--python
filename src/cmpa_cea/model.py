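"""The two-arm CMPA diagnostic decision tree.

Both strategies follow the same skeleton for a suspected infant entering at
``entry_age_months``:

1. **Diagnostic window** (4 weeks by default) on the arm's elimination
   formula, ending in a cow's-milk challenge test.  A negative challenge
   rules CMPA out and the child leaves the model.
2. **Rescue** (eHF-first arm only): the fraction of true-CMPA children who
   stay symptomatic on eHF receives one additional diagnostic window on AAF
   before their challenge.  The window accrues cost but no symptom-free
   time, and does not displace the age-anchored maintenance window.
3. **Maintenance** to 24 months on eHF (step-down, effective for
   ``ehf_effectiveness`` of confirmed children) or AAF (the rest), with the
   monthly price switching bands at ``age_band_switch_months`` and tolerance
   exits at the scheduled challenge ages.

Symptom-free months accrue to true-CMPA children whenever they are on a
formula that controls their symptoms; time on eHF without response accrues
nothing.  Suspected-but-not-allergic children contribute diagnostic-window
cost only.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import cohort as cohort_mod
from .parameters import Formula, ModelParameters
from .tree import Branch, Node, Payoff, chance, enumerate_paths, rollback, terminal


@dataclass(frozen=True)
class StrategyArm:
    name: str
    diagnostic_formula: Formula
    rescue_formula: Formula | None = None  # extra diagnostic window for non-responders


AAF_FIRST = StrategyArm("AAF_first", "AAF")
EHF_FIRST = StrategyArm("eHF_first", "eHF", rescue_formula="AAF")
ARMS = (AAF_FIRST, EHF_FIRST)


@dataclass(frozen=True)
class TraceRow:
    path: str
    probability: float
    children: float
    cost_per_child: float
    effect_per_child: float
    total_cost: float
    total_effect: float


@dataclass(frozen=True)
class StrategyResult:
    arm: str
    suspected: int
    per_child: Payoff
    total_cost: float
    total_symptom_free_months: float
    trace: tuple[TraceRow, ...]

    def to_plain(self) -> dict:
        return {
            "arm": self.arm,
            "suspected": self.suspected,
            "cost_per_child": self.per_child.cost,
            "effect_per_child": self.per_child.effect,
            "total_cost": self.total_cost,
            "total_symptom_free_months": self.total_symptom_free_months,
        }


def weeks_to_months(weeks: float, days_per_month: float) -> float:
    if weeks < 0:
        raise ValueError("weeks must be non-negative")
    return weeks * 7.0 / days_per_month


def _cost_scale(params: ModelParameters) -> float:
    """Cohort-average formula-cost multiplier for mixed feeding.

    Mixed-fed infants (a ``mixed_fraction`` / (1 - ``ebf_fraction``) share of
    the eligible cohort) are charged ``mixed_formula_share`` of the full
    formula cost; the default share of 1.0 makes this a no-op.
    """
    d = params.demographics
    non_ebf = 1.0 - d.ebf_fraction
    if non_ebf <= 0:
        return 1.0
    mixed = d.mixed_fraction / non_ebf
    return (1.0 - mixed) + mixed * d.mixed_formula_share


def _band_price(params: ModelParameters, formula: Formula, age: float) -> float:
    band = "young" if age < params.costs.age_band_switch_months else "old"
    return params.costs.price(formula, band)


def _diag_formula(params: ModelParameters, arm: StrategyArm) -> Formula:
    """Formula whose price is charged for the arm's diagnostic window.

    Under the default ``published`` accounting the standard-of-care arm
    carries the premium (AAF) diagnostic price and the AAF-first arm's window
    is costed at the eHF price; ``as_fed`` charges each arm its own
    diagnostic formula.  See CostTable for the rationale.
    """
    if params.costs.diagnostic_pricing == "as_fed":
        return arm.diagnostic_formula
    return "eHF" if arm.diagnostic_formula == "AAF" else "AAF"


def _phase_cost(params: ModelParameters, formula: Formula, start: float, end: float) -> float:
    """Formula cost of a [start, end) age interval, split across price bands."""
    if end <= start:
        return 0.0
    switch = params.costs.age_band_switch_months
    young = max(0.0, min(end, switch) - start)
    old = max(0.0, end - max(start, switch))
    return young * params.costs.price(formula, "young") + old * params.costs.price(formula, "old")


def _tolerance_hazards(params: ModelParameters) -> list[tuple[float, float]]:
    """(challenge age, conditional exit probability) pairs within the horizon.

    Challenges run every ``challenge_interval_months`` from age 12 to the
    horizon; an age gets a non-zero hazard only if the cumulative tolerance
    map has an entry there (no figure means no incremental tolerance).
    """
    c = params.clinical
    t = params.time
    ages: list[float] = []
    age = 12.0
    while age <= t.horizon_age_months + 1e-9:
        ages.append(age)
        age += c.challenge_interval_months
    hazards: list[tuple[float, float]] = []
    prev_cum = 0.0
    for a in ages:
        cum = c.tolerance_cumulative.get(int(a)) if float(a).is_integer() else None
        if cum is None:
            hazards.append((a, 0.0))
        else:
            denom = 1.0 - prev_cum
            hazards.append((a, 0.0 if denom <= 0 else (cum - prev_cum) / denom))
            prev_cum = cum
    return hazards


def _maintenance_node(params: ModelParameters, formula: Formula, scale: float) -> Node:
    """Tolerance-exit chance node for maintenance on one formula.

    Costs run from the end of the (single) diagnostic window to the exit age;
    effect is the same interval (every maintained child is asymptomatic).
    Under ``keep_effect`` a tolerant child's effect runs to the horizon even
    though cost stops at exit.
    """
    t = params.time
    a0 = t.entry_age_months + weeks_to_months(
        params.clinical.diagnostic_duration_weeks, t.days_per_month
    )
    horizon = t.horizon_age_months
    keep = params.clinical.tolerance_exit == "keep_effect"

    branches: list[Branch] = []
    surviving = 1.0
    for age, hazard in _tolerance_hazards(params):
        if hazard <= 0.0 or age >= horizon:
            continue
        exit_effect = max(0.0, (horizon if keep else age) - a0)
        branches.append(
            Branch(
                label=f"tolerant at {age:g} mo",
                prob=surviving * hazard,
                payoff=Payoff(_phase_cost(params, formula, a0, age) * scale, exit_effect),
                child=terminal(),
            )
        )
        surviving *= 1.0 - hazard
    # At the horizon the 24-month challenge outcome no longer changes payoffs,
    # but both leaves are kept so the trace mirrors the clinical pathway.
    final_hazard = next(
        (h for a, h in _tolerance_hazards(params) if abs(a - horizon) < 1e-9), 0.0
    )
    horizon_payoff = Payoff(
        _phase_cost(params, formula, a0, horizon) * scale, max(0.0, horizon - a0)
    )
    branches.append(
        Branch(
            label=f"tolerant at {horizon:g} mo",
            prob=surviving * final_hazard,
            payoff=horizon_payoff,
            child=terminal(),
        )
    )
    branches.append(
        Branch(
            label="not tolerant at horizon",
            prob=surviving * (1.0 - final_hazard),
            payoff=horizon_payoff,
            child=terminal(),
        )
    )
    return chance(f"maintenance on {formula}", branches)


def build_arm(params: ModelParameters, arm: StrategyArm) -> Node:
    """Per-child chance tree for one strategy arm."""
    c = params.clinical
    t = params.time
    br = cohort_mod.breakdown(params.demographics)
    r = br.confirmation_ratio
    scale = _cost_scale(params)
    diag_months = weeks_to_months(c.diagnostic_duration_weeks, t.days_per_month)
    diag_cost = (
        _band_price(params, _diag_formula(params, arm), t.entry_age_months)
        * diag_months
        * scale
    )
    responds = c.aaf_effectiveness if arm.diagnostic_formula == "AAF" else c.ehf_effectiveness

    branches = [
        Branch(
            label="challenge negative (no CMPA)",
            prob=1.0 - r,
            payoff=Payoff(diag_cost, 0.0),
            child=terminal("excluded"),
        )
    ]

    if arm.diagnostic_formula == "AAF":
        # Responders (all of them at base-case 100% effectiveness) step down
        # to eHF, with the eHF non-response fraction returning to AAF at zero
        # symptomatic time.
        stepdown = chance(
            "step-down after confirmation",
            [
                Branch(
                    "maintained on eHF",
                    prob=c.ehf_effectiveness,
                    child=_maintenance_node(params, "eHF", scale),
                ),
                Branch(
                    "returned to AAF",
                    prob=1.0 - c.ehf_effectiveness,
                    child=_maintenance_node(params, "AAF", scale),
                ),
            ],
        )
        branches.append(
            Branch(
                label="CMPA, asymptomatic on AAF",
                prob=r * responds,
                payoff=Payoff(diag_cost, diag_months),
                child=stepdown,
            )
        )
        if responds < 1.0:
            branches.append(
                Branch(
                    label="CMPA, symptomatic on AAF",
                    prob=r * (1.0 - responds),
                    payoff=Payoff(diag_cost, 0.0),
                    child=_maintenance_node(params, "AAF", scale),
                )
            )
    else:
        branches.append(
            Branch(
                label="CMPA, asymptomatic on eHF",
                prob=r * responds,
                payoff=Payoff(diag_cost, diag_months),
                child=_maintenance_node(params, "eHF", scale),
            )
        )
        rescue_cost = (
            _band_price(params, arm.rescue_formula or "AAF", t.entry_age_months)
            * diag_months
            * scale
        )
        rescue = chance(
            "AAF rescue window",
            [
                Branch(
                    "rescue on AAF, challenge positive",
                    prob=1.0,
                    payoff=Payoff(rescue_cost, 0.0),
                    child=_maintenance_node(params, arm.rescue_formula or "AAF", scale),
                )
            ],
        )
        branches.append(
            Branch(
                label="CMPA, symptomatic on eHF",
                prob=r * (1.0 - responds),
                payoff=Payoff(diag_cost, 0.0),
                child=rescue,
            )
        )

    return chance(arm.name, branches)


def evaluate_arm(params: ModelParameters, arm: StrategyArm) -> StrategyResult:
    """Roll the arm back and scale the per-child expectation to the cohort."""
    br = cohort_mod.breakdown(params.demographics)
    root = build_arm(params, arm)
    per_child = rollback(root)[arm.name]
    n = br.suspected
    trace = tuple(
        TraceRow(
            path=" / ".join(p.labels),
            probability=p.prob,
            children=p.prob * n,
            cost_per_child=p.payoff.cost,
            effect_per_child=p.payoff.effect,
            total_cost=p.prob * n * p.payoff.cost,
            total_effect=p.prob * n * p.payoff.effect,
        )
        for p in enumerate_paths(root)
    )
    return StrategyResult(
        arm=arm.name,
        suspected=n,
        per_child=per_child,
        total_cost=per_child.cost * n,
        total_symptom_free_months=per_child.effect * n,
        trace=trace,
    )


def evaluate_both(params: ModelParameters) -> dict[str, StrategyResult]:
    return {arm.name: evaluate_arm(params, arm) for arm in ARMS}


def closed_form_months_gained(params: ModelParameters) -> float:
    """Analytic effect delta, independent of the tree machinery.

    Only the diagnostic window differs between arms for a true-CMPA child:
    the eHF non-responders sit symptomatic for one window that AAF-first
    children spend symptom-free.  Hence

        confirmed x (aaf_eff - ehf_eff) x diagnostic_months.
    """
    br = cohort_mod.breakdown(params.demographics)
    c = params.clinical
    diag_months = weeks_to_months(c.diagnostic_duration_weeks, params.time.days_per_month)
    return br.confirmed_expected * (c.aaf_effectiveness - c.ehf_effectiveness) * diag_months


def months_gained(params: ModelParameters) -> float:
    """Tree-evaluated symptom-free months gained by AAF-first over eHF-first."""
    res = evaluate_both(params)
    return (
        res[AAF_FIRST.name].total_symptom_free_months
        - res[EHF_FIRST.name].total_symptom_free_months
    )


def cost_saved(params: ModelParameters) -> float:
    """Cost avoided by AAF-first relative to eHF-first (positive = saving)."""
    res = evaluate_both(params)
    return res[EHF_FIRST.name].total_cost - res[AAF_FIRST.name].total_cost
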