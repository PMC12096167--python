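"""The two-arm CMPA model: structure, accounting conventions, oracles."""
import pytest

from cmpa_cea.cohort import breakdown
from cmpa_cea.model import (
    AAF_FIRST,
    EHF_FIRST,
    build_arm,
    closed_form_months_gained,
    cost_saved,
    evaluate_arm,
    evaluate_both,
    months_gained,
    weeks_to_months,
)
from cmpa_cea.sensitivity import set_parameter
from cmpa_cea.tree import enumerate_paths, rollback


@pytest.mark.parametrize(
    "weeks, dpm, expected",
    [(4, 30.4375, 28 / 30.4375), (0, 30.4375, 0.0), (4, 28, 1.0)],
)
def test_weeks_to_months(weeks, dpm, expected):
    assert weeks_to_months(weeks, dpm) == pytest.approx(expected)


def test_challenge_negative_exit_probability(base_params):
    for arm in (AAF_FIRST, EHF_FIRST):
        root = build_arm(base_params, arm)
        exit_branch = next(
            b for b in root.branches if "challenge negative" in b.label
        )
        assert exit_branch.prob == pytest.approx(1 - 0.02 / 0.068, abs=1e-9)
        assert exit_branch.payoff.effect == 0.0


def test_symptomatic_failure_branch_child_count(base_params):
    res = evaluate_arm(base_params, EHF_FIRST)
    failures = [r for r in res.trace if "CMPA, symptomatic on eHF" in r.path]
    assert sum(r.children for r in failures) == pytest.approx(362.8, abs=0.1)


def test_no_rescue_branch_when_ehf_fully_effective(base_params):
    params = set_parameter(base_params, "clinical.ehf_effectiveness", 1.0)
    root = build_arm(params, EHF_FIRST)
    rescue = next(b for b in root.branches if b.label == "CMPA, symptomatic on eHF")
    assert rescue.prob == 0.0


def test_child_count_conservation_at_every_split(base_params):
    """Counts across mutually exclusive sub-branches rebuild the parent count."""
    br = breakdown(base_params.demographics)
    for arm in (AAF_FIRST, EHF_FIRST):
        res = evaluate_arm(base_params, arm)
        assert sum(r.children for r in res.trace) == pytest.approx(br.suspected)
        confirmed = [r for r in res.trace if "challenge negative" not in r.path]
        assert sum(r.children for r in confirmed) == pytest.approx(br.confirmed_expected)
        # every tolerance-exit split conserves the maintained children
        maintained = [r for r in confirmed]
        exits_12 = sum(r.children for r in maintained if "tolerant at 12" in r.path)
        assert exits_12 == pytest.approx(br.confirmed_expected * 0.56)


def test_rollback_matches_enumeration_on_both_arms(base_params):
    for arm in (AAF_FIRST, EHF_FIRST):
        root = build_arm(base_params, arm)
        ev = rollback(root)[arm.name]
        paths = enumerate_paths(root)
        assert ev.cost == pytest.approx(
            sum(p.prob * p.payoff.cost for p in paths), rel=1e-12
        )
        assert ev.effect == pytest.approx(
            sum(p.prob * p.payoff.effect for p in paths), rel=1e-12
        )


def test_tree_effect_delta_matches_closed_form_oracle(base_params):
    assert months_gained(base_params) == pytest.approx(
        closed_form_months_gained(base_params), abs=1e-6
    )


@pytest.mark.parametrize(
    "path, value",
    [
        ("clinical.ehf_effectiveness", 0.75),
        ("clinical.aaf_effectiveness", 0.95),
        ("time.entry_age_months", 5.0),
        ("clinical.diagnostic_duration_weeks", 2.0),
        ("clinical.tolerance_cumulative.12", 0.3),
        ("demographics.ebf_fraction", 0.30),
    ],
)
def test_closed_form_oracle_holds_away_from_base(base_params, path, value):
    params = set_parameter(base_params, path, value)
    assert months_gained(params) == pytest.approx(
        closed_form_months_gained(params), abs=1e-6
    )


def test_closed_form_examples(base_params):
    assert closed_form_months_gained(base_params) == pytest.approx(333.7, abs=0.1)
    eff = set_parameter(base_params, "clinical.ehf_effectiveness", 1.0)
    assert closed_form_months_gained(eff) == 0.0
    nodiag = set_parameter(base_params, "clinical.diagnostic_duration_weeks", 0.0)
    assert closed_form_months_gained(nodiag) == 0.0


def test_total_effect_bounded_by_cohort_time(base_params):
    t = base_params.time
    horizon_span = t.horizon_age_months - t.entry_age_months
    for res in evaluate_both(base_params).values():
        assert 0 < res.total_symptom_free_months <= res.suspected * horizon_span
        assert all(row.children >= 0 for row in res.trace)


def test_costs_monotone_in_every_monthly_price(base_params):
    base = evaluate_both(base_params)
    for formula in ("AAF", "eHF"):
        for band in ("young", "old"):
            path = f"costs.monthly_cost.{formula}.{band}"
            bumped = evaluate_both(
                set_parameter(base_params, path, base_params.costs.price(formula, band) * 1.1)
            )
            for arm in bumped:
                assert bumped[arm].total_cost >= base[arm].total_cost - 1e-6


def test_months_gained_non_increasing_in_ehf_effectiveness(base_params):
    gains = [
        months_gained(set_parameter(base_params, "clinical.ehf_effectiveness", e))
        for e in (0.5, 0.7, 0.9, 1.0)
    ]
    assert gains == sorted(gains, reverse=True)
    assert gains[-1] == pytest.approx(0.0, abs=1e-9)


def test_tolerance_exits_never_increase_cost(base_params):
    no_tol = set_parameter(
        set_parameter(base_params, "clinical.tolerance_cumulative.12", 0.0),
        "clinical.tolerance_cumulative.24",
        0.0,
    )
    res_no = evaluate_both(no_tol)
    res_base = evaluate_both(base_params)
    for arm in res_base:
        assert res_no[arm].total_cost >= res_base[arm].total_cost
    higher = set_parameter(base_params, "clinical.tolerance_cumulative.12", 0.7)
    for arm, res in evaluate_both(higher).items():
        assert res.total_cost <= res_base[arm].total_cost


def test_as_fed_pricing_charges_each_arm_its_own_formula(base_params):
    """Under as-fed diagnostic pricing the premium-formula arm pays more up
    front, so the strategy saving shrinks by the full-cohort diagnostic price
    difference twice over."""
    params = base_params.model_copy(deep=True)
    params.costs.diagnostic_pricing = "as_fed"
    diff = cost_saved(base_params) - cost_saved(params)
    n = breakdown(base_params.demographics).suspected
    expected = 2 * n * (1426 - 1170) * weeks_to_months(4, 30.4375)
    assert diff == pytest.approx(expected, rel=1e-9)
    # the effect delta is an accounting-independent clinical quantity
    assert months_gained(params) == pytest.approx(months_gained(base_params), abs=1e-9)


def test_keep_effect_convention_credits_time_after_tolerance(base_params):
    params = base_params.model_copy(deep=True)
    params.clinical.tolerance_exit = "keep_effect"
    base = evaluate_both(base_params)
    kept = evaluate_both(params)
    for arm in base:
        assert kept[arm].total_symptom_free_months > base[arm].total_symptom_free_months
        assert kept[arm].total_cost == pytest.approx(base[arm].total_cost)
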