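"""Decision-tree engine: rollback, enumeration, validation."""
import numpy as np
import pytest

from cmpa_cea.tree import (
    Branch,
    Payoff,
    TreeError,
    chance,
    decision,
    enumerate_paths,
    expected_value,
    rollback,
    terminal,
    to_plain,
    validate,
)


def leaf_branch(label, prob, cost, effect):
    return Branch(label, terminal(), prob=prob, payoff=Payoff(cost, effect))


def test_single_terminal_behind_certain_branch_is_identity():
    t = chance("root", [leaf_branch("only", 1.0, 5.0, 2.0)])
    assert expected_value(t) == Payoff(5.0, 2.0)
    paths = enumerate_paths(t)
    assert len(paths) == 1 and paths[0].prob == 1.0


def test_symmetric_two_branch_expectation():
    t = chance("root", [leaf_branch("a", 0.5, 10, 0), leaf_branch("b", 0.5, 0, 10)])
    assert expected_value(t) == Payoff(5.0, 5.0)


def test_unnormalized_probabilities_error_names_node():
    t = chance("broken", [leaf_branch("a", 0.5, 0, 0), leaf_branch("b", 0.4, 0, 0)])
    with pytest.raises(TreeError, match="broken"):
        validate(t)


def test_cycle_detection():
    node = chance("loop", [])
    node.branches.append(Branch("self", node, prob=1.0))
    with pytest.raises(TreeError, match="cycle"):
        validate(node)


def test_decision_root_reports_all_strategies_without_optimizing():
    cheap = chance("cheap", [leaf_branch("x", 1.0, 1, 1)])
    rich = chance("rich", [leaf_branch("y", 1.0, 100, 2)])
    root = decision("choice", [Branch("cheap", cheap), Branch("rich", rich)])
    out = rollback(root)
    assert out == {"cheap": Payoff(1, 1), "rich": Payoff(100, 2)}


def test_path_probabilities_sum_to_one():
    inner = chance("inner", [leaf_branch("c", 0.56, 1, 1), leaf_branch("d", 0.44, 2, 2)])
    t = chance(
        "root",
        [Branch("a", inner, prob=0.9, payoff=Payoff(1, 0)), leaf_branch("b", 0.1, 0, 0)],
    )
    paths = enumerate_paths(t)
    assert len(paths) == 3
    assert sum(p.prob for p in paths) == pytest.approx(1.0, abs=1e-12)


def _random_tree(rng, depth):
    if depth == 0 or rng.random() < 0.3:
        return terminal()
    n = rng.integers(1, 4)
    probs = rng.dirichlet(np.ones(n))
    return chance(
        f"n{depth}",
        [
            Branch(
                f"b{i}",
                _random_tree(rng, depth - 1),
                prob=float(probs[i]),
                payoff=Payoff(float(rng.uniform(0, 100)), float(rng.uniform(0, 10))),
            )
            for i in range(n)
        ],
    )


def test_rollback_equals_path_enumeration_on_random_trees():
    """Two independent evaluation routes agree on >=1000 seeded random trees."""
    rng = np.random.default_rng(20_240_508)
    checked = 0
    while checked < 1000:
        t = _random_tree(rng, 4)
        if t.kind == "terminal":
            continue
        ev = expected_value(t)
        paths = enumerate_paths(t)
        cost = sum(p.prob * p.payoff.cost for p in paths)
        effect = sum(p.prob * p.payoff.effect for p in paths)
        assert ev.cost == pytest.approx(cost, rel=1e-9, abs=1e-9)
        assert ev.effect == pytest.approx(effect, rel=1e-9, abs=1e-9)
        assert sum(p.prob for p in paths) == pytest.approx(1.0, abs=1e-9)
        checked += 1


def test_cost_scaling_is_linear():
    rng = np.random.default_rng(7)
    t = _random_tree(rng, 3)
    while t.kind == "terminal":
        t = _random_tree(rng, 3)
    base = expected_value(t)

    def scale(node, k):
        for b in node.branches:
            b.payoff = Payoff(b.payoff.cost * k, b.payoff.effect)
            scale(b.child, k)

    scale(t, 3.0)
    assert expected_value(t).cost == pytest.approx(3.0 * base.cost, rel=1e-12)
    assert expected_value(t).effect == pytest.approx(base.effect, rel=1e-12)


def test_plain_dump_is_json_compatible():
    import json

    t = chance("root", [leaf_branch("a", 1.0, 5, 2)])
    dumped = json.loads(json.dumps(to_plain(t)))
    assert dumped["branches"][0]["label"] == "a"
    assert dumped["branches"][0]["child"]["kind"] == "terminal"
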