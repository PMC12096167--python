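"""Deterministic decision-tree engine.

Nodes are decision, chance or terminal.  Payoffs (cost, effect) attach to
branches as increments and accumulate along root-to-leaf paths; terminal
nodes carry nothing themselves.  Two independent evaluation routes are
provided — expected-value rollback and exhaustive path enumeration — so each
can serve as an oracle for the other.
"""
from __future__ import annotations

from dataclasses import dataclass, field

PROB_TOL = 1e-9


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class Payoff:
    cost: float = 0.0
    effect: float = 0.0

    def __add__(self, other: "Payoff") -> "Payoff":
        return Payoff(self.cost + other.cost, self.effect + other.effect)

    def scaled(self, k: float) -> "Payoff":
        return Payoff(self.cost * k, self.effect * k)


@dataclass
class Branch:
    label: str
    child: "Node"
    prob: float | None = None  # None on decision-node branches
    payoff: Payoff = field(default_factory=Payoff)


@dataclass
class Node:
    kind: str  # "decision" | "chance" | "terminal"
    name: str = ""
    branches: list[Branch] = field(default_factory=list)


def terminal(name: str = "") -> Node:
    return Node("terminal", name)


def chance(name: str, branches: list[Branch]) -> Node:
    return Node("chance", name, branches)


def decision(name: str, branches: list[Branch]) -> Node:
    return Node("decision", name, branches)


def validate(node: Node, _stack: tuple[int, ...] = ()) -> None:
    """Check node kinds, probability normalization and acyclicity."""
    if id(node) in _stack:
        raise TreeError(f"cycle detected at node {node.name!r}")
    if node.kind == "terminal":
        if node.branches:
            raise TreeError(f"terminal node {node.name!r} has branches")
        return
    if node.kind not in ("chance", "decision"):
        raise TreeError(f"unknown node kind {node.kind!r} at {node.name!r}")
    if not node.branches:
        raise TreeError(f"{node.kind} node {node.name!r} has no branches")
    if node.kind == "chance":
        total = 0.0
        for b in node.branches:
            if b.prob is None or not -PROB_TOL <= b.prob <= 1 + PROB_TOL:
                raise TreeError(
                    f"chance node {node.name!r}, branch {b.label!r}: "
                    f"probability {b.prob!r} not in [0, 1]"
                )
            total += b.prob
        if abs(total - 1.0) > PROB_TOL:
            raise TreeError(
                f"chance node {node.name!r}: branch probabilities sum to {total!r}, not 1"
            )
    stack = _stack + (id(node),)
    for b in node.branches:
        validate(b.child, stack)


def expected_value(node: Node) -> Payoff:
    """Bottom-up expected payoff of a chance/terminal subtree."""
    if node.kind == "terminal":
        return Payoff()
    if node.kind == "decision":
        raise TreeError(
            f"decision node {node.name!r} inside expected-value rollback; "
            "use rollback() on the root"
        )
    out = Payoff()
    for b in node.branches:
        out = out + (b.payoff + expected_value(b.child)).scaled(b.prob)
    return out


def rollback(root: Node) -> dict[str, Payoff]:
    """Expected payoff per strategy.

    A decision root reports every child strategy (the analysis compares arms;
    nothing is maximized away).  A chance or terminal root reports a single
    entry keyed by its name.
    """
    validate(root)
    if root.kind == "decision":
        return {b.label: b.payoff + expected_value(b.child) for b in root.branches}
    return {root.name: expected_value(root)}


@dataclass(frozen=True)
class PathResult:
    labels: tuple[str, ...]
    prob: float
    payoff: Payoff


def enumerate_paths(node: Node) -> list[PathResult]:
    """Exhaustive root-to-leaf enumeration of a chance tree.

    Independent of rollback(): path probabilities multiply and payoffs add
    along each path; the probability-weighted payoff sum must equal the
    rollback expectation.
    """
    validate(node)

    def walk(n: Node, labels: tuple[str, ...], prob: float, acc: Payoff) -> list[PathResult]:
        if n.kind == "terminal":
            return [PathResult(labels, prob, acc)]
        if n.kind == "decision":
            raise TreeError(f"decision node {n.name!r} in path enumeration")
        out: list[PathResult] = []
        for b in n.branches:
            out.extend(walk(b.child, labels + (b.label,), prob * b.prob, acc + b.payoff))
        return out

    return walk(node, (), 1.0, Payoff())


def to_plain(node: Node) -> dict:
    """JSON-compatible dump for debugging."""
    out: dict = {"kind": node.kind, "name": node.name}
    if node.branches:
        out["branches"] = [
            {
                "label": b.label,
                "prob": b.prob,
                "cost": b.payoff.cost,
                "effect": b.payoff.effect,
                "child": to_plain(b.child),
            }
            for b in node.branches
        ]
    return out
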