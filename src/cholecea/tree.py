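"""Decision-tree representation and expected-value rollback.

Both care strategies share one fixed two-level chance structure: the root
node splits on intraoperative conversion to open surgery, and each limb then
splits on postoperative outcome (no/minor complications for completed
laparoscopic cases; no/minor/major complications or acute mortality for
converted cases).  Terminal nodes carry a payoff bundle of cost (AU$),
inpatient bed days, and QALYs over the one-year horizon.

``rollback`` computes the probability-weighted expectation of each payoff
component; ``enumerate_paths`` lists every root-to-terminal path explicitly
and serves as an independent oracle for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Union

import pandas as pd

from .parameters import (
    CHANCE_NODES,
    OUTCOME_STATES,
    STRATEGIES,
    ParameterSet,
    normalize_chance_probabilities,
)

__all__ = [
    "PayoffBundle",
    "TerminalNode",
    "ChanceNode",
    "StrategyTree",
    "qaly_from_state",
    "build_strategy_trees",
    "rollback",
    "enumerate_paths",
    "paths_frame",
    "MORTALITY_STATE",
]

#: Outcome state with zero QALY accrual (death assumed at t=0 of the horizon).
MORTALITY_STATE = "open_mortality"

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class PayoffBundle:
    """Terminal or expected payoff: cost in AU$, inpatient bed days, QALYs."""

    cost: float
    bed_days: float
    qaly: float

    def __post_init__(self) -> None:
        for v in (self.cost, self.bed_days, self.qaly):
            if not (v == v and abs(v) != float("inf")):
                raise ValueError("payoff components must be finite")


@dataclass(frozen=True)
class TerminalNode:
    label: str
    payoff: PayoffBundle


@dataclass(frozen=True)
class ChanceNode:
    """A chance node with ordered (probability, child) branches.

    Probabilities must form a distribution to within 1e-9; callers normalize
    first (see :func:`normalize_chance_probabilities`).
    """

    branches: tuple[tuple[float, Union["ChanceNode", TerminalNode]], ...]

    def __post_init__(self) -> None:
        if len(self.branches) < 2:
            raise ValueError("a chance node needs at least two branches")
        total = sum(p for p, _ in self.branches)
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"branch probabilities sum to {total}, not 1")
        if any(p < 0 for p, _ in self.branches):
            raise ValueError("branch probabilities must be non-negative")


Node = Union[ChanceNode, TerminalNode]


@dataclass(frozen=True)
class StrategyTree:
    name: str
    root: ChanceNode


def qaly_from_state(
    utility: float, horizon_years: float = 1.0, is_mortality: bool = False
) -> float:
    """QALYs accrued in one outcome state over the model horizon.

    One utility applies per outcome state for the whole (1-year) horizon, so
    QALY = utility x horizon with no discounting.  The acute-mortality state
    accrues zero regardless of the utility passed.
    """
    if not 0.0 <= utility <= 1.0:
        raise ValueError(f"utility {utility} outside [0, 1]")
    if is_mortality:
        return 0.0
    return utility * horizon_years


ValueOverrides = Mapping[Union[str, tuple[str, str]], float]


def _value_lookup(
    overrides: ValueOverrides | None,
) -> Callable[[str, str], float | None]:
    if not overrides:
        return lambda name, strategy: None

    def look(name: str, strategy: str) -> float | None:
        if (name, strategy) in overrides:
            return float(overrides[(name, strategy)])  # per-arm value
        if name in overrides:
            return float(overrides[name])
        return None

    return look


def build_strategy_trees(
    params: ParameterSet, overrides: ValueOverrides | None = None
) -> tuple[StrategyTree, StrategyTree]:
    """Build the (conventional, day_surgery) trees from a parameter set.

    Both trees share the branch probabilities (proportionally renormalized
    per chance node) but carry strategy-specific terminal payoffs; e.g. the
    day-surgery uncomplicated laparoscopic terminal carries the same-day
    procedure cost plus the remote-monitoring cost and a 1-day stay, while
    complicated day-surgery paths revert to inpatient payoffs.

    ``overrides`` maps parameter names (or ``(name, strategy)`` pairs for
    per-arm values of shared rows) to replacement values; anything not
    overridden uses its base-case value.  Used by the sensitivity analyses.
    """
    look = _value_lookup(overrides)
    horizon = params.settings.horizon_years

    def terminal(strategy: str, state: str) -> TerminalNode:
        u_rows = params.payoff_rows(strategy, state, "utility")
        d_rows = params.payoff_rows(strategy, state, "bed_days")
        c_rows = params.payoff_rows(strategy, state, "cost")
        for role, rows in (("utility", u_rows), ("bed_days", d_rows), ("cost", c_rows)):
            if not rows:
                raise ValueError(f"{strategy}/{state}: missing {role} payoff")

        def val(p):  # override-aware value
            v = look(p.name, strategy)
            return p.base if v is None else v

        utility = val(u_rows[0])
        return TerminalNode(
            label=state,
            payoff=PayoffBundle(
                cost=sum(val(c) for c in c_rows),
                bed_days=val(d_rows[0]),
                qaly=qaly_from_state(utility, horizon, state == MORTALITY_STATE),
            ),
        )

    def chance(strategy: str, node: str) -> ChanceNode:
        rows = params.node_rows(node)
        raw = []
        for p in rows:
            v = look(p.name, strategy)
            raw.append(p.base if v is None else v)
        probs = normalize_chance_probabilities(raw)
        branches = []
        for p, row in zip(probs, rows):
            child: Node
            if row.branch in CHANCE_NODES:  # subtree
                child = chance(strategy, row.branch)
            else:
                child = terminal(strategy, row.branch)
            branches.append((p, child))
        return ChanceNode(tuple(branches))

    return tuple(StrategyTree(s, chance(s, "root")) for s in STRATEGIES)  # type: ignore[return-value]


def rollback(tree: StrategyTree) -> PayoffBundle:
    """Expected payoff bundle by recursive probability-weighted averaging."""

    def expect(node: Node) -> tuple[float, float, float]:
        if isinstance(node, TerminalNode):
            return node.payoff.cost, node.payoff.bed_days, node.payoff.qaly
        c = d = q = 0.0
        for p, child in node.branches:
            cc, dd, qq = expect(child)
            c += p * cc
            d += p * dd
            q += p * qq
        return c, d, q

    return PayoffBundle(*expect(tree.root))


def enumerate_paths(tree: StrategyTree) -> list[tuple[float, TerminalNode]]:
    """All root-to-terminal paths as (path probability, terminal) pairs.

    Path probabilities multiply along branches and sum to 1; the weighted
    sum of terminal payoffs equals :func:`rollback` (used as its oracle).
    """
    out: list[tuple[float, TerminalNode]] = []

    def walk(node: Node, prob: float) -> None:
        if isinstance(node, TerminalNode):
            out.append((prob, node))
            return
        for p, child in node.branches:
            walk(child, prob * p)

    walk(tree.root, 1.0)
    return out


def paths_frame(*trees: StrategyTree) -> pd.DataFrame:
    """Audit table of every path: strategy, state, probability, payoffs."""
    rows = []
    for tree in trees:
        for prob, term in enumerate_paths(tree):
            rows.append(
                {
                    "strategy": tree.name,
                    "state": term.label,
                    "probability": prob,
                    "cost": term.payoff.cost,
                    "bed_days": term.payoff.bed_days,
                    "qaly": term.payoff.qaly,
                }
            )
    return pd.DataFrame(rows)
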