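"""Randomly parameterized two-strategy decision-tree models for testing.

These generators emit parameter sets in the same declarative schema as the
packaged cholecystitis table, but with branch probabilities drawn uniformly
on each chance node's simplex and payoffs drawn within configurable scales.
They exercise the rollback/enumeration oracle pair, the schema round-trip,
and the zero-variance limit of the probabilistic analysis on models whose
structure is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    CHANCE_NODES,
    OUTCOME_STATES,
    STRATEGIES,
    AnalysisSettings,
    ParameterSet,
    ParameterSpec,
)
from .tree import MORTALITY_STATE, PayoffBundle

__all__ = ["SyntheticModelConfig", "generate_model", "known_answer_model"]


@dataclass(frozen=True)
class SyntheticModelConfig:
    """Knobs for random model generation.

    ``variance_fraction`` scales every parameter's uncertainty (range half
    width and SD) relative to its base value; zero produces a point-mass
    parameter set whose probabilistic analysis must reproduce its own
    rollback exactly.
    """

    seed: int
    n_terminal_states: int = 6
    cost_scale: float = 10000.0
    effect_scale: float = 10.0
    qaly_range: tuple[float, float] = (0.5, 1.0)
    variance_fraction: float = 0.2

    def validate(self) -> None:
        if self.n_terminal_states != len(OUTCOME_STATES):
            raise ValueError(
                "the tree structure is fixed at "
                f"{len(OUTCOME_STATES)} terminal states"
            )
        if self.cost_scale <= 0 or self.effect_scale <= 0:
            raise ValueError("scales must be positive")
        lo, hi = self.qaly_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("qaly_range must be a sub-interval of [0, 1]")
        if self.variance_fraction < 0:
            raise ValueError("variance_fraction must be non-negative")


def generate_model(config: SyntheticModelConfig) -> ParameterSet:
    """Draw a complete, validating parameter set at random.

    Branch probabilities come from a symmetric Dirichlet(1) per chance node
    (so each node's raw values already sum to one); bed days, costs and
    utilities are uniform within their scales.  Ranges are base +/-
    ``variance_fraction`` (clipped to [0, 1] for probabilities and
    utilities) and SDs are ``variance_fraction * base``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vf = config.variance_fraction
    specs: list[ParameterSpec] = []

    def bounds(base: float, unit_interval: bool) -> tuple[float, float]:
        lo, hi = base * (1.0 - vf), base * (1.0 + vf)
        if unit_interval:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        return lo, hi

    for node, branches in CHANCE_NODES.items():
        probs = rng.dirichlet(np.ones(len(branches)))
        for i, (branch, p) in enumerate(zip(branches, probs)):
            lo, hi = bounds(float(p), True)
            specs.append(
                ParameterSpec(
                    name=f"p_{node}_{branch}",
                    strategy="shared",
                    role="probability",
                    base=float(p),
                    low=lo,
                    high=hi,
                    sd=vf * float(p),
                    dist="beta",
                    node=node,
                    branch=branch,
                    complement=(i == 0),
                )
            )

    qlo, qhi = config.qaly_range
    for strat in STRATEGIES:
        for state in OUTCOME_STATES:
            d = float(rng.uniform(0.1, 1.0) * config.effect_scale)
            lo, hi = bounds(d, False)
            specs.append(
                ParameterSpec(
                    name=f"los_{strat}_{state}",
                    strategy=strat,
                    role="bed_days",
                    base=d,
                    low=lo,
                    high=hi,
                    dist="pert",
                    applies=((strat, state),),
                )
            )
            c = float(rng.uniform(0.1, 1.0) * config.cost_scale)
            lo, hi = bounds(c, False)
            specs.append(
                ParameterSpec(
                    name=f"cost_{strat}_{state}",
                    strategy=strat,
                    role="cost",
                    base=c,
                    low=lo,
                    high=hi,
                    sd=vf * c,
                    dist="gamma",
                    applies=((strat, state),),
                )
            )
            if state == MORTALITY_STATE:
                u, du, dist = 0.0, (0.0, 0.0), "fixed"
            else:
                u = float(rng.uniform(qlo, qhi))
                du, dist = bounds(u, True), "beta"
            specs.append(
                ParameterSpec(
                    name=f"u_{strat}_{state}",
                    strategy=strat,
                    role="utility",
                    base=u,
                    low=du[0],
                    high=du[1],
                    sd=vf * u if dist == "beta" else None,
                    dist=dist,
                    applies=((strat, state),),
                )
            )

    return ParameterSet(specs, AnalysisSettings(seed=config.seed))


def known_answer_model() -> tuple[ParameterSet, dict[str, PayoffBundle]]:
    """A hand-constructed model with analytically known expected payoffs.

    All branch probabilities are uniform within their node (1/2 at the root
    and laparoscopic node, 1/4 in the converted-to-open node); costs are the
    round numbers 100..600, bed days are all 2, and utilities are 0.8
    (mortality 0).  Both strategies carry identical payoffs, so every
    incremental quantity is exactly zero.

    Expected values, by hand:
      cost = 0.5*(100+200)/2 + 0.5*(300+400+500+600)/4 = 150/2 + ... = 300
      bed days = 2
      qaly = 0.5*0.8 + 0.5*(3/4)*0.8 = 0.7
    """
    specs: list[ParameterSpec] = []
    for node, branches in CHANCE_NODES.items():
        p = 1.0 / len(branches)
        for i, branch in enumerate(branches):
            specs.append(
                ParameterSpec(
                    name=f"p_{node}_{branch}",
                    strategy="shared",
                    role="probability",
                    base=p,
                    low=p,
                    high=p,
                    dist="beta",
                    node=node,
                    branch=branch,
                    complement=(i == 0),
                )
            )
    costs = dict(zip(OUTCOME_STATES, (100.0, 200.0, 300.0, 400.0, 500.0, 600.0)))
    for state in OUTCOME_STATES:
        u = 0.0 if state == MORTALITY_STATE else 0.8
        specs.append(
            ParameterSpec(
                name=f"cost_{state}", strategy="shared", role="cost",
                base=costs[state], low=costs[state], high=costs[state],
                dist="gamma", applies=tuple((s, state) for s in STRATEGIES),
            )
        )
        specs.append(
            ParameterSpec(
                name=f"los_{state}", strategy="shared", role="bed_days",
                base=2.0, low=2.0, high=2.0, dist="pert",
                applies=tuple((s, state) for s in STRATEGIES),
            )
        )
        specs.append(
            ParameterSpec(
                name=f"u_{state}", strategy="shared", role="utility",
                base=u, low=u, high=u, dist="fixed",
                applies=tuple((s, state) for s in STRATEGIES),
            )
        )
    params = ParameterSet(specs, AnalysisSettings())
    expected = PayoffBundle(cost=300.0, bed_days=2.0, qaly=0.7)
    return params, {s: expected for s in STRATEGIES}
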