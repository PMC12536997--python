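"""Probabilistic sensitivity analysis by Monte Carlo simulation.

Every parameter row is sampled from its resolved distribution; branch
probabilities are drawn once per iteration and shared by both arms (the two
strategies face the same surgical-outcome uncertainty), while payoff rows —
including rows whose point estimate is shared between arms, such as the
utilities — are drawn independently for each arm they price.  Each chance
node's drawn probabilities are renormalized to a distribution, both trees
are re-evaluated, and the per-draw payoff bundles are recorded.

Sampling uses one independent, deterministically derived RNG substream per
(parameter, arm), so results are reproducible for a given seed and adding a
parameter does not reshuffle the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import Effect
from .distributions import FittedDistribution, resolve_distribution
from .parameters import (
    CHANCE_NODES,
    STRATEGIES,
    AnalysisSettings,
    ParameterSet,
)
from .tree import MORTALITY_STATE

__all__ = ["PSAResult", "run_psa", "ceac", "prob_cost_effective", "default_wtp_grid"]

_PROB_TOL = 1e-9


def _substream(seed: int, name: str, arm: str) -> np.random.Generator:
    """Independent RNG stream keyed by (root seed, parameter, arm)."""
    key = zlib.crc32(f"{name}|{arm}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


@dataclass
class PSAResult:
    """Per-draw payoff bundles for both strategies plus their differences.

    ``draws`` has one row per Monte Carlo iteration with columns
    ``{strategy}_{cost,bed_days,qaly}``, ``delta_cost`` (day-surgery minus
    conventional), ``days_saved`` (conventional minus day-surgery bed days)
    and ``delta_qaly``.  ``parameter_draws`` retains the raw sampled values
    (keyed by name for shared probability rows, by ``(name, strategy)`` for
    payoff rows) for auditing and oracle checks.
    """

    draws: pd.DataFrame
    seed: int
    n: int
    distributions: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    parameter_draws: dict = field(default_factory=dict)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws["delta_cost"].to_numpy()

    def delta_effect(self, effect: Effect | str) -> np.ndarray:
        effect = Effect(effect)
        col = "days_saved" if effect is Effect.BED_DAYS_SAVED else "delta_qaly"
        return self.draws[col].to_numpy()

    def inmb(self, wtp: float, effect: Effect | str) -> np.ndarray:
        """Per-draw incremental net monetary benefit (affine in ``wtp``)."""
        return wtp * self.delta_effect(effect) - self.delta_cost

    def mean_payoffs(self) -> pd.DataFrame:
        cols = [
            f"{s}_{c}" for s in STRATEGIES for c in ("cost", "bed_days", "qaly")
        ]
        return self.draws[cols].mean().to_frame("mean").T


def run_psa(
    params: ParameterSet,
    settings: AnalysisSettings | None = None,
    n: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Run the Monte Carlo simulation and return per-draw payoffs."""
    settings = settings or params.settings
    n = int(settings.n_psa if n is None else n)
    seed = int(settings.seed if seed is None else seed)
    if n < 1:
        raise ValueError("number of draws must be >= 1")

    dists: dict[str, FittedDistribution] = {}
    notes: list[str] = []
    for p in params:
        d, nts = resolve_distribution(p, settings)
        dists[p.name] = d
        notes.extend(nts)

    raw: dict = {}
    # shared probability draws
    for node, _branches in CHANCE_NODES.items():
        for row in params.node_rows(node):
            raw[row.name] = dists[row.name].sample(_substream(seed, row.name, "shared"), n)
    # per-arm payoff draws
    for p in params:
        if p.role == "probability":
            continue
        arms = sorted({s for s, _ in p.applies})
        for arm in arms:
            raw[(p.name, arm)] = dists[p.name].sample(_substream(seed, p.name, arm), n)

    # renormalize each chance node's draws (rows: draws, cols: branches)
    node_probs: dict[str, dict[str, np.ndarray]] = {}
    for node, branches in CHANCE_NODES.items():
        rows = params.node_rows(node)
        mat = np.column_stack([raw[r.name] for r in rows])
        total = mat.sum(axis=1)
        if np.any(total <= 0.0):
            raise RuntimeError(f"chance node {node!r}: all-zero draw encountered")
        mat = mat / total[:, None]
        node_probs[node] = {r.branch: mat[:, i] for i, r in enumerate(rows)}

    # path probability of each terminal state (shared by both arms)
    path_prob = {
        state: node_probs["root"]["lap" if state.startswith("lap") else "open"]
        * node_probs["lap" if state.startswith("lap") else "open"][state]
        for node in ("lap", "open")
        for state in CHANCE_NODES[node]
    }

    horizon = settings.horizon_years
    data: dict[str, np.ndarray] = {}
    for strat in STRATEGIES:
        cost = np.zeros(n)
        days = np.zeros(n)
        qaly = np.zeros(n)
        for node in ("lap", "open"):
            for state in CHANCE_NODES[node]:
                w = path_prob[state]
                c_rows = params.payoff_rows(strat, state, "cost")
                d_row = params.payoff_rows(strat, state, "bed_days")[0]
                u_row = params.payoff_rows(strat, state, "utility")[0]
                cost += w * sum(raw[(r.name, strat)] for r in c_rows)
                days += w * raw[(d_row.name, strat)]
                if state != MORTALITY_STATE:
                    u = np.clip(raw[(u_row.name, strat)], 0.0, 1.0)
                    qaly += w * u * horizon
        data[f"{strat}_cost"] = cost
        data[f"{strat}_bed_days"] = days
        data[f"{strat}_qaly"] = qaly

    data["delta_cost"] = data["day_surgery_cost"] - data["conventional_cost"]
    data["days_saved"] = data["conventional_bed_days"] - data["day_surgery_bed_days"]
    data["delta_qaly"] = data["day_surgery_qaly"] - data["conventional_qaly"]

    return PSAResult(
        draws=pd.DataFrame(data),
        seed=seed,
        n=n,
        distributions=dists,
        notes=notes,
        parameter_draws=raw,
    )


def prob_cost_effective(
    result: PSAResult, wtp: float, effect: Effect | str = Effect.BED_DAYS_SAVED
) -> float:
    """Fraction of draws with strictly positive incremental NMB at ``wtp``."""
    return float(np.mean(result.inmb(wtp, effect) > 0.0))


def default_wtp_grid(threshold: float, n_points: int = 101) -> np.ndarray:
    """0 to twice the headline threshold, inclusive of the threshold itself."""
    return np.linspace(0.0, 2.0 * threshold, n_points)


def ceac(
    result: PSAResult,
    wtp_grid: Sequence[float],
    effect: Effect | str = Effect.BED_DAYS_SAVED,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from stored draws.

    Recomputed from the per-draw (delta cost, delta effect) pairs — the INMB
    is affine in the willingness to pay, so no re-simulation is needed.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("wtp values must be non-negative")
    de = result.delta_effect(effect)
    dc = result.delta_cost
    probs = [(float(np.mean(l * de - dc > 0.0))) for l in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})
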