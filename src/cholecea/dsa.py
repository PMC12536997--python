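"""One-way deterministic sensitivity analysis (tornado diagram).

Each independent parameter is swept to its low and high bound with all
others held at base case, and the incremental net monetary benefit is
re-evaluated.  Perturbing a branch probability replaces that branch's raw
value and proportionally renormalizes the whole chance node, the same
normalization the base case applies — so collapsing a parameter's bounds to
its base value reproduces the base-case INMB exactly.  Rows whose value is
shared between the two arms are perturbed in both arms simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import Effect, incremental_analysis
from .parameters import AnalysisSettings, ParameterSet
from .tree import build_strategy_trees, rollback

__all__ = ["TornadoEntry", "one_way_sweep", "count_influential"]


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: INMB at the parameter's low and high bound."""

    parameter: str
    low: float          # input value at the low bound
    high: float         # input value at the high bound
    inmb_low: float     # INMB with the parameter at its low bound
    inmb_high: float    # INMB with the parameter at its high bound

    @property
    def width(self) -> float:
        return abs(self.inmb_high - self.inmb_low)


def _inmb(
    params: ParameterSet,
    effect: Effect,
    wtp: float,
    overrides: dict[str, float] | None = None,
) -> float:
    conv, day = build_strategy_trees(params, overrides)
    return incremental_analysis(rollback(conv), rollback(day), effect, wtp).inmb


def one_way_sweep(
    params: ParameterSet,
    settings: AnalysisSettings | None = None,
    effect: Effect | str = Effect.BED_DAYS_SAVED,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """Sweep every variable parameter over [low, high], one at a time.

    Returns one entry per variable parameter, sorted by descending bar
    width with ties broken alphabetically by parameter name.
    """
    settings = settings or params.settings
    effect = Effect(effect)
    if wtp is None:
        wtp = (
            settings.wtp_bed_day
            if effect is Effect.BED_DAYS_SAVED
            else settings.wtp_qaly
        )
    entries = []
    for p in params.variable:
        if p.low > p.high:
            raise ValueError(f"{p.name}: low bound exceeds high bound")
        lo = _inmb(params, effect, wtp, {p.name: p.low})
        hi = _inmb(params, effect, wtp, {p.name: p.high})
        entries.append(
            TornadoEntry(
                parameter=p.name, low=p.low, high=p.high, inmb_low=lo, inmb_high=hi
            )
        )
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def count_influential(entries: list[TornadoEntry], threshold: float) -> int:
    """Number of bars whose width exceeds ``threshold`` (AU$)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return sum(1 for e in entries if e.width > threshold)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado table: parameter, swept bounds, INMB endpoints, width, rank."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low,
                "high_value": e.high,
                "inmb_low": e.inmb_low,
                "inmb_high": e.inmb_high,
                "width": e.width,
                "rank": i + 1,
            }
            for i, e in enumerate(entries)
        ]
    )
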