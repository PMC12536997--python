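"""Incremental cost-effectiveness: ICER, dominance, net monetary benefit.

The conventional inpatient arm is the reference; the day-surgery arm is the
comparator.  Effects are oriented so that higher is better: for the primary
outcome the effect is inpatient *bed days saved* relative to the reference
(each valued at the bed-day willingness to pay), for the secondary outcome
it is QALYs gained.  Net monetary benefit per strategy is
``NMB = wtp * effect - cost`` and the incremental NMB is
``INMB = wtp * delta_effect - delta_cost``, positive values favouring the
comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .tree import PayoffBundle

__all__ = [
    "Effect",
    "Dominance",
    "IncrementalResult",
    "incremental_analysis",
    "ceiling_check",
]


class Effect(str, Enum):
    """Outcome scale for incremental comparisons."""

    BED_DAYS_SAVED = "bed_days_saved"
    QALY = "qaly"


class Dominance(str, Enum):
    """Classification of the comparator relative to the reference.

    ``DOMINANT``: more (or equally) effective and strictly cheaper, or
    strictly more effective at equal cost — the ICER is not needed.
    ``DOMINATED``: the mirror image.  ``UNDEFINED_ZERO_DELTA_EFFECT``: equal
    effect and equal cost (or zero effect difference with zero cost
    difference); no meaningful ratio.  ``TRADEOFF``: one arm costs more and
    delivers more; the ICER applies.
    """

    DOMINANT = "dominant"
    DOMINATED = "dominated"
    TRADEOFF = "tradeoff"
    UNDEFINED_ZERO_DELTA_EFFECT = "undefined_zero_delta_effect"


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison at a single willingness-to-pay."""

    effect: Effect
    wtp: float
    delta_cost: float          # comparator - reference, AU$
    delta_effect: float        # oriented so higher is better
    icer: float                # AU$/effect unit; NaN when dominance applies
    dominance: Dominance
    nmb_reference: float
    nmb_comparator: float
    inmb: float                # nmb_comparator - nmb_reference

    @property
    def icer_label(self) -> str:
        """Human-readable ICER: the ratio, or the dominance verdict."""
        if math.isnan(self.icer):
            return self.dominance.value
        return f"{self.icer:,.0f}"


def _classify(delta_cost: float, delta_effect: float) -> Dominance:
    if delta_effect > 0 and delta_cost <= 0:
        return Dominance.DOMINANT
    if delta_effect < 0 and delta_cost >= 0:
        return Dominance.DOMINATED
    if delta_effect == 0:
        if delta_cost < 0:
            return Dominance.DOMINANT      # dominant by cost
        if delta_cost > 0:
            return Dominance.DOMINATED
        return Dominance.UNDEFINED_ZERO_DELTA_EFFECT
    return Dominance.TRADEOFF


def incremental_analysis(
    reference: PayoffBundle,
    comparator: PayoffBundle,
    effect: Effect | str = Effect.BED_DAYS_SAVED,
    wtp: float = 4000.0,
) -> IncrementalResult:
    """Compare the comparator strategy against the reference strategy.

    For ``bed_days_saved`` the effect difference is
    ``reference.bed_days - comparator.bed_days`` (days the comparator frees
    up); for ``qaly`` it is ``comparator.qaly - reference.qaly``.  The ICER
    is ``delta_cost / delta_effect`` and is reported as NaN whenever a
    dominance verdict (or a zero effect difference) makes the ratio
    meaningless.
    """
    effect = Effect(effect)
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")

    delta_cost = comparator.cost - reference.cost
    if effect is Effect.BED_DAYS_SAVED:
        eff_ref, eff_cmp = 0.0, reference.bed_days - comparator.bed_days
    else:
        eff_ref, eff_cmp = reference.qaly, comparator.qaly
    delta_effect = eff_cmp - eff_ref

    dominance = _classify(delta_cost, delta_effect)
    icer = (
        delta_cost / delta_effect
        if dominance is Dominance.TRADEOFF
        else float("nan")
    )
    nmb_ref = wtp * eff_ref - reference.cost
    nmb_cmp = wtp * eff_cmp - comparator.cost
    return IncrementalResult(
        effect=effect,
        wtp=wtp,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=dominance,
        nmb_reference=nmb_ref,
        nmb_comparator=nmb_cmp,
        inmb=nmb_cmp - nmb_ref,
    )


def ceiling_check(result: IncrementalResult, threshold: float) -> bool:
    """Whether the comparator is cost-effective at a WTP ceiling.

    True if the comparator dominates, or if the ICER is defined and lies in
    ``[0, threshold]`` (the boundary counts as cost-effective).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if result.dominance is Dominance.DOMINANT:
        return True
    if result.dominance is not Dominance.TRADEOFF:
        return False
    return 0.0 <= result.icer <= threshold
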