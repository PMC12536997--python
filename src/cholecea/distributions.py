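"""Moment-matched sampling distributions for probabilistic analysis.

Probabilities and utilities are sampled from beta distributions, lengths of
stay from PERT (a rescaled beta with shape constant 4), and costs from gamma
distributions, each matched to a reported mean and standard deviation (or to
the reported plausible range where no usable SD exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import AnalysisSettings, ParameterSpec

__all__ = [
    "InfeasibleMomentsError",
    "FittedDistribution",
    "fit_beta_moments",
    "fit_gamma_moments",
    "pert_distribution",
    "sample_pert",
    "point_mass",
    "resolve_distribution",
]

#: Standard PERT shape constant (weight of the mode in the implied beta).
PERT_SHAPE = 4.0


class InfeasibleMomentsError(ValueError):
    """The requested (mean, sd) pair cannot be matched by the family."""


@dataclass(frozen=True)
class FittedDistribution:
    """A sampling distribution with family-specific shape parameters.

    ``family`` is one of ``beta`` (params ``alpha``, ``beta``), ``gamma``
    (``shape``, ``rate``), ``pert`` (``min``, ``mode``, ``max``, plus the
    implied ``alpha``/``beta``) or ``fixed`` (``value``).  ``source_mean``
    and ``source_sd`` record the moments the fit was asked to match.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    source_mean: float = 0.0
    source_sd: float = 0.0

    @property
    def mean(self) -> float:
        p = self.params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] / p["rate"]
        if self.family == "pert":
            return (p["min"] + PERT_SHAPE * p["mode"] + p["max"]) / (PERT_SHAPE + 2.0)
        return p["value"]

    @property
    def sd(self) -> float:
        p = self.params
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        if self.family == "gamma":
            return math.sqrt(p["shape"]) / p["rate"]
        if self.family == "pert":
            a, b = p["alpha"], p["beta"]
            span = p["max"] - p["min"]
            return span * math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        return 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], 1.0 / p["rate"], size)
        if self.family == "pert":
            u = rng.beta(p["alpha"], p["beta"], size)
            return p["min"] + (p["max"] - p["min"]) * u
        return np.full(size, p["value"])


def point_mass(value: float) -> FittedDistribution:
    return FittedDistribution("fixed", {"value": float(value)}, float(value), 0.0)


def fit_beta_moments(mean: float, sd: float) -> FittedDistribution:
    """Beta distribution matched to a mean and SD by the method of moments.

    With ``nu = mean(1-mean)/sd^2 - 1``, the shapes are ``alpha = mean*nu``
    and ``beta = (1-mean)*nu``.  An SD of zero returns a point mass; an SD
    at or beyond the Bernoulli bound ``sqrt(mean(1-mean))`` is infeasible
    for a beta on [0, 1] and raises :class:`InfeasibleMomentsError`.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean {mean} must lie strictly in (0, 1)")
    if sd < 0.0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        return point_mass(mean)
    if sd * sd >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"sd {sd} infeasible for a beta with mean {mean} "
            f"(bound {math.sqrt(mean * (1 - mean)):.4f})"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return FittedDistribution(
        "beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu}, mean, sd
    )


def fit_gamma_moments(mean: float, sd: float) -> FittedDistribution:
    """Gamma distribution matched to a mean and SD by the method of moments.

    ``shape = (mean/sd)^2`` and ``rate = mean/sd^2``.  An SD of zero returns
    a point mass.
    """
    if mean <= 0.0:
        raise ValueError(f"gamma mean {mean} must be positive")
    if sd < 0.0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        return point_mass(mean)
    return FittedDistribution(
        "gamma",
        {"shape": (mean / sd) ** 2, "rate": mean / (sd * sd)},
        mean,
        sd,
    )


def pert_distribution(lo: float, mode: float, hi: float) -> FittedDistribution:
    """PERT distribution on [lo, hi] with the given mode (shape constant 4).

    The implied beta shapes are ``alpha = 1 + 4(mode-lo)/(hi-lo)`` and
    ``beta = 1 + 4(hi-mode)/(hi-lo)``; the mean is ``(lo + 4*mode + hi)/6``.
    A degenerate range returns a point mass at the mode.
    """
    if not lo <= mode <= hi:
        raise ValueError(f"PERT requires min <= mode <= max, got {(lo, mode, hi)}")
    if lo == hi:
        return point_mass(mode)
    span = hi - lo
    alpha = 1.0 + PERT_SHAPE * (mode - lo) / span
    beta = 1.0 + PERT_SHAPE * (hi - mode) / span
    mean = (lo + PERT_SHAPE * mode + hi) / (PERT_SHAPE + 2.0)
    d = FittedDistribution(
        "pert",
        {"min": lo, "mode": mode, "max": hi, "alpha": alpha, "beta": beta},
        mean,
        0.0,
    )
    return d


def sample_pert(
    lo: float, mode: float, hi: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw from PERT(min, mode, max); always bounded in [min, max]."""
    return pert_distribution(lo, mode, hi).sample(rng, size)


# ---------------------------------------------------------------------------
# per-parameter resolution policy
# ---------------------------------------------------------------------------

def _range_sd(spec: ParameterSpec, settings: AnalysisSettings) -> float:
    """SD implied by the plausible range: (high - low)/4, i.e. the range is
    read as an approximate 95% interval.  A degenerate range (low == high)
    means the parameter carries no uncertainty; rows missing a range
    entirely are already widened to base +/- ``default_range_fraction`` when
    the parameter file is loaded."""
    return (spec.high - spec.low) / 4.0


def resolve_distribution(
    spec: ParameterSpec, settings: AnalysisSettings
) -> tuple[FittedDistribution, list[str]]:
    """Resolve one parameter row to a concrete sampling distribution.

    Policy, in order:

    * ``fixed`` rows (and any row with no uncertainty left) -> point mass.
    * ``pert`` rows -> PERT(low, base, high).
    * ``gamma`` rows -> moment-matched gamma with the reported SD, falling
      back to the range-implied SD ``(high - low)/4`` when none is reported.
    * ``beta`` utility rows -> moment-matched beta with the reported SD if it
      is feasible, otherwise the range-implied SD.
    * ``beta`` probability rows -> always the range-implied SD: the reported
      probability SDs are not on the probability scale (most exceed the
      feasible bound ``sqrt(p(1-p))``), whereas the range column is
      internally consistent.
    * Any still-infeasible beta SD is replaced by half the Bernoulli bound.

    Returns the distribution and a list of human-readable notes describing
    every fallback applied.
    """
    notes: list[str] = []
    if spec.dist == "fixed":
        return point_mass(spec.base), notes

    if spec.dist == "pert":
        return pert_distribution(spec.low, spec.base, spec.high), notes

    if spec.dist == "gamma":
        if spec.base == 0.0:
            return point_mass(0.0), notes
        sd = spec.sd
        if sd is None:
            sd = _range_sd(spec, settings)
            notes.append(f"{spec.name}: gamma SD from range -> {sd:g}")
        return fit_gamma_moments(spec.base, sd), notes

    # beta
    if spec.base <= 0.0 or spec.base >= 1.0:
        notes.append(f"{spec.name}: degenerate beta mean {spec.base}; fixed")
        return point_mass(spec.base), notes
    if spec.role == "probability":
        sd = _range_sd(spec, settings)
        if spec.sd is not None:
            notes.append(
                f"{spec.name}: reported probability SD {spec.sd:g} not on the "
                f"probability scale; using range-implied SD {sd:g}"
            )
    else:
        sd = spec.sd
        if sd is None:
            sd = _range_sd(spec, settings)
            notes.append(f"{spec.name}: beta SD from range -> {sd:g}")
        elif sd * sd >= spec.base * (1.0 - spec.base):
            sd = _range_sd(spec, settings)
            notes.append(
                f"{spec.name}: reported SD {spec.sd:g} infeasible for a beta "
                f"with mean {spec.base:g}; using range-implied SD {sd:g}"
            )
    if sd == 0.0:
        return point_mass(spec.base), notes
    bound = math.sqrt(spec.base * (1.0 - spec.base))
    if sd >= bound:
        notes.append(
            f"{spec.name}: range-implied SD {sd:g} still infeasible; "
            f"clamped to {0.5 * bound:g}"
        )
        sd = 0.5 * bound
    return fit_beta_moments(spec.base, sd), notes
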