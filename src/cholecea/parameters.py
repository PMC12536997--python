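"""Model parameter table: loading, validation, and derived quantities.

The model compares two care strategies for low-risk acute cholecystitis —
conventional inpatient care and an acute day-surgery pathway with remote
patient monitoring — on a shared two-level decision tree.  Every model input
(branch probability, outcome-state utility, length of stay, cost) is a row in
a declarative parameter file; this module owns that schema.

Each chance-node branch probability is a ``probability`` row attached to a
named node of the tree.  Payoff rows (``utility``, ``bed_days``, ``cost``)
declare which (strategy, outcome state) pairs they price via an ``applies``
list, so a single row can be shared between strategies (e.g. the open-surgery
cost) while strategy-specific rows (the same-day procedure cost, the remote
monitoring cost) attach to one arm only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "STRATEGIES",
    "OUTCOME_STATES",
    "CHANCE_NODES",
    "ParameterSpec",
    "AnalysisSettings",
    "ParameterSet",
    "ParameterValidationError",
    "load_parameters",
    "default_parameter_file",
    "derive_day_surgery_costs",
    "normalize_chance_probabilities",
]

#: The two care strategies being compared.
STRATEGIES = ("conventional", "day_surgery")

#: Terminal outcome states of the surgical pathway.  ``lap`` paths completed
#: laparoscopically; ``open`` paths were converted to open cholecystectomy.
OUTCOME_STATES = (
    "lap_no_comp",
    "lap_minor",
    "open_no_comp",
    "open_minor",
    "open_major",
    "open_mortality",
)

#: Chance-node layout of the (fixed, two-level) tree: node name -> ordered
#: branch labels.  The root splits on intraoperative conversion to open
#: surgery; the second level splits on postoperative outcome.
CHANCE_NODES: Mapping[str, tuple[str, ...]] = {
    "root": ("lap", "open"),
    "lap": ("lap_no_comp", "lap_minor"),
    "open": ("open_no_comp", "open_minor", "open_major", "open_mortality"),
}

_ROLES = ("probability", "utility", "bed_days", "cost")
_DISTS = ("beta", "gamma", "pert", "fixed")
_STRATEGY_TAGS = STRATEGIES + ("shared",)


class ParameterValidationError(ValueError):
    """A parameter file failed schema or domain validation."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input.

    Parameters
    ----------
    name
        Unique identifier.
    strategy
        ``conventional``, ``day_surgery`` or ``shared`` (used by both arms).
    role
        Semantic role: ``probability``, ``utility``, ``bed_days`` or ``cost``.
    base, low, high
        Base-case value and the plausible range used in one-way sensitivity
        analysis (``low <= base <= high``).
    sd
        Standard deviation for probabilistic sensitivity analysis, if a
        source reports one; ``None`` means "derive from the range".
    dist
        Sampling family for probabilistic analysis: ``beta`` for
        probabilities and utilities, ``pert`` for lengths of stay, ``gamma``
        for costs, ``fixed`` for constants.
    node, branch
        For probability rows only: the chance node this branch belongs to
        and its branch label.
    applies
        For payoff rows only: ``(strategy, state)`` pairs this row prices.
    complement
        Probability rows flagged as the balancing branch of their node.
        They carry a base value and range like any other row, but are not
        independently varied in one-way sensitivity analysis (perturbing
        their siblings already spans the node's uncertainty).
    """

    name: str
    strategy: str
    role: str
    base: float
    low: float
    high: float
    sd: float | None = None
    dist: str = "fixed"
    node: str | None = None
    branch: str | None = None
    applies: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    complement: bool = False

    @property
    def is_variable(self) -> bool:
        """Whether this row is an independent axis of uncertainty."""
        return self.dist != "fixed" and not self.complement

    def validate(self) -> None:
        e = ParameterValidationError
        if self.strategy not in _STRATEGY_TAGS:
            raise e(f"{self.name}: unknown strategy {self.strategy!r}")
        if self.role not in _ROLES:
            raise e(f"{self.name}: unknown role {self.role!r}")
        if self.dist not in _DISTS:
            raise e(f"{self.name}: unknown distribution {self.dist!r}")
        if not (self.low <= self.base <= self.high):
            raise e(
                f"{self.name}: base {self.base} outside range "
                f"[{self.low}, {self.high}]"
            )
        if self.role in ("probability", "utility"):
            if self.low < 0.0 or self.high > 1.0:
                raise e(
                    f"{self.name}: {self.role} range [{self.low}, {self.high}] "
                    "must lie within [0, 1]"
                )
        else:
            if self.low < 0.0:
                raise e(f"{self.name}: {self.role} must be non-negative")
        if self.sd is not None and self.sd < 0.0:
            raise e(f"{self.name}: sd must be non-negative")
        if self.role == "probability":
            if self.node not in CHANCE_NODES:
                raise e(f"{self.name}: probability row needs a valid node")
            if self.branch not in CHANCE_NODES[self.node]:
                raise e(
                    f"{self.name}: branch {self.branch!r} not in node "
                    f"{self.node!r}"
                )
        else:
            if not self.applies:
                raise e(f"{self.name}: payoff row needs an 'applies' list")
            for strat, state in self.applies:
                if strat not in STRATEGIES:
                    raise e(f"{self.name}: applies to unknown strategy {strat!r}")
                if state not in OUTCOME_STATES:
                    raise e(f"{self.name}: applies to unknown state {state!r}")


@dataclass(frozen=True)
class AnalysisSettings:
    """Analysis-level settings shared by all computations.

    ``wtp_bed_day`` is the willingness to pay per inpatient bed day saved
    (AU$/day); ``wtp_qaly`` per quality-adjusted life year (AU$/QALY).  The
    model runs over a fixed one-year horizon with no discounting.
    """

    wtp_bed_day: float = 4000.0
    wtp_qaly: float = 50000.0
    horizon_years: float = 1.0
    n_psa: int = 5000
    seed: int = 2023
    default_range_fraction: float = 0.5

    def validate(self) -> None:
        if self.horizon_years != 1.0:
            raise ParameterValidationError(
                "horizon_years must be 1 (single-cycle tree, no discounting)"
            )
        if self.n_psa < 1:
            raise ParameterValidationError("n_psa must be >= 1")
        if self.wtp_bed_day < 0 or self.wtp_qaly < 0:
            raise ParameterValidationError("WTP thresholds must be >= 0")
        if not 0.0 <= self.default_range_fraction:
            raise ParameterValidationError("default_range_fraction must be >= 0")


class ParameterSet:
    """An ordered, validated collection of :class:`ParameterSpec` rows plus
    :class:`AnalysisSettings`."""

    def __init__(
        self,
        parameters: Iterable[ParameterSpec],
        settings: AnalysisSettings | None = None,
    ):
        self._params: list[ParameterSpec] = list(parameters)
        self.settings = settings if settings is not None else AnalysisSettings()
        self._by_name = {p.name: p for p in self._params}
        if len(self._by_name) != len(self._params):
            seen: set[str] = set()
            for p in self._params:
                if p.name in seen:
                    raise ParameterValidationError(
                        f"duplicate parameter name {p.name!r}"
                    )
                seen.add(p.name)
        self.validate()

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no parameter named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._params == other._params and self.settings == other.settings

    # -- views ---------------------------------------------------------------
    @property
    def variable(self) -> list[ParameterSpec]:
        """Rows that are independent axes of uncertainty (swept in one-way
        sensitivity analysis)."""
        return [p for p in self._params if p.is_variable]

    @property
    def n_variable(self) -> int:
        return len(self.variable)

    def node_rows(self, node: str) -> list[ParameterSpec]:
        """Probability rows of one chance node, in branch order."""
        rows = {p.branch: p for p in self._params
                if p.role == "probability" and p.node == node}
        return [rows[b] for b in CHANCE_NODES[node]]

    def payoff_rows(self, strategy: str, state: str, role: str) -> list[ParameterSpec]:
        """All rows of ``role`` that price ``(strategy, state)``."""
        return [
            p for p in self._params
            if p.role == role and (strategy, state) in p.applies
        ]

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """A copy with the base value of selected parameters replaced.

        Range bounds are widened if needed so the override stays valid;
        sensitivity analyses use this for temporary perturbations only.
        """
        new = []
        for p in self._params:
            if p.name in overrides:
                v = float(overrides[p.name])
                new.append(replace(p, base=v, low=min(p.low, v), high=max(p.high, v)))
            else:
                new.append(p)
        return ParameterSet(new, self.settings)

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        self.settings.validate()
        for p in self._params:
            p.validate()
        # every chance node fully specified
        for node, branches in CHANCE_NODES.items():
            rows = [p for p in self._params
                    if p.role == "probability" and p.node == node]
            have = {p.branch for p in rows}
            missing = set(branches) - have
            if missing:
                raise ParameterValidationError(
                    f"chance node {node!r} is missing branch rows: "
                    f"{sorted(missing)}"
                )
            if sum(p.base for p in rows) <= 0.0:
                raise ParameterValidationError(
                    f"chance node {node!r} has all-zero branch probabilities"
                )
        # every (strategy, state) fully priced
        for strat in STRATEGIES:
            for state in OUTCOME_STATES:
                for role, need in (("utility", 1), ("bed_days", 1)):
                    n = len(self.payoff_rows(strat, state, role))
                    if n != need:
                        raise ParameterValidationError(
                            f"{strat}/{state}: expected exactly {need} "
                            f"{role} row, found {n}"
                        )
                if not self.payoff_rows(strat, state, "cost"):
                    raise ParameterValidationError(
                        f"{strat}/{state}: no cost row applies"
                    )

    # -- serialisation -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per parameter: name/strategy/role/base/low/high/sd/dist."""
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "strategy": p.strategy,
                    "role": p.role,
                    "base": p.base,
                    "low": p.low,
                    "high": p.high,
                    "sd": p.sd,
                    "dist": p.dist,
                }
                for p in self._params
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        params = []
        for p in self._params:
            d: dict = {
                "name": p.name,
                "strategy": p.strategy,
                "role": p.role,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "dist": p.dist,
            }
            if p.sd is not None:
                d["sd"] = p.sd
            if p.role == "probability":
                d["node"] = p.node
                d["branch"] = p.branch
                if p.complement:
                    d["complement"] = True
            else:
                d["applies"] = [f"{s}/{st}" for s, st in p.applies]
            params.append(d)
        s = self.settings
        return {
            "settings": {
                "wtp_bed_day": s.wtp_bed_day,
                "wtp_qaly": s.wtp_qaly,
                "horizon_years": s.horizon_years,
                "n_psa": s.n_psa,
                "seed": s.seed,
                "default_range_fraction": s.default_range_fraction,
            },
            "parameters": params,
        }

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _parse_applies(raw: Sequence[str], name: str) -> tuple[tuple[str, str], ...]:
    out: list[tuple[str, str]] = []
    for item in raw:
        try:
            strat, state = str(item).split("/")
        except ValueError:
            raise ParameterValidationError(
                f"{name}: applies entry {item!r} must be 'strategy/state'"
            ) from None
        if strat == "both":
            out.extend((s, state) for s in STRATEGIES)
        else:
            out.append((strat, state))
    return tuple(out)


def _spec_from_dict(
    d: Mapping, *, source: str, default_range_fraction: float
) -> ParameterSpec:
    try:
        name = str(d["name"])
    except KeyError:
        raise ParameterValidationError(f"{source}: parameter entry without a name")
    required = ("strategy", "role", "base")
    missing = [k for k in required if k not in d]
    if missing:
        raise ParameterValidationError(f"{name}: missing fields {missing}")
    base = float(d["base"])
    # rows without a reported range default to base +/- default_range_fraction
    # (clipped to [0, 1] for probabilities and utilities)
    if "low" in d and "high" in d:
        low, high = float(d["low"]), float(d["high"])
    elif "low" in d or "high" in d:
        raise ParameterValidationError(f"{name}: give both low and high, or neither")
    else:
        low = base * (1.0 - default_range_fraction)
        high = base * (1.0 + default_range_fraction)
        if d.get("role") in ("probability", "utility"):
            low, high = max(low, 0.0), min(high, 1.0)
    return ParameterSpec(
        name=name,
        strategy=str(d["strategy"]),
        role=str(d["role"]),
        base=base,
        low=low,
        high=high,
        sd=None if d.get("sd") is None else float(d["sd"]),
        dist=str(d.get("dist", "fixed")),
        node=d.get("node"),
        branch=d.get("branch"),
        applies=_parse_applies(d.get("applies", []), name)
        if d.get("role") != "probability"
        else (),
        complement=bool(d.get("complement", False)),
    )


def default_parameter_file() -> Path:
    """Path to the packaged cholecystitis parameter table."""
    return Path(
        importlib.resources.files("cholecea").joinpath("data/table1.yaml")  # type: ignore[arg-type]
    )


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file.

    With no argument, loads the packaged cholecystitis table (literature
    base-case values, ranges and standard deviations for both care models).
    Raises :class:`ParameterValidationError` naming the offending parameter
    on any schema or domain violation.
    """
    p = default_parameter_file() if path is None else Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping) or "parameters" not in raw:
        raise ParameterValidationError(f"{p}: expected a 'parameters' section")
    settings = AnalysisSettings(**raw.get("settings", {}))
    specs = [
        _spec_from_dict(
            d,
            source=str(p),
            default_range_fraction=settings.default_range_fraction,
        )
        for d in raw["parameters"]
    ]
    return ParameterSet(specs, settings)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def derive_day_surgery_costs(
    conventional_lap_cost: float,
    cost_ratio: float = 1.38,
    monitoring_fraction: float = 0.5,
) -> tuple[int, int]:
    """Derive the same-day procedure cost and the remote-monitoring budget.

    Converting an inpatient laparoscopic cholecystectomy to a same-day
    procedure divides its cost by ``cost_ratio``; a fraction
    ``monitoring_fraction`` of the resulting saving funds the remote
    patient-monitoring program.  Both outputs are rounded to the nearest
    dollar, so the monitoring cost can never exceed the full saving
    ``(1 - 1/cost_ratio) * conventional_lap_cost``.

    Returns ``(same_day_cost, monitoring_cost)`` in whole dollars.
    """
    if conventional_lap_cost <= 0:
        raise ValueError("conventional_lap_cost must be positive")
    if cost_ratio <= 1.0:
        raise ValueError("cost_ratio must exceed 1 (no saving to fund monitoring)")
    if not 0.0 <= monitoring_fraction <= 1.0:
        raise ValueError("monitoring_fraction must lie in [0, 1]")
    same_day = round(conventional_lap_cost / cost_ratio)
    monitoring = round(monitoring_fraction * (conventional_lap_cost - same_day))
    return int(same_day), int(monitoring)


def normalize_chance_probabilities(probs: Sequence[float]) -> list[float]:
    """Rescale non-negative branch weights to a proper distribution.

    Published branch probabilities sometimes sum to slightly less than one
    (the converted-to-open branches print as 0.88 + 0.08 + 0.01 + 0.02 =
    0.99); no branch is privileged, so all are scaled proportionally.
    Order is preserved and the output sums to 1 to within 1e-12.
    """
    if any(p < 0 for p in probs):
        raise ValueError("branch probabilities must be non-negative")
    total = float(sum(probs))
    if total <= 0.0:
        raise ValueError("branch probabilities sum to zero")
    return [float(p) / total for p in probs]
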