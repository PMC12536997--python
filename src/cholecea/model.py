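"""Model and Results objects tying the analysis pipeline together.

:class:`CostEffectivenessModel` is built from a validated parameter set
(usually the packaged cholecystitis table).  ``fit()`` rolls back both
strategy trees and returns :class:`BaseCaseResults` with the expected
payoffs, the incremental comparison on either outcome scale, and a text
summary.  ``fit_tornado()`` and ``fit_psa()`` return results objects for
the one-way and probabilistic sensitivity analyses, each carrying its own
tables, plots and CSV writers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import psa as _psa
from .cea import Effect, IncrementalResult, ceiling_check, incremental_analysis
from .dsa import TornadoEntry, count_influential, one_way_sweep, tornado_frame
from .parameters import (
    STRATEGIES,
    AnalysisSettings,
    ParameterSet,
    load_parameters,
)
from .tree import PayoffBundle, StrategyTree, build_strategy_trees, paths_frame, rollback

__all__ = [
    "CostEffectivenessModel",
    "BaseCaseResults",
    "TornadoResults",
    "PSAResults",
]

AUD_TO_USD = 0.66  # reporting-only conversion rate


class CostEffectivenessModel:
    """Two-strategy decision-tree cost-effectiveness model.

    Parameters
    ----------
    params
        A validated :class:`~cholecea.parameters.ParameterSet`.  Use
        :meth:`from_yaml` to read a parameter file, or the no-argument
        constructor :meth:`reference_case` for the packaged cholecystitis
        table.

    Examples
    --------
    >>> model = CostEffectivenessModel.reference_case()
    >>> res = model.fit()
    >>> res.payoffs["conventional"].bed_days  # doctest: +ELLIPSIS
    3.157...
    """

    def __init__(self, params: ParameterSet):
        self.params = params

    @classmethod
    def from_yaml(cls, path) -> "CostEffectivenessModel":
        return cls(load_parameters(path))

    @classmethod
    def reference_case(cls) -> "CostEffectivenessModel":
        """Model parameterized from the packaged cholecystitis table."""
        return cls(load_parameters())

    @property
    def settings(self) -> AnalysisSettings:
        return self.params.settings

    def build_trees(self) -> tuple[StrategyTree, StrategyTree]:
        return build_strategy_trees(self.params)

    def fit(self) -> "BaseCaseResults":
        """Base-case rollback of both strategy trees."""
        conv, day = self.build_trees()
        payoffs = {conv.name: rollback(conv), day.name: rollback(day)}
        return BaseCaseResults(self, payoffs, (conv, day))

    def fit_tornado(
        self, effect: Effect | str = Effect.BED_DAYS_SAVED, wtp: float | None = None
    ) -> "TornadoResults":
        """One-way sensitivity analysis over every variable parameter."""
        effect = Effect(effect)
        if wtp is None:
            wtp = (
                self.settings.wtp_bed_day
                if effect is Effect.BED_DAYS_SAVED
                else self.settings.wtp_qaly
            )
        entries = one_way_sweep(self.params, self.settings, effect, wtp)
        base = self.fit().incremental(effect, wtp).inmb
        return TornadoResults(self, entries, effect, wtp, base)

    def fit_psa(
        self, n: int | None = None, seed: int | None = None
    ) -> "PSAResults":
        """Probabilistic sensitivity analysis (Monte Carlo simulation)."""
        raw = _psa.run_psa(self.params, self.settings, n=n, seed=seed)
        return PSAResults(self, raw)


class BaseCaseResults:
    """Expected payoffs per strategy and their incremental comparison."""

    def __init__(
        self,
        model: CostEffectivenessModel,
        payoffs: dict[str, PayoffBundle],
        trees: tuple[StrategyTree, StrategyTree],
    ):
        self.model = model
        self.payoffs = payoffs
        self.trees = trees

    def incremental(
        self, effect: Effect | str = Effect.BED_DAYS_SAVED, wtp: float | None = None
    ) -> IncrementalResult:
        """Day-surgery vs conventional on the chosen outcome scale."""
        effect = Effect(effect)
        s = self.model.settings
        if wtp is None:
            wtp = s.wtp_bed_day if effect is Effect.BED_DAYS_SAVED else s.wtp_qaly
        return incremental_analysis(
            self.payoffs["conventional"], self.payoffs["day_surgery"], effect, wtp
        )

    def strategy_frame(self) -> pd.DataFrame:
        s = self.model.settings
        rows = []
        for name in STRATEGIES:
            b = self.payoffs[name]
            days_saved = (
                self.payoffs["conventional"].bed_days - b.bed_days
            )
            rows.append(
                {
                    "strategy": name,
                    "cost_aud": b.cost,
                    "cost_usd": b.cost * AUD_TO_USD,
                    "bed_days": b.bed_days,
                    "qaly": b.qaly,
                    "nmb_bed_day": s.wtp_bed_day * days_saved - b.cost,
                    "nmb_qaly": s.wtp_qaly * b.qaly - b.cost,
                }
            )
        return pd.DataFrame(rows)

    def incremental_frame(self) -> pd.DataFrame:
        rows = []
        for effect in Effect:
            r = self.incremental(effect)
            rows.append(
                {
                    "effect": effect.value,
                    "wtp": r.wtp,
                    "delta_cost": r.delta_cost,
                    "delta_effect": r.delta_effect,
                    "icer": r.icer_label,
                    "inmb": r.inmb,
                    "cost_effective": ceiling_check(r, r.wtp),
                }
            )
        return pd.DataFrame(rows)

    def paths(self) -> pd.DataFrame:
        """Audit listing of every root-to-terminal path of both trees."""
        return paths_frame(*self.trees)

    def summary(self) -> str:
        bed = self.incremental(Effect.BED_DAYS_SAVED)
        lines = [
            "Base case (1-year horizon, 2023 AU$)",
            "=" * 52,
            self.strategy_frame().round(3).to_string(index=False),
            "",
            self.incremental_frame().round(3).to_string(index=False),
            "",
            f"Verdict (bed-day outcome): day surgery is {bed.dominance.value} "
            f"(saves {bed.delta_effect:.2f} bed days and "
            f"AU${-bed.delta_cost:,.0f} per case).",
        ]
        return "\n".join(lines)

    def to_csv(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("basecase_strategies.csv", self.strategy_frame()),
            ("basecase_incremental.csv", self.incremental_frame()),
            ("basecase_paths.csv", self.paths()),
        ):
            path = outdir / name
            df.to_csv(path, index=False)
            written.append(path)
        return written


class TornadoResults:
    """Ordered one-way sensitivity results (tornado diagram)."""

    def __init__(
        self,
        model: CostEffectivenessModel,
        entries: list[TornadoEntry],
        effect: Effect,
        wtp: float,
        base_inmb: float,
    ):
        self.model = model
        self.entries = entries
        self.effect = effect
        self.wtp = wtp
        self.base_inmb = base_inmb

    def frame(self) -> pd.DataFrame:
        return tornado_frame(self.entries)

    def count_influential(self, threshold: float | None = None) -> int:
        """Bars wider than ``threshold`` AU$ (default 1% of base-case INMB)."""
        if threshold is None:
            threshold = 0.01 * abs(self.base_inmb)
        return count_influential(self.entries, threshold)

    def summary(self) -> str:
        return "\n".join(
            [
                f"One-way sensitivity of INMB ({self.effect.value}, "
                f"WTP AU${self.wtp:,.0f}); base INMB AU${self.base_inmb:,.0f}",
                "=" * 68,
                self.frame().round(2).to_string(index=False),
                "",
                f"{self.count_influential()} of {len(self.entries)} parameters "
                "move the INMB by more than 1% of its base value.",
            ]
        )

    def plot(self, path=None, max_bars: int | None = None):
        from .plotting import tornado_plot

        return tornado_plot(self, path=path, max_bars=max_bars)

    def to_csv(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"tornado_{self.effect.value}.csv"
        self.frame().to_csv(path, index=False)
        return [path]


class PSAResults:
    """Probabilistic sensitivity analysis results.

    Wraps the raw per-draw payoff matrix and derives the cost-effectiveness
    plane and acceptability curves on demand.
    """

    def __init__(self, model: CostEffectivenessModel, raw: _psa.PSAResult):
        self.model = model
        self.raw = raw

    @property
    def draws(self) -> pd.DataFrame:
        return self.raw.draws

    @property
    def seed(self) -> int:
        return self.raw.seed

    @property
    def n(self) -> int:
        return self.raw.n

    @property
    def notes(self) -> list[str]:
        return self.raw.notes

    def prob_cost_effective(
        self, wtp: float | None = None, effect: Effect | str = Effect.BED_DAYS_SAVED
    ) -> float:
        """Fraction of draws with positive INMB at the WTP threshold."""
        effect = Effect(effect)
        s = self.model.settings
        if wtp is None:
            wtp = s.wtp_bed_day if effect is Effect.BED_DAYS_SAVED else s.wtp_qaly
        return _psa.prob_cost_effective(self.raw, wtp, effect)

    def ceac(
        self,
        effect: Effect | str = Effect.BED_DAYS_SAVED,
        wtp_grid=None,
    ) -> pd.DataFrame:
        effect = Effect(effect)
        if wtp_grid is None:
            s = self.model.settings
            head = s.wtp_bed_day if effect is Effect.BED_DAYS_SAVED else s.wtp_qaly
            wtp_grid = _psa.default_wtp_grid(head)
        return _psa.ceac(self.raw, wtp_grid, effect)

    def ce_plane(self, effect: Effect | str = Effect.BED_DAYS_SAVED) -> pd.DataFrame:
        """Per-draw (delta effect, delta cost) scatter points."""
        effect = Effect(effect)
        return pd.DataFrame(
            {
                "delta_effect": self.raw.delta_effect(effect),
                "delta_cost": self.raw.delta_cost,
            }
        )

    def summary(self) -> str:
        s = self.model.settings
        p_bed = self.prob_cost_effective(effect=Effect.BED_DAYS_SAVED)
        p_qaly = self.prob_cost_effective(effect=Effect.QALY)
        mean = self.raw.mean_payoffs().round(3).to_string(index=False)
        return "\n".join(
            [
                f"Probabilistic sensitivity analysis ({self.n} draws, seed {self.seed})",
                "=" * 60,
                "Mean payoffs across draws:",
                mean,
                "",
                f"P(cost-effective) at AU${s.wtp_bed_day:,.0f}/bed day saved: "
                f"{p_bed:.1%}",
                f"P(cost-effective) at AU${s.wtp_qaly:,.0f}/QALY:          "
                f"{p_qaly:.1%}",
            ]
        )

    def plot_ce_plane(self, effect=Effect.BED_DAYS_SAVED, path=None):
        from .plotting import ce_plane_plot

        return ce_plane_plot(self, Effect(effect), path=path)

    def plot_ceac(self, effect=Effect.BED_DAYS_SAVED, path=None):
        from .plotting import ceac_plot

        return ceac_plot(self, Effect(effect), path=path)

    def to_csv(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        draws = self.draws.copy()
        draws.insert(0, "draw", np.arange(len(draws)))
        for name, df in (
            ("psa_draws.csv", draws),
            ("ceac_bed_days.csv", self.ceac(Effect.BED_DAYS_SAVED)),
            ("ceac_qaly.csv", self.ceac(Effect.QALY)),
        ):
            path = outdir / name
            df.to_csv(path, index=False)
            written.append(path)
        return written
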