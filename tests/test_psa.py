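"""Probabilistic sensitivity analysis: sampling, reproducibility, CEAC."""

import numpy as np
import pandas as pd
import pytest

from cholecea import (
    Effect,
    SyntheticModelConfig,
    build_strategy_trees,
    ceac,
    generate_model,
    prob_cost_effective,
    rollback,
    run_psa,
)
from cholecea.parameters import CHANCE_NODES


@pytest.fixture(scope="module")
def psa(model):
    return model.fit_psa(n=2000, seed=7)


class TestReproducibility:
    def test_same_seed_gives_identical_draws(self, table1):
        a = run_psa(table1, n=200, seed=11)
        b = run_psa(table1, n=200, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_different_seeds_differ(self, table1):
        a = run_psa(table1, n=200, seed=11)
        b = run_psa(table1, n=200, seed=12)
        assert not a.draws.equals(b.draws)

    def test_adding_a_parameter_does_not_reshuffle_others(self, table1):
        # substreams are keyed by parameter name, so an unrelated extra row
        # must leave existing draws untouched
        from cholecea.parameters import ParameterSet, ParameterSpec

        extra = ParameterSpec(
            name="cost_extra_audit",
            strategy="shared",
            role="cost",
            base=100.0,
            low=50.0,
            high=150.0,
            sd=25.0,
            dist="gamma",
            applies=(("conventional", "open_major"),),
        )
        bigger = ParameterSet(list(table1) + [extra], table1.settings)
        a = run_psa(table1, n=100, seed=5)
        b = run_psa(bigger, n=100, seed=5)
        np.testing.assert_array_equal(
            a.parameter_draws["p_lap"], b.parameter_draws["p_lap"]
        )
        np.testing.assert_array_equal(
            a.parameter_draws[("cost_lap_inpatient", "conventional")],
            b.parameter_draws[("cost_lap_inpatient", "conventional")],
        )


class TestConservation:
    def test_chance_nodes_renormalized_per_draw(self, table1, psa):
        raw = psa.raw.parameter_draws
        for node in CHANCE_NODES:
            rows = table1.node_rows(node)
            mat = np.column_stack([raw[r.name] for r in rows])
            norm = mat / mat.sum(axis=1)[:, None]
            np.testing.assert_allclose(norm.sum(axis=1), 1.0, atol=1e-9)

    def test_bed_day_draws_within_pert_bounds(self, table1, psa):
        raw = psa.raw.parameter_draws
        for p in table1:
            if p.role != "bed_days":
                continue
            for key, arr in raw.items():
                if isinstance(key, tuple) and key[0] == p.name:
                    assert arr.min() >= p.low and arr.max() <= p.high

    def test_cost_draws_nonnegative(self, psa):
        for key, arr in psa.raw.parameter_draws.items():
            if isinstance(key, tuple) and key[0].startswith("cost"):
                assert arr.min() >= 0.0

    def test_expected_bed_days_and_costs_positive(self, psa):
        d = psa.draws
        for strat in ("conventional", "day_surgery"):
            assert (d[f"{strat}_bed_days"] > 0).all()
            assert (d[f"{strat}_cost"] > 0).all()


class TestAgainstTreeOracle:
    def test_each_draw_matches_per_draw_tree_rebuild(self, table1):
        # rebuild both trees from the stored raw draws, one iteration at a
        # time, and compare with the vectorized engine
        res = run_psa(table1, n=25, seed=3)
        raw = res.parameter_draws
        for i in range(res.n):
            overrides = {k: float(v[i]) for k, v in raw.items()}
            conv, day = build_strategy_trees(table1, overrides)
            rc, rd = rollback(conv), rollback(day)
            row = res.draws.iloc[i]
            assert row["conventional_cost"] == pytest.approx(rc.cost, rel=1e-9)
            assert row["conventional_bed_days"] == pytest.approx(rc.bed_days, rel=1e-9)
            assert row["conventional_qaly"] == pytest.approx(rc.qaly, rel=1e-9)
            assert row["day_surgery_cost"] == pytest.approx(rd.cost, rel=1e-9)
            assert row["day_surgery_qaly"] == pytest.approx(rd.qaly, rel=1e-9)

    def test_zero_variance_psa_reproduces_rollback_exactly(self):
        params = generate_model(SyntheticModelConfig(seed=99, variance_fraction=0.0))
        conv, day = build_strategy_trees(params)
        res = run_psa(params, n=50, seed=1)
        rb = {"conventional": rollback(conv), "day_surgery": rollback(day)}
        for strat, bundle in rb.items():
            for comp in ("cost", "bed_days", "qaly"):
                col = res.draws[f"{strat}_{comp}"]
                np.testing.assert_allclose(col, getattr(bundle, comp), rtol=1e-12)

    def test_mean_payoffs_near_base_case(self, basecase, psa):
        # gamma/PERT/beta means match the base values except the PERT rows,
        # whose mean (min + 4*mode + max)/6 shifts slightly from the mode
        mean_cost = psa.draws["conventional_cost"].mean()
        assert mean_cost == pytest.approx(
            basecase.payoffs["conventional"].cost, rel=0.05
        )


class TestCEAC:
    def test_probability_at_zero_wtp_is_cost_saving_fraction(self, psa):
        frac = float((psa.raw.delta_cost < 0).mean())
        assert psa.prob_cost_effective(wtp=0.0) == pytest.approx(frac)

    def test_recomputation_from_stored_draws_is_stable(self, psa):
        grid = [0, 2000, 4000, 8000]
        a = ceac(psa.raw, grid)
        b = ceac(psa.raw, grid)
        pd.testing.assert_frame_equal(a, b)

    def test_ceac_matches_full_rerun_with_same_seed(self, table1):
        grid = np.linspace(0, 8000, 5)
        a = ceac(run_psa(table1, n=300, seed=21), grid)
        b = ceac(run_psa(table1, n=300, seed=21), grid)
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_in_wtp_for_bed_day_outcome(self, psa):
        # day surgery saves days in almost every draw; higher WTP can only
        # help when the effect difference is positive
        df = psa.ceac(Effect.BED_DAYS_SAVED)
        assert df["probability"].iloc[-1] >= df["probability"].iloc[0]

    def test_probabilities_within_unit_interval(self, psa):
        for effect in Effect:
            df = psa.ceac(effect)
            assert df["probability"].between(0, 1).all()

    def test_headline_threshold_on_default_grid(self, psa, model):
        df = psa.ceac(Effect.BED_DAYS_SAVED)
        assert model.settings.wtp_bed_day in df["wtp"].to_numpy()

    def test_single_draw_gives_degenerate_probabilities(self, table1):
        res = run_psa(table1, n=1, seed=2)
        p = prob_cost_effective(res, 4000.0)
        assert p in (0.0, 1.0)
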