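"""Parameter table: loading, validation, derived costs, normalization."""

import math

import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from cholecea import (
    ParameterValidationError,
    derive_day_surgery_costs,
    load_parameters,
    normalize_chance_probabilities,
)
from cholecea.parameters import CHANCE_NODES


class TestLoad:
    def test_fixture_has_23_variable_parameters(self, table1):
        assert table1.n_variable == 23

    def test_variable_breakdown_by_role(self, table1):
        by_role = {}
        for p in table1.variable:
            by_role[p.role] = by_role.get(p.role, 0) + 1
        assert by_role == {
            "probability": 5,
            "utility": 5,
            "bed_days": 7,
            "cost": 6,
        }

    def test_lap_no_conversion_row(self, table1):
        p = table1["p_lap"]
        assert (p.base, p.low, p.high, p.sd) == (0.97, 0.96, 0.98, 0.18)
        assert p.dist == "beta" and p.role == "probability"

    def test_mortality_utility_fixed_at_zero(self, table1):
        u = table1["u_mortality"]
        assert u.base == 0.0 and u.dist == "fixed" and not u.is_variable

    def test_dist_families_follow_roles(self, table1):
        for p in table1.variable:
            expected = {
                "probability": "beta",
                "utility": "beta",
                "bed_days": "pert",
                "cost": "gamma",
            }[p.role]
            assert p.dist == expected, p.name

    def test_round_trip_yaml(self, table1, tmp_path):
        out = tmp_path / "params.yaml"
        table1.write_yaml(out)
        again = load_parameters(out)
        assert again == table1

    def test_csv_dump_columns(self, table1, tmp_path):
        out = tmp_path / "params.csv"
        table1.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "name,strategy,role,base,low,high,sd,dist"

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_parameters(tmp_path / "nope.yaml")


class TestValidation:
    def _broken_copy(self, table1, tmp_path, mutate):
        doc = table1.to_dict()
        mutate(doc)
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    def test_probability_above_one_rejected(self, table1, tmp_path):
        def mutate(doc):
            row = next(p for p in doc["parameters"] if p["name"] == "p_lap_minor")
            row["base"] = 1.2
            row["high"] = 1.3

        path = self._broken_copy(table1, tmp_path, mutate)
        with pytest.raises(ParameterValidationError, match="p_lap_minor"):
            load_parameters(path)

    def test_base_outside_range_rejected(self, table1, tmp_path):
        def mutate(doc):
            row = next(p for p in doc["parameters"] if p["name"] == "cost_open")
            row["base"] = row["low"] - 1.0

        path = self._broken_copy(table1, tmp_path, mutate)
        with pytest.raises(ParameterValidationError, match="cost_open"):
            load_parameters(path)

    def test_missing_required_row_rejected(self, table1, tmp_path):
        def mutate(doc):
            doc["parameters"] = [
                p for p in doc["parameters"] if p["name"] != "u_open_major"
            ]

        path = self._broken_copy(table1, tmp_path, mutate)
        with pytest.raises(ParameterValidationError, match="open_major"):
            load_parameters(path)

    def test_missing_range_defaults_to_half_base(self, table1, tmp_path):
        def mutate(doc):
            row = next(
                p for p in doc["parameters"] if p["name"] == "cost_open_major"
            )
            del row["low"], row["high"]

        path = self._broken_copy(table1, tmp_path, mutate)
        p = load_parameters(path)["cost_open_major"]
        assert p.low == pytest.approx(0.5 * p.base)
        assert p.high == pytest.approx(1.5 * p.base)


class TestDerivedCosts:
    def test_same_day_cost_from_cost_ratio(self):
        same_day, monitoring = derive_day_surgery_costs(11300, 1.38, 0.5)
        assert same_day == 8188
        assert monitoring == 1556

    def test_zero_monitoring_fraction(self):
        _, monitoring = derive_day_surgery_costs(11300, 1.0001, 0.0)
        assert monitoring == 0

    def test_ratio_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            derive_day_surgery_costs(11300, 1.0, 0.5)

    def test_fixture_costs_match_derivation(self, table1):
        same_day, monitoring = derive_day_surgery_costs(
            table1["cost_lap_inpatient"].base
        )
        assert table1["cost_same_day_procedure"].base == same_day
        assert table1["cost_remote_monitoring"].base == monitoring

    @given(
        cost=st.floats(100.0, 1e6),
        ratio=st.floats(1.001, 10.0),
        fraction=st.floats(0.0, 1.0),
    )
    def test_monitoring_never_exceeds_full_saving(self, cost, ratio, fraction):
        # the monitoring budget is capped by the whole same-day cost saving;
        # both outputs round to the dollar, hence up to $1 of slack
        _, monitoring = derive_day_surgery_costs(cost, ratio, fraction)
        ceiling = (1.0 - 1.0 / ratio) * cost
        assert monitoring <= ceiling + 1.0


class TestNormalization:
    def test_open_branch_sum_099_scaled(self):
        out = normalize_chance_probabilities([0.88, 0.08, 0.01, 0.02])
        assert out == pytest.approx(
            [0.88 / 0.99, 0.08 / 0.99, 0.01 / 0.99, 0.02 / 0.99], abs=1e-15
        )

    def test_already_normalized_unchanged(self):
        assert normalize_chance_probabilities([0.94, 0.06]) == [0.94, 0.06]

    def test_symmetric_inputs(self):
        assert normalize_chance_probabilities([1.0, 1.0]) == [0.5, 0.5]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_chance_probabilities([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_chance_probabilities([0.5, -0.1])

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=6).filter(
            lambda xs: sum(xs) > 1e-9
        )
    )
    def test_sum_one_order_and_proportions_preserved(self, probs):
        out = normalize_chance_probabilities(probs)
        assert math.isclose(sum(out), 1.0, abs_tol=1e-12)
        total = sum(probs)
        for raw, scaled in zip(probs, out):
            assert math.isclose(scaled, raw / total, abs_tol=1e-12)

    def test_every_fixture_node_normalizes(self, table1):
        for node in CHANCE_NODES:
            vals = [p.base for p in table1.node_rows(node)]
            assert math.isclose(
                sum(normalize_chance_probabilities(vals)), 1.0, abs_tol=1e-12
            )
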