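import math

import pytest

from dndea.panel import (
    OECD_AVERAGE,
    PanelDataset,
    VariableSpec,
    WeightScheme,
    builtin_oecd7_fixture,
    change_over_horizon,
    descriptive_stats,
    load_panel,
    load_wide_panel,
    oecd7_schema,
    schema_from_yaml,
    schema_to_yaml,
    validate_panel,
    write_panel,
)


class TestVariableSpec:
    def test_link_needs_distinct_divisions(self):
        with pytest.raises(ValueError, match="distinct divisions"):
            VariableSpec("z", "a", "link", "a", "a", "as_output")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(role="link", link_source="a", link_target="b"),  # missing mode
            dict(role="carry_over"),  # missing class
            dict(role="input", carry_class="bad"),  # annotation on wrong role
            dict(role="output", link_mode="free"),
            dict(role="nonsense"),
        ],
    )
    def test_inconsistent_annotations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariableSpec("v", "a", **kwargs)


class TestWeightScheme:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WeightScheme({"t1": 0.6, "t2": 0.6}, {"k": 1.0})

    def test_nonnegative(self):
        with pytest.raises(ValueError, match="nonnegative"):
            WeightScheme({"t1": -0.5, "t2": 1.5}, {"k": 1.0})

    def test_uniform(self):
        w = WeightScheme.uniform(["a", "b", "c"], ["k1", "k2"])
        assert w.period_weights["a"] == pytest.approx(1 / 3)
        assert w.division_weights["k2"] == pytest.approx(1 / 2)


class TestLoadWrite:
    def test_round_trip_identity(self, tmp_path, fixture_panel):
        path = tmp_path / "panel.csv"
        write_panel(fixture_panel, path)
        loaded = load_panel(path, oecd7_schema(), reference_ids=[OECD_AVERAGE])
        assert loaded.values == fixture_panel.values
        assert set(loaded.dmu_ids) == set(fixture_panel.dmu_ids)
        assert loaded.periods == fixture_panel.periods

    def test_small_file_loads_each_row(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("dmu,period,variable,value\nA,t1,x,1.5\nA,t1,y,2\nA,t1,z,3\n")
        schema = [
            VariableSpec("x", "d", "input"),
            VariableSpec("y", "d", "output"),
            VariableSpec("z", "d", "output"),
        ]
        ds = load_panel(path, schema)
        assert len(ds.values) == 3
        assert ds.value("A", "x", "t1") == 1.5

    def test_missing_cell_flagged_by_validate_not_load(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("dmu,period,variable,value\nA,t1,x,1\nA,t1,y,2\nB,t1,x,1\n")
        schema = [VariableSpec("x", "d", "input"), VariableSpec("y", "d", "output")]
        ds = load_panel(path, schema)  # loads fine
        report = validate_panel(ds)
        assert not report.ok
        assert any("incomplete panel" in msg for _, _, msg in report.issues)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("dmu,period,value\nA,t1,1\n", "needs columns"),
            ("dmu,period,variable,value\nA,t1,unknown,1\n", "not in schema"),
            ("dmu,period,variable,value\nA,t1,x,abc\n", "non-numeric"),
            ("dmu,period,variable,value\nA,t1,x,-3\n", "negative"),
        ],
    )
    def test_malformed_files_rejected(self, tmp_path, content, match):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        schema = [VariableSpec("x", "d", "input")]
        with pytest.raises(ValueError, match=match):
            load_panel(path, schema)

    def test_wide_reader_agrees_with_long(self, tmp_path):
        wide = tmp_path / "wide.csv"
        wide.write_text("dmu,period,x,y\nA,t1,1,2\nB,t1,3,4\n")
        schema = [VariableSpec("x", "d", "input"), VariableSpec("y", "d", "output")]
        ds = load_wide_panel(wide, schema)
        assert ds.value("B", "y", "t1") == 4.0

    def test_schema_yaml_round_trip(self, tmp_path):
        schema = oecd7_schema()
        path = tmp_path / "schema.yaml"
        schema_to_yaml(schema, path)
        assert schema_from_yaml(path) == schema


class TestValidate:
    def test_fixture_is_valid(self, fixture_panel):
        assert validate_panel(fixture_panel).ok

    def test_zero_denominator_value_is_an_error(self, toy_panel):
        toy_panel.values[("A", "x", "t1")] = 0.0
        report = validate_panel(toy_panel)
        assert any("nonpositive denominator" in msg for _, _, msg in report.issues)

    def test_zero_output_is_allowed(self, toy_panel):
        toy_panel.values[("A", "y", "t1")] = 0.0
        assert validate_panel(toy_panel).ok

    def test_carryover_needs_two_periods(self):
        schema = [
            VariableSpec("x", "d", "input"),
            VariableSpec("c", "d", "carry_over", carry_class="bad"),
        ]
        ds = PanelDataset(
            ["A"], ["t1"], ["d"], schema,
            {("A", "x", "t1"): 1.0, ("A", "c", "t1"): 1.0},
        )
        report = validate_panel(ds)
        assert any("at least 2 periods" in msg for _, _, msg in report.issues)


class TestFixtureValues:
    @pytest.mark.parametrize(
        "dmu,variable,period,expected",
        [
            ("AUT", "alcohol", "2000", 13.20),
            ("JPN", "medical_technology", "2016", 107.17),
            ("MEX", "tobacco", "2016", 7.60),
            ("TUR", "infant_mortality", "2000", 28.40),
            ("GRC", "discharges", "2008", 20050.20),
        ],
    )
    def test_published_values(self, fixture_panel, dmu, variable, period, expected):
        assert fixture_panel.value(dmu, variable, period) == expected

    def test_average_row_is_not_a_dmu(self, fixture_panel):
        assert OECD_AVERAGE not in fixture_panel.dmu_ids
        assert OECD_AVERAGE in fixture_panel.reference_ids

    def test_twelve_model_variables(self, fixture_panel):
        assert len(fixture_panel.variables) == 12
        assert not any("expenditure" in v.name for v in fixture_panel.variables)


class TestChangeOverHorizon:
    def test_average_hale_gain(self, fixture_panel):
        assert change_over_horizon(fixture_panel, "hale", OECD_AVERAGE) == pytest.approx(3.12)

    def test_flat_series_is_zero(self, fixture_panel):
        assert change_over_horizon(fixture_panel, "tobacco", "AUT") == pytest.approx(0.0)

    def test_unknown_identifiers_raise(self, fixture_panel):
        with pytest.raises(KeyError):
            change_over_horizon(fixture_panel, "hale", "XXX")
        with pytest.raises(KeyError):
            change_over_horizon(fixture_panel, "nope", "AUT")


class TestDescriptiveStats:
    def test_min_mean_max_ordering(self, fixture_panel):
        stats = descriptive_stats(fixture_panel)
        assert (stats["min"] <= stats["mean"] + 1e-12).all()
        assert (stats["mean"] <= stats["max"] + 1e-12).all()

    def test_published_minimum(self, fixture_panel):
        stats = descriptive_stats(fixture_panel)
        row = stats[(stats.variable == "tobacco") & (stats.period == "2016")].iloc[0]
        assert row["min"] == 7.60  # Mexico

    def test_alcohol_mean_matches_hand_sum(self, fixture_panel):
        stats = descriptive_stats(fixture_panel)
        row = stats[(stats.variable == "alcohol") & (stats.period == "2000")].iloc[0]
        hand = (13.20 + 8.60 + 9.20 + 6.20 + 8.60 + 5.00 + 1.50) / 7
        assert row["mean"] == pytest.approx(hand)

    def test_single_dmu_collapses(self, toy_panel):
        ds = toy_panel.subset(["A"])
        stats = descriptive_stats(ds)
        assert (stats["mean"] == stats["min"]).all()
        assert (stats["mean"] == stats["max"]).all()
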