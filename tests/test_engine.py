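import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dndea.engine import (
    CRS,
    VRS,
    ModelOptions,
    build_problem,
    evaluate,
    evaluate_all,
    input_targets,
    score_decomposition,
    solve_overall,
)
from dndea.panel import PanelDataset, VariableSpec

from conftest import random_small_panel
from naive_dea import naive_overall_score

EFFICIENT_FIXTURE_COUNTRIES = ["AUT", "FIN", "CHL", "JPN", "MEX", "TUR"]


class TestStructure:
    def test_minimal_problem_counts(self):
        schema = [VariableSpec("x", "d", "input"), VariableSpec("y", "d", "output")]
        ds = PanelDataset(["A"], ["t1"], ["d"], schema, {("A", "x", "t1"): 2.0, ("A", "y", "t1"): 3.0})
        p = build_problem(ds, "A")
        assert (p.n_constraints, p.n_lambda, p.n_slacks) == (2, 1, 2)

    def test_fixture_lambda_count(self, fixture_panel):
        p = build_problem(fixture_panel, "AUT")
        assert p.n_lambda == 7 * 2 * 3

    def test_vrs_adds_one_convexity_row_per_cell(self, fixture_panel):
        crs = build_problem(fixture_panel, "AUT", options=ModelOptions(returns_to_scale=CRS))
        vrs = build_problem(fixture_panel, "AUT", options=ModelOptions(returns_to_scale=VRS))
        assert vrs.n_constraints - crs.n_constraints == 2 * 3

    def test_empty_reference_set_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="empty reference set"):
            build_problem(toy_panel, "A", [])

    def test_evaluated_dmu_must_be_referenced(self, toy_panel):
        with pytest.raises(ValueError, match="reference set"):
            build_problem(toy_panel, "A", ["B"])

    def test_single_period_carryover_rejected(self):
        schema = [
            VariableSpec("x", "d", "input"),
            VariableSpec("y", "d", "output"),
            VariableSpec("c", "d", "carry_over", carry_class="bad"),
        ]
        ds = PanelDataset(
            ["A"], ["t1"], ["d"], schema,
            {("A", "x", "t1"): 1.0, ("A", "y", "t1"): 1.0, ("A", "c", "t1"): 1.0},
        )
        with pytest.raises(ValueError, match="at least 2 periods"):
            build_problem(ds, "A")


class TestToySolutions:
    def test_self_evaluation_is_efficient(self, toy_panel):
        scores, result, _ = evaluate(toy_panel, "A", reference_dmus=["A"])
        assert scores.overall == pytest.approx(1.0)
        assert result.lambdas[("A", "d", "t1")] == pytest.approx(1.0)
        assert all(abs(s) < 1e-9 for s in result.slacks.values())

    def test_dominated_dmu_scores_half(self, toy_panel):
        scores, _, _ = evaluate(toy_panel, "B")
        assert scores.overall == pytest.approx(0.5)
        # single division & period: every family collapses to the same number
        assert scores.period["t1"] == pytest.approx(0.5)
        assert scores.divisional["d"] == pytest.approx(0.5)
        assert scores.period_divisional[("d", "t1")] == pytest.approx(0.5)

    def test_decomposition_requires_optimal_result(self, toy_panel):
        problem = build_problem(toy_panel, "B")
        from dndea.engine import SolveResult

        bad = SolveResult(status="infeasible", objective_value=float("nan"), lambdas={}, slacks={})
        with pytest.raises(ValueError, match="non-optimal"):
            score_decomposition(bad, problem)

    def test_input_targets_on_toy(self, toy_panel):
        _, result, problem = evaluate(toy_panel, "B")
        tgt = input_targets(result, problem)
        row = tgt[tgt.variable == "x"].iloc[0]
        assert row["target"] == pytest.approx(1.0)
        assert row["percent_reduction"] == pytest.approx(50.0)

    def test_efficient_dmu_has_zero_reductions(self, toy_panel):
        _, result, problem = evaluate(toy_panel, "A")
        tgt = input_targets(result, problem)
        assert (tgt["percent_reduction"].abs() < 1e-9).all()


class TestOracleEquivalence:
    """The engine must agree with a naive brute-force enumerator."""

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("rts", [CRS, VRS])
    def test_small_network_instances(self, seed, rts):
        ds = random_small_panel(seed)
        options = ModelOptions(returns_to_scale=rts)
        for dmu in ds.dmu_ids:
            scores, _, _ = evaluate(ds, dmu, options)
            expected = naive_overall_score(ds, dmu, rts=rts)
            assert scores.overall == pytest.approx(expected, abs=1e-7)

    @pytest.mark.parametrize("seed", range(4))
    def test_single_division_single_period(self, seed):
        ds = random_small_panel(seed, n_divisions=1, n_periods=1, with_link=False, with_carry=False)
        for dmu in ds.dmu_ids:
            scores, _, _ = evaluate(ds, dmu)
            assert scores.overall == pytest.approx(naive_overall_score(ds, dmu), abs=1e-7)


class TestProperties:
    def test_scores_within_unit_interval(self, fixture_panel):
        scores, _ = evaluate_all(fixture_panel)
        for s in scores.values():
            assert 0 < s.overall <= 1 + 1e-9
            for v in s.period_divisional.values():
                assert 0 < v <= 1 + 1e-9

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        factor=st.floats(min_value=1e-2, max_value=1e3, allow_nan=False),
        variable=st.sampled_from(["alcohol", "hale", "immunisation", "infant_mortality", "discharges"]),
    )
    def test_units_invariance(self, fixture_panel, factor, variable):
        """Rescaling any variable by a positive constant leaves scores unchanged."""
        base, _, _ = evaluate(fixture_panel, "GRC")
        rescaled = fixture_panel.rescaled(variable, factor)
        scores, _, _ = evaluate(rescaled, "GRC")
        assert scores.overall == pytest.approx(base.overall, abs=1e-6)

    def test_vrs_dominates_crs(self, fixture_panel):
        crs, _ = evaluate_all(fixture_panel, ModelOptions(returns_to_scale=CRS))
        vrs, _ = evaluate_all(fixture_panel, ModelOptions(returns_to_scale=VRS))
        for dmu in fixture_panel.dmu_ids:
            assert vrs[dmu].overall >= crs[dmu].overall - 1e-7

    def test_reference_subset_monotonicity(self, fixture_panel):
        full, _, _ = evaluate(fixture_panel, "GRC")
        for drop in ["AUT", "JPN", "MEX"]:
            refs = [d for d in fixture_panel.dmu_ids if d != drop]
            sub, _, _ = evaluate(fixture_panel, "GRC", reference_dmus=refs)
            assert sub.overall >= full.overall - 1e-9

    def test_aggregation_identities(self, fixture_panel):
        scores, _ = evaluate_all(fixture_panel)
        wp, wd = 1 / 3, 1 / 2
        for s in scores.values():
            overall = sum(wp * wd * v for v in s.period_divisional.values())
            assert s.overall == pytest.approx(overall, abs=1e-9)
            for t in fixture_panel.periods:
                assert s.period[t] == pytest.approx(
                    sum(wd * s.period_divisional[(k, t)] for k in fixture_panel.divisions), abs=1e-9
                )
            for k in fixture_panel.divisions:
                assert s.divisional[k] == pytest.approx(
                    sum(wp * s.period_divisional[(k, t)] for t in fixture_panel.periods), abs=1e-9
                )

    def test_tiebreak_pass_preserves_score(self, fixture_panel):
        plain, _, _ = evaluate(fixture_panel, "GRC")
        tie, _, _ = evaluate(
            fixture_panel, "GRC", ModelOptions(slack_tiebreak="max_total_slack_then_report")
        )
        assert tie.overall == pytest.approx(plain.overall, abs=1e-7)


class TestEvaluateAll:
    def test_fixture_efficient_countries(self, fixture_panel):
        scores, failures = evaluate_all(fixture_panel)
        assert failures == {}
        for dmu in EFFICIENT_FIXTURE_COUNTRIES:
            for t in fixture_panel.periods:
                assert scores[dmu].period[t] == pytest.approx(1.0, abs=1e-7)

    def test_link_as_input_mode_also_solves(self):
        from dndea.panel import builtin_oecd7_fixture

        ds = builtin_oecd7_fixture(link_mode="as_input")
        scores, failures = evaluate_all(ds)
        assert failures == {}
        for s in scores.values():
            assert 0 < s.overall <= 1 + 1e-9

    def test_invalid_panel_rejected(self, toy_panel):
        toy_panel.values[("A", "x", "t1")] = 0.0
        with pytest.raises(ValueError, match="validation"):
            evaluate_all(toy_panel)
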