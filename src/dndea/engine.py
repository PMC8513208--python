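"""Input-oriented dynamic network slacks-based DEA engine.

The model evaluates each decision-making unit (DMU) against an empirical
frontier spanned by intensity-weighted combinations of all reference DMUs,
separately per division and period, with three kinds of coupling:

* **links** tie the divisions together within a period (an intermediate
  product emitted by one division and consumed by the other);
* **carry-overs** tie consecutive periods of one division together (a stock
  such as infant mortality whose level observed in one period conditions
  the next);
* optional **continuity constraints** force the emitting- and
  receiving-side (resp. earlier- and later-period) frontier values of each
  link (carry-over) to agree.

The efficiency score is one minus a weighted average of normalised slacks:
for division ``k`` in period ``t`` the inefficiency term is

    (1 / (m_k + linkin_k + nbad_k)) *
        ( sum_i s_i^- / x_i  +  sum_l s_l^in / z_l  +  sum_c s_c^bad / z_c )

i.e. input excesses, as-input link excesses and bad-carry-over excesses,
each relative to the observed value.  Period weights ``W^t`` and division
weights ``w^k`` (exogenous, summing to one each) aggregate the terms into
the overall score; the same optimal slacks also yield period, divisional
and period-divisional scores.  The program is linear and is solved with
HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import PanelDataset, VariableSpec, WeightScheme, validate_panel

__all__ = [
    "ModelOptions",
    "EnvelopmentProblem",
    "SolveResult",
    "EfficiencyScores",
    "build_problem",
    "solve_overall",
    "score_decomposition",
    "input_targets",
    "evaluate",
    "evaluate_all",
    "scores_table",
]

CRS = "CRS"
VRS = "VRS"


@dataclass(frozen=True)
class ModelOptions:
    """Solver-facing configuration of the envelopment model.

    Parameters
    ----------
    returns_to_scale : {"CRS", "VRS"}
        Constant returns drop the convexity constraint; variable returns add
        one ``sum(lambda) = 1`` constraint per division and period.
    link_continuity : bool
        Tie the emitting- and receiving-side frontier value of every link.
    carryover_timing : {"start_of_interval", "end_of_interval"}
        Which period's observation forms the (t, t+1) carry-over value.
    carryover_continuity : bool
        Tie the frontier carry-over value between consecutive periods.
    terminal_carryover : {"ignored", "last_period_bad_term"}
        Whether the final period's otherwise-unused carry-over observation
        adds a bad-excess term to the final period's score.
    weights : WeightScheme or None
        Exogenous period/division weights; uniform when None.
    solver_tolerance : float
        Numerical slack allowed on reported nonnegativity/residuals,
        in (0, 1e-4].
    slack_tiebreak : {"none", "max_total_slack_then_report"}
        Optimal slack allocations may be non-unique; the default reports the
        solver's optimum, the alternative runs a diagnostic secondary pass
        maximising total slack at the optimal score.
    """

    returns_to_scale: str = CRS
    link_continuity: bool = True
    carryover_timing: str = "start_of_interval"
    carryover_continuity: bool = True
    terminal_carryover: str = "ignored"
    weights: WeightScheme | None = None
    solver_tolerance: float = 1e-7
    slack_tiebreak: str = "none"

    def __post_init__(self) -> None:
        if self.returns_to_scale not in (CRS, VRS):
            raise ValueError("returns_to_scale must be CRS or VRS")
        if self.carryover_timing not in ("start_of_interval", "end_of_interval"):
            raise ValueError("bad carryover_timing")
        if self.terminal_carryover not in ("ignored", "last_period_bad_term"):
            raise ValueError("bad terminal_carryover")
        if not (0 < self.solver_tolerance <= 1e-4):
            raise ValueError("solver_tolerance must lie in (0, 1e-4]")
        if self.slack_tiebreak not in ("none", "max_total_slack_then_report"):
            raise ValueError("bad slack_tiebreak")

    def resolved_weights(self, ds: PanelDataset) -> WeightScheme:
        if self.weights is not None:
            return self.weights
        return WeightScheme.uniform(ds.periods, ds.divisions)


@dataclass
class _Slack:
    """One slack column: identity, sign, and objective bookkeeping."""

    sid: str
    division: str
    period: str
    free: bool = False
    # rho_coeff > 0 marks an objective slack: its contribution to the
    # (division, period) inefficiency term is rho_coeff * slack value.
    rho_coeff: float = 0.0
    observed: float | None = None  # denominator value for objective slacks
    variable: str | None = None


@dataclass
class EnvelopmentProblem:
    """Assembled LP for one evaluated DMU (equality form A x = b, x in bounds)."""

    evaluated_dmu: str
    reference_dmus: list[str]
    divisions: list[str]
    periods: list[str]
    options: ModelOptions
    weights: WeightScheme
    lambda_index: dict[tuple[str, str, str], int]
    slacks: list[_Slack]
    a_rows: list[np.ndarray]
    b: list[float]
    denominators: dict[str, int]

    @property
    def n_lambda(self) -> int:
        return len(self.lambda_index)

    @property
    def n_slacks(self) -> int:
        return len(self.slacks)

    @property
    def n_vars(self) -> int:
        return self.n_lambda + self.n_slacks

    @property
    def n_constraints(self) -> int:
        return len(self.a_rows)

    def slack_col(self, i: int) -> int:
        return self.n_lambda + i

    def objective_vector(self) -> np.ndarray:
        """Minimising c @ x and adding 1 gives the overall efficiency score."""
        c = np.zeros(self.n_vars)
        for i, s in enumerate(self.slacks):
            if s.rho_coeff > 0:
                w = self.weights.period_weights[s.period] * self.weights.division_weights[s.division]
                c[self.slack_col(i)] = -w * s.rho_coeff
        return c


@dataclass
class SolveResult:
    """Optimal point of the envelopment program."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    lambdas: dict[tuple[str, str, str], float]
    slacks: dict[str, float]
    message: str = ""


@dataclass
class EfficiencyScores:
    """The four score families derived from one optimal slack allocation."""

    overall: float
    period: dict[str, float]
    divisional: dict[str, float]
    period_divisional: dict[tuple[str, str], float]


def _division_io(ds: PanelDataset, division: str) -> tuple[list[VariableSpec], list[VariableSpec]]:
    inputs = ds.variables_for(division, "input")
    outputs = ds.variables_for(division, "output")
    return inputs, outputs


def _denominator(ds: PanelDataset, division: str, options: ModelOptions) -> int:
    """m_k + linkin_k + nbad_k for one division.

    ``linkin_k`` counts as-input links received by the division (the excess
    of an as-input link is charged to the division that consumes it) and
    ``nbad_k`` the division's bad carry-overs.
    """
    m = len(ds.variables_for(division, "input"))
    linkin = sum(
        1 for v in ds.variables if v.role == "link" and v.link_mode == "as_input" and v.link_target == division
    )
    nbad = sum(
        1
        for v in ds.variables
        if v.role == "carry_over" and v.carry_class == "bad" and v.division == division
    )
    return m + linkin + nbad


def build_problem(
    ds: PanelDataset,
    evaluated_dmu: str,
    reference_dmus: Sequence[str] | None = None,
    options: ModelOptions = ModelOptions(),
) -> EnvelopmentProblem:
    """Assemble the envelopment LP for one evaluated DMU.

    Constraint blocks, per division ``k`` and period ``t``:
    input ``x_o = X lambda + s-``; output ``y_o = Y lambda - s+``; link
    value constraints according to the link's mode, with the cross-division
    continuity tie when enabled; carry-over value constraints according to
    class, with inter-period continuity when enabled; and, under VRS, the
    convexity constraint ``sum(lambda) = 1``.
    """
    if reference_dmus is None:
        reference_dmus = list(ds.dmu_ids)
    reference_dmus = list(reference_dmus)
    if not reference_dmus:
        raise ValueError("empty reference set")
    if evaluated_dmu not in reference_dmus:
        raise ValueError("evaluated DMU must belong to the reference set")
    has_carry = any(v.role == "carry_over" for v in ds.variables)
    if has_carry and len(ds.periods) < 2:
        raise ValueError("carry-overs require at least 2 periods")

    weights = options.resolved_weights(ds)
    denominators = {k: _denominator(ds, k, options) for k in ds.divisions}

    lam_index: dict[tuple[str, str, str], int] = {}
    for k in ds.divisions:
        for t in ds.periods:
            for j in reference_dmus:
                lam_index[(j, k, t)] = len(lam_index)
    slacks: list[_Slack] = []
    rows: list[dict[int, float]] = []
    b: list[float] = []
    o = evaluated_dmu

    def new_row() -> dict[int, float]:
        rows.append({})
        b.append(0.0)
        return rows[-1]

    def add_slack(s: _Slack) -> int:
        slacks.append(s)
        return len(slacks) - 1

    def lam_cols(row: dict[int, float], division: str, period: str, values: Mapping[str, float], sign: float = 1.0) -> None:
        for j in reference_dmus:
            row[lam_index[(j, division, period)]] = row.get(lam_index[(j, division, period)], 0.0) + sign * values[j]

    n_lam = len(lam_index)

    # inputs and outputs
    for k in ds.divisions:
        inputs, outputs = _division_io(ds, k)
        den = denominators[k]
        for t in ds.periods:
            for v in inputs:
                obs = ds.value(o, v.name, t)
                row = new_row()
                lam_cols(row, k, t, {j: ds.value(j, v.name, t) for j in reference_dmus})
                idx = add_slack(
                    _Slack(
                        sid=f"in:{v.name}:{t}",
                        division=k,
                        period=t,
                        rho_coeff=(1.0 / (den * obs)) if den else 0.0,
                        observed=obs,
                        variable=v.name,
                    )
                )
                row[n_lam + idx] = 1.0
                b[-1] = obs
            for v in outputs:
                obs = ds.value(o, v.name, t)
                row = new_row()
                lam_cols(row, k, t, {j: ds.value(j, v.name, t) for j in reference_dmus})
                idx = add_slack(_Slack(sid=f"out:{v.name}:{t}", division=k, period=t, variable=v.name))
                row[n_lam + idx] = -1.0
                b[-1] = obs

    # links
    for v in ds.variables:
        if v.role != "link":
            continue
        k_from, k_to = v.link_source, v.link_target
        for t in ds.periods:
            obs = ds.value(o, v.name, t)
            zvals = {j: ds.value(j, v.name, t) for j in reference_dmus}
            if v.link_mode == "as_input":
                row = new_row()
                lam_cols(row, k_to, t, zvals)
                den = denominators[k_to]
                idx = add_slack(
                    _Slack(
                        sid=f"linkin:{v.name}:{t}",
                        division=k_to,
                        period=t,
                        rho_coeff=(1.0 / (den * obs)) if den else 0.0,
                        observed=obs,
                        variable=v.name,
                    )
                )
                row[n_lam + idx] = 1.0
                b[-1] = obs
            elif v.link_mode == "as_output":
                row = new_row()
                lam_cols(row, k_from, t, zvals)
                idx = add_slack(_Slack(sid=f"linkout:{v.name}:{t}", division=k_from, period=t, variable=v.name))
                row[n_lam + idx] = -1.0
                b[-1] = obs
            elif v.link_mode == "free":
                row = new_row()
                lam_cols(row, k_to, t, zvals)
                idx = add_slack(
                    _Slack(sid=f"linkfree:{v.name}:{t}", division=k_to, period=t, free=True, variable=v.name)
                )
                row[n_lam + idx] = 1.0
                b[-1] = obs
            else:  # fixed
                row = new_row()
                lam_cols(row, k_to, t, zvals)
                b[-1] = obs
            if options.link_continuity:
                row = new_row()
                lam_cols(row, k_from, t, zvals)
                lam_cols(row, k_to, t, zvals, sign=-1.0)
                b[-1] = 0.0

    # carry-overs
    last = ds.periods[-1]
    for v in ds.variables:
        if v.role != "carry_over":
            continue
        k = v.division
        den = denominators[k]
        for p in range(len(ds.periods) - 1):
            t0, t1 = ds.periods[p], ds.periods[p + 1]
            t_obs = t0 if options.carryover_timing == "start_of_interval" else t1
            obs = ds.value(o, v.name, t_obs)
            zvals = {j: ds.value(j, v.name, t_obs) for j in reference_dmus}
            row = new_row()
            lam_cols(row, k, t0, zvals)
            b[-1] = obs
            if v.carry_class == "bad":
                idx = add_slack(
                    _Slack(
                        sid=f"carrybad:{v.name}:{t0}",
                        division=k,
                        period=t0,
                        rho_coeff=(1.0 / (den * obs)) if den and obs > 0 else 0.0,
                        observed=obs,
                        variable=v.name,
                    )
                )
                row[n_lam + idx] = 1.0
            elif v.carry_class == "good":
                idx = add_slack(_Slack(sid=f"carrygood:{v.name}:{t0}", division=k, period=t0, variable=v.name))
                row[n_lam + idx] = -1.0
            elif v.carry_class == "free":
                idx = add_slack(
                    _Slack(sid=f"carryfree:{v.name}:{t0}", division=k, period=t0, free=True, variable=v.name)
                )
                row[n_lam + idx] = 1.0
            # fixed: equality, no slack
            if options.carryover_continuity:
                row = new_row()
                lam_cols(row, k, t0, zvals)
                lam_cols(row, k, t1, zvals, sign=-1.0)
                b[-1] = 0.0
        if options.terminal_carryover == "last_period_bad_term" and v.carry_class == "bad":
            obs = ds.value(o, v.name, last)
            zvals = {j: ds.value(j, v.name, last) for j in reference_dmus}
            row = new_row()
            lam_cols(row, k, last, zvals)
            idx = add_slack(
                _Slack(
                    sid=f"carrybad:{v.name}:{last}",
                    division=k,
                    period=last,
                    rho_coeff=(1.0 / (den * obs)) if den and obs > 0 else 0.0,
                    observed=obs,
                    variable=v.name,
                )
            )
            row[n_lam + idx] = 1.0
            b[-1] = obs

    # convexity under VRS
    if options.returns_to_scale == VRS:
        for k in ds.divisions:
            for t in ds.periods:
                row = new_row()
                lam_cols(row, k, t, {j: 1.0 for j in reference_dmus})
                b[-1] = 1.0

    n_vars = n_lam + len(slacks)
    a_rows = []
    for row in rows:
        arr = np.zeros(n_vars)
        for col, val in row.items():
            arr[col] = val
        a_rows.append(arr)

    return EnvelopmentProblem(
        evaluated_dmu=evaluated_dmu,
        reference_dmus=reference_dmus,
        divisions=list(ds.divisions),
        periods=list(ds.periods),
        options=options,
        weights=weights,
        lambda_index=lam_index,
        slacks=slacks,
        a_rows=a_rows,
        b=b,
        denominators=denominators,
    )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_overall(problem: EnvelopmentProblem) -> SolveResult:
    """Minimise the overall-efficiency objective over the assembled LP."""
    c = problem.objective_vector()
    A = np.vstack(problem.a_rows) if problem.a_rows else np.zeros((0, problem.n_vars))
    b = np.asarray(problem.b)
    bounds = [(0.0, None)] * problem.n_lambda + [
        ((None, None) if s.free else (0.0, None)) for s in problem.slacks
    ]
    res = linprog(c, A_eq=A, b_eq=b, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return SolveResult(status=status, objective_value=math.nan, lambdas={}, slacks={}, message=res.message)
    x = res.x
    if problem.options.slack_tiebreak == "max_total_slack_then_report":
        x = _tiebreak_max_slack(problem, A, b, bounds, c, res.fun)
    lambdas = {key: float(x[col]) for key, col in problem.lambda_index.items()}
    slacks = {s.sid: float(x[problem.slack_col(i)]) for i, s in enumerate(problem.slacks)}
    return SolveResult(status="optimal", objective_value=float(1.0 + res.fun), lambdas=lambdas, slacks=slacks)


def _tiebreak_max_slack(problem, A, b, bounds, c, opt_val):
    """Diagnostic secondary pass: among optimal points, maximise total slack."""
    A2 = np.vstack([A, c])
    b2 = np.append(b, opt_val)
    c2 = np.zeros(problem.n_vars)
    for i, s in enumerate(problem.slacks):
        if not s.free:
            c2[problem.slack_col(i)] = -1.0
    res2 = linprog(c2, A_eq=A2, b_eq=b2, bounds=bounds, method="highs")
    if res2.status == 0:
        return res2.x
    return linprog(c, A_eq=A, b_eq=b, bounds=bounds, method="highs").x


def score_decomposition(result: SolveResult, problem: EnvelopmentProblem) -> EfficiencyScores:
    """Derive all four score families from one optimal slack allocation.

    The period-divisional score rho(k, t) is one minus that cell's
    normalised-slack term; period, divisional and overall scores are its
    division-, period- and double-weighted aggregates, so the aggregation
    identities hold by construction.
    """
    if result.status != "optimal":
        raise ValueError(f"cannot decompose a non-optimal result (status={result.status})")
    ineff: dict[tuple[str, str], float] = {
        (k, t): 0.0 for k in problem.divisions for t in problem.periods
    }
    for s in problem.slacks:
        if s.rho_coeff > 0:
            ineff[(s.division, s.period)] += s.rho_coeff * result.slacks[s.sid]
    rho = {cell: 1.0 - v for cell, v in ineff.items()}
    wp = problem.weights.period_weights
    wd = problem.weights.division_weights
    period = {t: sum(wd[k] * rho[(k, t)] for k in problem.divisions) for t in problem.periods}
    divisional = {k: sum(wp[t] * rho[(k, t)] for t in problem.periods) for k in problem.divisions}
    overall = sum(wp[t] * wd[k] * rho[(k, t)] for k in problem.divisions for t in problem.periods)
    return EfficiencyScores(overall=overall, period=period, divisional=divisional, period_divisional=rho)


def input_targets(result: SolveResult, problem: EnvelopmentProblem) -> pd.DataFrame:
    """Projection targets for every slack that enters the objective.

    ``target = observed - slack``; ``percent_reduction = slack/observed*100``.
    Covers inputs, as-input links and bad carry-overs (the excess-type
    quantities an inefficient DMU should shed).
    """
    if result.status != "optimal":
        raise ValueError("input_targets needs an optimal result")
    records = []
    for s in problem.slacks:
        if s.rho_coeff <= 0 or s.observed is None:
            continue
        slack = result.slacks[s.sid]
        records.append(
            {
                "variable": s.variable,
                "period": s.period,
                "division": s.division,
                "observed": s.observed,
                "target": max(s.observed - slack, 0.0),
                "percent_reduction": slack / s.observed * 100.0,
            }
        )
    return pd.DataFrame(records, columns=["variable", "period", "division", "observed", "target", "percent_reduction"])


def evaluate(
    ds: PanelDataset,
    dmu: str,
    options: ModelOptions = ModelOptions(),
    reference_dmus: Sequence[str] | None = None,
) -> tuple[EfficiencyScores, SolveResult, EnvelopmentProblem]:
    """Build, solve and decompose the program for one DMU."""
    problem = build_problem(ds, dmu, reference_dmus, options)
    result = solve_overall(problem)
    if result.status != "optimal":
        raise RuntimeError(f"solve failed for {dmu}: {result.status} {result.message}")
    return score_decomposition(result, problem), result, problem


def evaluate_all(
    ds: PanelDataset, options: ModelOptions = ModelOptions()
) -> tuple[dict[str, EfficiencyScores], dict[str, str]]:
    """Score every DMU against the full DMU set.

    Returns per-DMU scores plus a failure map (dmu -> diagnostic) for any
    DMU whose program did not solve; the run continues past failures.
    """
    report = validate_panel(ds)
    if not report.ok:
        raise ValueError(f"panel failed validation: {report.errors()[:5]}")
    scores: dict[str, EfficiencyScores] = {}
    failures: dict[str, str] = {}
    for dmu in ds.dmu_ids:
        try:
            scores[dmu], _, _ = evaluate(ds, dmu, options)
        except (RuntimeError, ValueError) as exc:
            failures[dmu] = str(exc)
    return scores, failures


def scores_table(scores: Mapping[str, EfficiencyScores]) -> pd.DataFrame:
    """Tidy score table with one row per (dmu, scope)."""
    rows = []
    for dmu, s in scores.items():
        rows.append({"dmu": dmu, "scope": "overall", "score": s.overall})
        for t, v in s.period.items():
            rows.append({"dmu": dmu, "scope": f"period:{t}", "score": v})
        for k, v in s.divisional.items():
            rows.append({"dmu": dmu, "scope": f"division:{k}", "score": v})
        for (k, t), v in s.period_divisional.items():
            rows.append({"dmu": dmu, "scope": f"cell:{k}:{t}", "score": v})
    return pd.DataFrame(rows, columns=["dmu", "scope", "score"])
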