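"""Malmquist productivity index per division with catch-up / frontier-shift
decomposition.

For one DMU, one division and two periods t0 < t1 the index compares the
unit's distance to the best-practice frontier of each period:

* catch-up  ``CU = E^{t1}(t1) / E^{t0}(t0)`` — movement of the unit
  relative to the contemporaneous frontier (management effect);
* frontier shift ``FS = sqrt( [E^{t0}(t1)/E^{t1}(t1)] *
  [E^{t0}(t0)/E^{t1}(t0)] )`` — movement of the frontier itself
  (technology effect);
* ``MI = CU * FS``.

``E^{s}(t)`` is the slacks-based efficiency of the unit's period-t division
observation against the frontier spanned by all units' period-s
observations, using the division's own inputs and outputs (links and
carry-overs are excluded by default, which keeps each division's index
self-contained).  Mixed-period programs can be infeasible (the old frontier
may be unable to reach a later, better observation); such components are
flagged and dropped from geometric means with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .engine import CRS, VRS, ModelOptions
from .panel import PanelDataset

__all__ = [
    "MalmquistResult",
    "cross_period_efficiency",
    "malmquist",
    "malmquist_table",
    "overall_mi",
    "classify_profiles",
    "geometric_mean",
]


@dataclass
class MalmquistResult:
    """Per-DMU Malmquist decomposition across divisions."""

    dmu: str
    per_division: dict[str, tuple[float, float, float]]  # division -> (MI, CU, FS)
    overall_mi: float

    def statuses(self) -> tuple[str, str, str]:
        """(EC_status, TC_status, productivity_status) at 2-decimal rounding."""
        mi = round(self.overall_mi, 2)
        cu = round(geometric_mean([v[1] for v in self.per_division.values()]), 2)
        fs = round(geometric_mean([v[2] for v in self.per_division.values()]), 2)

        def status(x: float) -> str:
            return "progress" if x > 1 else ("regress" if x < 1 else "none")

        return status(cu), status(fs), status(mi)


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log(values))); every value must be strictly positive."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _division_variables(
    ds: PanelDataset,
    division: str,
    include_links: bool,
    include_carryovers: bool,
) -> tuple[list[str], list[str]]:
    """(input-like, output-like) variable names for a standalone division model."""
    inputs = [v.name for v in ds.variables_for(division, "input")]
    outputs = [v.name for v in ds.variables_for(division, "output")]
    if include_links:
        for v in ds.variables:
            if v.role != "link":
                continue
            if v.link_mode == "as_input" and v.link_target == division:
                inputs.append(v.name)
            elif v.link_mode == "as_output" and v.link_source == division:
                outputs.append(v.name)
    if include_carryovers:
        for v in ds.variables:
            if v.role == "carry_over" and v.division == division:
                if v.carry_class == "bad":
                    inputs.append(v.name)
                elif v.carry_class == "good":
                    outputs.append(v.name)
    return inputs, outputs


def cross_period_efficiency(
    ds: PanelDataset,
    dmu: str,
    data_period: str,
    frontier_period: str,
    division: str,
    options: ModelOptions = ModelOptions(),
    include_links: bool = False,
    include_carryovers: bool = False,
) -> float | None:
    """Slacks-based efficiency of a period's observation against another
    period's frontier, for one division.

    Returns ``None`` when the mixed-period program is infeasible.  With
    ``data_period == frontier_period`` this is the ordinary within-period
    divisional score of the standalone (single-division, single-period)
    model.
    """
    for t in (data_period, frontier_period):
        if t not in ds.periods:
            raise KeyError(f"unknown period {t!r}")
    if division not in ds.divisions:
        raise KeyError(f"unknown division {division!r}")
    in_names, out_names = _division_variables(ds, division, include_links, include_carryovers)
    if not in_names:
        raise ValueError(f"division {division!r} has no input-like variables")
    n = len(ds.dmu_ids)
    m, r = len(in_names), len(out_names)
    x_o = np.array([ds.value(dmu, v, data_period) for v in in_names])
    y_o = np.array([ds.value(dmu, v, data_period) for v in out_names])
    X = np.array([[ds.value(j, v, frontier_period) for j in ds.dmu_ids] for v in in_names])
    Y = np.array([[ds.value(j, v, frontier_period) for j in ds.dmu_ids] for v in out_names])

    # variables: lambda (n), s- (m), s+ (r); min 1 - (1/m) sum s-/x_o
    n_vars = n + m + r
    c = np.zeros(n_vars)
    c[n : n + m] = -1.0 / (m * x_o)
    A = np.zeros((m + r, n_vars))
    b = np.concatenate([x_o, y_o])
    A[:m, :n] = X
    A[:m, n : n + m] = np.eye(m)
    A[m:, :n] = Y
    A[m:, n + m :] = -np.eye(r)
    rows = [A]
    if options.returns_to_scale == VRS:
        conv = np.zeros((1, n_vars))
        conv[0, :n] = 1.0
        rows.append(conv)
        b = np.append(b, 1.0)
    res = linprog(c, A_eq=np.vstack(rows), b_eq=b, bounds=[(0, None)] * n_vars, method="highs")
    if res.status == 2:  # infeasible
        return None
    if res.status != 0:
        raise RuntimeError(f"mixed-period solve failed: {res.message}")
    return float(1.0 + res.fun)


def malmquist(
    ds: PanelDataset,
    dmu: str,
    t0: str,
    t1: str,
    division: str,
    options: ModelOptions = ModelOptions(),
    include_links: bool = False,
    include_carryovers: bool = False,
) -> tuple[float, float, float]:
    """(MI, CU, FS) for one DMU and division between periods t0 < t1.

    Infeasible mixed-period components are dropped from the frontier-shift
    geometric mean with a warning; if both are infeasible FS is NaN.
    """
    if ds.periods.index(t0) >= ds.periods.index(t1):
        raise ValueError("t0 must precede t1")
    kw = dict(options=options, include_links=include_links, include_carryovers=include_carryovers)
    e00 = cross_period_efficiency(ds, dmu, t0, t0, division, **kw)
    e11 = cross_period_efficiency(ds, dmu, t1, t1, division, **kw)
    e01 = cross_period_efficiency(ds, dmu, t1, t0, division, **kw)  # t1 data, t0 frontier
    e10 = cross_period_efficiency(ds, dmu, t0, t1, division, **kw)  # t0 data, t1 frontier
    if e00 is None or e11 is None or e00 <= 0 or e11 <= 0:
        raise ValueError(f"within-period score undefined for {dmu}/{division}")
    cu = e11 / e00
    ratios = []
    if e01 is not None and e01 > 0:
        ratios.append(e01 / e11)
    else:
        warnings.warn(f"mixed-period program infeasible for {dmu}/{division} ({t1} data, {t0} frontier)")
    if e10 is not None and e10 > 0:
        ratios.append(e00 / e10)
    else:
        warnings.warn(f"mixed-period program infeasible for {dmu}/{division} ({t0} data, {t1} frontier)")
    fs = geometric_mean(ratios) if ratios else math.nan
    return cu * fs, cu, fs


def overall_mi(divisional: Mapping[str, float]) -> float:
    """Aggregate divisional indices by geometric mean."""
    return geometric_mean(list(divisional.values()))


def malmquist_table(
    ds: PanelDataset,
    t0: str,
    t1: str,
    options: ModelOptions = ModelOptions(),
    include_links: bool = False,
    include_carryovers: bool = False,
) -> tuple[pd.DataFrame, list[MalmquistResult]]:
    """Per-DMU Malmquist decomposition for every division plus the overall
    geometric-mean aggregate, in long form (one row per dmu x scope)."""
    results = []
    rows = []
    for dmu in ds.dmu_ids:
        per_div = {}
        for k in ds.divisions:
            mi, cu, fs = malmquist(ds, dmu, t0, t1, k, options, include_links, include_carryovers)
            per_div[k] = (mi, cu, fs)
            rows.append({"dmu": dmu, "division": k, "MI": mi, "CU": cu, "FS": fs})
        omi = overall_mi({k: v[0] for k, v in per_div.items()})
        res = MalmquistResult(dmu=dmu, per_division=per_div, overall_mi=omi)
        results.append(res)
        ec, tc, prod = res.statuses()
        rows.append(
            {
                "dmu": dmu,
                "division": "overall",
                "MI": omi,
                "CU": geometric_mean([v[1] for v in per_div.values()]),
                "FS": geometric_mean([v[2] for v in per_div.values()]),
                "EC_status": ec,
                "TC_status": tc,
                "productivity_status": prod,
            }
        )
    return pd.DataFrame(rows), results


def classify_profiles(results: Sequence[MalmquistResult]) -> pd.DataFrame:
    """Progress/regress profile per DMU.

    Efficiency change (EC) is judged on the catch-up component, technical
    change (TC) on the frontier shift, productivity on the overall index;
    equality with one is decided after rounding to 2 decimals.
    """
    rows = []
    for res in results:
        ec, tc, prod = res.statuses()
        rows.append(
            {
                "dmu": res.dmu,
                "EC_status": ec,
                "TC_status": tc,
                "productivity_status": prod,
                "MI": res.overall_mi,
            }
        )
    return pd.DataFrame(rows, columns=["dmu", "EC_status", "TC_status", "productivity_status", "MI"])
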