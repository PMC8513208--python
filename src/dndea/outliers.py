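"""Box-plot (Tukey) outlier screening for DEA panels.

DEA frontiers are spanned by extreme observations, so a single outlying
indicator value can depress every other unit's score.  The screen flags,
per (variable, period), values outside the Tukey fences
``[Q1 - k*IQR, Q3 + k*IQR]`` (linear-interpolation quartiles, default
k = 1.5), removes any DMU with at least one flag anywhere, and compares
scores before and after the reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = ["OutlierReport", "tukey_flags", "reduce_dataset", "compare_runs"]


@dataclass
class OutlierReport:
    """Flags per (dmu, variable, period, value, fence_low, fence_high)."""

    flags: list[tuple[str, str, str, float, float, float]]
    removed_dmus: set[str]
    kept_dmus: set[str]
    k: float = 1.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flags,
            columns=["dmu", "variable", "period", "value", "fence_low", "fence_high"],
        )


def tukey_flags(ds: PanelDataset, k: float = 1.5) -> OutlierReport:
    """Flag values outside the Tukey fences, pooling nothing across
    variables or periods: quartiles are taken over DMUs separately per
    (variable, period).  A DMU is removed iff it is flagged at least once.

    With fewer than 4 DMUs quartiles are not meaningful; a warning is
    emitted and nothing is flagged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    flags: list[tuple[str, str, str, float, float, float]] = []
    if len(ds.dmu_ids) < 4:
        warnings.warn("fewer than 4 DMUs: quartiles unreliable, no outliers flagged")
        return OutlierReport([], set(), set(ds.dmu_ids), k)
    for v in ds.variables:
        for t in ds.periods:
            xs = np.array([ds.value(d, v.name, t) for d in ds.dmu_ids])
            q1, q3 = np.percentile(xs, [25, 75])  # linear interpolation
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            for d, x in zip(ds.dmu_ids, xs):
                if x < lo or x > hi:
                    flags.append((d, v.name, t, float(x), float(lo), float(hi)))
    removed = {f[0] for f in flags}
    kept = set(ds.dmu_ids) - removed
    return OutlierReport(flags, removed, kept, k)


def reduce_dataset(ds: PanelDataset, report: OutlierReport) -> PanelDataset:
    """Panel restricted to the DMUs the screen kept."""
    if not report.kept_dmus:
        raise ValueError("outlier screen removed every DMU; nothing to evaluate")
    return ds.subset([d for d in ds.dmu_ids if d in report.kept_dmus])


def compare_runs(
    scores_before: Mapping[str, float],
    scores_after: Mapping[str, float],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Before/after score comparison for one period.

    ``percent_change = (after - before) / before * 100`` per DMU present in
    both runs.  Summary means are arithmetic; standard deviations are the
    population (divide-by-N) form.
    """
    extra = set(scores_after) - set(scores_before)
    if extra:
        raise ValueError(f"after-run contains unknown DMUs {sorted(extra)}")
    rows = []
    for dmu, before in scores_before.items():
        if dmu in scores_after:
            after = scores_after[dmu]
            rows.append(
                {
                    "dmu": dmu,
                    "before": before,
                    "after": after,
                    "percent_change": (after - before) / before * 100.0,
                }
            )
    table = pd.DataFrame(rows, columns=["dmu", "before", "after", "percent_change"])
    before_all = np.array(list(scores_before.values()), dtype=float)
    after_all = np.array([r["after"] for r in rows], dtype=float)
    summary = {
        "mean_before": float(before_all.mean()),
        "mean_after": float(after_all.mean()) if after_all.size else float("nan"),
        "sd_before": float(before_all.std()),
        "sd_after": float(after_all.std()) if after_all.size else float("nan"),
    }
    return table, summary
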