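"""End-to-end pipeline and the summary-statistics layer.

``run_pipeline`` chains the full analysis — load or generate a panel,
validate it, score every DMU under constant and variable returns to scale,
optionally screen outliers and re-score the reduced sample, decompose
productivity change between two periods, and test whether the CRS and VRS
score distributions differ — writing one CSV/JSON artifact per stage plus a
run log that records every modelling default, so a report is
self-describing.

Rounding happens only here (scores to 4 decimals, Malmquist components and
percent changes to 2); the library layers never round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import engine, outliers, productivity
from .density import li_density_test
from .engine import CRS, VRS, ModelOptions
from .panel import PanelDataset, builtin_oecd7_fixture, load_panel, oecd7_schema, validate_panel
from .synthetic import SynthConfig, generate_panel

__all__ = [
    "RunConfig",
    "run_pipeline",
    "column_mean",
    "count_above_mean",
    "count_above_value",
    "population_sd",
]

log = logging.getLogger("dndea")


def column_mean(scores: Sequence[float]) -> float:
    """Arithmetic mean of a score column."""
    if len(scores) == 0:
        raise ValueError("empty score column")
    return float(np.mean(scores))


def count_above_mean(scores: Sequence[float]) -> int:
    """How many values exceed (strictly) the column's own mean."""
    if len(scores) == 0:
        raise ValueError("empty score column")
    mean = np.mean(scores)
    return int(np.sum(np.asarray(scores) > mean))


def count_above_value(scores: Sequence[float], threshold: float) -> int:
    """How many values exceed (strictly) a fixed threshold."""
    return int(np.sum(np.asarray(scores) > threshold))


def population_sd(scores: Sequence[float]) -> float:
    """Divide-by-N standard deviation."""
    if len(scores) == 0:
        raise ValueError("empty score column")
    return float(np.std(scores))


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one of fixture / input_csv / synth."""

    fixture: bool = False
    input_csv: str | Path | None = None
    synth: SynthConfig | None = None
    crs_options: ModelOptions = field(default_factory=lambda: ModelOptions(returns_to_scale=CRS))
    vrs_options: ModelOptions = field(default_factory=lambda: ModelOptions(returns_to_scale=VRS))
    screen_outliers: bool = True
    outlier_k: float = 1.5
    mi_periods: tuple[str, str] | None = None  # default: first and last period
    density_reps: int = 1000
    seed: int = 0
    out_dir: str | Path = "dndea_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = sum([self.fixture, self.input_csv is not None, self.synth is not None])
        if sources != 1:
            raise ValueError("exactly one input source (fixture, input_csv or synth) required")


def _period_scores(scores: Mapping[str, engine.EfficiencyScores], period: str) -> dict[str, float]:
    return {d: s.period[period] for d, s in scores.items()}


def _pooled_scores(scores: Mapping[str, engine.EfficiencyScores]) -> list[float]:
    """All per-period overall scores, pooled over DMUs and periods, clipped
    into (0, 1] against solver round-off."""
    vals = [v for s in scores.values() for v in s.period.values()]
    return [min(max(v, 1e-9), 1.0) for v in vals]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    stage = "load"
    try:
        if config.fixture:
            ds = builtin_oecd7_fixture()
            log.info("input: built-in seven-country OECD panel")
        elif config.input_csv is not None:
            ds = load_panel(config.input_csv, oecd7_schema())
            log.info("input: %s", config.input_csv)
        else:
            ds, truth = generate_panel(config.synth)
            log.info("input: synthetic panel %s", config.synth)
        for opt_name, opt in (("CRS", config.crs_options), ("VRS", config.vrs_options)):
            log.info(
                "%s model: rts=%s link_continuity=%s carryover_timing=%s "
                "carryover_continuity=%s terminal_carryover=%s weights=%s tiebreak=%s",
                opt_name, opt.returns_to_scale, opt.link_continuity, opt.carryover_timing,
                opt.carryover_continuity, opt.terminal_carryover,
                opt.weights or "uniform", opt.slack_tiebreak,
            )
        log.info(
            "outlier screen: %s (Tukey k=%s, linear-interpolation quartiles, "
            "union removal rule); density test: Gaussian kernel, pooled "
            "Silverman bandwidth, reflection at 1, boundary jitter, reps=%d, seed=%d",
            config.screen_outliers, config.outlier_k, config.density_reps, config.seed,
        )

        stage = "validate"
        report = validate_panel(ds)
        if not report.ok:
            raise ValueError(f"validation failed: {report.errors()[:5]}")

        stage = "evaluate"
        crs_scores, crs_fail = engine.evaluate_all(ds, config.crs_options)
        vrs_scores, vrs_fail = engine.evaluate_all(ds, config.vrs_options)
        for d, msg in {**crs_fail, **vrs_fail}.items():
            log.warning("solve failure for %s: %s", d, msg)
        tables = []
        for label, scores in (("CRS", crs_scores), ("VRS", vrs_scores)):
            tab = engine.scores_table(scores)
            tab.insert(0, "model", label)
            tables.append(tab)
        score_table = pd.concat(tables, ignore_index=True)
        score_table["score"] = score_table["score"].round(4)
        score_table.to_csv(out / "scores.csv", index=False)

        slack_rows = []
        for dmu in ds.dmu_ids:
            _, result, problem = engine.evaluate(ds, dmu, config.crs_options)
            tgt = engine.input_targets(result, problem)
            tgt.insert(0, "dmu", dmu)
            slack_rows.append(tgt)
        slacks = pd.concat(slack_rows, ignore_index=True)
        slacks["percent_reduction"] = slacks["percent_reduction"].round(2)
        slacks.to_csv(out / "slacks.csv", index=False)

        summary: dict = {"n_dmus": len(ds.dmu_ids), "periods": ds.periods, "failures": {**crs_fail, **vrs_fail}}
        for label, scores in (("crs", crs_scores), ("vrs", vrs_scores)):
            per_period = {}
            for t in ds.periods:
                col = list(_period_scores(scores, t).values())
                per_period[t] = {
                    "mean": round(column_mean(col), 4),
                    "sd": round(population_sd(col), 4),
                    "n_above_mean": count_above_mean(col),
                }
            summary[label] = per_period

        stage = "outlier_screen"
        if config.screen_outliers:
            flags = outliers.tukey_flags(ds, config.outlier_k)
            flags.to_frame().to_csv(out / "outliers.csv", index=False)
            log.info("outlier screen removed %d of %d DMUs", len(flags.removed_dmus), len(ds.dmu_ids))
            summary["outliers_removed"] = sorted(flags.removed_dmus)
            if flags.removed_dmus and flags.kept_dmus:
                reduced = outliers.reduce_dataset(ds, flags)
                red_scores, red_fail = engine.evaluate_all(reduced, config.vrs_options)
                comp_frames = []
                for t in ds.periods:
                    tab, stats = outliers.compare_runs(
                        _period_scores(vrs_scores, t), _period_scores(red_scores, t)
                    )
                    tab.insert(1, "period", t)
                    comp_frames.append(tab)
                    summary.setdefault("outlier_comparison", {})[t] = {
                        k: round(v, 4) for k, v in stats.items()
                    }
                comp = pd.concat(comp_frames, ignore_index=True)
                for c in ("before", "after"):
                    comp[c] = comp[c].round(4)
                comp["percent_change"] = comp["percent_change"].round(2)
                comp.to_csv(out / "comparison.csv", index=False)

        stage = "malmquist"
        t0, t1 = config.mi_periods or (ds.periods[0], ds.periods[-1])
        mi_table, mi_results = productivity.malmquist_table(ds, t0, t1, config.crs_options)
        for c in ("MI", "CU", "FS"):
            mi_table[c] = mi_table[c].round(2)
        mi_table.to_csv(out / "malmquist.csv", index=False)
        profiles = productivity.classify_profiles(mi_results)
        profiles["MI"] = profiles["MI"].round(2)
        profiles.to_csv(out / "profiles.csv", index=False)
        overall_col = [r.overall_mi for r in mi_results if np.isfinite(r.overall_mi)]
        n_dropped = len(mi_results) - len(overall_col)
        if n_dropped:
            log.warning("%d DMUs dropped from Malmquist aggregates (infeasible mixed-period programs)", n_dropped)
        summary["malmquist"] = {
            "periods": [t0, t1],
            "n_undefined": n_dropped,
            "geometric_mean_MI": round(productivity.geometric_mean(overall_col), 2) if overall_col else None,
            "n_progress": int(sum(round(v, 2) > 1 for v in overall_col)),
            "n_regress": int(sum(round(v, 2) < 1 for v in overall_col)),
        }

        stage = "density_test"
        dt = li_density_test(
            _pooled_scores(crs_scores), _pooled_scores(vrs_scores),
            reps=config.density_reps, seed=config.seed,
        )
        (out / "densitytest.json").write_text(json.dumps(dt.to_dict(), indent=2))
        summary["density_test"] = dt.to_dict()

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log.info("pipeline complete: %s", out)
        return summary
    except Exception:
        log.exception("pipeline failed at stage %r (partial outputs kept in %s)", stage, out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
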