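"""Synthetic panels with the two-division health-system network structure
and known ground-truth inefficiency.

The generator emulates the statistical shape of the observed OECD panel
(same twelve indicators, value envelopes matching the published per-year
min/max ranges) while controlling exactly which DMUs are efficient:

* ``n_frontier`` units are identical copies of a single anchor observation,
  so they cannot dominate each other and score exactly 1;
* the remaining units are the anchor with every input and bad carry-over
  (and as-input link, when the schema uses that mode) inflated by factors
  >= 1 drawn as exp(|N(0, inefficiency_scale)|), so each has strictly
  positive feasible slacks and scores < 1 under constant returns to scale.

Output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import PanelDataset, VariableSpec, oecd7_schema

__all__ = ["SynthConfig", "GroundTruth", "generate_panel", "perturb_with_outliers", "DEFAULT_RANGES"]

# Envelopes spanning the published per-year min/max of each indicator.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "alcohol": (1.3, 14.2),
    "tobacco": (7.6, 39.7),
    "hale": (60.6, 74.8),
    "immunisation": (78.0, 99.0),
    "breast_screening": (0.9, 90.4),
    "cervical_screening": (6.3, 90.6),
    "infant_mortality": (0.7, 28.4),
    "medical_technology": (2.5, 107.2),
    "employment": (2.3, 22.0),
    "discharges": (4016.6, 28114.5),
    "consultations": (2.4, 17.0),
    "cancer_incidence": (91.0, 420.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic panel draw."""

    n_dmus: int = 20
    n_periods: int = 3
    n_frontier: int = 5
    inefficiency_scale: float = 0.3
    indicator_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    seed: int = 0
    link_mode: str = "as_output"

    def __post_init__(self) -> None:
        if self.n_dmus < 2:
            raise ValueError("n_dmus must be >= 2")
        if self.n_periods < 2:
            raise ValueError("n_periods must be >= 2 (the network carries stocks over time)")
        if not (1 <= self.n_frontier <= self.n_dmus):
            raise ValueError("n_frontier must lie in [1, n_dmus]")
        if self.inefficiency_scale < 0:
            raise ValueError("inefficiency_scale must be nonnegative")
        for name, (lo, hi) in self.indicator_ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} needs low < high")
            if lo <= 0:
                raise ValueError(f"range for {name!r} needs low > 0 (positivity of model values)")


@dataclass
class GroundTruth:
    """What the generator planted: who is efficient and by how much not."""

    frontier: dict[str, bool]
    inflation: dict[tuple[str, str, str], float]  # (dmu, division, period) -> factor >= 1

    def mean_inflation(self, dmu: str) -> float:
        vals = [f for (d, _, _), f in self.inflation.items() if d == dmu]
        return float(np.mean(vals)) if vals else 1.0


def _inflated_variables(schema: list[VariableSpec]) -> dict[str, str]:
    """variable name -> owning division, for every inflated (excess-type) variable."""
    out: dict[str, str] = {}
    for v in schema:
        if v.role == "input":
            out[v.name] = v.division
        elif v.role == "link" and v.link_mode == "as_input":
            out[v.name] = v.link_target  # charged to the consuming division
        elif v.role == "carry_over" and v.carry_class == "bad":
            out[v.name] = v.division
    return out


def generate_panel(config: SynthConfig) -> tuple[PanelDataset, GroundTruth]:
    """Draw one synthetic panel plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    schema = oecd7_schema(config.link_mode)
    missing = [v.name for v in schema if v.name not in config.indicator_ranges]
    if missing:
        raise ValueError(f"indicator_ranges missing {missing}")
    periods = [f"t{p+1}" for p in range(config.n_periods)]
    dmus = [f"D{i+1:03d}" for i in range(config.n_dmus)]
    divisions: list[str] = []
    for v in schema:
        for div in filter(None, (v.division, v.link_source, v.link_target)):
            if div not in divisions:
                divisions.append(div)

    # one anchor observation per (variable, period), shared by all DMUs
    anchor = {
        (v.name, t): rng.uniform(*config.indicator_ranges[v.name])
        for v in schema
        for t in periods
    }
    inflated = _inflated_variables(schema)
    frontier_ids = dmus[: config.n_frontier]

    values: dict[tuple[str, str, str], float] = {}
    truth_frontier: dict[str, bool] = {}
    inflation: dict[tuple[str, str, str], float] = {}
    for d in dmus:
        on_frontier = d in frontier_ids
        truth_frontier[d] = on_frontier
        factors = {}
        for k in divisions:
            for t in periods:
                if on_frontier or config.inefficiency_scale == 0:
                    f = 1.0
                else:
                    f = float(np.exp(abs(rng.normal(0.0, config.inefficiency_scale))))
                factors[(k, t)] = f
                inflation[(d, k, t)] = f
        for v in schema:
            for t in periods:
                base = anchor[(v.name, t)]
                if v.name in inflated:
                    base *= factors[(inflated[v.name], t)]
                values[(d, v.name, t)] = base

    ds = PanelDataset(
        dmu_ids=dmus,
        periods=periods,
        divisions=divisions,
        variables=schema,
        values=values,
    )
    return ds, GroundTruth(frontier=truth_frontier, inflation=inflation)


def perturb_with_outliers(
    ds: PanelDataset, n_extreme: int, magnitude: float, seed: int = 0
) -> tuple[PanelDataset, list[str]]:
    """Multiply one randomly chosen variable of ``n_extreme`` randomly chosen
    DMUs by ``magnitude`` (across all periods).  Returns the perturbed panel
    and the affected DMU ids; deterministic given the seed."""
    if n_extreme >= len(ds.dmu_ids):
        raise ValueError("n_extreme must be smaller than the number of DMUs")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(ds.dmu_ids, size=n_extreme, replace=False).tolist())
    values = dict(ds.values)
    for d in chosen:
        var = ds.variables[int(rng.integers(len(ds.variables)))].name
        for t in ds.periods:
            values[(d, var, t)] = values[(d, var, t)] * magnitude
    out = PanelDataset(
        dmu_ids=list(ds.dmu_ids),
        periods=list(ds.periods),
        divisions=list(ds.divisions),
        variables=list(ds.variables),
        values=values,
        reference_ids=list(ds.reference_ids),
    )
    return out, chosen
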