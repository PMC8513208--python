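"""Panel data structures for dynamic network DEA.

A panel holds nonnegative indicator values indexed by decision-making unit
(DMU), variable and period.  Each variable carries a role annotation that
determines how the envelopment model treats it:

``input`` / ``output``
    Ordinary resources consumed / products delivered by one division.
``link``
    An intermediate product flowing between two divisions within a period
    (e.g. preventive-screening rates produced by public health and consumed
    by medical care).
``carry_over``
    A stock connecting consecutive periods of the same division (e.g. infant
    mortality, cancer incidence), classed good / bad / free / fixed.

The module also ships the built-in seven-country OECD panel (Austria,
Finland, Greece, Chile, Japan, Mexico, Turkey observed in 2000, 2008 and
2016) used throughout the tests and the worked examples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "PanelDataset",
    "WeightScheme",
    "ValidationReport",
    "load_panel",
    "write_panel",
    "load_wide_panel",
    "validate_panel",
    "schema_to_yaml",
    "schema_from_yaml",
    "builtin_oecd7_fixture",
    "oecd7_schema",
    "change_over_horizon",
    "descriptive_stats",
]

ROLES = ("input", "output", "link", "carry_over")
LINK_MODES = ("as_input", "as_output", "free", "fixed")
CARRY_CLASSES = ("good", "bad", "free", "fixed")


@dataclass(frozen=True)
class VariableSpec:
    """Role annotation for one indicator.

    Parameters
    ----------
    name : str
        Identifier used in data files.
    division : str
        Division the variable belongs to.  For links this is the emitting
        division (and must equal ``link_source``).
    role : str
        One of ``input``, ``output``, ``link``, ``carry_over``.
    link_source, link_target : str, optional
        Emitting / receiving division of a link (links only).
    link_mode : str, optional
        ``as_input``, ``as_output``, ``free`` or ``fixed`` (links only).
    carry_class : str, optional
        ``good``, ``bad``, ``free`` or ``fixed`` (carry-overs only).
    units : str
        Free-text unit description.
    """

    name: str
    division: str
    role: str
    link_source: str | None = None
    link_target: str | None = None
    link_mode: str | None = None
    carry_class: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.role == "link":
            if self.link_mode not in LINK_MODES:
                raise ValueError(f"link {self.name!r} needs link_mode in {LINK_MODES}")
            if not self.link_source or not self.link_target:
                raise ValueError(f"link {self.name!r} needs link_source and link_target")
            if self.link_source == self.link_target:
                raise ValueError(f"link {self.name!r} must connect two distinct divisions")
            if self.carry_class is not None:
                raise ValueError(f"link {self.name!r} cannot have carry_class")
        elif self.role == "carry_over":
            if self.carry_class not in CARRY_CLASSES:
                raise ValueError(
                    f"carry-over {self.name!r} needs carry_class in {CARRY_CLASSES}"
                )
            if self.link_mode is not None:
                raise ValueError(f"carry-over {self.name!r} cannot have link_mode")
        else:
            if self.link_mode is not None or self.carry_class is not None:
                raise ValueError(
                    f"{self.role} variable {self.name!r} cannot carry link/carry annotations"
                )


@dataclass(frozen=True)
class WeightScheme:
    """Exogenous period and division weights, each set summing to one."""

    period_weights: Mapping[str, float]
    division_weights: Mapping[str, float]

    _TOL = 1e-12

    def __post_init__(self) -> None:
        for label, weights in (
            ("period", self.period_weights),
            ("division", self.division_weights),
        ):
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{label} weights must be nonnegative")
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} weights must sum to 1, got {total!r}")

    @classmethod
    def uniform(cls, periods: Sequence[str], divisions: Sequence[str]) -> "WeightScheme":
        wp = 1.0 / len(periods)
        wd = 1.0 / len(divisions)
        return cls({t: wp for t in periods}, {k: wd for k in divisions})


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`; ``ok`` iff no error-severity issue."""

    issues: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def add(self, severity: str, location: str, message: str) -> None:
        self.issues.append((severity, location, message))

    def errors(self) -> list[tuple[str, str, str]]:
        return [i for i in self.issues if i[0] == "error"]


@dataclass
class PanelDataset:
    """DMU x variable x period indicator panel with role annotations.

    ``reference_ids`` name rows (e.g. an OECD-average column) that carry
    values but are not decision-making units: they never enter a frontier.
    """

    dmu_ids: list[str]
    periods: list[str]
    divisions: list[str]
    variables: list[VariableSpec]
    values: dict[tuple[str, str, str], float]
    reference_ids: list[str] = field(default_factory=list)

    def value(self, dmu: str, variable: str, period: str) -> float:
        key = (dmu, variable, period)
        if key not in self.values:
            raise KeyError(f"no value for dmu={dmu!r}, variable={variable!r}, period={period!r}")
        return self.values[key]

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}")

    def variables_for(
        self, division: str, role: str, **attrs: str | None
    ) -> list[VariableSpec]:
        """Variables of a division filtered by role and extra spec attributes.

        Links are attributed to their emitting division (``link_source``).
        """
        out = []
        for v in self.variables:
            if v.role != role:
                continue
            home = v.link_source if v.role == "link" else v.division
            if home != division:
                continue
            if all(getattr(v, a) == val for a, val in attrs.items()):
                out.append(v)
        return out

    def subset(self, dmus: Iterable[str]) -> "PanelDataset":
        keep = [d for d in self.dmu_ids if d in set(dmus)]
        missing = set(dmus) - set(self.dmu_ids)
        if missing:
            raise KeyError(f"unknown DMUs {sorted(missing)}")
        vals = {
            (d, v, t): x
            for (d, v, t), x in self.values.items()
            if d in set(keep) or d in set(self.reference_ids)
        }
        return PanelDataset(
            dmu_ids=keep,
            periods=list(self.periods),
            divisions=list(self.divisions),
            variables=list(self.variables),
            values=vals,
            reference_ids=list(self.reference_ids),
        )

    def rescaled(self, variable: str, factor: float) -> "PanelDataset":
        """A copy with one variable multiplied by ``factor`` everywhere."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        vals = {
            (d, v, t): (x * factor if v == variable else x)
            for (d, v, t), x in self.values.items()
        }
        return replace(self, values=vals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dmu": d, "period": t, "variable": v, "value": x}
            for (d, v, t), x in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["dmu", "period", "variable", "value"])


def _denominator_variable(spec: VariableSpec) -> bool:
    """True when the variable's observed value divides a slack in the objective."""
    return (
        spec.role == "input"
        or (spec.role == "link" and spec.link_mode == "as_input")
        or (spec.role == "carry_over" and spec.carry_class == "bad")
    )


def validate_panel(ds: PanelDataset) -> ValidationReport:
    """Check panel invariants; problems are reported, never raised.

    Errors: missing (dmu, variable, period) cells; nonpositive values of
    variables that appear in slack-ratio denominators (inputs, as-input
    links, bad carry-overs); negative values anywhere; carry-overs present
    with fewer than two periods; duplicate identifiers.
    """
    report = ValidationReport()
    if len(set(ds.dmu_ids)) != len(ds.dmu_ids):
        report.add("error", "dmu_ids", "duplicate DMU identifiers")
    names = [v.name for v in ds.variables]
    if len(set(names)) != len(names):
        report.add("error", "variables", "duplicate variable names")
    for v in ds.variables:
        for div in filter(None, (v.division, v.link_source, v.link_target)):
            if div not in ds.divisions:
                report.add("error", v.name, f"unknown division {div!r}")
    has_carry = any(v.role == "carry_over" for v in ds.variables)
    if has_carry and len(ds.periods) < 2:
        report.add("error", "periods", "carry-overs require at least 2 periods")
    all_rows = list(ds.dmu_ids) + list(ds.reference_ids)
    for d in all_rows:
        for v in ds.variables:
            for t in ds.periods:
                key = (d, v.name, t)
                loc = f"({d}, {v.name}, {t})"
                if key not in ds.values:
                    report.add("error", loc, "incomplete panel: missing cell")
                    continue
                x = ds.values[key]
                if x < 0:
                    report.add("error", loc, f"negative value {x}")
                elif x == 0 and _denominator_variable(v) and d in ds.dmu_ids:
                    report.add("error", loc, "nonpositive denominator variable")
    return report


def load_panel(
    path: str | Path,
    schema: Sequence[VariableSpec],
    reference_ids: Sequence[str] = (),
) -> PanelDataset:
    """Read a long-format CSV (columns dmu, period, variable, value).

    Period labels are sorted ascending as opaque tokens.  Divisions are
    inferred from the schema.  Raises on malformed files; completeness and
    positivity problems are left to :func:`validate_panel`.
    """
    path = Path(path)
    known = {v.name for v in schema}
    values: dict[tuple[str, str, str], float] = {}
    dmus: list[str] = []
    periods: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"dmu", "period", "variable", "value"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: long CSV needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            name = row["variable"]
            if name not in known:
                raise ValueError(f"{path}:{i}: variable {name!r} not in schema")
            try:
                x = float(row["value"])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: non-numeric value {row['value']!r}") from exc
            if x < 0:
                raise ValueError(f"{path}:{i}: negative value {x}")
            d, t = row["dmu"], row["period"]
            if d not in dmus and d not in reference_ids:
                dmus.append(d)
            periods.add(t)
            values[(d, name, t)] = x
    divisions: list[str] = []
    for v in schema:
        for div in filter(None, (v.division, v.link_source, v.link_target)):
            if div not in divisions:
                divisions.append(div)
    return PanelDataset(
        dmu_ids=dmus,
        periods=sorted(periods),
        divisions=divisions,
        variables=list(schema),
        values=values,
        reference_ids=list(reference_ids),
    )


def write_panel(ds: PanelDataset, path: str | Path) -> None:
    """Write the long CSV dialect read by :func:`load_panel` (round-trip safe)."""
    ds.to_frame().to_csv(Path(path), index=False)


def load_wide_panel(
    path: str | Path,
    schema: Sequence[VariableSpec],
    reference_ids: Sequence[str] = (),
) -> PanelDataset:
    """Convenience reader for wide CSVs (dmu, period, one column per variable)."""
    df = pd.read_csv(path)
    if not {"dmu", "period"}.issubset(df.columns):
        raise ValueError("wide CSV needs columns dmu, period")
    long = df.melt(id_vars=["dmu", "period"], var_name="variable", value_name="value")
    import io

    buf = io.StringIO()
    long.to_csv(buf, index=False)
    buf.seek(0)
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as tmp:
        tmp.write(buf.getvalue())
        name = tmp.name
    try:
        return load_panel(name, schema, reference_ids)
    finally:
        Path(name).unlink(missing_ok=True)


# -- schema (de)serialisation -------------------------------------------------

def schema_to_yaml(schema: Sequence[VariableSpec], path: str | Path) -> None:
    payload = [
        {k: v for k, v in vars(s).items() if v not in (None, "")} for s in schema
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def schema_from_yaml(path: str | Path) -> list[VariableSpec]:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return [VariableSpec(**entry) for entry in payload]


# -- built-in seven-country OECD panel ---------------------------------------

PUBLIC = "public_health"
MEDICAL = "medical_care"
OECD_AVERAGE = "OECD_AVG"

_FIXTURE_DMUS = ["AUT", "FIN", "GRC", "CHL", "JPN", "MEX", "TUR"]
_FIXTURE_PERIODS = ["2000", "2008", "2016"]

# Published indicator values for the seven above-average-efficiency OECD
# countries plus the OECD-average reference column, observed 2000/2008/2016.
# Row order within each period: AUT, FIN, GRC, CHL, JPN, MEX, TUR, OECD_AVG.
_FIXTURE_VALUES: dict[str, dict[str, tuple[float, ...]]] = {
    "alcohol": {
        "2000": (13.20, 8.60, 9.20, 6.20, 8.60, 5.00, 1.50, 9.48),
        "2008": (12.00, 10.30, 9.50, 7.40, 7.50, 4.00, 1.50, 9.70),
        "2016": (11.40, 8.40, 6.50, 7.90, 7.20, 4.40, 1.30, 8.91),
    },
    "tobacco": {
        "2000": (24.30, 23.40, 35.00, 33.00, 27.00, 12.40, 32.10, 25.74),
        "2008": (23.20, 20.40, 39.70, 29.80, 21.80, 10.80, 27.40, 22.18),
        "2016": (24.30, 15.00, 27.30, 24.50, 18.30, 7.60, 26.50, 18.83),
    },
    "hale": {
        "2000": (69.50, 68.50, 69.60, 67.80, 72.50, 65.60, 60.60, 67.98),
        "2008": (71.40, 70.40, 71.50, 68.90, 73.80, 66.50, 64.40, 70.11),
        "2016": (72.40, 71.70, 72.00, 69.70, 74.80, 67.70, 66.00, 71.10),
    },
    "immunisation": {
        "2000": (81.00, 99.00, 89.00, 91.00, 85.00, 97.00, 85.00, 92.89),
        "2008": (83.00, 99.00, 99.00, 95.00, 98.00, 96.00, 96.00, 95.22),
        "2016": (87.00, 92.00, 99.00, 95.00, 99.00, 97.00, 98.00, 95.42),
    },
    "breast_screening": {
        "2000": (80.20, 87.40, 49.60, 16.40, 23.80, 0.90, 30.20, 51.67),
        "2008": (80.20, 84.90, 53.80, 19.30, 23.80, 9.60, 24.70, 57.60),
        "2016": (72.70, 82.20, 59.60, 36.90, 41.00, 18.10, 33.20, 60.20),
    },
    "cervical_screening": {
        "2000": (81.50, 70.30, 59.40, 64.50, 22.60, 6.30, 36.80, 56.14),
        "2008": (82.30, 69.00, 70.00, 68.00, 24.50, 19.00, 24.00, 59.87),
        "2016": (86.60, 69.80, 75.50, 55.90, 42.40, 18.20, 47.80, 61.91),
    },
    "infant_mortality": {
        "2000": (4.80, 3.80, 5.90, 8.90, 3.20, 20.80, 28.40, 6.77),
        "2008": (3.70, 2.60, 2.70, 7.80, 2.60, 15.10, 15.70, 4.63),
        "2016": (3.10, 1.90, 4.20, 6.90, 2.00, 12.10, 10.00, 3.87),
    },
    "medical_technology": {
        "2000": (26.09, 13.52, 25.48, 10.20, 92.62, 2.45, 4.89, 16.11),
        "2008": (29.68, 16.45, 31.05, 10.20, 96.97, 4.01, 10.68, 21.21),
        "2016": (29.07, 24.20, 36.66, 14.76, 107.17, 6.12, 14.53, 25.94),
    },
    "employment": {
        "2000": (11.01, 13.21, 7.12, 2.34, 10.36, 3.78, 2.36, 10.01),
        "2008": (12.13, 15.86, 9.39, 2.70, 11.73, 4.24, 3.00, 11.30),
        "2016": (13.12, 17.62, 9.84, 5.02, 13.77, 5.25, 3.76, 12.49),
    },
    "discharges": {
        "2000": (25933.30, 21444.70, 16242.50, 10057.90, 10326.50, 4016.60, 7711.90, 15982.29),
        "2008": (28114.50, 18405.90, 20050.20, 9639.60, 11161.70, 4603.50, 13629.90, 16105.10),
        "2016": (25310.00, 16555.40, 19645.60, 9000.00, 12638.80, 4617.20, 16785.70, 15816.70),
    },
    "consultations": {
        "2000": (6.70, 4.30, 4.30, 2.40, 14.40, 2.50, 2.80, 6.17),
        "2008": (6.90, 4.30, 4.00, 3.00, 13.20, 2.80, 6.70, 6.52),
        "2016": (6.60, 4.30, 4.00, 3.50, 12.80, 2.90, 8.60, 6.85),
    },
    "cancer_incidence": {
        "2000": (237.00, 247.00, 162.00, 176.70, 201.10, 91.00, 144.80, 277.87),
        "2008": (250.60, 250.10, 162.00, 176.70, 201.10, 128.40, 144.80, 259.93),
        "2016": (254.10, 256.80, 163.00, 175.70, 217.10, 131.50, 205.10, 269.26),
    },
}


def oecd7_schema(link_mode: str = "as_output") -> list[VariableSpec]:
    """Variable roles of the two-division health-system network.

    Public health consumes alcohol and tobacco exposure and produces HALE;
    the three preventive services link public health to medical care; infant
    mortality is public health's bad carry-over.  Medical care consumes CT
    density and health employment, produces discharges and consultations,
    and carries cancer incidence as a bad stock.
    """
    return [
        VariableSpec("alcohol", PUBLIC, "input", units="litres/capita 15+"),
        VariableSpec("tobacco", PUBLIC, "input", units="grams/capita 15+"),
        VariableSpec("hale", PUBLIC, "output", units="years"),
        VariableSpec("immunisation", PUBLIC, "link", PUBLIC, MEDICAL, link_mode, units="% children <1y"),
        VariableSpec("breast_screening", PUBLIC, "link", PUBLIC, MEDICAL, link_mode, units="% women 50-69"),
        VariableSpec("cervical_screening", PUBLIC, "link", PUBLIC, MEDICAL, link_mode, units="% women 20-69"),
        VariableSpec("infant_mortality", PUBLIC, "carry_over", carry_class="bad", units="deaths/1000 births"),
        VariableSpec("medical_technology", MEDICAL, "input", units="CT devices/1e6 pop"),
        VariableSpec("employment", MEDICAL, "input", units="doctors+nurses/1000 pop"),
        VariableSpec("discharges", MEDICAL, "output", units="discharges/100k pop"),
        VariableSpec("consultations", MEDICAL, "output", units="consultations/physician"),
        VariableSpec("cancer_incidence", MEDICAL, "carry_over", carry_class="bad", units="new cases/100k pop"),
    ]


def builtin_oecd7_fixture(link_mode: str = "as_output") -> PanelDataset:
    """The embedded seven-country x three-period OECD panel.

    Values are stored at printed precision; the OECD-average column is kept
    as a non-DMU reference row excluded from every frontier.  Health
    expenditure is not a model variable and is not included.
    """
    schema = oecd7_schema(link_mode)
    rows = _FIXTURE_DMUS + [OECD_AVERAGE]
    values: dict[tuple[str, str, str], float] = {}
    for var, by_period in _FIXTURE_VALUES.items():
        for t, row in by_period.items():
            for dmu, x in zip(rows, row):
                values[(dmu, var, t)] = x
    return PanelDataset(
        dmu_ids=list(_FIXTURE_DMUS),
        periods=list(_FIXTURE_PERIODS),
        divisions=[PUBLIC, MEDICAL],
        variables=schema,
        values=values,
        reference_ids=[OECD_AVERAGE],
    )


def change_over_horizon(ds: PanelDataset, variable: str, dmu: str) -> float:
    """Last-period minus first-period value for one DMU (or reference row)."""
    if dmu not in ds.dmu_ids and dmu not in ds.reference_ids:
        raise KeyError(f"unknown DMU {dmu!r}")
    ds.variable(variable)  # raises on unknown name
    return ds.value(dmu, variable, ds.periods[-1]) - ds.value(dmu, variable, ds.periods[0])


def descriptive_stats(ds: PanelDataset) -> pd.DataFrame:
    """Per-variable per-period mean/min/max over DMUs (reference rows excluded)."""
    records = []
    for v in ds.variables:
        for t in ds.periods:
            xs = [ds.value(d, v.name, t) for d in ds.dmu_ids]
            records.append(
                {
                    "variable": v.name,
                    "period": t,
                    "mean": sum(xs) / len(xs),
                    "min": min(xs),
                    "max": max(xs),
                }
            )
    return pd.DataFrame(records)
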