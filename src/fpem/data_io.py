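"""Tabular input/output for the family planning estimation tool.

The tool consumes four CSV tables (surveys, service statistics, population
counts of married/in-union women of reproductive age, and the country
hierarchy) and ships verbatim transcriptions of the three printed report
tables as validation fixtures.

All proportions are stored on the (0, 1) scale.  Calendar time is expressed
in decimal years; a survey carried out within a single calendar year Y and
lacking explicit fieldwork months is placed at mid-year, Y + 0.5.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "INDICATORS",
    "SOURCE_TYPES",
    "SurveyObservation",
    "ServiceStatObservation",
    "CountryMeta",
    "PopulationCount",
    "Dataset",
    "ReportFixture",
    "Issue",
    "mid_year",
    "load_dataset",
    "write_dataset",
    "validate_dataset",
    "load_report_fixtures",
    "country_lookup",
]

INDICATORS = ("total_cpr", "modern_cpr", "trad_cpr", "unmet_any")
SOURCE_TYPES = ("DHS", "MICS", "PMA", "RHS", "NATIONAL", "OTHER")

#: plausible range for decimal years appearing in any input table
YEAR_RANGE = (1960.0, 2030.0)


def mid_year(year: int) -> float:
    """Mid-year decimal time for a calendar year (1990 -> 1990.5)."""
    return year + 0.5


@dataclass(frozen=True)
class SurveyObservation:
    """One survey datapoint for a single indicator.

    ``value`` is a proportion in (0, 1).  ``period_start``/``period_end``
    bound the fieldwork reference period in decimal years; the observation
    informs the average of the indicator over that interval.
    ``sampling_se`` is the survey sampling standard error on the proportion
    scale, or ``None`` when it was not reported (it is then imputed
    downstream, never silently zeroed).
    """

    country_code: str
    indicator: str
    value: float
    source_type: str
    period_start: float
    period_end: float
    sampling_se: float | None = None


@dataclass(frozen=True)
class ServiceStatObservation:
    """Estimated modern use (EMU) derived from service statistics."""

    country_code: str
    year: float
    emu: float


@dataclass(frozen=True)
class CountryMeta:
    country_code: str
    name: str
    subregion: str
    region: str
    fp2020_commitment: bool


@dataclass(frozen=True)
class PopulationCount:
    """Married/in-union women aged 15-49 in a country-year (persons)."""

    country_code: str
    year: int
    mwra: float


@dataclass
class Dataset:
    surveys: list[SurveyObservation] = field(default_factory=list)
    service_stats: list[ServiceStatObservation] = field(default_factory=list)
    meta: list[CountryMeta] = field(default_factory=list)
    populations: list[PopulationCount] = field(default_factory=list)

    def countries(self) -> list[str]:
        return [m.country_code for m in self.meta]

    def meta_by_code(self) -> dict[str, CountryMeta]:
        return {m.country_code: m for m in self.meta}

    def surveys_for(self, country_code: str) -> list[SurveyObservation]:
        return [s for s in self.surveys if s.country_code == country_code]

    def service_stats_for(self, country_code: str) -> list[ServiceStatObservation]:
        return [s for s in self.service_stats if s.country_code == country_code]

    def population(self, country_code: str, year: int) -> float:
        for p in self.populations:
            if p.country_code == country_code and p.year == year:
                return p.mwra
        raise KeyError(f"no population count for {country_code} in {year}")


@dataclass(frozen=True)
class ReportFixture:
    """A packaged transcription of one of the printed report tables."""

    table_id: str
    rows: pd.DataFrame


@dataclass(frozen=True)
class Issue:
    """A validation finding: which record, which rule."""

    table: str
    record: int
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.record}]: {self.rule}"


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

_TABLES = ("surveys", "service_stats", "populations", "hierarchy")


def _as_paths(paths: str | Path | Mapping[str, str | Path]) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {t: base / f"{t}.csv" for t in _TABLES}
    return {t: Path(paths[t]) for t in _TABLES}


class ParseError(ValueError):
    """Malformed row in an input table; names file and line."""


def _fail(path: Path, line: int, msg: str) -> None:
    raise ParseError(f"{path}:{line}: {msg}")


def _check_proportion(x: float, what: str, path: Path, line: int) -> None:
    if not (0.0 < x < 1.0):
        _fail(path, line, f"{what} must lie strictly in (0, 1), got {x}")


def _check_year(x: float, what: str, path: Path, line: int) -> None:
    if not (YEAR_RANGE[0] <= x <= YEAR_RANGE[1]):
        _fail(path, line, f"{what} {x} outside plausible range {YEAR_RANGE}")


def load_dataset(paths: str | Path | Mapping[str, str | Path]) -> Dataset:
    """Read and validate the four input tables.

    ``paths`` is either a directory containing ``surveys.csv``,
    ``service_stats.csv``, ``populations.csv`` and ``hierarchy.csv``, or a
    mapping from those table names to file locations.  Raises
    :class:`ParseError` on a malformed row (naming file and line) and keeps
    missing sampling standard errors as missing.
    """
    p = _as_paths(paths)
    for t, fp in p.items():
        if not fp.exists():
            raise FileNotFoundError(f"missing input table {t!r}: {fp}")

    meta: list[CountryMeta] = []
    hier = pd.read_csv(p["hierarchy"], dtype=str)
    for i, row in hier.iterrows():
        line = i + 2  # header is line 1
        commit = str(row["fp2020_commitment"]).strip().lower()
        if commit not in {"0", "1", "true", "false"}:
            _fail(p["hierarchy"], line, f"bad fp2020_commitment {row['fp2020_commitment']!r}")
        meta.append(
            CountryMeta(
                country_code=row["country_code"],
                name=row["name"],
                subregion=row["subregion"],
                region=row["region"],
                fp2020_commitment=commit in {"1", "true"},
            )
        )
    known = {m.country_code for m in meta}

    surveys: list[SurveyObservation] = []
    sv = pd.read_csv(p["surveys"])
    for i, row in sv.iterrows():
        line = i + 2
        if row["country_code"] not in known:
            _fail(p["surveys"], line, f"unknown country code {row['country_code']!r}")
        if row["indicator"] not in INDICATORS:
            _fail(p["surveys"], line, f"unknown indicator {row['indicator']!r}")
        if row["source_type"] not in SOURCE_TYPES:
            _fail(p["surveys"], line, f"unknown source type {row['source_type']!r}")
        value = float(row["value"])
        start, end = float(row["period_start"]), float(row["period_end"])
        _check_proportion(value, "value", p["surveys"], line)
        _check_year(start, "period_start", p["surveys"], line)
        _check_year(end, "period_end", p["surveys"], line)
        if end < start:
            _fail(p["surveys"], line, f"period_end {end} before period_start {start}")
        se = row.get("sampling_se")
        se = None if se is None or (isinstance(se, float) and math.isnan(se)) else float(se)
        if se is not None and not se > 0:
            _fail(p["surveys"], line, f"sampling_se must be > 0 when present, got {se}")
        surveys.append(
            SurveyObservation(
                country_code=row["country_code"],
                indicator=row["indicator"],
                value=value,
                source_type=row["source_type"],
                period_start=start,
                period_end=end,
                sampling_se=se,
            )
        )

    service: list[ServiceStatObservation] = []
    ss = pd.read_csv(p["service_stats"])
    for i, row in ss.iterrows():
        line = i + 2
        if row["country_code"] not in known:
            _fail(p["service_stats"], line, f"unknown country code {row['country_code']!r}")
        year, emu = float(row["year"]), float(row["emu"])
        _check_year(year, "year", p["service_stats"], line)
        _check_proportion(emu, "emu", p["service_stats"], line)
        service.append(ServiceStatObservation(row["country_code"], year, emu))

    pops: list[PopulationCount] = []
    pp = pd.read_csv(p["populations"])
    for i, row in pp.iterrows():
        line = i + 2
        if row["country_code"] not in known:
            _fail(p["populations"], line, f"unknown country code {row['country_code']!r}")
        mwra = float(row["mwra"])
        if not mwra > 0:
            _fail(p["populations"], line, f"mwra must be > 0, got {mwra}")
        pops.append(PopulationCount(row["country_code"], int(row["year"]), mwra))

    return Dataset(surveys=surveys, service_stats=service, meta=meta, populations=pops)


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write the four standard CSVs; inverse of :func:`load_dataset`."""
    base = Path(directory)
    base.mkdir(parents=True, exist_ok=True)
    out = {t: base / f"{t}.csv" for t in _TABLES}
    pd.DataFrame(
        [
            {
                "country_code": s.country_code,
                "indicator": s.indicator,
                "value": s.value,
                "source_type": s.source_type,
                "period_start": s.period_start,
                "period_end": s.period_end,
                "sampling_se": s.sampling_se,
            }
            for s in dataset.surveys
        ],
        columns=[
            "country_code", "indicator", "value", "source_type",
            "period_start", "period_end", "sampling_se",
        ],
    ).to_csv(out["surveys"], index=False)
    pd.DataFrame(
        [{"country_code": s.country_code, "year": s.year, "emu": s.emu} for s in dataset.service_stats],
        columns=["country_code", "year", "emu"],
    ).to_csv(out["service_stats"], index=False)
    pd.DataFrame(
        [{"country_code": q.country_code, "year": q.year, "mwra": q.mwra} for q in dataset.populations],
        columns=["country_code", "year", "mwra"],
    ).to_csv(out["populations"], index=False)
    pd.DataFrame(
        [
            {
                "country_code": m.country_code,
                "name": m.name,
                "subregion": m.subregion,
                "region": m.region,
                "fp2020_commitment": int(m.fp2020_commitment),
            }
            for m in dataset.meta
        ],
        columns=["country_code", "name", "subregion", "region", "fp2020_commitment"],
    ).to_csv(out["hierarchy"], index=False)
    return out


# ---------------------------------------------------------------------------
# validation (reports, never throws)
# ---------------------------------------------------------------------------

def validate_dataset(dataset: Dataset) -> list[Issue]:
    """Check every type and referential invariant; return the violations."""
    issues: list[Issue] = []
    known = {m.country_code for m in dataset.meta}

    sub_of: dict[str, str] = {}
    reg_of: dict[str, str] = {}
    for i, m in enumerate(dataset.meta):
        if m.country_code in sub_of and sub_of[m.country_code] != m.subregion:
            issues.append(Issue("hierarchy", i, "country mapped to more than one subregion"))
        sub_of[m.country_code] = m.subregion
        if m.subregion in reg_of and reg_of[m.subregion] != m.region:
            issues.append(Issue("hierarchy", i, f"subregion {m.subregion!r} mapped to more than one region"))
        reg_of[m.subregion] = m.region

    for i, s in enumerate(dataset.surveys):
        if s.country_code not in known:
            issues.append(Issue("surveys", i, f"country {s.country_code!r} absent from hierarchy"))
        if s.indicator not in INDICATORS:
            issues.append(Issue("surveys", i, f"unknown indicator {s.indicator!r}"))
        if s.source_type not in SOURCE_TYPES:
            issues.append(Issue("surveys", i, f"unknown source type {s.source_type!r}"))
        if not (0.0 < s.value < 1.0):
            issues.append(Issue("surveys", i, f"value {s.value} outside (0, 1)"))
        if s.period_end < s.period_start:
            issues.append(Issue("surveys", i, "period_end before period_start"))
        for what, y in (("period_start", s.period_start), ("period_end", s.period_end)):
            if not (YEAR_RANGE[0] <= y <= YEAR_RANGE[1]):
                issues.append(Issue("surveys", i, f"{what} {y} outside plausible range"))
        if s.sampling_se is not None and not s.sampling_se > 0:
            issues.append(Issue("surveys", i, f"sampling_se {s.sampling_se} not positive"))

    for i, s in enumerate(dataset.service_stats):
        if s.country_code not in known:
            issues.append(Issue("service_stats", i, f"country {s.country_code!r} absent from hierarchy"))
        if not (0.0 < s.emu < 1.0):
            issues.append(Issue("service_stats", i, f"emu {s.emu} outside (0, 1)"))
        if not (YEAR_RANGE[0] <= s.year <= YEAR_RANGE[1]):
            issues.append(Issue("service_stats", i, f"year {s.year} outside plausible range"))

    for i, q in enumerate(dataset.populations):
        if q.country_code not in known:
            issues.append(Issue("populations", i, f"country {q.country_code!r} absent from hierarchy"))
        if not q.mwra > 0:
            issues.append(Issue("populations", i, f"mwra {q.mwra} not positive"))

    return issues


# ---------------------------------------------------------------------------
# packaged report fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {"T1": "table1.csv", "T2": "table2.csv", "T3": "table3.csv"}


def _fixture_path(name: str):
    return resources.files("fpem").joinpath("fixtures", name)


def load_report_fixtures(table_id: str) -> ReportFixture:
    """Load the packaged transcription of report table T1, T2 or T3.

    Numeric cells were normalised from middle-dot decimals ("77·4") to
    ordinary floats at transcription time; point estimates and 95%
    uncertainty bounds occupy separate columns.
    """
    if table_id not in _FIXTURE_FILES:
        raise KeyError(f"unknown table_id {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}")
    with resources.as_file(_fixture_path(_FIXTURE_FILES[table_id])) as fp:
        rows = pd.read_csv(fp)
    return ReportFixture(table_id=table_id, rows=rows)


def country_lookup() -> pd.DataFrame:
    """Packaged name/ISO3/subregion/region lookup for the 68 focus countries."""
    with resources.as_file(_fixture_path("countries.csv")) as fp:
        return pd.read_csv(fp)
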