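"""Derived indicators, population-weighted aggregation and summaries.

All derived quantities are computed draw by draw and only then summarised,
so that uncertainty intervals have a coherent joint-posterior
interpretation.  In particular demand satisfied is the draw-wise ratio
mCPR / (mCPR + unmet need for modern methods); the same ratio applied to
summary medians holds only approximately.

Unmet need for modern methods counts women with an unmet need for any
method together with traditional-method users; demand satisfied with a
modern method is modern use divided by total demand (modern use plus unmet
need for modern methods).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import Dataset, PopulationCount
from .inference import PosteriorDraws

__all__ = [
    "IndicatorDraws",
    "Summary",
    "derive_indicators",
    "additional_users",
    "aggregate",
    "summarize",
    "change_table",
    "round_half_away",
    "plugin_demand_satisfied",
    "population_matrix",
]


@dataclass(frozen=True)
class Summary:
    """Posterior median with a central 95% uncertainty interval."""

    median: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.median <= self.upper):
            raise ValueError(f"summary out of order: {self}")


@dataclass
class IndicatorDraws:
    """Draw-level indicator values for a set of units (countries or groups).

    Arrays are shaped ``(draw, unit, year)``; proportions lie in [0, 1).
    ``users`` (modern-method users, persons) is present when population
    counts were supplied.
    """

    units: list[str]
    years: np.ndarray
    mcpr: np.ndarray
    trad: np.ndarray
    unmet_any: np.ndarray
    unmet_modern: np.ndarray
    demand_satisfied: np.ndarray
    users: np.ndarray | None = None

    def unit_index(self, unit: str) -> int:
        return self.units.index(unit)

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(f"year {year} not available")
        return idx

    def at(self, field: str, unit: str, year: int) -> np.ndarray:
        """Draws of one field for one unit-year."""
        return getattr(self, field)[:, self.unit_index(unit), self.year_index(year)]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report-table convention)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def plugin_demand_satisfied(mcpr_pct: float, unmet_modern_pct: float) -> float:
    """Demand satisfied (%) from point estimates of mCPR and unmet need (%).

    The plug-in identity applied to published medians; exact draw-wise but
    only approximate on summaries.
    """
    return round_half_away(100.0 * mcpr_pct / (mcpr_pct + unmet_modern_pct), 1)


def population_matrix(
    populations: Sequence[PopulationCount], units: Sequence[str], years: np.ndarray
) -> np.ndarray:
    """Dense (unit, year) matrix of married/in-union women counts.

    Missing country-years are NaN; operations that need them raise.
    """
    out = np.full((len(units), years.size), np.nan)
    uidx = {u: i for i, u in enumerate(units)}
    yidx = {int(y): i for i, y in enumerate(years)}
    for p in populations:
        if p.country_code in uidx and p.year in yidx:
            out[uidx[p.country_code], yidx[p.year]] = p.mwra
    return out


def derive_indicators(
    draws: PosteriorDraws, populations: Sequence[PopulationCount] | None = None
) -> IndicatorDraws:
    """Compute the reported indicators from posterior draws, draw-wise.

    ``unmet_modern = unmet_any + trad_cpr`` and
    ``demand_satisfied = mcpr / (mcpr + unmet_modern)`` for every draw.
    """
    mcpr = draws.quantity("modern_cpr")
    trad = draws.quantity("trad_cpr")
    unmet_any = draws.quantity("unmet_any")
    unmet_modern = unmet_any + trad
    demand = mcpr + unmet_modern
    if np.any(demand <= 0):
        raise ValueError("demand satisfied undefined where mcpr + unmet_modern = 0")
    users = None
    if populations is not None:
        pop = population_matrix(populations, draws.countries, draws.years)
        users = mcpr * pop  # NaN where populations are missing
    return IndicatorDraws(
        units=list(draws.countries),
        years=draws.years.copy(),
        mcpr=mcpr,
        trad=trad,
        unmet_any=unmet_any,
        unmet_modern=unmet_modern,
        demand_satisfied=mcpr / demand,
        users=users,
    )


def additional_users(
    ind: IndicatorDraws,
    populations: Sequence[PopulationCount],
    y0: int,
    y1: int,
) -> Summary:
    """Change in the total number of modern-method users between two years.

    Per draw: sum over units of mwra * mcpr at ``y1`` minus the same at
    ``y0``; population counts are treated as known (no uncertainty).
    Summarised over draws, in persons.
    """
    pop = population_matrix(populations, ind.units, ind.years)
    i0, i1 = ind.year_index(y0), ind.year_index(y1)
    for idx, year in ((i0, y0), (i1, y1)):
        if np.isnan(pop[:, idx]).any():
            missing = [u for u, v in zip(ind.units, pop[:, idx]) if np.isnan(v)]
            raise ValueError(f"missing population counts for {missing} in {year}")
    per_draw = ind.mcpr[:, :, i1] @ pop[:, i1] - ind.mcpr[:, :, i0] @ pop[:, i0]
    return summarize(per_draw)


def aggregate(
    ind: IndicatorDraws,
    populations: Sequence[PopulationCount],
    grouping: Mapping[str, str],
) -> IndicatorDraws:
    """Population-weighted aggregation of countries into groups.

    Prevalence-type indicators are mwra-weighted means per draw and year;
    user counts add exactly; unmet need for modern methods and demand
    satisfied are recomputed from the aggregated components per draw, which
    preserves the draw-wise identities at the group level.
    """
    missing = [u for u in ind.units if u not in grouping]
    if missing:
        raise KeyError(f"countries missing from grouping: {missing}")
    pop = population_matrix(populations, ind.units, ind.years)
    if np.isnan(pop).any():
        raise ValueError("population counts required for every country-year")
    groups = sorted(set(grouping.values()))
    shape = (ind.mcpr.shape[0], len(groups), ind.years.size)
    mcpr = np.empty(shape)
    trad = np.empty(shape)
    unmet_any = np.empty(shape)
    users = np.empty(shape)
    member = np.array([groups.index(grouping[u]) for u in ind.units])
    for g in range(len(groups)):
        sel = member == g
        w = pop[sel]  # (members, year)
        wsum = w.sum(axis=0)
        mcpr[:, g] = (ind.mcpr[:, sel] * w).sum(axis=1) / wsum
        trad[:, g] = (ind.trad[:, sel] * w).sum(axis=1) / wsum
        unmet_any[:, g] = (ind.unmet_any[:, sel] * w).sum(axis=1) / wsum
        users[:, g] = (ind.mcpr[:, sel] * w).sum(axis=1)
    unmet_modern = unmet_any + trad
    return IndicatorDraws(
        units=groups,
        years=ind.years.copy(),
        mcpr=mcpr,
        trad=trad,
        unmet_any=unmet_any,
        unmet_modern=unmet_modern,
        demand_satisfied=mcpr / (mcpr + unmet_modern),
        users=users,
    )


def summarize(values: np.ndarray) -> Summary:
    """Median and central 95% interval over draws.

    Percentiles use linear interpolation between order statistics
    (inclusive, the numpy default).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty set of draws")
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return Summary(median=float(med), lower=float(lo), upper=float(hi))


def change_table(ind: IndicatorDraws, y0: int, y1: int) -> pd.DataFrame:
    """Per-unit changes between two grid years, summarised over draws.

    Columns give median and 95% bounds of the change in mCPR, unmet need
    for modern methods and demand satisfied (percentage points) and in
    users (persons, when available).  ``progress_positive`` applies the
    two-indicator rule: median mCPR change and median demand-satisfied
    change both positive.
    """
    i0, i1 = ind.year_index(y0), ind.year_index(y1)
    records = []
    for u, unit in enumerate(ind.units):
        row: dict[str, object] = {"unit": unit}
        for name, arr, scale in (
            ("mcpr", ind.mcpr, 100.0),
            ("unmet_modern", ind.unmet_modern, 100.0),
            ("demand_satisfied", ind.demand_satisfied, 100.0),
        ):
            s = summarize(scale * (arr[:, u, i1] - arr[:, u, i0]))
            row[f"{name}_change"] = s.median
            row[f"{name}_change_lower"] = s.lower
            row[f"{name}_change_upper"] = s.upper
        if ind.users is not None:
            s = summarize(ind.users[:, u, i1] - ind.users[:, u, i0])
            row["users_change"] = s.median
            row["users_change_lower"] = s.lower
            row["users_change_upper"] = s.upper
        row["progress_positive"] = bool(
            row["mcpr_change"] > 0 and row["demand_satisfied_change"] > 0
        )
        records.append(row)
    return pd.DataFrame.from_records(records)
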