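"""Counterfactual "pre-FP2020 expectation" analysis.

The dataset is truncated at a cutoff year (2012 by default): every survey
or service-statistic observation whose reference period *starts* strictly
after the cutoff is removed, and the model is refitted.  The truncated fit
projects what contraceptive use was expected to look like had post-cutoff
information never arrived.  For each country the full-data estimate of mCPR
in its most recent observation year is compared against the counterfactual
projection: the attainment probability is the fraction of counterfactual
draws at or above the full-data median — the pre-cutoff probability of
attaining the level actually observed.  Countries are grouped at the 25%
and 75% probability thresholds, and progress is called positive when the
estimate exceeds the expectation and the attainment probability is below
50%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import Dataset
from .fpem_core import ModelConfig
from .indicators import round_half_away
from .inference import FitConfig, PosteriorDraws, fit
from .measurement_error import ErrorModelConfig

__all__ = [
    "AttainmentResult",
    "truncate_dataset",
    "attainment_probability",
    "classify_attainment",
    "progress_assessment",
    "eval_years",
    "run_counterfactual",
    "attainment_table",
]

GROUPS = ("LE25", "MID", "GE75")


@dataclass(frozen=True)
class AttainmentResult:
    """Counterfactual comparison for one country.

    ``gap_pp`` is the full-data median mCPR minus the counterfactual median
    in the evaluation year, in percentage points; ``gap_users`` the same
    difference scaled by the number of married/in-union women (persons).
    """

    country_code: str
    eval_year: int
    gap_pp: float
    gap_users: float
    attainment_prob: float
    group: str
    commitment: bool
    progress_positive: bool


def truncate_dataset(dataset: Dataset, cutoff_year: float = 2012.0) -> Dataset:
    """Drop observations whose start date is strictly after the cutoff.

    A survey whose reference period starts exactly at the cutoff is
    retained.  Service statistics are dropped on their observation year.
    Metadata and population counts are untouched.
    """
    return Dataset(
        surveys=[s for s in dataset.surveys if s.period_start <= cutoff_year],
        service_stats=[s for s in dataset.service_stats if s.year <= cutoff_year],
        meta=list(dataset.meta),
        populations=list(dataset.populations),
    )


def attainment_probability(cf_draws: np.ndarray, estimate: float) -> float:
    """Fraction of counterfactual draws at or above the full-data estimate."""
    cf_draws = np.asarray(cf_draws, dtype=float)
    if cf_draws.size == 0:
        raise ValueError("attainment probability needs at least one draw")
    return float(np.mean(cf_draws >= estimate))


def classify_attainment(p: float) -> str:
    """Report grouping: <=25%, 26-74%, >=75% attainment probability."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability outside [0, 1]: {p}")
    pct = 100.0 * p
    if pct <= 25.0:
        return "LE25"
    if pct >= 75.0:
        return "GE75"
    return "MID"


def progress_assessment(gap_pp: float, attainment_prob: float) -> bool:
    """Positive progress: estimate above expectation, attainment below 50%.

    Both inequalities are strict.
    """
    return gap_pp > 0.0 and attainment_prob < 0.5


def eval_years(dataset: Dataset) -> dict[str, int]:
    """Most recent observation year per country (latest period end).

    Service-statistic years count as observations.  Countries with no
    observations at all are omitted.
    """
    latest: dict[str, float] = {}
    for s in dataset.surveys:
        latest[s.country_code] = max(latest.get(s.country_code, -math.inf), s.period_end)
    for s in dataset.service_stats:
        latest[s.country_code] = max(latest.get(s.country_code, -math.inf), s.year)
    return {c: int(math.floor(y)) for c, y in latest.items()}


def run_counterfactual(
    dataset: Dataset,
    model_cfg: ModelConfig | None = None,
    fit_cfg: FitConfig | None = None,
    error_cfg: ErrorModelConfig | None = None,
    cutoff_year: float = 2012.0,
    full_draws: PosteriorDraws | None = None,
    cf_draws: PosteriorDraws | None = None,
    countries: Sequence[str] | None = None,
) -> list[AttainmentResult]:
    """Full pipeline: truncate, refit, and score every requested country.

    Precomputed posterior draws may be passed to avoid refitting (the
    truncated fit uses a spawned seed so the two fits are independent).
    ``countries`` defaults to those that lost observations to the
    truncation; when the cutoff postdates every observation that set is
    empty, so all countries are scored (the self-consistency case).
    """
    model_cfg = model_cfg or ModelConfig()
    fit_cfg = fit_cfg or FitConfig()
    truncated = truncate_dataset(dataset, cutoff_year)
    if full_draws is None:
        full_draws, _ = fit(dataset, model_cfg, fit_cfg, error_cfg)
    if cf_draws is None:
        cf_fit_cfg = replace(fit_cfg, seed=fit_cfg.seed + 1_000_003)
        cf_draws, _ = fit(truncated, model_cfg, cf_fit_cfg, error_cfg)

    if countries is None:
        kept = {(s.country_code, s.period_start) for s in truncated.surveys}
        lost = {
            s.country_code
            for s in dataset.surveys
            if (s.country_code, s.period_start) not in kept
        } | {
            s.country_code
            for s in dataset.service_stats
            if s.year > cutoff_year
        }
        countries = sorted(lost) if lost else list(dataset.countries())

    years = eval_years(dataset)
    commitment = {m.country_code: m.fp2020_commitment for m in dataset.meta}
    results = []
    for code in countries:
        year = years[code]
        yi = full_draws.year_index(year)
        ci = full_draws.country_index(code)
        est = float(np.median(full_draws.quantity("modern_cpr")[:, ci, yi]))
        cf = cf_draws.quantity("modern_cpr")[:, cf_draws.country_index(code), cf_draws.year_index(year)]
        cf_med = float(np.median(cf))
        prob = attainment_probability(cf, est)
        gap_pp = 100.0 * (est - cf_med)
        mwra = dataset.population(code, year)
        results.append(
            AttainmentResult(
                country_code=code,
                eval_year=year,
                gap_pp=gap_pp,
                gap_users=(est - cf_med) * mwra,
                attainment_prob=prob,
                group=classify_attainment(prob),
                commitment=commitment[code],
                progress_positive=progress_assessment(gap_pp, prob),
            )
        )
    results.sort(key=lambda r: (r.attainment_prob, -r.gap_pp))
    return results


def attainment_table(results: Sequence[AttainmentResult]) -> pd.DataFrame:
    """Report-shaped table, sorted by increasing attainment probability.

    Gaps are rounded to one decimal (percentage points; users in millions
    to two decimals) and probabilities to whole percent, the printed
    convention.
    """
    return pd.DataFrame.from_records(
        [
            {
                "country_code": r.country_code,
                "eval_year": r.eval_year,
                "gap_pp": round_half_away(r.gap_pp, 1),
                "gap_users_millions": round_half_away(r.gap_users / 1e6, 2),
                "attainment_prob_pct": int(round_half_away(100.0 * r.attainment_prob, 0)),
                "fp2020_commitment": r.commitment,
                "group": r.group,
                "progress_positive": r.progress_positive,
            }
            for r in results
        ]
    )
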