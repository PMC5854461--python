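"""Synthetic data generation.

Produces complete datasets with the statistical structure the estimation
model assumes: hierarchically shared logistic trends, AR(1) rate (and
level) distortions, sparse irregular surveys with source biases, sampling
and non-sampling noise and multi-year reference periods, service-statistic
(EMU) series with a country-level offset, and population counts.  Truth
parameters are drawn from the model's own priors, so a fit to generated
data is a draw from a self-consistent Bayesian experiment — posterior
intervals should attain their nominal coverage up to Monte Carlo error.

The ``fp2020_like`` scenario mirrors the scale of the multi-country survey
database behind the published analysis: 68 countries and roughly 730
survey events of contraceptive prevalence, just under two thirds of which
also record unmet need, plus ~85 service-statistic observations
concentrated in 13 countries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CountryMeta,
    Dataset,
    PopulationCount,
    ServiceStatObservation,
    SurveyObservation,
    SOURCE_TYPES,
)
from .fpem_core import ModelConfig
from .inference import QUANTITIES, SharedParams, _ar1_sample, _expit, _logit

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "gen_truth",
    "gen_observations",
    "gen_dataset",
    "make_scenario",
    "write_truth",
]


@dataclass
class ScenarioConfig:
    """Shape and noise settings of a synthetic study.

    Survey counts are per country, drawn uniformly on the inclusive range;
    each survey event yields a total-use and a modern-use row and, with
    probability ``p_unmet``, an unmet-need row.  ``source_mix`` must sum to
    one.  Reference periods last one year with probability 0.7 and two
    years otherwise.

    Sampling error follows survey practice: each survey has an effective
    sample size drawn uniformly on ``n_eff_range``, and the logit-scale
    sampling variance of an indicator is ``1 / (n_eff p (1 - p))`` (the
    delta-method image of a binomial proportion at the true level ``p``).
    The reported proportion-scale standard error encodes that design-based
    variance under the pipeline's logit convention — it equals the exact
    logit-scale SD mapped back through the delta method at the reported
    value — mirroring variance estimation from survey micro-data rather
    than a plug-in of the noisy point estimate.  DHS rows always carry
    their standard error, other sources omit theirs with probability
    ``p_missing_se``.
    """

    n_regions: int = 1
    n_subregions_per_region: int = 1
    n_countries_per_subregion: int = 3
    surveys_per_country: tuple[int, int] = (3, 5)
    obs_window: tuple[float, float] = (1978.0, 2017.0)
    p_two_year_period: float = 0.3
    p_unmet: float = 0.63
    source_mix: dict[str, float] = field(
        default_factory=lambda: {
            "DHS": 0.45,
            "MICS": 0.2,
            "PMA": 0.1,
            "RHS": 0.05,
            "NATIONAL": 0.15,
            "OTHER": 0.05,
        }
    )
    n_eff_range: tuple[float, float] = (1500.0, 8000.0)
    min_reported_prevalence: float = 0.01
    p_missing_se: float = 0.5
    n_emu_countries: int = 1
    emu_points: tuple[int, int] = (5, 8)
    emu_window: tuple[int, int] = (2008, 2016)
    emu_offset_sd: float = 0.3
    emu_noise_sd: float = 0.05
    p_commitment: float = 0.5
    mwra_log10_range: tuple[float, float] = (5.3, 7.3)
    mwra_growth_range: tuple[float, float] = (0.01, 0.03)
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if min(self.n_regions, self.n_subregions_per_region, self.n_countries_per_subregion) < 1:
            raise ValueError("hierarchy counts must be >= 1")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source mix proportions must sum to 1")

    @property
    def n_countries(self) -> int:
        return self.n_regions * self.n_subregions_per_region * self.n_countries_per_subregion


def _codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for i in range(n):
        out.append("Z" + letters[i // 26] + letters[i % 26])
    return out


@dataclass
class SyntheticTruth:
    """Everything the generator drew: parameters, paths and populations."""

    config: ScenarioConfig
    meta: list[CountryMeta]
    theta: np.ndarray  # (country, 7)
    world: np.ndarray
    region_means: dict[str, np.ndarray]
    subregion_means: dict[str, np.ndarray]
    sd_region: np.ndarray
    sd_subregion: np.ndarray
    sd_country: np.ndarray
    beta: float
    rho_eta: float
    tau_eta: float
    rho_unmet: float
    tau_unmet: float
    bias: dict[str, float]
    nonsampling_sd: dict[str, float]
    delta_eta: np.ndarray  # (country, T-1)
    delta_unmet: np.ndarray  # (country, T)
    values: np.ndarray  # (country, T, quantity) proportion scale
    populations: list[PopulationCount]
    seed: int

    @property
    def codes(self) -> list[str]:
        return [m.country_code for m in self.meta]

    @property
    def years(self) -> np.ndarray:
        return self.config.model.grid

    def true_value(self, code: str, quantity: str, year: int) -> float:
        c = self.codes.index(code)
        y = int(np.searchsorted(self.years, year))
        return float(self.values[c, y, QUANTITIES.index(quantity)])

    def shared_params(self) -> SharedParams:
        """The generating shared parameters, for frozen-globals fits."""
        return SharedParams(
            subregion_means=dict(self.subregion_means),
            sd_country=self.sd_country.copy(),
            beta=self.beta,
            rho_eta=self.rho_eta,
            tau_eta=self.tau_eta,
            rho_unmet=self.rho_unmet,
            tau_unmet=self.tau_unmet,
            bias=dict(self.bias),
            nonsampling_sd=dict(self.nonsampling_sd),
        )


def _halfnormal(rng: np.random.Generator, scale, size=None):
    return np.abs(rng.normal(0.0, scale, size=size))


def gen_truth(cfg: ScenarioConfig) -> SyntheticTruth:
    """Draw hierarchy, country parameters, distortions and populations."""
    mcfg = cfg.model
    root = np.random.Generator(np.random.Philox(np.random.SeedSequence([cfg.seed, 1])))
    grid = mcfg.grid
    T = grid.size

    m0, s0 = mcfg.world_mean_vector(), mcfg.world_sd_vector()
    lo, hi = _logit(np.array(mcfg.ptilde_bounds))
    world = m0 + s0 * root.standard_normal(7)
    while not (lo < world[0] < hi):
        world[0] = m0[0] + s0[0] * root.standard_normal()
    scales = mcfg.hier_scale_vector()
    sd_region = _halfnormal(root, scales)
    sd_subregion = _halfnormal(root, scales)
    sd_country = _halfnormal(root, scales)

    meta: list[CountryMeta] = []
    region_means: dict[str, np.ndarray] = {}
    subregion_means: dict[str, np.ndarray] = {}
    codes = _codes(cfg.n_countries)
    k = 0
    sub_names = []
    for r in range(cfg.n_regions):
        rname = f"Region {r + 1}"
        region_means[rname] = world + sd_region * root.standard_normal(7)
        for s in range(cfg.n_subregions_per_region):
            sname = f"Subregion {r + 1}.{s + 1}"
            sub_names.append(sname)
            subregion_means[sname] = region_means[rname] + sd_subregion * root.standard_normal(7)
            for _ in range(cfg.n_countries_per_subregion):
                code = codes[k]
                meta.append(
                    CountryMeta(
                        country_code=code,
                        name=f"Country {code}",
                        subregion=sname,
                        region=rname,
                        fp2020_commitment=bool(root.uniform() < cfg.p_commitment),
                    )
                )
                k += 1

    beta = float(root.normal(0.0, mcfg.beta_prior_sd))
    rho_eta = float(root.uniform(0.0, mcfg.rho_max))
    tau_eta = float(_halfnormal(root, mcfg.tau_prior_scale))
    rho_unmet = float(root.uniform(0.0, mcfg.rho_max))
    tau_unmet = float(_halfnormal(root, mcfg.tau_prior_scale))
    err_scale = 0.2  # matches the estimation priors for biases and non-sampling SDs
    bias = {s: 0.0 if s == "DHS" else float(root.normal(0.0, err_scale)) for s in SOURCE_TYPES}
    nonsampling_sd = {s: float(_halfnormal(root, err_scale)) for s in SOURCE_TYPES}

    C = cfg.n_countries
    theta = np.empty((C, 7))
    delta_eta = np.empty((C, T - 1))
    delta_unmet = np.empty((C, T))
    values = np.empty((C, T, len(QUANTITIES)))
    children = np.random.SeedSequence([cfg.seed, 2]).spawn(C)
    for c, m in enumerate(meta):
        crng = np.random.Generator(np.random.Philox(children[c]))
        th = subregion_means[m.subregion] + sd_country * crng.standard_normal(7)
        theta[c] = th
        delta_eta[c] = _ar1_sample(crng, T - 1, rho_eta, tau_eta)
        delta_unmet[c] = _ar1_sample(crng, T, rho_unmet, tau_unmet)
        curve = _expit(th[0]) * _expit(math.exp(th[1]) * (grid - th[2]))
        zc = _logit(curve)
        eta = zc[0] + np.concatenate(([0.0], np.cumsum(np.diff(zc) + delta_eta[c])))
        total = _expit(eta)
        share = _expit(th[3]) * _expit(math.exp(th[4]) * (grid - th[5]))
        modern = total * share
        unmet = (1.0 - total) * _expit(th[6] + beta * eta + delta_unmet[c])
        values[c, :, 0] = total
        values[c, :, 1] = modern
        values[c, :, 2] = total - modern
        values[c, :, 3] = unmet

    pops: list[PopulationCount] = []
    prng = np.random.Generator(np.random.Philox(np.random.SeedSequence([cfg.seed, 3])))
    for c, m in enumerate(meta):
        base = 10.0 ** prng.uniform(*cfg.mwra_log10_range)
        growth = prng.uniform(*cfg.mwra_growth_range)
        for y in grid:
            pops.append(
                PopulationCount(
                    country_code=m.country_code,
                    year=int(y),
                    mwra=float(round(base * (1.0 + growth) ** (int(y) - 2000))),
                )
            )

    return SyntheticTruth(
        config=cfg,
        meta=meta,
        theta=theta,
        world=world,
        region_means=region_means,
        subregion_means=subregion_means,
        sd_region=sd_region,
        sd_subregion=sd_subregion,
        sd_country=sd_country,
        beta=beta,
        rho_eta=rho_eta,
        tau_eta=tau_eta,
        rho_unmet=rho_unmet,
        tau_unmet=tau_unmet,
        bias=bias,
        nonsampling_sd=nonsampling_sd,
        delta_eta=delta_eta,
        delta_unmet=delta_unmet,
        values=values,
        populations=pops,
        seed=cfg.seed,
    )


def _period_average(truth: SyntheticTruth, c: int, q: int, start: float, end: float) -> float:
    grid = truth.years
    if end == start:
        w = ((grid <= start) & (start < grid + 1)).astype(float)
    else:
        w = np.clip(np.minimum(end, grid + 1) - np.maximum(start, grid), 0.0, None)
    w = w / w.sum()
    return float(w @ truth.values[c, :, q])


def gen_observations(truth: SyntheticTruth, cfg: ScenarioConfig | None = None) -> Dataset:
    """Sample surveys, EMU series and assemble a full dataset.

    Each survey's observed proportion is the period-averaged truth,
    perturbed on the logit scale by the source bias plus Normal noise with
    the observation's total error variance (delta-method sampling variance
    plus squared source non-sampling SD).
    """
    cfg = cfg or truth.config
    grid = truth.years
    root = np.random.Generator(np.random.Philox(np.random.SeedSequence([cfg.seed, 4])))
    sources = list(cfg.source_mix)
    probs = np.array([cfg.source_mix[s] for s in sources])
    surveys: list[SurveyObservation] = []
    service: list[ServiceStatObservation] = []

    children = np.random.SeedSequence([cfg.seed, 5]).spawn(len(truth.meta))
    emu_countries = set(
        root.choice(len(truth.meta), size=min(cfg.n_emu_countries, len(truth.meta)), replace=False)
    )
    q_idx = {q: i for i, q in enumerate(QUANTITIES)}
    for c, m in enumerate(truth.meta):
        rng = np.random.Generator(np.random.Philox(children[c]))
        n_surveys = int(rng.integers(cfg.surveys_per_country[0], cfg.surveys_per_country[1] + 1))
        starts = np.sort(rng.uniform(cfg.obs_window[0], cfg.obs_window[1], size=n_surveys))
        for t0 in starts:
            # mid-year placement; one- or two-year fieldwork periods
            y0 = math.floor(t0) + 0.5
            length = 2 if rng.uniform() < cfg.p_two_year_period else 1
            y1 = min(y0 + (length - 1), grid[-1] + 0.5)
            source = sources[int(rng.choice(len(sources), p=probs))]
            indicators = ["total_cpr", "modern_cpr"]
            if rng.uniform() < cfg.p_unmet:
                indicators.append("unmet_any")
            n_eff = float(rng.uniform(*cfg.n_eff_range))
            for indicator in indicators:
                p_true = _period_average(truth, c, q_idx[indicator], y0, y1)
                if p_true < cfg.min_reported_prevalence:
                    # reporting floor: compiled prevalence databases do not
                    # carry sub-percent entries
                    continue
                v_samp = 1.0 / (n_eff * p_true * (1.0 - p_true))
                v_total = v_samp + truth.nonsampling_sd[source] ** 2
                z = (
                    _logit(np.array(p_true))
                    + truth.bias[source]
                    + math.sqrt(v_total) * rng.standard_normal()
                )
                missing = source != "DHS" and rng.uniform() < cfg.p_missing_se
                # measurement floor: reported proportions stay strictly inside
                # (0, 1) even when the latent level is vanishingly small
                value = float(np.clip(_expit(np.array(z)), 1e-6, 1.0 - 1e-6))
                se = math.sqrt(v_samp) * value * (1.0 - value)
                surveys.append(
                    SurveyObservation(
                        country_code=m.country_code,
                        indicator=indicator,
                        value=value,
                        source_type=source,
                        period_start=y0,
                        period_end=y1,
                        sampling_se=None if missing else se,
                    )
                )
        if c in emu_countries:
            n_pts = int(rng.integers(cfg.emu_points[0], cfg.emu_points[1] + 1))
            y_hi = min(cfg.emu_window[1], int(grid[-1]))
            y_start = int(rng.integers(cfg.emu_window[0], max(cfg.emu_window[0], y_hi - n_pts + 1) + 1))
            offset = rng.normal(0.0, cfg.emu_offset_sd)
            for y in range(y_start, min(y_start + n_pts, y_hi + 1)):
                yi = int(np.searchsorted(grid, y))
                z = (
                    _logit(np.array(truth.values[c, yi, q_idx["modern_cpr"]]))
                    + offset
                    + rng.normal(0.0, cfg.emu_noise_sd)
                )
                service.append(
                    ServiceStatObservation(
                        country_code=m.country_code,
                        year=y + 0.5,
                        emu=float(np.clip(_expit(np.array(z)), 1e-6, 1.0 - 1e-6)),
                    )
                )

    return Dataset(
        surveys=surveys,
        service_stats=service,
        meta=list(truth.meta),
        populations=list(truth.populations),
    )


def gen_dataset(cfg: ScenarioConfig) -> tuple[Dataset, SyntheticTruth]:
    truth = gen_truth(cfg)
    return gen_observations(truth, cfg), truth


def make_scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Named study shapes: ``tiny`` (smoke tests), ``small`` (16 countries),
    ``fp2020_like`` (the scale of the published database)."""
    if name == "tiny":
        return ScenarioConfig(seed=seed)
    if name == "small":
        return ScenarioConfig(
            n_regions=2,
            n_subregions_per_region=2,
            n_countries_per_subregion=4,
            surveys_per_country=(4, 8),
            n_emu_countries=4,
            seed=seed,
        )
    if name == "fp2020_like":
        # survey and unmet-need rates chosen so that, net of sub-percent
        # censoring, retained observations number ~733 (prevalence) and
        # ~462 (unmet need) as in the database
        return ScenarioConfig(
            n_regions=2,
            n_subregions_per_region=2,
            n_countries_per_subregion=17,
            surveys_per_country=(11, 17),
            p_unmet=0.5,
            n_emu_countries=13,
            seed=seed,
        )
    raise KeyError(f"unknown scenario {name!r}")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Tidy CSV of the true indicator paths, for recovery checks."""
    grid = truth.years
    rows = []
    for c, code in enumerate(truth.codes):
        for yi, y in enumerate(grid):
            for qi, q in enumerate(QUANTITIES):
                rows.append((code, int(y), q, truth.values[c, yi, qi]))
    pd.DataFrame(rows, columns=["country_code", "year", "quantity", "value"]).to_csv(
        path, index=False
    )
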