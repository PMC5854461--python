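"""Latent process and joint posterior of the family planning estimation model.

For each country the total contraceptive prevalence follows, on the logit
scale, the expected path of a logistic growth curve (slow uptake, rapid
mid-transition growth, saturation below an asymptote) perturbed by an AR(1)
series of *rate-of-change* distortions: the year-on-year logit increments of
the latent path equal the increments of the expected curve plus a
stationary AR(1) term.  Modern-method use is the product of total use and a
logistic modern-share curve.  Unmet need is modelled among non-users, with
a country intercept, a global slope on the logit of total prevalence, and
AR(1) *level* distortions.

Observations enter on the logit scale after averaging the relevant
proportion over the integer grid years intersecting the survey's reference
period; service statistics (EMU) inform first differences of logit modern
prevalence so that a constant level bias cancels.

Curve parameters are shared hierarchically: country values are drawn around
subregion means, subregion means around region means, and region means
around a world mean, with an unknown standard deviation at each level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import Dataset, SOURCE_TYPES
from .measurement_error import (
    ErrorModelConfig,
    TransformedObservation,
    prepare_observations,
)

__all__ = [
    "PARAM_NAMES",
    "ModelConfig",
    "LogisticParams",
    "ModernShareParams",
    "UnmetParams",
    "ARParams",
    "CountryParams",
    "HierarchyParams",
    "ModelParams",
    "CountryTrajectory",
    "logistic_curve",
    "expected_increments",
    "ar1_logdensity",
    "build_trajectory",
    "trajectory_proportions",
    "period_weights",
    "observation_loglik",
    "service_stat_loglik",
    "joint_logposterior",
    "flag_outliers",
    "normal_logpdf",
    "halfnormal_logpdf",
]

#: transformed country-level parameter vector, in this order
PARAM_NAMES = (
    "logit_ptilde",  # logit of total-prevalence asymptote
    "log_omega",     # log growth rate of total prevalence (per year)
    "Omega",         # midpoint year of the total-prevalence transition
    "logit_rtilde",  # logit of asymptotic modern share
    "log_psi",       # log growth rate of the modern share
    "Xi",            # midpoint year of the modern-share transition
    "alpha",         # country intercept of unmet need among non-users (logit)
)

LOG2PI = math.log(2.0 * math.pi)


def normal_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * LOG2PI


def halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        0.5 * math.log(2.0 / math.pi) - np.log(scale) - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    # numerically stable on both tails
    out = np.empty_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Grid bounds and prior hyperparameters.

    Defaults are declared choices, all overridable: world-mean priors for
    the transformed country parameters; half-normal scales for the
    hierarchy standard deviations (0.5 on logit/log-scale parameters, 5
    calendar years for the two midpoint years); a Uniform(0, 0.95) prior
    for the AR autocorrelations and half-normal(0.1) for the stationary
    AR standard deviations; N(0, 0.5^2) for the slope linking unmet need
    to total prevalence.  The total-prevalence asymptote is kept inside
    ``ptilde_bounds`` at the world level.
    """

    year_start: int = 1970
    year_end: int = 2030
    world_prior_mean: dict[str, float] = field(
        default_factory=lambda: {
            "logit_ptilde": 0.5,
            "log_omega": math.log(0.1),
            "Omega": 2000.0,
            "logit_rtilde": 0.5,
            "log_psi": math.log(0.1),
            "Xi": 2000.0,
            "alpha": 0.0,
        }
    )
    world_prior_sd: dict[str, float] = field(
        default_factory=lambda: {
            "logit_ptilde": 1.0,
            "log_omega": 0.5,
            "Omega": 10.0,
            "logit_rtilde": 1.0,
            "log_psi": 0.5,
            "Xi": 10.0,
            "alpha": 1.0,
        }
    )
    hier_sd_scale: dict[str, float] = field(
        default_factory=lambda: {
            "logit_ptilde": 0.5,
            "log_omega": 0.5,
            "Omega": 5.0,
            "logit_rtilde": 0.5,
            "log_psi": 0.5,
            "Xi": 5.0,
            "alpha": 0.5,
        }
    )
    ptilde_bounds: tuple[float, float] = (0.1, 0.95)
    rho_max: float = 0.95
    tau_prior_scale: float = 0.1
    beta_prior_sd: float = 0.5
    outlier_screen: bool = False

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def world_mean_vector(self) -> np.ndarray:
        return np.array([self.world_prior_mean[n] for n in PARAM_NAMES])

    def world_sd_vector(self) -> np.ndarray:
        return np.array([self.world_prior_sd[n] for n in PARAM_NAMES])

    def hier_scale_vector(self) -> np.ndarray:
        return np.array([self.hier_sd_scale[n] for n in PARAM_NAMES])


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticParams:
    """Logistic trend of total prevalence: asymptote, rate, midpoint year."""

    p_tilde: float
    omega: float
    Omega: float

    def __post_init__(self):
        if not (0.0 < self.p_tilde < 1.0):
            raise ValueError(f"asymptote must lie in (0, 1), got {self.p_tilde}")
        if not self.omega > 0:
            raise ValueError(f"growth rate must be positive, got {self.omega}")


@dataclass(frozen=True)
class ModernShareParams:
    """Logistic trend of the modern share of total use."""

    r_tilde: float
    psi: float
    Xi: float

    def __post_init__(self):
        if not (0.0 < self.r_tilde < 1.0):
            raise ValueError(f"asymptote must lie in (0, 1), got {self.r_tilde}")
        if not self.psi > 0:
            raise ValueError(f"growth rate must be positive, got {self.psi}")


@dataclass(frozen=True)
class UnmetParams:
    """Unmet need among non-users: country intercept and global slope."""

    alpha_c: float
    beta: float


@dataclass(frozen=True)
class ARParams:
    rho: float
    tau: float

    def __post_init__(self):
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class CountryParams:
    logistic: LogisticParams
    share: ModernShareParams
    unmet: UnmetParams

    def theta(self) -> np.ndarray:
        """Transformed parameter vector in ``PARAM_NAMES`` order."""
        return np.array(
            [
                _logit(self.logistic.p_tilde),
                math.log(self.logistic.omega),
                self.logistic.Omega,
                _logit(self.share.r_tilde),
                math.log(self.share.psi),
                self.share.Xi,
                self.unmet.alpha_c,
            ]
        )

    @staticmethod
    def from_theta(theta: np.ndarray, beta: float) -> "CountryParams":
        return CountryParams(
            logistic=LogisticParams(
                p_tilde=float(_expit(np.asarray(theta[0]))),
                omega=math.exp(theta[1]),
                Omega=float(theta[2]),
            ),
            share=ModernShareParams(
                r_tilde=float(_expit(np.asarray(theta[3]))),
                psi=math.exp(theta[4]),
                Xi=float(theta[5]),
            ),
            unmet=UnmetParams(alpha_c=float(theta[6]), beta=beta),
        )


@dataclass
class HierarchyParams:
    """Current values of the hierarchical means and level SDs (7-vectors)."""

    world: np.ndarray
    region: dict[str, np.ndarray]
    subregion: dict[str, np.ndarray]
    sd_region: np.ndarray
    sd_subregion: np.ndarray
    sd_country: np.ndarray


@dataclass
class ModelParams:
    """Everything except the distortion series: country curve parameters,
    hierarchy, AR parameters and the measurement-error parameters."""

    countries: dict[str, CountryParams]
    hierarchy: HierarchyParams
    ar_eta: ARParams
    ar_unmet: ARParams
    error: ErrorModelConfig


@dataclass
class CountryTrajectory:
    """Annual latent paths on the logit scale.

    ``eta``: logit total prevalence; ``s``: logit modern share;
    ``u``: logit unmet need among non-users.
    """

    grid: np.ndarray
    eta: np.ndarray
    s: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        if not (np.diff(self.grid) == 1).all():
            raise ValueError("grid years must be contiguous integers")


# ---------------------------------------------------------------------------
# latent process
# ---------------------------------------------------------------------------

def logistic_curve(t, params: LogisticParams):
    """Expected total prevalence at decimal year(s) ``t``."""
    t = np.asarray(t, dtype=float)
    out = params.p_tilde * _expit(params.omega * (t - params.Omega))
    return float(out) if out.ndim == 0 else out


def share_curve(t, params: ModernShareParams):
    """Expected modern share of total use at decimal year(s) ``t``."""
    t = np.asarray(t, dtype=float)
    out = params.r_tilde * _expit(params.psi * (t - params.Xi))
    return float(out) if out.ndim == 0 else out


def expected_increments(params: LogisticParams, grid: np.ndarray) -> np.ndarray:
    """Year-on-year increments of the expected curve on the logit scale."""
    grid = np.asarray(grid)
    if not (np.diff(grid) == 1).all():
        raise ValueError("grid years must be contiguous integers")
    z = _logit(logistic_curve(grid, params))
    return np.diff(z)


def ar1_logdensity(delta: np.ndarray, ar: ARParams) -> float:
    """Log density of a stationary AR(1) series.

    ``delta[0] ~ N(0, tau^2)`` and
    ``delta[t+1] | delta[t] ~ N(rho * delta[t], tau^2 (1 - rho^2))``.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        return 0.0
    ll = float(normal_logpdf(delta[0], 0.0, ar.tau))
    if delta.size > 1:
        sd = ar.tau * math.sqrt(1.0 - ar.rho**2)
        ll += float(np.sum(normal_logpdf(delta[1:], ar.rho * delta[:-1], sd)))
    return ll


def build_trajectory(
    params: LogisticParams,
    share: ModernShareParams,
    unmet: UnmetParams,
    delta_eta: np.ndarray,
    delta_u: np.ndarray,
    grid: np.ndarray,
) -> CountryTrajectory:
    """Assemble the three latent paths from parameters and distortions.

    The total-prevalence path starts on the expected curve at the first
    grid year and accumulates expected increments plus rate distortions
    (``len(delta_eta) == len(grid) - 1``); unmet need receives one level
    distortion per grid year.
    """
    grid = np.asarray(grid)
    delta_eta = np.asarray(delta_eta, dtype=float)
    delta_u = np.asarray(delta_u, dtype=float)
    if delta_eta.shape != (grid.size - 1,):
        raise ValueError(
            f"delta_eta must have length {grid.size - 1}, got {delta_eta.size}"
        )
    if delta_u.shape != (grid.size,):
        raise ValueError(f"delta_u must have length {grid.size}, got {delta_u.size}")
    eta0 = _logit(logistic_curve(grid[0], params))
    eta = eta0 + np.concatenate(
        ([0.0], np.cumsum(expected_increments(params, grid) + delta_eta))
    )
    s = _logit(share_curve(grid, share))
    u = unmet.alpha_c + unmet.beta * eta + delta_u
    return CountryTrajectory(grid=grid, eta=eta, s=s, u=u)


def trajectory_proportions(traj: CountryTrajectory) -> dict[str, np.ndarray]:
    """Proportion-scale indicator paths implied by a trajectory.

    ``unmet_any`` is unmet need among *all* women: the share of non-users
    times unmet need among non-users, which keeps
    ``total_cpr + unmet_any <= 1`` by construction.
    """
    total = _expit(traj.eta)
    share = _expit(traj.s)
    q = _expit(traj.u)
    modern = total * share
    return {
        "total_cpr": total,
        "modern_cpr": modern,
        "trad_cpr": total - modern,
        "unmet_any": (1.0 - total) * q,
    }


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def period_weights(grid: np.ndarray, start: float, end: float) -> np.ndarray:
    """Fractional-year overlap of [start, end] with each interval [Y, Y+1).

    Weights are normalised to sum to one.  A degenerate period (start ==
    end) puts all weight on the year interval containing the point.
    """
    grid = np.asarray(grid)
    if end < start:
        raise ValueError("period_end before period_start")
    if start < grid[0] or end >= grid[-1] + 1:
        raise ValueError(
            f"reference period [{start}, {end}] outside grid "
            f"[{grid[0]}, {grid[-1] + 1})"
        )
    if end == start:
        w = ((grid <= start) & (start < grid + 1)).astype(float)
    else:
        w = np.clip(np.minimum(end, grid + 1) - np.maximum(start, grid), 0.0, None)
    return w / w.sum()


def observation_loglik(
    obs: TransformedObservation,
    traj: CountryTrajectory,
    cfg: ErrorModelConfig,
) -> float:
    """Normal log likelihood of one survey observation.

    The model value is the overlap-weighted average of the relevant
    indicator on the proportion scale over the grid years intersecting the
    reference period, taken to the logit scale and shifted by the source
    bias; the variance is the observation's total error variance.
    """
    w = period_weights(traj.grid, obs.base.period_start, obs.base.period_end)
    series = trajectory_proportions(traj)[obs.base.indicator]
    mu = float(_logit(np.asarray(w @ series))) + cfg.bias[obs.base.source_type]
    return float(normal_logpdf(obs.z, mu, math.sqrt(obs.v_total)))


def service_stat_loglik(
    years: Sequence[float],
    emu: Sequence[float],
    traj: CountryTrajectory,
    variance_emu: float,
) -> float:
    """Log likelihood of a country's EMU series via first differences.

    First differences of logit EMU are modelled as Normal around the first
    differences of logit modern prevalence at the corresponding grid years,
    so any constant level offset of the service statistics cancels.  Fewer
    than two points carry no information and contribute zero.
    """
    years = np.asarray(years, dtype=float)
    emu = np.asarray(emu, dtype=float)
    if years.size < 2:
        import logging

        logging.getLogger(__name__).warning(
            "service-statistic series with < 2 points contributes no information"
        )
        return 0.0
    order = np.argsort(years)
    years, emu = years[order], emu[order]
    idx = np.searchsorted(traj.grid, np.floor(years).astype(int))
    modern = trajectory_proportions(traj)["modern_cpr"]
    d_model = np.diff(_logit(modern[idx]))
    d_obs = np.diff(_logit(emu))
    return float(np.sum(normal_logpdf(d_obs, d_model, math.sqrt(variance_emu))))


# ---------------------------------------------------------------------------
# joint posterior
# ---------------------------------------------------------------------------

def _hierarchy_logprior(params: ModelParams, data: Dataset, cfg: ModelConfig) -> float:
    h = params.hierarchy
    lp = 0.0
    # world means
    m0, s0 = cfg.world_mean_vector(), cfg.world_sd_vector()
    lo, hi = cfg.ptilde_bounds
    pt = float(_expit(np.asarray(h.world[0])))
    if not (lo < pt < hi):
        return -math.inf
    lp += float(np.sum(normal_logpdf(h.world, m0, s0)))
    # level SDs
    scales = cfg.hier_scale_vector()
    for sd in (h.sd_region, h.sd_subregion, h.sd_country):
        v = halfnormal_logpdf(sd, scales)
        if not np.all(np.isfinite(v)):
            return -math.inf
        lp += float(np.sum(v))
    # region and subregion means
    sub_region = {m.subregion: m.region for m in data.meta}
    for r, vec in h.region.items():
        lp += float(np.sum(normal_logpdf(vec, h.world, h.sd_region)))
    for s, vec in h.subregion.items():
        lp += float(np.sum(normal_logpdf(vec, h.region[sub_region[s]], h.sd_subregion)))
    # country parameters
    sub_of = {m.country_code: m.subregion for m in data.meta}
    for c, cp in params.countries.items():
        lp += float(
            np.sum(normal_logpdf(cp.theta(), h.subregion[sub_of[c]], h.sd_country))
        )
    return lp


def _global_logprior(params: ModelParams, cfg: ModelConfig) -> float:
    lp = 0.0
    beta = next(iter(params.countries.values())).unmet.beta
    lp += float(normal_logpdf(beta, 0.0, cfg.beta_prior_sd))
    for ar in (params.ar_eta, params.ar_unmet):
        if not (0.0 <= ar.rho <= cfg.rho_max):
            return -math.inf
        lp += -math.log(cfg.rho_max)  # Uniform(0, rho_max)
        lp += float(halfnormal_logpdf(ar.tau, cfg.tau_prior_scale))
    err = params.error
    for s in SOURCE_TYPES:
        if s != "DHS":
            lp += float(normal_logpdf(err.bias[s], 0.0, err.bias_prior_sd))
        v = float(halfnormal_logpdf(err.nonsampling_sd[s], err.nonsampling_prior_scale))
        if not math.isfinite(v):
            return -math.inf
        lp += v
    return lp


def joint_logposterior(
    params: ModelParams,
    distortions: Mapping[str, tuple[np.ndarray, np.ndarray]],
    data: Dataset,
    cfg: ModelConfig,
) -> float:
    """Unnormalised joint log posterior of the full model.

    ``distortions`` maps country codes to ``(delta_eta, delta_u)``.  The sum
    comprises the hierarchical priors, the priors on the global parameters,
    the AR(1) log densities of every distortion series, and the survey and
    service-statistic log likelihoods.
    """
    lp = _hierarchy_logprior(params, data, cfg) + _global_logprior(params, cfg)
    if not math.isfinite(lp):
        return -math.inf
    grid = cfg.grid
    trajectories = {}
    for c, cp in params.countries.items():
        de, du = distortions[c]
        lp += ar1_logdensity(de, params.ar_eta)
        lp += ar1_logdensity(du, params.ar_unmet)
        trajectories[c] = build_trajectory(cp.logistic, cp.share, cp.unmet, de, du, grid)
    for obs in prepare_observations(data, params.error):
        lp += observation_loglik(obs, trajectories[obs.base.country_code], params.error)
    by_country: dict[str, list] = {}
    for s in data.service_stats:
        by_country.setdefault(s.country_code, []).append(s)
    for c, series in by_country.items():
        lp += service_stat_loglik(
            [s.year for s in series],
            [s.emu for s in series],
            trajectories[c],
            params.error.emu_variance,
        )
    return lp


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

def flag_outliers(
    observed_value: float, projection_mean: float, projection_sd: float
) -> bool:
    """Two-standard-deviation screen against a projected trend.

    Flags an observation whose distance from the projected mean *strictly*
    exceeds two projection standard deviations; a value at exactly two
    standard deviations is retained.
    """
    if projection_sd <= 0:
        raise ValueError(f"projection SD must be positive, got {projection_sd}")
    return abs(observed_value - projection_mean) > 2.0 * projection_sd
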