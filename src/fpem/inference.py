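"""Markov chain Monte Carlo fitting of the joint model.

The posterior defined in :mod:`fpem.fpem_core` is sampled with a
block-updating scheme tailored to the model's structure:

* country curve-parameter vectors (7 transformed scalars each) move by
  adaptive random-walk Metropolis with a per-country proposal covariance
  learned during warmup;
* the Gaussian AR(1) distortion series are updated by elliptical slice
  sampling, which proposes from the exact AR(1) prior and therefore mixes
  well regardless of the prior autocorrelation;
* hierarchical means are conjugate normal draws; hierarchy standard
  deviations, AR parameters, the unmet-need slope and the non-sampling
  error SDs use univariate slice sampling; source biases are conjugate.

Chains are run sequentially from independently spawned random streams, so
results are bitwise reproducible for a given seed, configuration and data.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from numba import njit
from scipy.signal import lfilter
from scipy.special import expit as _sp_expit
from scipy.stats import truncnorm

from .data_io import Dataset, INDICATORS, SOURCE_TYPES, validate_dataset
from .fpem_core import (
    LOG2PI,
    ModelConfig,
    PARAM_NAMES,
    period_weights,
)
from .measurement_error import ErrorModelConfig, prepare_observations

__all__ = [
    "FitConfig",
    "SharedParams",
    "PosteriorDraws",
    "Diagnostics",
    "fit",
    "check_convergence",
]

logger = logging.getLogger(__name__)

QUANTITIES = INDICATORS  # ("total_cpr", "modern_cpr", "trad_cpr", "unmet_any")

@dataclass
class SharedParams:
    """Fixed values for every parameter shared across countries.

    When supplied through :class:`FitConfig`, these parameters are held
    constant instead of being sampled, making country posteriors exactly
    independent of each other's data.  Used for debugging and for the
    leave-one-country-out invariance check.
    """

    subregion_means: dict[str, np.ndarray]  # 7-vector per subregion
    sd_country: np.ndarray  # 7-vector
    beta: float
    rho_eta: float
    tau_eta: float
    rho_unmet: float
    tau_unmet: float
    bias: dict[str, float]
    nonsampling_sd: dict[str, float]


@dataclass
class FitConfig:
    """MCMC settings.  ``seed`` drives every source of randomness."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0
    shared: SharedParams | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_warmup < 1 or self.n_samples < 1:
            raise ValueError("chain, warmup and sample counts must be positive")

    @classmethod
    def for_tests(cls, seed: int = 0) -> "FitConfig":
        return cls(n_chains=2, n_warmup=500, n_samples=500, seed=seed)


@dataclass
class Diagnostics:
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


@dataclass
class PosteriorDraws:
    """Posterior draws of the four indicator paths, on the proportion scale.

    ``values`` has shape ``(chain, draw, country, year, quantity)`` with the
    quantity axis ordered as :data:`QUANTITIES`; ``params`` holds scalar
    parameter chains of shape ``(chain, draw)`` for diagnostics.
    """

    countries: list[str]
    years: np.ndarray
    values: np.ndarray
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c, d, nc, ny, nq = self.values.shape
        assert nc == len(self.countries) and ny == self.years.size and nq == len(QUANTITIES)

    @property
    def n_draws(self) -> int:
        return self.values.shape[0] * self.values.shape[1]

    def stacked(self) -> np.ndarray:
        """Chains pooled: shape (draw, country, year, quantity)."""
        s = self.values.shape
        return self.values.reshape(s[0] * s[1], s[2], s[3], s[4])

    def quantity(self, name: str) -> np.ndarray:
        """Pooled draws of one quantity: shape (draw, country, year)."""
        return self.stacked()[..., QUANTITIES.index(name)]

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(f"year {year} not on the estimation grid")
        return idx

    def country_index(self, code: str) -> int:
        return self.countries.index(code)

    def to_frame(self):
        """Tidy draws table (draw, country_code, year, quantity, value)."""
        import pandas as pd

        flat = self.stacked()
        n, nc, ny, nq = flat.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.countries, self.years, QUANTITIES],
            names=["draw", "country_code", "year", "quantity"],
        )
        return pd.DataFrame({"value": flat.ravel()}, index=idx).reset_index()


# ---------------------------------------------------------------------------
# vectorised numerics
# ---------------------------------------------------------------------------

def _expit(x):
    # scipy's ufunc: accurate in both tails (underflows only below ~ -745)
    return _sp_expit(x)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _ar1_sample(rng: np.random.Generator, n: int, rho: float, tau: float) -> np.ndarray:
    """Exact draw from the stationary AR(1) prior."""
    e = rng.standard_normal(n)
    innov = np.empty(n)
    innov[0] = tau * e[0]
    innov[1:] = tau * math.sqrt(1.0 - rho**2) * e[1:]
    return lfilter([1.0], [1.0, -rho], innov)


def _ar1_ll_rows(d: np.ndarray, rho: float, tau: float) -> float:
    """Sum of stationary AR(1) log densities over the rows of ``d``."""
    if d.size == 0:
        return 0.0
    n_rows = d.shape[0]
    ll = -0.5 * np.sum((d[:, 0] / tau) ** 2) - n_rows * (math.log(tau) + 0.5 * LOG2PI)
    if d.shape[1] > 1:
        sd = tau * math.sqrt(1.0 - rho**2)
        resid = d[:, 1:] - rho * d[:, :-1]
        ll += -0.5 * np.sum((resid / sd) ** 2) - resid.size * (
            math.log(sd) + 0.5 * LOG2PI
        )
    return float(ll)


def _slice1d(
    x0: float,
    logf: Callable[[float], float],
    rng: np.random.Generator,
    width: float,
    lo: float = -np.inf,
    hi: float = np.inf,
    max_steps: int = 12,
    f0: float | None = None,
) -> float:
    """Univariate slice sampler with stepping out (Neal 2003).

    ``f0`` may supply the (often cached) log density at ``x0`` to save one
    evaluation.
    """
    if f0 is None:
        f0 = logf(x0)
    logy = f0 + math.log(max(rng.uniform(), 1e-300))
    left = x0 - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if left <= lo or logf(max(left, lo)) <= logy:
            break
        left -= width
    for _ in range(max_steps):
        if right >= hi or logf(min(right, hi)) <= logy:
            break
        right += width
    left, right = max(left, lo), min(right, hi)
    for _ in range(100):
        x = rng.uniform(left, right)
        if logf(x) > logy:
            return x
        if x < x0:
            left = x
        else:
            right = x
    return x0  # pathological shrinkage; keep current value




# ---------------------------------------------------------------------------
# compiled likelihood kernel
# ---------------------------------------------------------------------------

_TINY = 1e-14


@njit(cache=True)
def _softplus(x: float) -> float:
    # log(1 + e^x), stable in both tails
    if x > 35.0:
        return x
    if x < -35.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


@njit(cache=True)
def _expit_s(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _paths_kernel(grid, theta, de, du, beta):
    """Indicator paths (4, T), proportion scale, clipped inside (0, 1)."""
    T = grid.shape[0]
    om = math.exp(theta[1])
    ps = math.exp(theta[4])
    sp0 = _softplus(-theta[0])
    zc_prev = 0.0
    eta = np.empty(T)
    for t in range(T):
        lc = -sp0 - _softplus(-om * (grid[t] - theta[2]))
        zc = lc - math.log1p(-math.exp(lc))
        if t == 0:
            eta[0] = zc
        else:
            eta[t] = eta[t - 1] + (zc - zc_prev) + de[t - 1]
        zc_prev = zc
    sh_asym = _expit_s(theta[3])
    P = np.empty((4, T))
    for t in range(T):
        tot = _expit_s(eta[t])
        if tot < _TINY:
            tot = _TINY
        elif tot > 1.0 - _TINY:
            tot = 1.0 - _TINY
        share = sh_asym * _expit_s(ps * (grid[t] - theta[5]))
        if share < _TINY:
            share = _TINY
        elif share > 1.0 - _TINY:
            share = 1.0 - _TINY
        mod = tot * share
        un = (1.0 - tot) * _expit_s(theta[6] + beta * eta[t] + du[t])
        if un < _TINY:
            un = _TINY
        P[0, t] = tot
        P[1, t] = mod
        P[2, t] = tot - mod
        P[3, t] = un
    return P


@njit(cache=True)
def _ll_kernel(
    grid, theta, de, du, beta,
    W, w_lo, w_hi, ind, z, v_samp, src,
    bias, nssd, emu_pos, emu_dz, emu_var,
):
    """Country log likelihood plus survey and EMU residuals."""
    P = _paths_kernel(grid, theta, de, du, beta)
    n = z.shape[0]
    r = np.empty(n)
    ll = 0.0
    for i in range(n):
        mv = 0.0
        q = ind[i]
        for t in range(w_lo[i], w_hi[i]):
            mv += W[i, t] * P[q, t]
        ri = z[i] - (math.log(mv) - math.log1p(-mv))
        r[i] = ri
        e = ri - bias[src[i]]
        v = v_samp[i] + nssd[src[i]] * nssd[src[i]]
        ll += -0.5 * (e * e / v + math.log(v) + 1.8378770664093453)
    m = emu_pos.shape[0]
    n_emu = m - 1 if m >= 2 else 0
    remu = np.empty(n_emu)
    for k in range(n_emu):
        a = P[1, emu_pos[k]]
        b = P[1, emu_pos[k + 1]]
        dmod = (math.log(b) - math.log1p(-b)) - (math.log(a) - math.log1p(-a))
        rr = emu_dz[k] - dmod
        remu[k] = rr
        ll += -0.5 * (rr * rr / emu_var + math.log(emu_var) + 1.8378770664093453)
    return ll, r, remu


# ---------------------------------------------------------------------------
# prepared data
# ---------------------------------------------------------------------------

class _CountryData:
    __slots__ = (
        "code", "sub", "z", "v_samp", "src", "ind", "W", "w_lo", "w_hi",
        "emu_pos", "emu_dz", "n_obs",
    )

    def __init__(self, code, sub, z, v_samp, src, ind, W, emu_pos, emu_dz):
        self.code = code
        self.sub = sub
        self.z = z
        self.v_samp = v_samp
        self.src = np.ascontiguousarray(src)
        self.ind = np.ascontiguousarray(ind)
        self.W = np.ascontiguousarray(W)
        # each weight row is non-zero on a short consecutive run of years
        nz = W > 0
        self.w_lo = np.array(
            [int(np.argmax(row)) if row.any() else 0 for row in nz], dtype=np.int64
        )
        self.w_hi = np.array(
            [int(len(row) - np.argmax(row[::-1])) if row.any() else 0 for row in nz],
            dtype=np.int64,
        )
        self.emu_pos = np.ascontiguousarray(emu_pos, dtype=np.int64)
        self.emu_dz = np.ascontiguousarray(emu_dz)
        self.n_obs = z.size


def _prepare(data: Dataset, model_cfg: ModelConfig, error_cfg: ErrorModelConfig):
    grid = model_cfg.grid
    obs = prepare_observations(data, error_cfg)
    per_country: dict[str, list] = {c: [] for c in data.countries()}
    for o in obs:
        per_country[o.base.country_code].append(o)
    emu_by_country: dict[str, list] = {}
    for s in data.service_stats:
        emu_by_country.setdefault(s.country_code, []).append(s)

    sub_of = {m.country_code: m.subregion for m in data.meta}
    out = []
    for code in data.countries():
        rows = per_country[code]
        z = np.array([o.z for o in rows])
        v = np.array([o.v_sampling for o in rows])
        src = np.array([SOURCE_TYPES.index(o.base.source_type) for o in rows], dtype=int)
        ind = np.array([INDICATORS.index(o.base.indicator) for o in rows], dtype=int)
        W = np.zeros((len(rows), grid.size))
        for i, o in enumerate(rows):
            W[i] = period_weights(grid, o.base.period_start, o.base.period_end)
        series = sorted(emu_by_country.get(code, []), key=lambda s: s.year)
        if len(series) >= 2:
            pos = np.searchsorted(grid, np.floor([s.year for s in series]).astype(int))
            dz = np.diff(_logit(np.array([s.emu for s in series])))
        else:
            if len(series) == 1:
                logger.warning(
                    "country %s has a single service-statistic point; it carries "
                    "no information under the first-difference model",
                    code,
                )
            pos = np.empty(0, dtype=int)
            dz = np.empty(0)
        out.append(_CountryData(code, sub_of[code], z, v, src, ind, W, pos, dz))
    return out


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Sampler:
    def __init__(
        self,
        data: Dataset,
        model_cfg: ModelConfig,
        fit_cfg: FitConfig,
        error_cfg: ErrorModelConfig,
        rng: np.random.Generator,
    ):
        self.cfg = model_cfg
        self.fit_cfg = fit_cfg
        self.rng = rng
        self.grid = model_cfg.grid
        self.grid_f = self.grid.astype(float)
        self.T = self.grid.size
        self.cfg_emu_variance = error_cfg.emu_variance
        self.err_bias_prior_sd = error_cfg.bias_prior_sd
        self.err_nonsampling_scale = error_cfg.nonsampling_prior_scale
        self.cdata = _prepare(data, model_cfg, error_cfg)
        self.codes = [cd.code for cd in self.cdata]
        self.C = len(self.cdata)
        self.subregions = sorted({cd.sub for cd in self.cdata})
        self.sub_idx = {s: i for i, s in enumerate(self.subregions)}
        meta = {m.country_code: m for m in data.meta}
        self.regions = sorted({m.region for m in data.meta})
        self.reg_idx = {r: i for i, r in enumerate(self.regions)}
        self.sub_parent = np.array(
            [
                self.reg_idx[next(m.region for m in data.meta if m.subregion == s)]
                for s in self.subregions
            ]
        )
        self.c_sub = np.array([self.sub_idx[cd.sub] for cd in self.cdata])

        self.m0 = model_cfg.world_mean_vector()
        self.s0 = model_cfg.world_sd_vector()
        self.hier_scale = model_cfg.hier_scale_vector()
        self.src_present = sorted(
            {int(s) for cd in self.cdata for s in cd.src}
        )

        shared = fit_cfg.shared
        self.frozen = shared is not None

        # --- state -------------------------------------------------------
        self.m_w = self.m0.copy()
        self.m_r = np.tile(self.m0, (len(self.regions), 1))
        self.m_s = np.tile(self.m0, (len(self.subregions), 1))
        self.sig = np.vstack([self.hier_scale / 2.0] * 3)  # region, subregion, country
        self.beta = 0.0
        self.rho_e, self.tau_e = 0.5, 0.05
        self.rho_u, self.tau_u = 0.5, 0.05
        self.bias = np.zeros(len(SOURCE_TYPES))
        self.nssd = np.full(len(SOURCE_TYPES), 0.1)
        if self.frozen:
            self.m_s = np.vstack([shared.subregion_means[s] for s in self.subregions])
            self.sig[2] = shared.sd_country
            self.beta = shared.beta
            self.rho_e, self.tau_e = shared.rho_eta, shared.tau_eta
            self.rho_u, self.tau_u = shared.rho_unmet, shared.tau_unmet
            self.bias = np.array([shared.bias[s] for s in SOURCE_TYPES])
            self.nssd = np.array([shared.nonsampling_sd[s] for s in SOURCE_TYPES])

        self.theta = self.m_s[self.c_sub] + 0.1 * rng.standard_normal((self.C, 7))
        self.de = np.zeros((self.C, self.T - 1))
        self.du = np.zeros((self.C, self.T))

        # residual caches and likelihood cache
        self.r_obs = [np.empty(0)] * self.C
        self.r_emu = [np.empty(0)] * self.C
        self.clik = np.zeros(self.C)
        for c in range(self.C):
            self._refresh_country(c)

        # slice widths for the country parameter components
        self.theta_widths = np.array([0.5, 0.3, 5.0, 0.5, 0.3, 5.0, 0.5])

    # -- core likelihood ---------------------------------------------------

    TINY = 1e-14

    def _paths(self, theta, de, du):
        """Indicator paths (4, T) on the proportion scale for one country."""
        P = _paths_kernel(self.grid_f, theta, de, du, self.beta)
        return P, P[1]

    def _ll_from_resids(self, c, r, r_emu):
        cd = self.cdata[c]
        ll = 0.0
        if r.size:
            v = cd.v_samp + self.nssd[cd.src] ** 2
            e = r - self.bias[cd.src]
            ll += float(-0.5 * np.sum(e * e / v + np.log(v) + LOG2PI))
        if r_emu.size:
            v = self.cfg_emu_variance
            ll += float(
                -0.5 * np.sum(r_emu * r_emu / v) - 0.5 * r_emu.size * (math.log(v) + LOG2PI)
            )
        return ll

    def _country_ll(self, c, theta, de, du):
        cd = self.cdata[c]
        return _ll_kernel(
            self.grid_f, theta, de, du, self.beta,
            cd.W, cd.w_lo, cd.w_hi, cd.ind, cd.z, cd.v_samp, cd.src,
            self.bias, self.nssd, cd.emu_pos, cd.emu_dz, self.cfg_emu_variance,
        )

    def _refresh_country(self, c):
        ll, r, r_emu = self._country_ll(c, self.theta[c], self.de[c], self.du[c])
        self.clik[c] = ll
        self.r_obs[c] = r
        self.r_emu[c] = r_emu

    # -- parameter blocks --------------------------------------------------

    def _curve_logit(self, theta):
        # logit of p_tilde * expit(omega (t - Omega)) without underflow:
        # log curve = log p_tilde - softplus(-omega (t - Omega))
        x = math.exp(theta[1]) * (self.grid - theta[2])
        log_curve = -np.logaddexp(0.0, -theta[0]) - np.logaddexp(0.0, -x)
        return log_curve - np.log1p(-np.exp(log_curve))

    def _update_theta(self):
        """Slice-sample each country parameter in compensated coordinates.

        The state is reparametrized so that the year-on-year increments of
        the total-use path and the unmet-need path are held fixed while a
        curve parameter moves: the rate distortions absorb the change in
        the expected increments (and the unmet path absorbs the intercept
        and level shifts).  In these coordinates each component's full
        conditional is a smooth univariate density -- its hierarchical
        prior, the AR(1) prior of the implied distortions, and the small
        residual likelihood change from the expected curve's starting
        level -- which univariate slice sampling explores without tuning,
        avoiding the funnel between curve parameters and distortions.
        """
        for c in range(self.C):
            m = self.m_s[self.c_sub[c]]
            sd = self.sig[2]
            for j in range(7):
                th = self.theta[c].copy()
                zc0 = self._curve_logit(th)
                d0 = np.diff(zc0)
                ar_cur = _ar1_ll_rows(self.de[c][None, :], self.rho_e, self.tau_e)
                ar_u_cur = _ar1_ll_rows(self.du[c][None, :], self.rho_u, self.tau_u)

                def logf(x, j=j, th=th, zc0=zc0, d0=d0, m=m, sd=sd, c=c):
                    thx = th.copy()
                    thx[j] = x
                    de_x, du_x = self.de[c], self.du[c]
                    lp = -0.5 * ((x - m[j]) / sd[j]) ** 2
                    if j in (0, 1, 2):
                        zcx = self._curve_logit(thx)
                        de_x = de_x + d0 - np.diff(zcx)
                        du_x = du_x - self.beta * (zcx[0] - zc0[0])
                        lp += _ar1_ll_rows(de_x[None, :], self.rho_e, self.tau_e)
                        lp += _ar1_ll_rows(du_x[None, :], self.rho_u, self.tau_u)
                    elif j == 6:
                        du_x = du_x + (th[6] - x)
                        lp += _ar1_ll_rows(du_x[None, :], self.rho_u, self.tau_u)
                    ll, _, _ = self._country_ll(c, thx, de_x, du_x)
                    return lp + ll

                f0 = -0.5 * ((th[j] - m[j]) / sd[j]) ** 2 + self.clik[c]
                if j in (0, 1, 2):
                    f0 += ar_cur + ar_u_cur
                elif j == 6:
                    f0 += ar_u_cur
                x = _slice1d(
                    th[j], logf, self.rng, width=self.theta_widths[j], f0=f0
                )
                if x != th[j]:
                    thx = th.copy()
                    thx[j] = x
                    if j in (0, 1, 2):
                        zcx = self._curve_logit(thx)
                        self.de[c] = self.de[c] + d0 - np.diff(zcx)
                        self.du[c] = self.du[c] - self.beta * (zcx[0] - zc0[0])
                    elif j == 6:
                        self.du[c] = self.du[c] + (th[6] - x)
                    self.theta[c] = thx
                    self._refresh_country(c)

    def _ess_update(self, c, which: str):
        """Elliptical slice update of one distortion series."""
        if which == "eta":
            cur = self.de[c]
            nu = _ar1_sample(self.rng, self.T - 1, self.rho_e, self.tau_e)
            ll = lambda d: self._country_ll(c, self.theta[c], d, self.du[c])
        else:
            cur = self.du[c]
            nu = _ar1_sample(self.rng, self.T, self.rho_u, self.tau_u)
            ll = lambda d: self._country_ll(c, self.theta[c], self.de[c], d)
        logy = self.clik[c] + math.log(max(self.rng.uniform(), 1e-300))
        angle = self.rng.uniform(0.0, 2.0 * math.pi)
        lo, hi = angle - 2.0 * math.pi, angle
        for _ in range(50):
            prop = cur * math.cos(angle) + nu * math.sin(angle)
            ll_prop, r, r_emu = ll(prop)
            if ll_prop > logy:
                if which == "eta":
                    self.de[c] = prop
                else:
                    self.du[c] = prop
                self.clik[c] = ll_prop
                self.r_obs[c], self.r_emu[c] = r, r_emu
                return
            if angle < 0:
                lo = angle
            else:
                hi = angle
            angle = self.rng.uniform(lo, hi)
        # bracket collapsed; keep current state

    def _update_beta(self):
        def logf(b):
            saved = self.beta
            self.beta = b
            tot = sum(
                self._country_ll(c, self.theta[c], self.de[c], self.du[c])[0]
                for c in range(self.C)
            )
            self.beta = saved
            return tot - 0.5 * (b / self.cfg.beta_prior_sd) ** 2

        f0 = float(np.sum(self.clik)) - 0.5 * (self.beta / self.cfg.beta_prior_sd) ** 2
        self.beta = _slice1d(self.beta, logf, self.rng, width=0.2, f0=f0)
        for c in range(self.C):
            self._refresh_country(c)

    def _update_measurement(self):
        # Collect per-source residuals and sampling variances once.
        rs: dict[int, list] = {s: [] for s in self.src_present}
        vs: dict[int, list] = {s: [] for s in self.src_present}
        for c, cd in enumerate(self.cdata):
            for k in self.src_present:
                mask = cd.src == k
                if mask.any():
                    rs[k].append(self.r_obs[c][mask])
                    vs[k].append(cd.v_samp[mask])
        err_cfg_bias_sd = self.err_bias_prior_sd
        for k in self.src_present:
            r = np.concatenate(rs[k])
            v_samp = np.concatenate(vs[k])
            if SOURCE_TYPES[k] != "DHS":
                v = v_samp + self.nssd[k] ** 2
                prec = np.sum(1.0 / v) + 1.0 / err_cfg_bias_sd**2
                mean = np.sum(r / v) / prec
                self.bias[k] = mean + self.rng.standard_normal() / math.sqrt(prec)
            e = r - self.bias[k]

            def logf(sd, e=e, v_samp=v_samp):
                v = v_samp + sd * sd
                return float(
                    -0.5 * np.sum(e * e / v + np.log(v))
                    - 0.5 * (sd / self.err_nonsampling_scale) ** 2
                )

            self.nssd[k] = _slice1d(
                self.nssd[k], logf, self.rng, width=0.05, lo=0.0
            )
        for c in range(self.C):
            self.clik[c] = self._ll_from_resids(c, self.r_obs[c], self.r_emu[c])

    def _update_ar(self):
        for attr_rho, attr_tau, d in (
            ("rho_e", "tau_e", self.de),
            ("rho_u", "tau_u", self.du),
        ):
            rho, tau = getattr(self, attr_rho), getattr(self, attr_tau)
            rho = _slice1d(
                rho,
                lambda r: _ar1_ll_rows(d, r, tau),
                self.rng,
                width=0.2,
                lo=0.0,
                hi=self.cfg.rho_max,
            )
            scale = self.cfg.tau_prior_scale
            tau = _slice1d(
                tau,
                lambda t: _ar1_ll_rows(d, rho, t) - 0.5 * (t / scale) ** 2,
                self.rng,
                width=0.05,
                lo=1e-6,
            )
            setattr(self, attr_rho, rho)
            setattr(self, attr_tau, tau)

    def _update_hierarchy(self):
        rng = self.rng
        # subregion means given country params and region means
        for s in range(len(self.subregions)):
            members = self.theta[self.c_sub == s]
            n = members.shape[0]
            prec = n / self.sig[2] ** 2 + 1.0 / self.sig[1] ** 2
            mean = (
                members.sum(axis=0) / self.sig[2] ** 2
                + self.m_r[self.sub_parent[s]] / self.sig[1] ** 2
            ) / prec
            self.m_s[s] = mean + rng.standard_normal(7) / np.sqrt(prec)
        # region means given subregion means and world mean
        for r in range(len(self.regions)):
            members = self.m_s[self.sub_parent == r]
            n = members.shape[0]
            prec = n / self.sig[1] ** 2 + 1.0 / self.sig[0] ** 2
            mean = (members.sum(axis=0) / self.sig[1] ** 2 + self.m_w / self.sig[0] ** 2) / prec
            self.m_r[r] = mean + rng.standard_normal(7) / np.sqrt(prec)
        # world mean given region means; the asymptote component is kept
        # inside its declared bounds with a truncated-normal draw
        n = self.m_r.shape[0]
        prec = n / self.sig[0] ** 2 + 1.0 / self.s0**2
        mean = (self.m_r.sum(axis=0) / self.sig[0] ** 2 + self.m0 / self.s0**2) / prec
        self.m_w = mean + rng.standard_normal(7) / np.sqrt(prec)
        lo, hi = self.cfg.ptilde_bounds
        lo_z, hi_z = _logit(np.array([lo, hi]))
        sd0 = 1.0 / math.sqrt(prec[0])
        a, b = (lo_z - mean[0]) / sd0, (hi_z - mean[0]) / sd0
        self.m_w[0] = truncnorm.rvs(a, b, loc=mean[0], scale=sd0, random_state=rng)
        # level SDs
        groups = (
            (self.m_r, np.tile(self.m_w, (n, 1)), 0),
            (self.m_s, self.m_r[self.sub_parent], 1),
            (self.theta, self.m_s[self.c_sub], 2),
        )
        for values, means, level in groups:
            resid = values - means
            m = resid.shape[0]
            for j in range(7):
                ss = float(np.sum(resid[:, j] ** 2))
                scale = self.hier_scale[j]

                def logf(sd):
                    return -m * math.log(sd) - 0.5 * ss / sd**2 - 0.5 * (sd / scale) ** 2

                self.sig[level, j] = _slice1d(
                    self.sig[level, j], logf, self.rng, width=scale / 2.0, lo=1e-4
                )

    # -- iteration ---------------------------------------------------------

    def step(self, warmup: bool):
        self._update_theta()
        for c in range(self.C):
            self._ess_update(c, "eta")
            self._ess_update(c, "unmet")
        if not self.frozen:
            self._update_beta()
            self._update_measurement()
            self._update_ar()
            self._update_hierarchy()

    def snapshot_values(self) -> np.ndarray:
        out = np.empty((self.C, self.T, len(QUANTITIES)))
        for c in range(self.C):
            P, _ = self._paths(self.theta[c], self.de[c], self.du[c])
            out[c] = P.T
        return out

    def snapshot_params(self) -> dict[str, float]:
        p: dict[str, float] = {
            "beta": self.beta,
            "rho_eta": self.rho_e,
            "tau_eta": self.tau_e,
            "rho_unmet": self.rho_u,
            "tau_unmet": self.tau_u,
        }
        for k in self.src_present:
            name = SOURCE_TYPES[k]
            p[f"nonsampling_sd[{name}]"] = self.nssd[k]
            if name != "DHS":
                p[f"bias[{name}]"] = self.bias[k]
        for c, code in enumerate(self.codes):
            for j, pname in enumerate(PARAM_NAMES):
                p[f"theta[{code}][{pname}]"] = self.theta[c, j]
        for s, name in enumerate(self.subregions):
            p[f"subregion_mean[{name}][logit_ptilde]"] = self.m_s[s, 0]
        p["sd_country[logit_ptilde]"] = self.sig[2, 0]
        return p


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit(
    data: Dataset,
    model_cfg: ModelConfig | None = None,
    fit_cfg: FitConfig | None = None,
    error_cfg: ErrorModelConfig | None = None,
) -> tuple[PosteriorDraws, Diagnostics]:
    """Sample the joint posterior and return indicator draws with diagnostics.

    The dataset must validate cleanly.  Non-convergence (any split-R-hat at
    or above 1.1) is reported through ``Diagnostics.converged`` and a logged
    warning; draws are returned regardless so that downstream pipelines can
    proceed.
    """
    model_cfg = model_cfg or ModelConfig()
    fit_cfg = fit_cfg or FitConfig()
    error_cfg = error_cfg or ErrorModelConfig()
    issues = validate_dataset(data)
    if issues:
        raise ValueError(f"dataset has {len(issues)} validation issues; first: {issues[0]}")

    seed_seq = np.random.SeedSequence(fit_cfg.seed)
    chain_seeds = seed_seq.spawn(fit_cfg.n_chains)
    codes = data.countries()
    grid = model_cfg.grid

    values = np.empty(
        (fit_cfg.n_chains, fit_cfg.n_samples, len(codes), grid.size, len(QUANTITIES))
    )
    param_chains: dict[str, np.ndarray] = {}
    for k in range(fit_cfg.n_chains):
        rng = np.random.Generator(np.random.Philox(chain_seeds[k]))
        sampler = _Sampler(data, model_cfg, fit_cfg, error_cfg, rng)
        for _ in range(fit_cfg.n_warmup):
            sampler.step(warmup=True)
        for i in range(fit_cfg.n_samples):
            sampler.step(warmup=False)
            values[k, i] = sampler.snapshot_values()
            for name, v in sampler.snapshot_params().items():
                param_chains.setdefault(
                    name, np.empty((fit_cfg.n_chains, fit_cfg.n_samples))
                )[k, i] = v

    draws = PosteriorDraws(
        countries=list(codes), years=grid, values=values, params=param_chains
    )
    if fit_cfg.n_chains >= 2:
        diag = check_convergence(param_chains)
    else:
        diag = Diagnostics(rhat={}, ess={}, converged=False)
        logger.warning("single chain: convergence cannot be assessed")
    if not diag.converged:
        logger.warning(
            "convergence not reached (max split-R-hat %.3f); returning draws anyway",
            diag.max_rhat(),
        )
    return draws, diag


def check_convergence(param_chains: Mapping[str, np.ndarray]) -> Diagnostics:
    """Split-R-hat and effective sample size for each scalar parameter.

    Expects arrays of shape ``(chain, draw)`` with at least two chains.
    ``converged`` is true when every split-R-hat is below 1.1.
    """
    import warnings

    import arviz as az

    first = next(iter(param_chains.values()))
    if first.shape[0] < 2:
        raise ValueError("convergence assessment requires at least two chains")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in param_chains.items():
            rhat[name] = float(az.rhat(np.asarray(arr), method="split"))
            ess[name] = float(az.ess(np.asarray(arr)))
    finite = [v for v in rhat.values() if math.isfinite(v)]
    converged = bool(finite) and all(v < 1.1 for v in finite)
    return Diagnostics(rhat=rhat, ess=ess, converged=converged)
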