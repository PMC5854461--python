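import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from fpem import (
    ARParams,
    CountryParams,
    ErrorModelConfig,
    LogisticParams,
    ModelConfig,
    ModernShareParams,
    UnmetParams,
    ar1_logdensity,
    build_trajectory,
    expected_increments,
    flag_outliers,
    joint_logposterior,
    logistic_curve,
    observation_loglik,
    prepare_observations,
    service_stat_loglik,
    trajectory_proportions,
)
from fpem.fpem_core import HierarchyParams, ModelParams, PARAM_NAMES, period_weights
from scipy.special import expit, logit


PARAMS = LogisticParams(p_tilde=0.8, omega=0.2, Omega=2000.0)
SHARE = ModernShareParams(r_tilde=0.7, psi=0.15, Xi=1995.0)
GRID = np.arange(1990, 2021)


class TestLogisticCurve:
    def test_midpoint_is_half_asymptote(self):
        assert logistic_curve(2000.0, PARAMS) == pytest.approx(0.4, rel=1e-12)

    def test_scalar_value(self):
        # 0.8 / (1 + e^-2), checked against high-precision evaluation
        assert logistic_curve(2010.0, PARAMS) == pytest.approx(
            0.8 / (1.0 + math.exp(-2.0)), rel=1e-12
        )
        assert logistic_curve(2010.0, PARAMS) == pytest.approx(0.7046377, rel=1e-6)

    def test_vanishes_in_the_distant_past(self):
        assert logistic_curve(1800.0, PARAMS) < 1e-15

    def test_strictly_increasing_and_bounded(self):
        vals = logistic_curve(GRID, PARAMS)
        assert (np.diff(vals) > 0).all()
        assert (vals > 0).all() and (vals < PARAMS.p_tilde).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(p_tilde=1.2, omega=0.1, Omega=2000.0)
        with pytest.raises(ValueError):
            LogisticParams(p_tilde=0.5, omega=-0.1, Omega=2000.0)


class TestExpectedIncrements:
    def test_telescoping_sum(self):
        d = expected_increments(PARAMS, GRID)
        total = logit(logistic_curve(GRID[-1], PARAMS)) - logit(
            logistic_curve(GRID[0], PARAMS)
        )
        assert d.sum() == pytest.approx(total, rel=1e-12)
        assert (d > 0).all()

    def test_flat_curve_limit(self):
        flat = LogisticParams(p_tilde=0.8, omega=1e-9, Omega=2000.0)
        assert np.max(np.abs(expected_increments(flat, GRID))) < 1e-6

    def test_two_year_grid_scalar_value(self):
        d = expected_increments(PARAMS, np.array([2000, 2001]))
        expected = logit(0.8 / (1 + math.exp(-0.2))) - logit(0.4)
        assert d[0] == pytest.approx(expected, rel=1e-12)


class TestAR1Density:
    def test_independence_limit(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        ar = ARParams(rho=0.0, tau=0.3)
        iid = sum(-0.5 * (xi / 0.3) ** 2 - math.log(0.3) - 0.5 * math.log(2 * math.pi) for xi in x)
        assert ar1_logdensity(x, ar) == pytest.approx(iid, rel=1e-12)

    def test_matches_dense_multivariate_normal_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            T = int(rng.integers(2, 11))
            rho = float(rng.uniform(-0.9, 0.9))
            tau = float(rng.uniform(0.05, 0.5))
            x = rng.normal(scale=tau, size=T)
            cov = tau**2 * rho ** np.abs(np.subtract.outer(range(T), range(T)))
            oracle = multivariate_normal(mean=np.zeros(T), cov=cov).logpdf(x)
            assert ar1_logdensity(x, ARParams(rho, tau)) == pytest.approx(oracle, abs=1e-8)

    def test_unit_root_rejected(self):
        with pytest.raises(ValueError):
            ARParams(rho=1.0, tau=0.1)


class TestBuildTrajectory:
    def test_zero_distortions_reproduce_expected_curve(self):
        un = UnmetParams(alpha_c=-0.4, beta=0.0)
        traj = build_trajectory(
            PARAMS, SHARE, un, np.zeros(GRID.size - 1), np.zeros(GRID.size), GRID
        )
        expected = logit(logistic_curve(GRID, PARAMS))
        np.testing.assert_allclose(traj.eta, expected, atol=1e-10)
        # beta = 0 and no distortions: unmet-need path constant at the intercept
        np.testing.assert_allclose(traj.u, -0.4, atol=1e-12)

    def test_constant_rate_distortion_accumulates_linearly(self):
        un = UnmetParams(alpha_c=0.0, beta=0.0)
        k = 0.05
        traj = build_trajectory(
            PARAMS, SHARE, un, np.full(GRID.size - 1, k), np.zeros(GRID.size), GRID
        )
        expected = logit(logistic_curve(GRID, PARAMS)) + k * (GRID - GRID[0])
        np.testing.assert_allclose(traj.eta, expected, atol=1e-10)

    def test_telescoping_identity_is_exact(self):
        rng = np.random.default_rng(3)
        de = rng.normal(scale=0.05, size=GRID.size - 1)
        un = UnmetParams(alpha_c=0.2, beta=-0.3)
        traj = build_trajectory(PARAMS, SHARE, un, de, np.zeros(GRID.size), GRID)
        assert traj.eta[-1] - traj.eta[0] == pytest.approx(
            float(np.sum(expected_increments(PARAMS, GRID) + de)), rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        un = UnmetParams(alpha_c=0.0, beta=0.0)
        with pytest.raises(ValueError):
            build_trajectory(PARAMS, SHARE, un, np.zeros(5), np.zeros(GRID.size), GRID)

    def test_zero_distortion_total_prevalence_monotone(self):
        un = UnmetParams(alpha_c=0.0, beta=0.1)
        traj = build_trajectory(
            PARAMS, SHARE, un, np.zeros(GRID.size - 1), np.zeros(GRID.size), GRID
        )
        props = trajectory_proportions(traj)
        assert (np.diff(props["total_cpr"]) > 0).all()
        assert props["total_cpr"].max() < 1
        total = props["modern_cpr"] + props["trad_cpr"]
        np.testing.assert_allclose(total, props["total_cpr"], rtol=1e-12)
        assert (props["total_cpr"] + props["unmet_any"] <= 1).all()


def _flat_trajectory(values, grid=GRID):
    """Trajectory whose total-use path passes through given proportions.

    The first grid year is pinned to the expected curve (a structural
    property of the model); all later years take the requested values via
    rate distortions.
    """
    eta = logit(np.asarray(values, dtype=float))
    eta[0] = logit(logistic_curve(grid[0], PARAMS))
    un = UnmetParams(alpha_c=0.0, beta=0.0)
    de = np.diff(eta) - expected_increments(PARAMS, grid)
    return build_trajectory(PARAMS, SHARE, un, de, np.zeros(grid.size), grid)


class TestObservationLoglik:
    def _tobs(self, value, start, end, se=0.01, indicator="total_cpr"):
        from fpem import SurveyObservation
        from fpem.measurement_error import TransformedObservation, transform_observation

        base = SurveyObservation("AAA", indicator, value, "DHS", start, end, se)
        z, v = transform_observation(base)
        return TransformedObservation(base=base, z=z, v_sampling=v, v_total=v + 0.01, imputed=False)

    def test_single_year_period_equals_plain_normal(self):
        traj = _flat_trajectory(np.linspace(0.2, 0.5, GRID.size))
        obs = self._tobs(0.33, 2005.5, 2005.5)
        w = period_weights(GRID, 2005.5, 2005.5)
        mu = logit(float(w @ trajectory_proportions(traj)["total_cpr"]))
        expected = (
            -0.5 * (obs.z - mu) ** 2 / obs.v_total
            - 0.5 * math.log(2 * math.pi * obs.v_total)
        )
        got = observation_loglik(obs, traj, ErrorModelConfig())
        assert got == pytest.approx(expected, rel=1e-12)
        # single-year weights select exactly one grid year
        assert w.max() == 1.0 and w.sum() == 1.0

    def test_constant_trajectory_average_is_the_constant(self):
        traj = _flat_trajectory(np.full(GRID.size, 0.35))
        one = observation_loglik(self._tobs(0.3, 2001.5, 2001.5), traj, ErrorModelConfig())
        many = observation_loglik(self._tobs(0.3, 2001.5, 2006.5), traj, ErrorModelConfig())
        assert one == pytest.approx(many, rel=1e-12)

    def test_equal_overlap_two_year_average(self):
        values = np.full(GRID.size, 0.3)
        values[GRID >= 2011] = 0.4
        traj = _flat_trajectory(values)
        # [2010.5, 2011.5] overlaps years 2010 and 2011 equally -> mean 0.35
        obs = self._tobs(0.35, 2010.5, 2011.5)
        w = period_weights(GRID, 2010.5, 2011.5)
        assert w[GRID == 2010] == pytest.approx(0.5)
        assert w[GRID == 2011] == pytest.approx(0.5)
        mv = float(w @ trajectory_proportions(traj)["total_cpr"])
        assert mv == pytest.approx(0.35, rel=1e-12)
        expected = -0.5 * (obs.z - logit(mv)) ** 2 / obs.v_total - 0.5 * math.log(
            2 * math.pi * obs.v_total
        )
        assert observation_loglik(obs, traj, ErrorModelConfig()) == pytest.approx(expected)

    def test_period_outside_grid_rejected(self):
        traj = _flat_trajectory(np.full(GRID.size, 0.35))
        with pytest.raises(ValueError):
            observation_loglik(self._tobs(0.3, 1980.5, 1980.5), traj, ErrorModelConfig())


class TestServiceStatLoglik:
    def test_exact_match_gives_zero_residual_contribution(self):
        values = np.linspace(0.2, 0.5, GRID.size)
        traj = _flat_trajectory(values)
        modern = trajectory_proportions(traj)["modern_cpr"]
        years = [2010.5, 2011.5, 2012.5]
        emu = [modern[GRID == int(y)][0] for y in years]
        var = 0.004
        got = service_stat_loglik(years, emu, traj, var)
        max_ll = 2 * (-0.5 * math.log(2 * math.pi * var))
        assert got == pytest.approx(max_ll, rel=1e-12)

    def test_constant_offset_cancels(self):
        traj = _flat_trajectory(np.linspace(0.2, 0.5, GRID.size))
        modern = trajectory_proportions(traj)["modern_cpr"]
        years = [2010.5, 2011.5, 2012.5]
        emu = [expit(logit(modern[GRID == int(y)][0]) + 0.7) for y in years]
        var = 0.004
        assert service_stat_loglik(years, emu, traj, var) == pytest.approx(
            2 * (-0.5 * math.log(2 * math.pi * var)), rel=1e-9
        )

    def test_single_point_contributes_nothing(self):
        traj = _flat_trajectory(np.full(GRID.size, 0.3))
        assert service_stat_loglik([2010.5], [0.3], traj, 0.004) == 0.0


class TestJointLogPosterior:
    def _setup(self, toy_dataset):
        cfg = ModelConfig(year_start=1995, year_end=2016)
        beta = -0.2
        countries = {
            "AAA": CountryParams(
                LogisticParams(0.6, 0.08, 2005.0),
                ModernShareParams(0.75, 0.1, 2000.0),
                UnmetParams(alpha_c=-0.3, beta=beta),
            ),
            "BBB": CountryParams(
                LogisticParams(0.7, 0.1, 2000.0),
                ModernShareParams(0.8, 0.12, 1998.0),
                UnmetParams(alpha_c=0.1, beta=beta),
            ),
        }
        hier = HierarchyParams(
            world=np.array([0.5, math.log(0.1), 2000.0, 0.5, math.log(0.1), 2000.0, 0.0]),
            region={"Region 1": np.array([0.4, -2.2, 2001.0, 0.5, -2.3, 1999.0, 0.1])},
            subregion={"Subregion 1": np.array([0.45, -2.25, 2002.0, 0.55, -2.2, 1998.5, 0.05])},
            sd_region=np.full(7, 0.4),
            sd_subregion=np.full(7, 0.4),
            sd_country=np.full(7, 0.4),
        )
        params = ModelParams(
            countries=countries,
            hierarchy=hier,
            ar_eta=ARParams(0.5, 0.06),
            ar_unmet=ARParams(0.4, 0.08),
            error=ErrorModelConfig(),
        )
        rng = np.random.default_rng(7)
        T = cfg.grid.size
        distortions = {
            c: (rng.normal(0, 0.03, T - 1), rng.normal(0, 0.05, T)) for c in countries
        }
        return params, distortions, cfg

    def test_empty_dataset_reduces_to_prior(self, toy_dataset):
        from fpem import Dataset

        params, distortions, cfg = self._setup(toy_dataset)
        empty = Dataset(surveys=[], service_stats=[], meta=toy_dataset.meta, populations=[])
        lp = joint_logposterior(params, distortions, empty, cfg)
        from fpem.fpem_core import _global_logprior, _hierarchy_logprior

        prior = _hierarchy_logprior(params, empty, cfg) + _global_logprior(params, cfg)
        for c, (de, du) in distortions.items():
            prior += ar1_logdensity(de, params.ar_eta) + ar1_logdensity(du, params.ar_unmet)
        assert lp == pytest.approx(prior, rel=1e-12)

    def test_equals_term_by_term_oracle(self, toy_dataset):
        """Brute-force recomputation: every prior and likelihood term summed
        independently of the implementation's code path."""
        params, distortions, cfg = self._setup(toy_dataset)
        lp = joint_logposterior(params, distortions, toy_dataset, cfg)

        def norm(x, m, s):
            return -0.5 * ((x - m) / s) ** 2 - math.log(s) - 0.5 * math.log(2 * math.pi)

        def halfnorm(x, s):
            return 0.5 * math.log(2 / math.pi) - math.log(s) - 0.5 * (x / s) ** 2

        h = params.hierarchy
        oracle = 0.0
        for j, name in enumerate(PARAM_NAMES):
            oracle += norm(h.world[j], cfg.world_prior_mean[name], cfg.world_prior_sd[name])
            oracle += norm(h.region["Region 1"][j], h.world[j], h.sd_region[j])
            oracle += norm(
                h.subregion["Subregion 1"][j], h.region["Region 1"][j], h.sd_subregion[j]
            )
            for sd in (h.sd_region[j], h.sd_subregion[j], h.sd_country[j]):
                oracle += halfnorm(sd, cfg.hier_sd_scale[name])
        for code, cp in params.countries.items():
            th = cp.theta()
            for j in range(7):
                oracle += norm(th[j], h.subregion["Subregion 1"][j], h.sd_country[j])
        oracle += norm(-0.2, 0.0, cfg.beta_prior_sd)
        for ar in (params.ar_eta, params.ar_unmet):
            oracle += -math.log(cfg.rho_max) + halfnorm(ar.tau, cfg.tau_prior_scale)
        for s in ("MICS", "PMA", "RHS", "NATIONAL", "OTHER"):
            oracle += norm(params.error.bias[s], 0.0, params.error.bias_prior_sd)
        for s in ("DHS", "MICS", "PMA", "RHS", "NATIONAL", "OTHER"):
            oracle += halfnorm(params.error.nonsampling_sd[s], params.error.nonsampling_prior_scale)
        trajs = {}
        for code, cp in params.countries.items():
            de, du = distortions[code]
            oracle += ar1_logdensity(de, params.ar_eta)
            oracle += ar1_logdensity(du, params.ar_unmet)
            trajs[code] = build_trajectory(cp.logistic, cp.share, cp.unmet, de, du, cfg.grid)
        for o in prepare_observations(toy_dataset, params.error):
            oracle += observation_loglik(o, trajs[o.base.country_code], params.error)
        ss = toy_dataset.service_stats
        oracle += service_stat_loglik(
            [s.year for s in ss], [s.emu for s in ss], trajs["BBB"], params.error.emu_variance
        )
        assert lp == pytest.approx(oracle, rel=1e-10)

    def test_duplicated_observation_adds_its_loglik_twice(self, toy_dataset):
        from fpem import Dataset

        params, distortions, cfg = self._setup(toy_dataset)
        lp1 = joint_logposterior(params, distortions, toy_dataset, cfg)
        doubled = Dataset(
            surveys=toy_dataset.surveys + [toy_dataset.surveys[0]],
            service_stats=toy_dataset.service_stats,
            meta=toy_dataset.meta,
            populations=toy_dataset.populations,
        )
        lp2 = joint_logposterior(params, distortions, doubled, cfg)
        cp = params.countries["AAA"]
        de, du = distortions["AAA"]
        traj = build_trajectory(cp.logistic, cp.share, cp.unmet, de, du, cfg.grid)
        o = prepare_observations(toy_dataset, params.error)[0]
        assert lp2 - lp1 == pytest.approx(
            observation_loglik(o, traj, params.error), rel=1e-9
        )

    def test_invariant_to_observation_ordering(self, toy_dataset):
        from fpem import Dataset

        params, distortions, cfg = self._setup(toy_dataset)
        shuffled = Dataset(
            surveys=list(reversed(toy_dataset.surveys)),
            service_stats=list(reversed(toy_dataset.service_stats)),
            meta=toy_dataset.meta,
            populations=toy_dataset.populations,
        )
        assert joint_logposterior(params, distortions, toy_dataset, cfg) == pytest.approx(
            joint_logposterior(params, distortions, shuffled, cfg), rel=1e-12
        )


class TestOutlierScreen:
    def test_flagged_beyond_two_sd(self):
        assert flag_outliers(0.36, 0.30, 0.025)

    def test_at_mean_not_flagged(self):
        assert not flag_outliers(0.30, 0.30, 0.025)

    def test_exactly_two_sd_not_flagged(self):
        assert not flag_outliers(0.35, 0.30, 0.025)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers(0.3, 0.3, 0.0)
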