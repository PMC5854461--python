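import numpy as np
import pytest

from fpem import (
    PopulationCount,
    additional_users,
    aggregate,
    change_table,
    derive_indicators,
    plugin_demand_satisfied,
    summarize,
)
from fpem.indicators import IndicatorDraws, round_half_away
from fpem.inference import PosteriorDraws, QUANTITIES


def _draws(values_by_country, years, n_draws=1, jitter=0.0, seed=0):
    """PosteriorDraws from per-country dicts of quantity paths."""
    countries = sorted(values_by_country)
    years = np.asarray(years)
    rng = np.random.default_rng(seed)
    values = np.empty((1, n_draws, len(countries), years.size, len(QUANTITIES)))
    for c, code in enumerate(countries):
        for q, name in enumerate(QUANTITIES):
            base = np.broadcast_to(
                np.asarray(values_by_country[code][name], dtype=float), (years.size,)
            )
            for d in range(n_draws):
                values[0, d, c, :, q] = base + (
                    jitter * rng.normal(size=years.size) if jitter else 0.0
                )
    return PosteriorDraws(countries=countries, years=years, values=values)


YEARS = np.arange(2010, 2018)


def _country(total, modern_share, unmet_any):
    return {
        "total_cpr": total,
        "modern_cpr": total * modern_share,
        "trad_cpr": total * (1 - modern_share),
        "unmet_any": unmet_any,
    }


class TestDeriveIndicators:
    def test_worked_example(self):
        draws = _draws({"AAA": _country(0.40, 0.75, 0.10)}, YEARS)
        ind = derive_indicators(draws)
        assert ind.at("mcpr", "AAA", 2012)[0] == pytest.approx(0.30)
        assert ind.at("trad", "AAA", 2012)[0] == pytest.approx(0.10)
        assert ind.at("unmet_modern", "AAA", 2012)[0] == pytest.approx(0.20)
        assert ind.at("demand_satisfied", "AAA", 2012)[0] == pytest.approx(0.60)

    def test_no_traditional_use_collapses_unmet_definitions(self):
        draws = _draws({"AAA": _country(0.40, 1.0, 0.10)}, YEARS)
        ind = derive_indicators(draws)
        np.testing.assert_allclose(ind.unmet_modern, ind.unmet_any)

    def test_nicaragua_style_plugin_identity(self):
        # published point estimates: mCPR 77.4%, unmet need for modern
        # methods 10.2% -> demand satisfied 88.4%
        assert plugin_demand_satisfied(77.4, 10.2) == 88.4

    def test_draw_wise_identity_exact(self):
        draws = _draws(
            {"AAA": _country(0.40, 0.75, 0.10), "BBB": _country(0.3, 0.6, 0.2)},
            YEARS,
            n_draws=50,
            jitter=0.01,
        )
        ind = derive_indicators(draws)
        np.testing.assert_allclose(
            ind.demand_satisfied * (ind.mcpr + ind.unmet_modern), ind.mcpr, rtol=1e-12
        )


def _pops(units, years, mwra):
    return [
        PopulationCount(u, int(y), mwra[u] if isinstance(mwra, dict) else mwra)
        for u in units
        for y in years
    ]


class TestAdditionalUsers:
    def test_no_change_gives_zero(self):
        draws = _draws({"AAA": _country(0.40, 0.75, 0.10)}, YEARS)
        ind = derive_indicators(draws)
        s = additional_users(ind, _pops(["AAA"], YEARS, 1e6), 2012, 2017)
        assert s.median == s.lower == s.upper == 0.0

    def test_single_country_arithmetic(self):
        vals = _country(0.40, 0.75, 0.10)
        vals["modern_cpr"] = np.where(YEARS >= 2017, 0.30, 0.20)
        vals["total_cpr"] = np.where(YEARS >= 2017, 0.40, 0.30)
        vals["trad_cpr"] = vals["total_cpr"] - vals["modern_cpr"]
        draws = _draws({"AAA": vals}, YEARS)
        ind = derive_indicators(draws)
        pops = [
            PopulationCount("AAA", int(y), 1.2e6 if y >= 2017 else 1.0e6) for y in YEARS
        ]
        s = additional_users(ind, pops, 2012, 2017)
        assert s.median == pytest.approx(1.2e6 * 0.30 - 1.0e6 * 0.20)

    def test_additive_over_countries(self):
        a = _country(0.40, 0.75, 0.10)
        b = _country(0.30, 0.50, 0.20)
        draws_ab = _draws({"AAA": a, "BBB": b}, YEARS, n_draws=20, jitter=0.01, seed=1)
        ind_ab = derive_indicators(draws_ab)
        pops = _pops(["AAA", "BBB"], YEARS, {"AAA": 1e6, "BBB": 2e6})
        joint = additional_users(ind_ab, pops, 2012, 2017)
        i0, i1 = ind_ab.year_index(2012), ind_ab.year_index(2017)
        per_draw = (
            ind_ab.mcpr[:, 0, i1] * 1e6 + ind_ab.mcpr[:, 1, i1] * 2e6
            - ind_ab.mcpr[:, 0, i0] * 1e6 - ind_ab.mcpr[:, 1, i0] * 2e6
        )
        assert joint.median == pytest.approx(float(np.median(per_draw)))

    def test_missing_population_year_rejected(self):
        draws = _draws({"AAA": _country(0.40, 0.75, 0.10)}, YEARS)
        ind = derive_indicators(draws)
        with pytest.raises((ValueError, KeyError)):
            additional_users(ind, _pops(["AAA"], YEARS[:-1], 1e6), 2012, 2017)


class TestAggregate:
    def test_single_country_group_is_identity(self):
        draws = _draws({"AAA": _country(0.40, 0.75, 0.10)}, YEARS, n_draws=10, jitter=0.01)
        ind = derive_indicators(draws)
        out = aggregate(ind, _pops(["AAA"], YEARS, 1e6), {"AAA": "G"})
        np.testing.assert_allclose(out.mcpr[:, 0], ind.mcpr[:, 0], rtol=1e-12)
        np.testing.assert_allclose(out.demand_satisfied[:, 0], ind.demand_satisfied[:, 0], rtol=1e-12)

    def test_equal_weights_give_plain_mean(self):
        draws = _draws(
            {"AAA": _country(0.2, 1.0, 0.1), "BBB": _country(0.4, 1.0, 0.1)}, YEARS
        )
        ind = derive_indicators(draws)
        out = aggregate(ind, _pops(["AAA", "BBB"], YEARS, 1e6), {"AAA": "G", "BBB": "G"})
        assert out.mcpr[0, 0, 0] == pytest.approx(0.3)

    def test_population_weighted_mean(self):
        draws = _draws(
            {"AAA": _country(0.2, 1.0, 0.1), "BBB": _country(0.4, 1.0, 0.1)}, YEARS
        )
        ind = derive_indicators(draws)
        pops = _pops(["AAA", "BBB"], YEARS, {"AAA": 1e6, "BBB": 3e6})
        out = aggregate(ind, pops, {"AAA": "G", "BBB": "G"})
        assert out.mcpr[0, 0, 0] == pytest.approx(0.35)

    def test_users_conserved_exactly(self):
        draws = _draws(
            {"AAA": _country(0.23, 0.8, 0.12), "BBB": _country(0.41, 0.7, 0.2)},
            YEARS,
            n_draws=25,
            jitter=0.02,
            seed=3,
        )
        pops = _pops(["AAA", "BBB"], YEARS, {"AAA": 1.3e6, "BBB": 2.7e6})
        ind = derive_indicators(draws, pops)
        out = aggregate(ind, pops, {"AAA": "G", "BBB": "G"})
        np.testing.assert_allclose(
            out.users[:, 0], ind.users[:, 0] + ind.users[:, 1], rtol=1e-12
        )

    def test_missing_country_in_grouping_rejected(self):
        draws = _draws({"AAA": _country(0.4, 0.75, 0.1)}, YEARS)
        ind = derive_indicators(draws)
        with pytest.raises(KeyError):
            aggregate(ind, _pops(["AAA"], YEARS, 1e6), {})


class TestSummarize:
    def test_constant_draws(self):
        s = summarize(np.full(100, 0.37))
        assert s.median == s.lower == s.upper == 0.37

    def test_order_statistic_interpolation(self):
        s = summarize(np.arange(1.0, 101.0))
        assert s.median == pytest.approx(50.5)
        # linear interpolation between order statistics (inclusive rule)
        assert s.lower == pytest.approx(1 + 2.475)
        assert s.upper == pytest.approx(1 + 96.525)

    def test_bounds_ordered(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = summarize(rng.normal(size=37))
            assert s.lower <= s.median <= s.upper

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.array([]))


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.05, 0.1), (-0.05, -0.1), (0.14, 0.1), (2.25, 2.3), (-2.25, -2.3)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 1) == expected


class TestChangeTable:
    def test_same_year_changes_are_zero(self):
        draws = _draws({"AAA": _country(0.4, 0.75, 0.1)}, YEARS, n_draws=10, jitter=0.01)
        ind = derive_indicators(draws, _pops(["AAA"], YEARS, 1e6))
        tab = change_table(ind, 2012, 2012)
        assert tab.loc[0, "mcpr_change"] == 0.0
        assert not tab.loc[0, "progress_positive"]

    def test_users_change_matches_additional_users_for_one_country(self):
        draws = _draws({"AAA": _country(0.4, 0.75, 0.1)}, YEARS, n_draws=30, jitter=0.02, seed=5)
        pops = _pops(["AAA"], YEARS, 1e6)
        ind = derive_indicators(draws, pops)
        tab = change_table(ind, 2012, 2017)
        s = additional_users(ind, pops, 2012, 2017)
        assert tab.loc[0, "users_change"] == pytest.approx(s.median)

    def test_progress_flag_requires_both_indicators(self):
        up = _country(0.4, 0.75, 0.10)
        up["modern_cpr"] = np.linspace(0.28, 0.32, YEARS.size)
        up["trad_cpr"] = up["total_cpr"] - up["modern_cpr"]
        down = _country(0.4, 0.75, 0.10)
        down["modern_cpr"] = np.linspace(0.32, 0.28, YEARS.size)
        down["trad_cpr"] = down["total_cpr"] - down["modern_cpr"]
        draws = _draws({"UPP": up, "DWN": down}, YEARS)
        ind = derive_indicators(draws)
        tab = change_table(ind, 2012, 2017).set_index("unit")
        assert bool(tab.loc["UPP", "progress_positive"])
        assert not bool(tab.loc["DWN", "progress_positive"])
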