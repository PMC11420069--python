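import numpy as np
import pytest

from agrocarbon import constants
from agrocarbon.market import (
    CalibrationError,
    MACCPoint,
    PriceTrajectory,
    adoption_cost,
    build_macc,
    calibrate_slope,
    initialize_state,
    make_scenario,
    marginal_cost,
    optimal_adoption,
    run_horizon,
    run_period,
)
from agrocarbon.options import SequestrationOption
from agrocarbon.world import World, WorldConfig, generate_world

from conftest import make_region


def option(seq=0.6, c1=0.0, s=50.0, cap=0.9, oid="soc_crop"):
    return SequestrationOption(
        id=oid, land_type="cropland", seq_coeff=seq, saturation_years=20,
        max_share=cap, base_cost=c1, slope=s,
    )


@pytest.fixture(scope="module")
def small_world():
    return generate_world(WorldConfig(n_regions=3, seed=4))


class TestPriceTrajectory:
    def test_zero_before_start_linear_to_endpoint(self):
        tr = PriceTrajectory(endpoint=100.0)
        assert tr.price(2020) == 0.0
        assert tr.price(2030) == 0.0
        assert tr.price(2040) == pytest.approx(50.0)
        assert tr.price(2050) == pytest.approx(100.0)
        # linear continuation beyond 2050 for extended horizons
        assert tr.price(2070) == pytest.approx(200.0)


class TestAdoptionCost:
    def test_zero_share_zero_cost(self):
        assert adoption_cost(option(), 0.0) == 0.0

    def test_share_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            adoption_cost(option(), -0.1)
        with pytest.raises(ValueError):
            adoption_cost(option(cap=1.0), 1.3)

    def test_marginal_cost_is_derivative(self):
        opt = option(c1=5.0, s=80.0)
        h = 1e-7
        for a in (0.1, 0.4, 0.8):
            fd = (adoption_cost(opt, a + h) - adoption_cost(opt, a - h)) / (2 * h)
            assert marginal_cost(opt, a) == pytest.approx(fd, abs=1e-5)

    def test_quadratic_part_linear_in_slope(self):
        a = 0.5
        c1 = 3.0
        single = adoption_cost(option(c1=c1, s=40.0), a) - c1 * a
        double = adoption_cost(option(c1=c1, s=80.0), a) - c1 * a
        assert double == pytest.approx(2 * single, rel=1e-12)


class TestOptimalAdoption:
    def test_no_price_no_cobenefit_positive_intercept_means_zero(self):
        assert optimal_adoption(option(c1=10.0), 0.0, 0.0) == 0.0

    def test_zero_slope_corner_solution(self):
        assert optimal_adoption(option(c1=0.0, s=0.0), 50.0) == option().max_share

    def test_matches_brute_force_grid_search(self):
        """Profit p*q*a + v*a - C(a) maximized on a 1e-4 grid, 100 draws."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            opt = option(
                seq=rng.uniform(0.1, 2.5),
                c1=rng.uniform(0.0, 50.0),
                s=rng.uniform(10.0, 500.0),
                cap=rng.uniform(0.3, 1.0),
            )
            price = rng.uniform(0.0, 200.0)
            v = rng.uniform(0.0, 30.0)
            a_star = optimal_adoption(opt, price, v)
            grid = np.arange(0.0, opt.max_share + 1e-9, 1e-4)
            profit = (price * opt.seq_coeff + v) * grid - (
                opt.base_cost * grid + 0.5 * opt.slope * grid**2
            )
            assert a_star == pytest.approx(grid[np.argmax(profit)], abs=2e-4)

    def test_adoption_non_decreasing_in_price(self):
        opt = option(c1=10.0, s=100.0)
        shares = [optimal_adoption(opt, p) for p in np.linspace(0, 300, 31)]
        assert all(b >= a for a, b in zip(shares, shares[1:]))


class TestCalibration:
    def test_cropland_soc_round_trip_at_stated_price(self):
        opt = option(seq=0.6, c1=0.0, s=0.0, cap=0.90)
        s = calibrate_slope(opt, 0.90, calib_price=100.0)
        recovered = optimal_adoption(
            SequestrationOption(**{**opt.__dict__, "slope": s}), 100.0
        )
        assert recovered == pytest.approx(0.90, abs=1e-6)

    def test_pasture_soc_round_trip(self):
        opt = option(seq=0.5, c1=0.0, s=0.0, cap=0.60, oid="soc_pasture")
        s = calibrate_slope(opt, 0.60, calib_price=100.0)
        recovered = optimal_adoption(
            SequestrationOption(**{**opt.__dict__, "slope": s}), 100.0
        )
        assert recovered == pytest.approx(0.60, abs=1e-6)

    def test_closed_form_agrees_with_bisection(self):
        opt = option(seq=0.8, c1=5.0, s=0.0, cap=0.90)
        target = 0.75
        s_closed = calibrate_slope(opt, target, calib_price=120.0)
        # bisection oracle on s: adoption decreasing in s
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            a = optimal_adoption(
                SequestrationOption(**{**opt.__dict__, "slope": mid}), 120.0
            )
            if a > target:
                lo = mid
            else:
                hi = mid
        assert s_closed == pytest.approx(0.5 * (lo + hi), rel=1e-8)

    def test_recovers_known_slope_from_synthetic_adoption(self):
        """Parameter recovery: generate observed shares from a known slope,
        refit, compare to 1e-6 relative."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            s_true = rng.uniform(20.0, 400.0)
            opt = option(seq=rng.uniform(0.2, 2.0), c1=0.0, s=s_true, cap=1.0)
            price = rng.uniform(50.0, 150.0)
            observed = optimal_adoption(opt, price)
            if observed >= opt.max_share:  # corner carries no slope information
                continue
            s_fit = calibrate_slope(opt, observed, calib_price=price)
            assert s_fit == pytest.approx(s_true, rel=1e-6)

    def test_infeasible_calibration_raises(self):
        opt = option(seq=0.1, c1=500.0, s=0.0)
        with pytest.raises(CalibrationError):
            calibrate_slope(opt, 0.9, calib_price=100.0)


class TestRunPeriod:
    def test_baseline_scenario_adopts_nothing(self, small_world):
        state = initialize_state(small_world, seed=1)
        scenario = make_scenario("baseline")
        run_horizon(state, scenario)
        assert state.ledger.vintages == {} or all(
            area == 0 for v in state.ledger.vintages.values() for _, area in v
        )

    def test_off_grid_year_rejected(self, small_world):
        state = initialize_state(small_world, seed=1)
        with pytest.raises(ValueError, match="grid"):
            run_period(state, make_scenario("agCO2"), 2033)

    def test_single_region_reaches_calibrated_share_at_calibration_price(self):
        """Endpoint 100 USD2000: the 2050 price equals the calibration
        price, so cropland SOC lands exactly on the 90% calibration share."""
        world = generate_world(WorldConfig(n_regions=1, seed=1))
        state = initialize_state(world, seed=1)
        scenario = make_scenario("agCO2", endpoint=100.0)
        report = run_horizon(state, scenario)
        soc = report[(report.option == "soc_crop") & (report.year == 2050)]
        assert soc["share"].iloc[0] == pytest.approx(0.90, abs=1e-6)

    def test_higher_endpoint_adopts_earlier(self, small_world):
        shares = {}
        for endpoint in (100.0, 200.0):
            state = initialize_state(small_world, seed=1)
            scenario = make_scenario("agCO2", endpoint=endpoint)
            for year in (2020, 2025, 2030, 2035):
                rep = run_period(state, scenario, year)
            soc = rep[rep.option == "soc_crop"]
            shares[endpoint] = soc["share"].sum()
        assert shares[200.0] > shares[100.0]

    def test_vintages_never_shrink(self, small_world):
        state = initialize_state(small_world, seed=1)
        scenario = make_scenario("agCO2", endpoint=150.0)
        prev: dict = {}
        for year in scenario.years:
            run_period(state, scenario, year)
            now = {
                key: sum(a for _, a in v) for key, v in state.ledger.vintages.items()
            }
            for key, area in prev.items():
                assert now.get(key, 0.0) >= area - 1e-12
            prev = now

    def test_caps_respected_including_silvo_exclusivity(self, small_world):
        state = initialize_state(small_world, seed=1)
        scenario = make_scenario("agCO2", endpoint=200.0)
        report = run_horizon(state, scenario)
        last = report[report.year == 2050]
        for region in small_world.regions:
            sub = last[last.region == region.id].set_index("option")
            assert sub.loc["soc_crop", "share"] <= 0.90 + 1e-9
            assert sub.loc["soc_pasture", "share"] <= 0.60 + 1e-9
            silvo = sub.loc["silvo_bioenergy", "share"] + sub.loc["silvo_carbon", "share"]
            assert silvo <= 0.50 + 1e-9


class TestMACC:
    def test_duplicate_endpoints_give_identical_points(self, small_world):
        pts = build_macc(small_world, [100.0, 100.0], seed=2)
        assert pts[0].price == pts[1].price
        assert pts[0].mitigation == pytest.approx(pts[1].mitigation, rel=1e-12)

    def test_cumulative_macc_monotone_over_stated_endpoints(self, small_world):
        pts = build_macc(
            small_world, list(constants.PRICE_ENDPOINTS_USD2000), seed=2
        )
        cums = [p.mitigation for p in pts]
        assert all(b >= a - 1e-9 for a, b in zip(cums, cums[1:]))
        assert pts[-1].mitigation >= pts[3].mitigation  # 200 vs 100

    def test_prices_reported_in_usd2022(self, small_world):
        pts = build_macc(small_world, [100.0, 200.0], seed=2)
        assert pts[0].price == pytest.approx(163.0)
        assert pts[1].price == pytest.approx(326.0)

    def test_short_saturation_makes_2050_flux_non_monotone(self, small_world):
        """Early adoption under a high price saturates before 2050, so the
        top endpoint's 2050 annual flux falls below a mid endpoint's."""
        override = dict.fromkeys(
            ["soc_crop", "soc_pasture", "biochar", "silvo_bioenergy", "silvo_carbon"], 5
        )
        pts = build_macc(small_world, [100.0, 200.0], seed=2,
                         saturation_override=override)
        assert pts[1].annual_2050 < pts[0].annual_2050

    def test_single_endpoint_rejected(self, small_world):
        with pytest.raises(ValueError):
            build_macc(small_world, [100.0])

    def test_macc_point_rejects_negative_mitigation(self):
        with pytest.raises(ValueError):
            MACCPoint(price=10.0, mitigation=-1.0, annual_2050=0.0)
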