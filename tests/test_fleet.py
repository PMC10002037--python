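"""Fleet turnover: cohort accounting against a brute-force oracle, V2V shares."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roadsafe.fleet import (
    FleetState,
    SalesSeries,
    SurvivalCurve,
    fleet_v2v_share,
    project_stock,
    read_sales_csv,
    read_survival_csv,
    write_sales_csv,
    write_survival_csv,
)
from roadsafe.scenarios import (
    PenetrationSchedule,
    V2VLevel,
    v2v_equipage_rule,
)


def brute_force_stock(sales, survival, schedule, year):
    """Independent cohort enumeration: explicit double loop over sale year
    and age, splitting each cohort by the sale-year penetration."""
    stock = np.zeros(4)
    for j, sold in sales.values.items():
        age = year - j
        if age < 0 or age >= survival.lifespan:
            continue
        p1, p2, p3 = schedule.shares(j)
        split = np.array([1 - p1 - p2 - p3, p1, p2, p3])
        stock += sold * survival.probabilities[age] * split
    return stock


@st.composite
def toy_inputs(draw):
    lifespan = draw(st.integers(min_value=1, max_value=6))
    first, last = 2000, 2009
    sales = SalesSeries(
        {
            y: draw(st.floats(min_value=0, max_value=100))
            for y in range(first - lifespan, last + 1)
        }
    )
    decay = [draw(st.floats(min_value=0.0, max_value=1.0)) for _ in range(lifespan - 1)]
    survival = SurvivalCurve(lifespan, np.cumprod([1.0] + decay))
    p = sorted(draw(st.tuples(*[st.floats(0, 1)] * 3)))
    shares = (p[0], p[1] - p[0], p[2] - p[1])  # non-negative, sums <= 1
    schedule = PenetrationSchedule({first: (0.0, 0.0, 0.0), last: shares})
    years = list(range(first, last + 1))
    return sales, survival, schedule, years


class TestProjectStock:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(toy_inputs())
    def test_matches_brute_force_oracle(self, inputs):
        sales, survival, schedule, years = inputs
        states = project_stock(sales, survival, schedule, years)
        for state in states:
            expected = brute_force_stock(sales, survival, schedule, state.year)
            np.testing.assert_allclose(state.stock_by_type, expected, rtol=1e-12, atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(toy_inputs())
    def test_type_split_conserves_total_stock(self, inputs):
        sales, survival, schedule, years = inputs
        states = project_stock(sales, survival, schedule, years)
        for state in states:
            total = sum(
                sales[state.year - a] * survival(a) for a in range(survival.lifespan)
            )
            assert state.total_stock == pytest.approx(total, rel=1e-12, abs=1e-9)

    def test_zero_sales_give_zero_stock(self):
        sales = SalesSeries({y: 0.0 for y in range(1990, 2011)})
        survival = SurvivalCurve.weibull(10, 4, 12)
        schedule = PenetrationSchedule({2000: (0.1, 0.1, 0.1)})
        for state in project_stock(sales, survival, schedule, range(2002, 2011)):
            assert state.total_stock == 0.0

    def test_missing_sales_years_named_in_error(self):
        sales = SalesSeries({y: 1.0 for y in range(2000, 2011)})
        survival = SurvivalCurve.weibull(10, 4, 12)
        schedule = PenetrationSchedule({2000: (0, 0, 0)})
        with pytest.raises(ValueError, match="1999"):
            project_stock(sales, survival, schedule, [2010])

    def test_observation_reading_converts_old_cohorts(self):
        # under the literal reading, the split follows the observation year
        sales = SalesSeries({y: 10.0 for y in range(1995, 2011)})
        survival = SurvivalCurve(5, np.ones(5))
        schedule = PenetrationSchedule({2000: (0, 0, 0), 2010: (0.5, 0.3, 0.2)})
        (obs,) = project_stock(sales, survival, schedule, [2010], penetration_at="observation")
        np.testing.assert_allclose(obs.stock_by_type, 50 * np.array([0.0, 0.5, 0.3, 0.2]))
        (coh,) = project_stock(sales, survival, schedule, [2010], penetration_at="sale")
        assert coh.stock_by_type[0] > 0  # older cohorts stay traditional


class TestSurvivalCurve:
    def test_basic_invariants(self):
        c = SurvivalCurve.weibull(16, 4.5, 20)
        assert c(0) == 1.0
        assert c(20) == 0.0 and c(50) == 0.0
        assert all(c(a + 1) <= c(a) for a in range(25))

    def test_rejects_increasing_curve(self):
        with pytest.raises(ValueError):
            SurvivalCurve(3, np.array([1.0, 0.5, 0.8]))

    def test_time_scaling_stretches_service_life(self):
        c = SurvivalCurve.weibull(16, 4.5, 20)
        longer = c.time_scaled(1.5)
        assert longer.lifespan == 30
        assert longer.expected_service_years > c.expected_service_years
        assert longer(0) == 1.0


class TestV2VShare:
    def test_full_equipage_is_exactly_one_after_2025(self):
        f = FleetState(2026, np.array([10.0, 1.0, 1.0, 0.0]))
        assert fleet_v2v_share(f, v2v_equipage_rule(V2VLevel.FV2V)) == 1.0

    def test_no_v2v_is_zero(self):
        f = FleetState(2030, np.array([10.0, 1.0, 1.0, 5.0]))
        assert fleet_v2v_share(f, v2v_equipage_rule(V2VLevel.NV2V)) == 0.0

    def test_hv2v_share_equals_av_stock_share(self):
        # with 2030 stock shares of 28.3 / 14.1 / 3.4 % the AV share is 45.8 %
        f = FleetState(2030, np.array([54.2, 28.3, 14.1, 3.4]))
        assert fleet_v2v_share(f, v2v_equipage_rule(V2VLevel.HV2V)) == pytest.approx(0.458)

    def test_apv2v_share_is_partially_plus_fully(self):
        f = FleetState(2030, np.array([54.2, 28.3, 14.1, 3.4]))
        assert fleet_v2v_share(f, v2v_equipage_rule(V2VLevel.APV2V)) == pytest.approx(0.175)

    def test_zero_stock_warns_and_returns_zero(self):
        f = FleetState(2030, np.zeros(4))
        with pytest.warns(UserWarning, match="zero total stock"):
            assert fleet_v2v_share(f, v2v_equipage_rule(V2VLevel.FV2V)) == 0.0

    @pytest.mark.parametrize("year", range(2015, 2051, 5))
    def test_equipage_monotone_across_v2v_levels(self, year):
        f = FleetState(year, np.array([7.0, 3.0, 2.0, 1.0]))
        shares = [
            fleet_v2v_share(f, v2v_equipage_rule(lv))
            for lv in (V2VLevel.NV2V, V2VLevel.APV2V, V2VLevel.HV2V, V2VLevel.FV2V)
        ]
        assert shares == sorted(shares)


class TestCsvRoundTrip:
    def test_sales_and_survival_round_trip(self, tmp_path):
        sales = SalesSeries({2000: 1.5, 2001: 2.25, 2002: 0.0})
        curve = SurvivalCurve.weibull(8, 3, 10)
        write_sales_csv(sales, tmp_path / "s.csv")
        write_survival_csv(curve, tmp_path / "c.csv")
        assert read_sales_csv(tmp_path / "s.csv").values == sales.values
        back = read_survival_csv(tmp_path / "c.csv")
        np.testing.assert_array_equal(back.probabilities, curve.probabilities)
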