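"""Impact engine: effectiveness blending, conservation, dominance, SDG check."""

import numpy as np
import pandas as pd
import pytest

from roadsafe.fleet import FleetState
from roadsafe.impact import (
    EffectivenessTable,
    annual_series,
    blended_survival_factor,
    cumulative_reductions,
    read_effectiveness_csv,
    scenario_fatalities,
    sdg_check,
    write_effectiveness_csv,
)
from roadsafe.risk import Severity
from roadsafe.scenarios import (
    V2VLevel,
    VehicleType,
    baseline_scenario,
    scenario_from_label,
    v2v_equipage_rule,
)

EFF = EffectivenessTable()
AVKT = 15_000.0
FPT_UNIT = 1e9 / AVKT  # makes stock * AVKT * FPT / 1e9 == stock


def single_type_fleet(v, stock=1000.0, year=2030):
    arr = np.zeros(4)
    arr[int(v)] = stock
    return FleetState(year, arr)


class TestBlend:
    @pytest.mark.parametrize("v", list(VehicleType))
    @pytest.mark.parametrize("r", [0, 1])
    @pytest.mark.parametrize("vv", [0, 1])
    def test_degenerate_corners_pass_effectiveness_through(self, v, r, vv):
        # at the corners the blend must reproduce 1 - Eff for that cell exactly
        factor = blended_survival_factor(v, ptr1=float(r), pvv=float(vv), eff=EFF)
        assert factor == pytest.approx(1.0 - EFF[int(v), r, vv], abs=1e-15)

    def test_unassisted_traditional_keeps_full_risk(self):
        assert blended_survival_factor(VehicleType.TRADITIONAL, 0.0, 0.0) == 1.0

    def test_hand_computed_mixed_branch(self):
        # partially AV, half travel on IR, 60% V2V share: weight 0.36 on the
        # V2V branches gives 0.5*0.04644 + 0.5*0.37524 = 0.21084
        got = blended_survival_factor(VehicleType.PARTIALLY, 0.5, 0.6)
        assert got == pytest.approx(0.21084, abs=1e-10)

    def test_monotone_in_exposure_and_equipage(self):
        grid = np.linspace(0, 1, 21)
        for v in VehicleType:
            f_ptr = [blended_survival_factor(v, p, 0.5) for p in grid]
            f_pvv = [blended_survival_factor(v, 0.5, p) for p in grid]
            assert all(a >= b - 1e-12 for a, b in zip(f_ptr, f_ptr[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(f_pvv, f_pvv[1:]))

    def test_linear_mixing_gives_more_v2v_benefit_at_partial_equipage(self):
        sq = blended_survival_factor(VehicleType.PRIMARY, 0.5, 0.6, v2v_mixing="squared")
        lin = blended_survival_factor(VehicleType.PRIMARY, 0.5, 0.6, v2v_mixing="linear")
        assert lin < sq

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            blended_survival_factor(0, 1.5, 0.0)

    def test_table_validation(self):
        bad = EFF.values.copy()
        bad[0, 0, 0] = 0.1
        with pytest.raises(ValueError):
            EffectivenessTable(bad)
        decreasing = EFF.values.copy()
        decreasing[3, 1, 1] = 0.5  # below the no-V2V cell: not monotone
        with pytest.raises(ValueError):
            EffectivenessTable(decreasing)


class TestScenarioFatalities:
    def test_pure_fully_av_on_ir_with_v2v_leaves_1_2_percent(self):
        fleet = single_type_fleet(VehicleType.FULLY)
        fat = scenario_fatalities(fleet, 1.0, 1.0, FPT_UNIT, AVKT)
        assert fat == pytest.approx(0.012 * fleet.total_stock, rel=1e-12)

    def test_pure_partially_av_with_v2v_on_traditional_roads(self):
        fleet = single_type_fleet(VehicleType.PARTIALLY)
        fat = scenario_fatalities(fleet, 0.0, 1.0, FPT_UNIT, AVKT)
        assert fat == pytest.approx(0.253 * fleet.total_stock, rel=1e-12)

    def test_zero_effectiveness_reproduces_baseline_exactly(self):
        eff0 = EffectivenessTable(np.zeros((4, 2, 2)))
        fleet = FleetState(2030, np.array([5e7, 3e7, 2e7, 1e7]))
        fat = scenario_fatalities(fleet, 0.7, 0.9, FPT_UNIT, AVKT, eff=eff0)
        assert fat == pytest.approx(fleet.total_stock, rel=1e-12)

    def test_mixed_fleet_printed_2030_inputs(self):
        # printed 2030 stock shares against the 2030 baseline of 63,972
        shares = np.array([0.542, 0.283, 0.141, 0.034])
        fleet = FleetState(2030, shares * 63_972.0)
        fat = scenario_fatalities(fleet, 1.0, 1.0, FPT_UNIT, AVKT)
        assert fat == pytest.approx(1.98e4, rel=0.02)

    def test_type_aware_mode_removes_v2v_from_ineligible_types(self):
        fleet = FleetState(2030, np.array([100.0, 0, 0, 0]))
        rule = v2v_equipage_rule(V2VLevel.APV2V)
        fat_literal = scenario_fatalities(fleet, 0.0, 1.0, FPT_UNIT, AVKT)
        fat_aware = scenario_fatalities(
            fleet, 0.0, 1.0, FPT_UNIT, AVKT, v2v_eligible=rule.eligible_at(2030)
        )
        assert fat_literal == pytest.approx(100 * (1 - 0.267))
        assert fat_aware == pytest.approx(100.0)


def toy_series(spec, pvv_value=1.0, years=(2029, 2030, 2031)):
    fleets = [FleetState(y, np.array([50.0, 30.0, 15.0, 5.0])) for y in years]
    ptr1 = {y: 0.5 for y in years}
    pvv = {y: pvv_value for y in years}
    fpt = {y: FPT_UNIT for y in years}
    base = {y: 100.0 for y in years}
    return annual_series(spec, fleets, ptr1, pvv, fpt, base, AVKT)


class TestAnnualSeries:
    def test_baseline_spec_zero_reduction_when_effectiveness_inactive(self):
        spec = baseline_scenario()
        fleets = [FleetState(y, np.array([100.0, 0, 0, 0])) for y in (2029, 2030)]
        series = {y: 0.0 for y in (2029, 2030)}
        res = annual_series(
            spec, fleets, series, series, {y: FPT_UNIT for y in series},
            {y: 100.0 for y in series}, AVKT
        )
        assert np.allclose(res.table["reduction_fatalities"], 0.0)
        assert np.allclose(res.table["fatalities"], 100.0)

    def test_reductions_cover_all_severities_consistently(self):
        res = toy_series(scenario_from_label("RGAV-FIR-FV2V"))
        t = res.table
        np.testing.assert_allclose(t["severe"], 4 * t["fatalities"])
        np.testing.assert_allclose(t["pdo"], 135 * t["fatalities"])
        np.testing.assert_allclose(
            t["reduction_minor"], t["baseline_minor"] - t["minor"]
        )

    def test_misaligned_series_is_input_error(self):
        spec = scenario_from_label("RGAV-FIR-FV2V")
        fleets = [FleetState(2030, np.array([1.0, 0, 0, 0]))]
        with pytest.raises(ValueError, match="missing years"):
            annual_series(spec, fleets, {}, {2030: 1.0}, {2030: 1.0}, {2030: 1.0}, AVKT)


class TestCumulative:
    def test_sum_equals_total_of_annual_values(self):
        res = toy_series(scenario_from_label("RGAV-FIR-FV2V"))
        cum = cumulative_reductions(res, range(2029, 2032))
        assert cum[Severity.FATAL] == pytest.approx(
            float(res.table["reduction_fatalities"].sum())
        )

    def test_window_subsets_are_additive(self):
        res = toy_series(scenario_from_label("RGAV-FIR-FV2V"))
        left = cumulative_reductions(res, range(2029, 2030))
        right = cumulative_reductions(res, range(2030, 2032))
        full = cumulative_reductions(res, range(2029, 2032))
        for s in Severity:
            assert full[s] == pytest.approx(left[s] + right[s])

    def test_empty_window_rejected(self):
        res = toy_series(scenario_from_label("RGAV-FIR-FV2V"))
        with pytest.raises(ValueError):
            cumulative_reductions(res, range(2060, 2060))


class TestSdg:
    def test_fraction_one_is_always_met(self):
        res = toy_series(scenario_from_label("RGAV-FIR-FV2V"), years=(2020, 2030))
        met, ratio = sdg_check(res, 2020, 2030, fraction=1.0)
        assert met and 0 < ratio <= 1

    def test_out_of_range_year_rejected(self):
        res = toy_series(scenario_from_label("RGAV-FIR-FV2V"))
        with pytest.raises(ValueError):
            sdg_check(res, 1990, 2030)


class TestCsv:
    def test_effectiveness_round_trip(self, tmp_path):
        write_effectiveness_csv(EFF, tmp_path / "eff.csv")
        back = read_effectiveness_csv(tmp_path / "eff.csv")
        np.testing.assert_array_equal(back.values, EFF.values)
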