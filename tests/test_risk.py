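"""Risk laws: fitting, model selection, baseline rates, severity expansion."""

import numpy as np
import pytest

from roadsafe.risk import (
    FittingError,
    ModelForm,
    RiskHistory,
    RiskModel,
    Severity,
    SeverityMultipliers,
    baseline_annual,
    expand_to_severities,
    fit_fatality_model,
    read_history_csv,
    select_fatality_model,
    write_history_csv,
)


def synth_history(form, a, b, years=range(2000, 2021), noise_sd=0.0, seed=0):
    """History generated from a known law; the independent oracle for fits."""
    rng = np.random.default_rng(seed)
    records = {}
    for i, y in enumerate(years):
        stock = 50e6 + 15e6 * i
        pop = 1.3e9 + 1e6 * i
        m = stock / pop
        rate = np.exp(a) * m ** (-b) if form is ModelForm.SMEED else a * np.exp(-b * m)
        fat = stock * rate * (1.0 + rng.normal(0, noise_sd)) if noise_sd else stock * rate
        records[y] = (stock, pop, fat)
    return RiskHistory(records)


class TestFitting:
    @pytest.mark.parametrize(
        "form, a, b",
        [
            (ModelForm.SMEED, -9.5, 0.9),
            (ModelForm.SMEED, -8.0, 0.3),
            (ModelForm.BROSOS, 3e-4, 5.0),
        ],
    )
    def test_noiseless_parameter_recovery(self, form, a, b):
        history = synth_history(form, a, b)
        model = fit_fatality_model(history, form)
        assert model.a == pytest.approx(a, abs=1e-6)
        assert model.b == pytest.approx(b, abs=1e-6)

    def test_refit_round_trip(self):
        model = fit_fatality_model(synth_history(ModelForm.SMEED, -9.0, 0.7), ModelForm.SMEED)
        again = fit_fatality_model(
            synth_history(ModelForm.SMEED, model.a, model.b), ModelForm.SMEED
        )
        assert again.a == pytest.approx(model.a, abs=1e-6)
        assert again.b == pytest.approx(model.b, abs=1e-6)

    def test_zero_exponent_means_constant_per_vehicle_rate(self):
        model = RiskModel(ModelForm.SMEED, a=-9.0, b=0.0)
        assert model.rate_per_vehicle(0.1) == model.rate_per_vehicle(0.4)
        # fatalities then scale linearly with stock
        _, f1 = baseline_annual(model, 2030, 1e8, 1.4e9)
        _, f2 = baseline_annual(model, 2030, 2e8, 1.4e9)
        assert f2 == pytest.approx(2 * f1)

    def test_rate_decreasing_in_motorisation_for_positive_b(self):
        m = np.linspace(0.05, 0.5, 50)
        for model in (
            RiskModel(ModelForm.SMEED, -9.0, 0.8),
            RiskModel(ModelForm.BROSOS, 3e-4, 4.0),
        ):
            rates = model.rate_per_vehicle(m)
            assert np.all(np.diff(rates) < 0)
            assert np.all(rates > 0)

    def test_singular_fit_raises(self):
        records = {y: (1e8, 1.4e9, 50_000.0) for y in range(2000, 2010)}
        with pytest.raises(FittingError):
            fit_fatality_model(RiskHistory(records), ModelForm.SMEED)

    def test_non_positive_history_rejected(self):
        with pytest.raises(ValueError):
            RiskHistory({2000: (1e8, 1.4e9, 0.0)})


class TestSelection:
    def test_smeed_generator_selects_smeed(self):
        history = synth_history(ModelForm.SMEED, -9.5, 0.9, noise_sd=0.01, seed=3)
        assert select_fatality_model(history).form is ModelForm.SMEED

    def test_brosos_generator_selects_brosos(self):
        history = synth_history(ModelForm.BROSOS, 3e-4, 5.0, noise_sd=0.01, seed=3)
        assert select_fatality_model(history).form is ModelForm.BROSOS

    def test_china_like_history_selects_smeed(self, calibrated_bundle):
        assert select_fatality_model(calibrated_bundle.history).form is ModelForm.SMEED

    def test_oversized_holdout_rejected(self):
        history = synth_history(ModelForm.SMEED, -9.5, 0.9, years=range(2000, 2010))
        with pytest.raises(ValueError):
            select_fatality_model(history, holdout_years=10)


class TestBaseline:
    def test_zero_stock_means_zero_fatalities(self):
        model = RiskModel(ModelForm.SMEED, -9.5, 0.9)
        assert baseline_annual(model, 2030, 0.0, 1.4e9) == (0.0, 0.0)

    def test_fpt_unit_identity(self):
        # stock * AVKT * FPT / 1e9 must equal stock * per-vehicle rate exactly
        model = RiskModel(ModelForm.SMEED, -9.5, 0.9, avkt=12_345.0)
        stock, pop = 2.5e8, 1.4e9
        fpt, fatalities = baseline_annual(model, 2030, stock, pop)
        assert fatalities == pytest.approx(stock * model.rate_per_vehicle(stock / pop), rel=1e-12)
        assert fpt == pytest.approx(
            model.rate_per_vehicle(stock / pop) / model.avkt * 1e9, rel=1e-12
        )

    def test_fatalities_increase_with_stock_for_sublinear_decline(self):
        # with b < 1 the rate falls slower than 1/stock, so counts still rise
        model = RiskModel(ModelForm.SMEED, -9.5, 0.9)
        stocks = np.linspace(1e8, 5e8, 40)
        counts = [baseline_annual(model, 2030, s, 1.4e9)[1] for s in stocks]
        assert np.all(np.diff(counts) > 0)


class TestSeverities:
    def test_printed_multipliers(self):
        out = expand_to_severities(1000.0)
        assert out[Severity.PDO] == 135_000
        assert out[Severity.MINOR] == 42_000
        assert out[Severity.SEVERE] == 4_000
        assert out[Severity.FATAL] == 1_000

    def test_2020_fatalities_imply_severe_count(self):
        assert expand_to_severities(61_703.0)[Severity.SEVERE] == pytest.approx(246_812)

    def test_zero_maps_to_zero(self):
        assert all(v == 0 for v in expand_to_severities(0.0).values())

    def test_linearity_and_order(self):
        m = SeverityMultipliers()
        a, b = expand_to_severities(10.0, m), expand_to_severities(3.0, m)
        both = expand_to_severities(13.0, m)
        for s in Severity:
            assert both[s] == pytest.approx(a[s] + b[s])
        assert a[Severity.PDO] > a[Severity.MINOR] > a[Severity.SEVERE] > a[Severity.FATAL]

    def test_negative_fatalities_rejected(self):
        with pytest.raises(ValueError):
            expand_to_severities(-1.0)


class TestIO:
    def test_history_csv_round_trip(self, tmp_path):
        history = synth_history(ModelForm.SMEED, -9.5, 0.9, years=range(2010, 2016))
        write_history_csv(history, tmp_path / "h.csv")
        assert read_history_csv(tmp_path / "h.csv").records == history.records

    def test_model_json_round_trip(self, tmp_path):
        model = RiskModel(ModelForm.BROSOS, 3e-4, 5.0, avkt=14_000.0)
        model.to_json(tmp_path / "m.json")
        assert RiskModel.from_json(tmp_path / "m.json") == model
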