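#!/usr/bin/env python
"""Fit the Smeed and Brosos fatality laws to the synthetic national history,
select the better predictor on a 3-year holdout, and project the baseline
(no-deployment) fatality series to 2050.

Writes results/baseline_fatalities.csv and results/risk_model.json.
"""

import csv
from pathlib import Path

from roadsafe import risk, synthetic

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
YEARS = range(2015, 2051)


def main() -> None:
    bundle = synthetic.calibrate_to_anchors(synthetic.generate_inputs(SEED))
    selected = risk.select_fatality_model(bundle.history, holdout_years=3, avkt=bundle.avkt)
    model = risk.fit_fatality_model(bundle.history, selected.form, avkt=bundle.avkt)
    print(f"selected form: {model.form.value} (a={model.a:.4f}, b={model.b:.4f})")

    stocks = synthetic.baseline_total_stock(bundle, YEARS)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    model.to_json(out / "risk_model.json")
    with open(out / "baseline_fatalities.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "stock", "fpt_per_billion_km", "baseline_fatalities"])
        for y in YEARS:
            fpt, fat = risk.baseline_annual(model, y, stocks[y], bundle.population[y])
            w.writerow([y, f"{stocks[y]:.0f}", f"{fpt:.4f}", f"{fat:.1f}"])
            if y in (2020, 2030, 2040, 2050):
                print(f"  {y}: {fat:,.0f} baseline fatalities "
                      f"({fpt:.2f} per billion km at AVKT {model.avkt:,.0f} km/y)")


if __name__ == "__main__":
    main()
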