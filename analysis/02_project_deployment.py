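#!/usr/bin/env python
"""Project the three deployment dimensions over 2015-2050: AV composition of
the vehicle stock per uptake level, fleet V2V equipage per programme, and
intelligent-road mileage / travel coverage per construction level.

Writes results/deployment.csv (one row per year with the headline shares).
"""

import csv
from pathlib import Path

from roadsafe import fleet, roads, scenarios, synthetic

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
YEARS = range(2015, 2051)


def main() -> None:
    bundle = synthetic.calibrate_to_anchors(synthetic.generate_inputs(SEED))
    rgav = fleet.project_stock(
        bundle.sales, bundle.survival, scenarios.DEFAULT_SCHEDULES[scenarios.AVLevel.RGAV],
        list(YEARS),
    )
    rules = {lv: scenarios.v2v_equipage_rule(lv) for lv in scenarios.V2VLevel}
    mix = bundle.mix

    rows = []
    for st in rgav:
        y = st.year
        shares = st.type_shares()
        row = {"year": y, "total_stock_m": st.total_stock / 1e6}
        for t in scenarios.VehicleType:
            row[f"stock_share_{t.name.lower()}"] = shares[t]
        for lv in (scenarios.V2VLevel.APV2V, scenarios.V2VLevel.HV2V, scenarios.V2VLevel.FV2V):
            row[f"pvv_{lv.value.lower()}"] = fleet.fleet_v2v_share(st, rules[lv])
        for lv in (scenarios.IRLevel.APIR, scenarios.IRLevel.RGIR, scenarios.IRLevel.FIR):
            sched = roads.coverage_schedule(lv)
            row[f"ptr1_{lv.value.lower()}"] = roads.proportion_travel_on_ir(mix, sched, y)
            row[f"ir_mileage_{lv.value.lower()}"] = roads.ir_mileage(bundle.inventory, sched, y)
        rows.append(row)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "deployment.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]))
        w.writeheader()
        for row in rows:
            w.writerow({k: (f"{v:.6f}" if isinstance(v, float) else v) for k, v in row.items()})

    marks = {r["year"]: r for r in rows}
    for y in (2025, 2030, 2040, 2050):
        r = marks[y]
        print(
            f"{y}: stock {r['total_stock_m']:.1f} M | AV shares "
            f"{r['stock_share_primary']:.1%}/{r['stock_share_partially']:.1%}/"
            f"{r['stock_share_fully']:.1%} | PVV ap/h/f "
            f"{r['pvv_apv2v']:.1%}/{r['pvv_hv2v']:.1%}/{r['pvv_fv2v']:.0%} | "
            f"IR mileage FIR {r['ir_mileage_fir']:.0f} thousand km"
        )


if __name__ == "__main__":
    main()
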