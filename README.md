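# roadsafe

Country-level projection of the road-safety benefits of co-deploying
**autonomous vehicles (AV)**, **intelligent roads (IR)** and
**vehicle-to-vehicle communication (V2V)**, built for transport-safety and
injury-epidemiology analysts who need scenario numbers — annual and
cumulative fatalities, injuries, property-damage-only (PDO) crashes and the
economic cost of all of them — rather than microscopic traffic simulation.

The package models China-like national conditions over 2015–2050 and
evaluates a 3 × 4 × 4 deployment grid (AV uptake × IR construction × V2V
equipage), filtered to the 26 practically meaningful "synergetic" scenarios
plus the no-deployment baseline, including the test against the SDG 3.6
ambition of halving road deaths by 2030 relative to 2020.

## The model

Annual fatalities in scenario *s* blend, per vehicle automation type *v*
(traditional, primary, partially, fully automated), the travel split across
road classes and the availability of a V2V interaction:

```
Fata[y,s] = Σ_v  VS[v,y] · AVKT · FPT[y]/10⁹ ·
            Σ_r  PTR[r,y] · ( PVV[y]² · (1 − Eff[v,r,on])
                            + (1 − PVV[y]²) · (1 − Eff[v,r,off]) )
```

* `VS[v,y]` — vehicle stock by type, from cohort fleet turnover:
  `VS[v,y] = Σ_j Sales[j] · PR[v,j] · SR[y−j]`, with an S-shaped survival
  curve `SR` and AV sales penetration `PR` evaluated at the sale year;
* `PTR[1,y] = Σ_t DDR[t] · RIR[t,y]` — share of travel on intelligent roads,
  the travel-mix-weighted IR coverage over eight road types;
* `PVV[y]` — V2V-equipped share of the stock; it enters **squared** because
  a cooperative safety function needs both interacting vehicles equipped;
* `Eff[v,r,vv]` — a 16-cell crash-avoidance effectiveness table (vehicle
  type × road class × V2V state), e.g. 98.8 % for a fully automated vehicle
  on an intelligent road with V2V working;
* `FPT[y]` — baseline fatalities per billion vehicle-km, from a Smeed
  power law `rate/vehicle = e^a · (VS/Pop)^(−b)` (or the exponential
  Brosos variant) fitted to national history on the log scale, with the
  better predictor chosen on a held-out tail.

Injury severities scale off fatalities (severe 4×, minor 42×, PDO 135×) and
avoided crashes are priced at national unit costs (2017 USD: 1,670 / 2,995 /
128,195 / 471,192 from PDO to fatal).

Because no machine-readable deposit of the national inputs exists, the
`synthetic` module generates a China-emulating bundle and calibrates it onto
published milestones (stock 317.7 M in 2022 and 432.1 M in 2030; 61,703
fatalities in 2020; a 63,972-fatality 2030 baseline) by shape-preserving
rescaling.

## Worked example

```python
from roadsafe.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))
top = result.summary[0]
print(top["label"], round(top["fatalities_2030"]), round(top["sdg_ratio"], 2))
base = result.results["NAV-NIR-NV2V"].table
print(round(base.loc[2030, "fatalities"]))
```

prints

```
RGAV-FIR-FV2V 21470 0.35
63972
```

i.e. on calibrated synthetic inputs the baseline holds at 63,972 fatalities
in 2030, while full deployment (rapid AV growth + full IR coverage + fleet-
wide V2V) cuts 2030 fatalities to about 21,500 — 35 % of the 2020 level, well
inside the halving target — and accumulates ≈ 1.35 million avoided fatalities
and ≈ $1.8 trillion of avoided crash costs over 2015–2050. Every FV2V
scenario that builds intelligent roads meets the 2030 halving target; the
AV-only scenarios (`*-NIR-NV2V`) do not come close.

The same numbers are produced by the numbered drivers:

```bash
python analysis/01_generate_inputs.py    # calibrate synthetic inputs
python analysis/02_project_deployment.py # fleet, V2V and IR trajectories
python analysis/03_fit_baseline_risk.py  # Smeed/Brosos fit + baseline series
python analysis/04_run_scenarios.py      # 26 scenarios + SDG check
python analysis/05_economic_savings.py   # crash-cost savings
```

which write their tables under `results/`. A `roadsafe` CLI wraps the same
pipeline (`roadsafe run`, `roadsafe generate --seed 1 --out dir`,
`roadsafe scenarios`); `RunConfig.from_yaml` documents the accepted keys
(horizon, seed, scenario subset, `v2v_mixing: squared|linear`,
`type_aware_v2v`, `penetration_at: sale|observation`, IR `ramp_start`, …).

## Layout

```
src/roadsafe/      scenarios, fleet, roads, risk, impact, economics,
                   synthetic, pipeline, cli
analysis/          numbered narrative drivers (write results/)
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    modelling assumptions, parameters and limitations
```
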