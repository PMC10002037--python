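# Methods

This note records the model, its parameters and defaults, the synthetic-data
design, and the numerical choices that were genuinely open.

## Model structure

The pipeline is a bottom-up chain of five stages, each a pure function of
its inputs:

1. **Fleet turnover.** The stock of automation type *v* in year *y*
   accumulates surviving sale cohorts, `VS[v,y] = Σ_j Sales[j]·PR[v,j]·SR[y−j]`.
   Penetration `PR` is evaluated at the **sale year**: a cohort keeps the
   technology mix it was sold with. The alternative reading — applying the
   observation year's mix to every cohort, which retroactively converts old
   vehicles — is available as `penetration_at="observation"` but is not the
   default, because reported stock compositions (e.g. primary/partially/fully
   shares of 28.3/14.1/3.4 % in 2030 under rapid AV growth) are only
   consistent with cohort accumulation.
2. **Road exposure.** Eight road types; an IR level prescribes per-type
   linear construction ramps (default start 2023) ending at the programme's
   full-coverage year. Travel share on IR is the travel-mix-weighted
   coverage. The travel mix assigns 87.6 % of lifetime vehicle-km to the
   five "selected" types (urban expressways, urban ordinary roads,
   expressways, Class I, Class II), split within each group in proportion
   to 2021 mileages.
3. **Baseline risk.** Smeed (`rate = e^a·m^(−b)`) and Brosos
   (`rate = a·e^(−b·m)`) laws on the motorisation ratio `m = stock/population`,
   fitted by OLS on the log per-vehicle rate (both laws are log-linear, so no
   iterative optimiser is needed). Model selection: fit both on all but the
   last `holdout_years` (default 3) of the history, score MAPE of predicted
   fatality counts on the held-out years, keep the winner (tie → Smeed), then
   refit the winning form on the full history before projecting.
4. **Impact blend.** For each scenario-year, each vehicle type's baseline
   risk is multiplied by a survival factor blending (road class × V2V state)
   branches of the 16-cell effectiveness table by the travel split and by
   the **squared** fleet V2V share — both the ego and the interacting
   vehicle must be equipped for a cooperative function to fire
   (`v2v_mixing="linear"` preserves the single-sided reading). With all
   effectiveness values zero the blend collapses to the baseline exactly;
   this conservation identity is asserted in the tests.
5. **Valuation.** Avoided crashes by severity × constant 2017-USD unit
   costs; no discounting by default (`discount_rate` hook available).

## Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| horizon | 2015–2050 | years | reporting and cumulative window |
| AVKT | 15,000 | km/vehicle/year | cancels out of fatality counts; only sets the FPT display scale |
| survival curve | Weibull, shape 4.5, characteristic 16 y, truncated at 20 y | — | ≈ 15 effective service years |
| severity multipliers | 4 / 42 / 135 | per fatality | severe / minor / PDO |
| unit costs | 1,670 / 2,995 / 128,195 / 471,192 | 2017 USD | PDO → fatal, strictly increasing enforced |
| IR ramp start | 2023 | year | linear to each full-coverage year |
| V2V programme start | 2025 | year | retrofit year for HV2V / FV2V |
| holdout | 3 | years | model-selection window |

AV sales-penetration milestones: observed primary-AV shares 20 % (2021) and
32.4 % (2022); rapid-growth (RGAV) milestones (primary, partially, fully) =
(40, 9, 1) % in 2025, (35, 35, 20) % in 2030, (1, 9, 90) % in 2050; slow
(SAV) = (40, 10, 0), (35, 55, 0), (1, 99, 0); everything is AV from 2035 on.
Between milestones shares are piecewise-linear — the simplest scheme
consistent with every stated point. Because straight interpolation of the
2030 and 2050 milestones would leave a 7.5 % traditional share in 2035, a
2035 milestone is interposed: the component-wise interpolation renormalised
to sum to one.

V2V equipage: `APV2V` equips partially/fully AVs from market entry; `HV2V`
("all AVs since 2025") and `FV2V` ("all vehicles since 2025") are modelled
as instantaneous retrofit of the eligible stock in 2025 — the only reading
that makes the fleet share jump to 100 % in 2025 under FV2V. Before 2025
both fall back to the APV2V rule (connected AVs carry the hardware from
manufacture), which keeps equipage monotone across programmes in every year.

Effectiveness table (fraction of crashes avoided):

|  | traditional | primary | partially | fully |
|---|---|---|---|---|
| traditional road | 0.0 | 36.8 | 55.6 | 89.1 |
| … with V2V | 26.7 | 60.4 | 74.7 | 92.0 |
| intelligent road | 26.7 | 92.9 | 94.6 | 98.3 |
| … with V2V | 46.3 | 95.2 | 96.7 | 98.8 |

Values must lie in [0, 1), be zero for an unassisted traditional vehicle,
and be non-decreasing along each axis; these constraints are enforced on
load and give the grid-wide dominance property (more deployment never
increases fatalities).

## Synthetic data and calibration

The generator emulates the Chinese national inputs: a sales curve growing
from ≈ 28 M (2022) to ≈ 35 M (2030) and settling near 30 M; a slowly
declining population; a 2000–2020 fatality history drawn from a Smeed law
with 1 % multiplicative Gaussian noise (seeded; noiseless mode available);
the 2021 road-type mileages held on a configurable growth path; and the
87.6 / 12.4 travel split. One integer seed drives all randomness.

Calibration is coordinate-wise multiplicative rescaling, never curve
re-shaping: one scale on historical sales (≤ 2022) targets the 2022 stock,
one scale on projected sales (≥ 2023) targets the 2030 stock, the Smeed
parameters are moved through the two fatality anchors in closed form (with
the history regenerated and refitted until the fitted law lands on target),
and the road inventory's growth is rescaled toward the full-coverage 2050
mileage anchor. An already-satisfied bundle is returned unchanged;
non-convergence raises with the residual per anchor. On the default anchors
the sales scales converge in ~3 iterations to ≈ 0.97 (historical) and
≈ 0.99 (projected), and the fatality anchors are met to numerical precision.

The default survival curve was chosen so that the two stock anchors are
reachable with sales scales near one: with the published sales curve, an
effective service life of ~15 years (Weibull truncated at 20) reproduces
both 317.7 M (2022) and 432.1 M (2030). Late-horizon stock prints
(506–536 M around 2039–2050) are *not* anchors: they are jointly
inconsistent with the 2022/2030 stocks and a ~30 M sales plateau under any
stationary survival curve (they would require scrappage to triple between
the 2020s and 2040s), so the model runs ~10–15 % below them after 2040 and
the cumulative-reduction comparisons carry a correspondingly wide tolerance.

**What the synthetic bundle does not emulate:** vehicle-class and regional
heterogeneity, macroeconomic shocks to sales, survival curves that drift
over time, per-road-type risk differences, and reporting artefacts in
official crash counts. Tests passing on this bundle therefore demonstrate
the correctness and internal consistency of the pipeline under realistic
magnitudes — not forecasts for any real country.

## Numerical choices and degenerate inputs

* Fractional vehicles are kept as real numbers throughout; rounding happens
  only in report formatting.
* FPT is stored per km internally and rendered per billion km, avoiding
  unit ambiguity; fatality counts are AVKT-invariant by construction
  (`stock · AVKT · FPT/10⁹ ≡ stock · rate`).
* A zero-stock fleet yields a V2V share of 0 with a warning rather than an
  error; zero stock yields zero fatalities.
* Crash counts and casualty counts are used interchangeably at each
  severity (one fatal crash ↔ one fatality); reports inherit this
  conflation.
* Scenario enumeration is lexicographic by (AV, IR, V2V) level index so
  output files are stable across runs; summary rows are sorted by
  cumulative fatality reduction with the label as tie-break.
* Determinism: identical configuration + seed produces byte-identical
  output tables; every table carries a hash of the scientific configuration.

## Known limitations

* Point estimates only; no uncertainty propagation or probabilistic
  sensitivity analysis.
* The effectiveness table is an exogenous input; its derivation from
  sensing technologies and safety functions is out of scope, as are
  passive-safety measures and deployment costs (no cost–benefit analysis).
* No scenario optimisation: the grid is fixed, and no search is performed
  for a least-cost deployment meeting a safety target.
* Risk is not stratified by road user class (pedestrians, cyclists) or by
  road type; IR benefits enter only through the travel-share blend.
* The 2030 halving verdicts for scenarios near the 50 % line (several HV2V
  and APV2V combinations sit at 46–50 % on the calibrated bundle) are
  sensitive to input assumptions; the robust qualitative finding is that
  fleet-wide V2V plus intelligent-road coverage is what moves a scenario
  clearly inside the target, while AV-only deployment stays far outside it.
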