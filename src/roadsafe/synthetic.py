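"""Synthetic country input bundles emulating the Chinese vehicle system.

No machine-readable deposit of the national inputs (sales series, survival
curve, population, crash history, road inventory, travel mix) exists, so this
module generates a statistically plausible stand-in and then calibrates it to
the printed national milestones: vehicle stock 317.7 M in 2022 and 432.1 M in
2030, 61,703 road fatalities in 2020, a baseline prediction of 63,972
fatalities in 2030, and 7,425 thousand km of intelligent road under full
coverage in 2050.

The generator is deterministic for a fixed seed.  Sales follow a smooth
growth-then-plateau curve (≈28 M in 2022, ≈35 M in 2030, settling near 30 M);
population slowly declines after the mid-2020s; the fatality history is drawn
from a Smeed law with configurable multiplicative noise.  Calibration is
coordinate-wise multiplicative rescaling — segment scales on sales, a time
scale on the survival curve, a closed-form two-point update of the risk law,
and a terminal rescale of the road inventory — so every curve keeps its
shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .fleet import SalesSeries, SurvivalCurve, project_stock
from .risk import (
    DEFAULT_AVKT,
    ModelForm,
    RiskHistory,
    RiskModel,
    fit_fatality_model,
    select_fatality_model,
)
from .roads import (
    MILEAGE_2021,
    ROAD_TYPES,
    RoadInventory,
    TravelMix,
    coverage_schedule,
    default_travel_mix,
    interpolated_inventory,
    ir_mileage,
)
from .scenarios import AVLevel, DEFAULT_SCHEDULES, IRLevel

__all__ = [
    "GeneratorConfig",
    "CountryInputBundle",
    "Anchor",
    "AnchorSet",
    "CalibrationError",
    "CalibrationReport",
    "default_anchors",
    "generate_inputs",
    "calibrate_to_anchors",
    "baseline_total_stock",
]

_M = 1e6

# Smoothed national vehicle-sales trajectory (millions): explosive growth to
# the late 2010s, a dip around 2019-2020, recovery to ~35 M in 2030 and a
# long plateau near 30 M.
_SALES_ANCHORS_M: dict[int, float] = {
    1978: 0.15, 1985: 0.44, 1990: 0.51, 1995: 1.45, 2000: 2.09, 2002: 3.25,
    2005: 5.76, 2008: 9.38, 2009: 13.64, 2010: 18.06, 2012: 19.31, 2014: 23.49,
    2016: 28.03, 2017: 28.88, 2019: 25.77, 2020: 25.31, 2021: 26.28,
    2022: 28.40, 2026: 31.60, 2030: 34.90, 2034: 32.00, 2040: 30.00, 2050: 30.00,
}

# Slowly peaking-then-declining population (millions, UN-style medium path).
_POP_ANCHORS_M: dict[int, float] = {
    1978: 956.0, 1990: 1135.0, 2000: 1263.0, 2010: 1341.0, 2015: 1376.0,
    2020: 1412.0, 2024: 1413.0, 2030: 1406.0, 2035: 1394.0, 2040: 1378.0,
    2045: 1349.0, 2050: 1313.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable shape of the synthetic country."""

    first_year: int = 1978
    last_year: int = 2050
    history_years: tuple[int, int] = (2000, 2020)
    # survival: smooth S-curve with ~15 effective service years
    survival_shape: float = 4.5
    survival_characteristic: float = 16.0
    survival_lifespan: int = 20
    # risk law generating the fatality history (per-vehicle rate scale/slope)
    smeed_a: float = -9.89
    smeed_b: float = 0.90
    history_noise_sd: float = 0.01
    avkt: float = DEFAULT_AVKT
    inventory_growth_2050: float = 1.0  # terminal mileage multiplier vs 2021
    sales_anchors_m: Mapping[int, float] = field(
        default_factory=lambda: dict(_SALES_ANCHORS_M)
    )
    pop_anchors_m: Mapping[int, float] = field(
        default_factory=lambda: dict(_POP_ANCHORS_M)
    )

    def __post_init__(self) -> None:
        if self.first_year >= self.last_year:
            raise ValueError("first_year must precede last_year")
        if self.survival_lifespan < 1 or self.survival_characteristic <= 0:
            raise ValueError("invalid survival configuration")
        if self.history_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class CountryInputBundle:
    """Everything the projection pipeline consumes for one country."""

    sales: SalesSeries
    survival: SurvivalCurve
    population: Mapping[int, float]
    history: RiskHistory
    inventory: RoadInventory
    mix: TravelMix
    avkt: float
    seed: int
    config: GeneratorConfig
    calibration: "CalibrationReport | None" = None


@dataclass(frozen=True)
class Anchor:
    """A printed national milestone the bundle must reproduce."""

    quantity: str  # total_stock | fatalities | baseline_fatalities | fir_mileage | sales
    year: int
    value: float
    rel_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("tolerance must be positive")


AnchorSet = tuple[Anchor, ...]


def default_anchors() -> AnchorSet:
    return (
        Anchor("total_stock", 2022, 317.7e6, 0.02),
        Anchor("total_stock", 2030, 432.1e6, 0.01),
        Anchor("fatalities", 2020, 61_703.0, 0.02),
        Anchor("baseline_fatalities", 2030, 63_972.0, 0.02),
        Anchor("fir_mileage", 2050, 7_425.0, 0.10),
    )


class CalibrationError(RuntimeError):
    def __init__(self, message: str, residuals: dict[str, float]):
        super().__init__(f"{message}; residuals: {residuals}")
        self.residuals = residuals


@dataclass(frozen=True)
class CalibrationReport:
    """Relative residual (value/target - 1) per anchor after calibration."""

    residuals: dict[str, float]
    iterations: int
    scales: dict[str, float]

    @property
    def max_abs_residual(self) -> float:
        return max((abs(r) for r in self.residuals.values()), default=0.0)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _interp_series(anchors_m: Mapping[int, float], years: range) -> dict[int, float]:
    xs = sorted(anchors_m)
    ys = [anchors_m[x] * _M for x in xs]
    return {y: float(np.interp(y, xs, ys)) for y in years}


def generate_inputs(seed: int, config: GeneratorConfig | None = None) -> CountryInputBundle:
    """Build a deterministic China-like input bundle for ``seed``."""
    cfg = config or GeneratorConfig()
    years = range(cfg.first_year, cfg.last_year + 1)
    sales = SalesSeries(_interp_series(cfg.sales_anchors_m, years))
    population = _interp_series(cfg.pop_anchors_m, years)
    survival = SurvivalCurve.weibull(
        cfg.survival_characteristic, cfg.survival_shape, cfg.survival_lifespan
    )
    history = _generate_history(sales, survival, population, cfg, seed)
    inv_2050 = {t: m * cfg.inventory_growth_2050 for t, m in MILEAGE_2021.items()}
    inventory = interpolated_inventory(
        {2021: dict(MILEAGE_2021), 2050: inv_2050}, range(2015, 2051)
    )
    return CountryInputBundle(
        sales=sales,
        survival=survival,
        population=population,
        history=history,
        inventory=inventory,
        mix=default_travel_mix(),
        avkt=cfg.avkt,
        seed=int(seed),
        config=cfg,
    )


def _generate_history(
    sales: SalesSeries,
    survival: SurvivalCurve,
    population: Mapping[int, float],
    cfg: GeneratorConfig,
    seed: int,
) -> RiskHistory:
    """Fatality history drawn from the configured Smeed law (seeded noise)."""
    y0, y1 = cfg.history_years
    hist_years = list(range(y0, y1 + 1))
    states = project_stock(sales, survival, DEFAULT_SCHEDULES[AVLevel.NAV], hist_years)
    law = RiskModel(ModelForm.SMEED, cfg.smeed_a, cfg.smeed_b, cfg.avkt)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 17]))
    noise = rng.normal(0.0, cfg.history_noise_sd, size=len(hist_years))
    records = {}
    for st, eps in zip(states, noise):
        stock = st.total_stock
        pop = population[st.year]
        fat = stock * law.rate_per_vehicle(stock / pop) * (1.0 + eps)
        records[st.year] = (stock, pop, fat)
    return RiskHistory(records)


def baseline_total_stock(bundle: CountryInputBundle, years) -> dict[int, float]:
    """Total stock per year (type split is irrelevant for totals)."""
    states = project_stock(
        bundle.sales, bundle.survival, DEFAULT_SCHEDULES[AVLevel.NAV], list(years)
    )
    return {st.year: st.total_stock for st in states}


def fitted_risk_model(bundle: CountryInputBundle, holdout_years: int = 3) -> RiskModel:
    """Pipeline fit: select the better law on a holdout, refit on all years."""
    selected = select_fatality_model(bundle.history, holdout_years, avkt=bundle.avkt)
    return fit_fatality_model(bundle.history, selected.form, avkt=bundle.avkt)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_SALES_SPLIT_YEAR = 2022  # historical vs projected sales segments


def _evaluate_anchor(
    anchor: Anchor,
    bundle: CountryInputBundle,
    stock_cache: dict[int, float],
    model: RiskModel | None,
) -> float:
    if anchor.quantity == "total_stock":
        return stock_cache[anchor.year]
    if anchor.quantity == "sales":
        return bundle.sales[anchor.year]
    if anchor.quantity in ("fatalities", "baseline_fatalities"):
        assert model is not None
        stock = stock_cache[anchor.year]
        pop = bundle.population[anchor.year]
        return stock * model.rate_per_vehicle(stock / pop)
    if anchor.quantity == "fir_mileage":
        return ir_mileage(bundle.inventory, coverage_schedule(IRLevel.FIR), anchor.year)
    raise ValueError(f"unknown anchor quantity: {anchor.quantity!r}")


def _anchor_key(a: Anchor) -> str:
    return f"{a.quantity}@{a.year}"


def calibrate_to_anchors(
    bundle: CountryInputBundle,
    anchors: AnchorSet | None = None,
    max_iter: int = 100,
) -> CountryInputBundle:
    """Rescale the bundle until every anchor is met within its tolerance.

    Sales are scaled per segment (historical vs projected), the survival
    curve is time-scaled only if the stock anchors demand it, the Smeed law
    is moved through the fatality anchors in closed form (and the history
    regenerated from it), and the road inventory's growth is rescaled for
    mileage anchors.  Already-satisfied bundles are returned unchanged.
    """
    anchors = default_anchors() if anchors is None else tuple(anchors)
    work = replace(bundle)
    s_hist = s_future = 1.0

    def residuals(b: CountryInputBundle) -> dict[str, float]:
        stock_cache = baseline_total_stock(b, _years_needed(anchors, b))
        model = (
            fitted_risk_model(b)
            if any(a.quantity.endswith("fatalities") for a in anchors)
            else None
        )
        out = {}
        for a in anchors:
            val = _evaluate_anchor(a, b, stock_cache, model)
            out[_anchor_key(a)] = val / a.value - 1.0
        return out

    res = residuals(work)
    if all(abs(res[_anchor_key(a)]) <= a.rel_tol for a in anchors):
        work.calibration = CalibrationReport(res, 0, {})
        return work

    stock_anchors = [a for a in anchors if a.quantity == "total_stock"]
    hist_anchors = [a for a in stock_anchors if a.year <= _SALES_SPLIT_YEAR]
    fut_anchors = [a for a in stock_anchors if a.year > _SALES_SPLIT_YEAR]

    iterations = 0
    for iterations in range(1, max_iter + 1):
        stock_cache = baseline_total_stock(work, _years_needed(anchors, work))
        updated = False
        if hist_anchors:
            a = hist_anchors[0]
            r = a.value / stock_cache[a.year]
            if abs(r - 1.0) > a.rel_tol / 2:
                s_hist *= r
                updated = True
        if fut_anchors:
            a = fut_anchors[0]
            # future cohorts carry roughly their sales share of this stock
            r = a.value / stock_cache[a.year]
            if abs(r - 1.0) > a.rel_tol / 2:
                s_future *= r ** 1.0
                updated = True
        if not updated:
            break
        work.sales = bundle.sales.scaled(
            lambda y: s_hist if y <= _SALES_SPLIT_YEAR else s_future
        )

    # Risk law: move the generating Smeed law through the fatality anchors
    # (closed form on the log rate), regenerate the history, and repeat a few
    # times so the noisy refit lands on target.
    fat_anchors = sorted(
        (a for a in anchors if a.quantity in ("fatalities", "baseline_fatalities")),
        key=lambda a: a.year,
    )
    if fat_anchors:
        cfg = work.config
        stock_cache = baseline_total_stock(work, _years_needed(anchors, work))
        for _ in range(5):
            work.history = _generate_history(
                work.sales, work.survival, work.population, cfg, work.seed
            )
            model = fitted_risk_model(work)
            log_errs = {}
            for a in fat_anchors:
                stock = stock_cache[a.year]
                pred = stock * model.rate_per_vehicle(stock / work.population[a.year])
                log_errs[a.year] = np.log(a.value / pred)
            if max(abs(e) for e in log_errs.values()) < 1e-3:
                break
            years_ = [a.year for a in fat_anchors]
            m = {
                y: stock_cache[y] / work.population[y] for y in years_
            }
            if len(years_) >= 2:
                y0, y1 = years_[0], years_[-1]
                db = -(log_errs[y1] - log_errs[y0]) / np.log(m[y1] / m[y0])
                da = log_errs[y0] + db * np.log(m[y0])
            else:
                y0 = years_[0]
                db, da = 0.0, log_errs[y0]
            cfg = replace(cfg, smeed_a=cfg.smeed_a + da, smeed_b=cfg.smeed_b + db)
        work.config = cfg

    # Road inventory: rescale the growth trajectory toward mileage anchors.
    mil_anchors = [a for a in anchors if a.quantity == "fir_mileage"]
    for a in mil_anchors:
        current = ir_mileage(work.inventory, coverage_schedule(IRLevel.FIR), a.year)
        ratio = a.value / current
        if abs(ratio - 1.0) > a.rel_tol / 2:
            work.inventory = _rescale_inventory(work.inventory, a.year, ratio)

    res = residuals(work)
    unmet = {
        k: r
        for a in anchors
        if abs((r := res[_anchor_key(a)])) > a.rel_tol
        for k in [_anchor_key(a)]
    }
    report = CalibrationReport(
        res, iterations, {"sales_hist": s_hist, "sales_future": s_future}
    )
    if unmet:
        raise CalibrationError("calibration did not converge", unmet)
    work.calibration = report
    return work


def _years_needed(anchors: AnchorSet, bundle: CountryInputBundle) -> list[int]:
    ys = {a.year for a in anchors if a.quantity != "fir_mileage"}
    ys.update(bundle.history.years)
    return sorted(ys)


def _rescale_inventory(inventory: RoadInventory, year: int, ratio: float) -> RoadInventory:
    """Multiply mileage by a factor ramping linearly from 1 (at 2021) to
    ``ratio`` at ``year`` — shapes and type proportions are preserved."""
    base_year = 2021
    table = {}
    for y in inventory.years:
        w = np.clip((y - base_year) / (year - base_year), 0.0, 1.0)
        f = 1.0 + (ratio - 1.0) * w
        table[y] = {t: inventory.mileage[y][t] * f for t in ROAD_TYPES}
    return RoadInventory(table)
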