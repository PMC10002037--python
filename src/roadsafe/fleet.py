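"""Vehicle-fleet turnover: stock projection from sales, survival and AV uptake.

The stock of automation type ``v`` in year ``y`` accumulates surviving sale
cohorts::

    VS[v, y] = sum_{j = y-l .. y}  Sales[j] * PR[v, j] * SR[y - j]

where ``SR`` is the age-survival curve (zero at and beyond the lifespan
``l``) and ``PR[v, j]`` is the AV penetration of new sales in the sale year
``j``.  Evaluating penetration at the sale year keeps cohorts faithful to
what was actually sold; the alternative reading (penetration at the
observation year, which retroactively converts old cohorts) is available via
``penetration_at="observation"``.

The fleet-wide V2V share PVV is the equipped fraction of the stock under a
:class:`~roadsafe.scenarios.EquipageRule`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scenarios import EquipageRule, PenetrationSchedule, VehicleType

__all__ = [
    "SalesSeries",
    "SurvivalCurve",
    "FleetState",
    "project_stock",
    "fleet_v2v_share",
    "read_sales_csv",
    "write_sales_csv",
    "read_survival_csv",
    "write_survival_csv",
    "write_fleet_csv",
]


@dataclass(frozen=True)
class SalesSeries:
    """Annual new-vehicle sales (units: vehicles)."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        bad = {y: v for y, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"negative sales: {bad}")

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    @property
    def years(self) -> list[int]:
        return sorted(self.values)

    def scaled(self, factor_for_year) -> "SalesSeries":
        """New series with each year multiplied by ``factor_for_year(year)``."""
        return SalesSeries({y: v * factor_for_year(y) for y, v in self.values.items()})


@dataclass(frozen=True)
class SurvivalCurve:
    """Probability that a vehicle is still in service at integer age.

    ``probabilities[a]`` is the survival at age ``a`` for ``a = 0..lifespan-1``;
    survival is defined as 0 at and beyond ``lifespan``.
    """

    lifespan: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if len(p) != self.lifespan:
            raise ValueError("need one survival value per age 0..lifespan-1")
        if not np.isclose(p[0], 1.0):
            raise ValueError("survival at age 0 must be 1")
        if np.any(np.diff(p) > 1e-12) or np.any(p < 0):
            raise ValueError("survival must be non-increasing and non-negative")

    def __call__(self, age: int) -> float:
        if age < 0:
            raise ValueError("age must be non-negative")
        return float(self.probabilities[age]) if age < self.lifespan else 0.0

    @classmethod
    def weibull(cls, characteristic_life: float, shape: float, lifespan: int) -> "SurvivalCurve":
        """Smooth S-shaped curve exp(-(age/T)^k), truncated at ``lifespan``."""
        ages = np.arange(lifespan)
        return cls(lifespan, np.exp(-((ages / characteristic_life) ** shape)))

    def time_scaled(self, factor: float) -> "SurvivalCurve":
        """Stretch the age axis by ``factor`` (> 1 means longer-lived fleet)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        new_l = max(1, int(round(self.lifespan * factor)))
        old_ages = np.arange(self.lifespan)
        new_ages = np.arange(new_l) / factor
        p = np.interp(new_ages, old_ages, self.probabilities, right=0.0)
        p[0] = 1.0
        return SurvivalCurve(new_l, np.maximum.accumulate(p[::-1])[::-1])

    @property
    def expected_service_years(self) -> float:
        return float(self.probabilities.sum())


@dataclass
class FleetState:
    """Vehicle stock of one calendar year, split by automation type."""

    year: int
    stock_by_type: np.ndarray  # index = VehicleType, counts
    pvv: float | None = None  # filled per V2V scenario

    def __post_init__(self) -> None:
        s = np.asarray(self.stock_by_type, dtype=float)
        if s.shape != (4,):
            raise ValueError("stock_by_type must have one entry per vehicle type")
        if np.any(s < -1e-6):
            raise ValueError("negative stock")
        self.stock_by_type = s

    @property
    def total_stock(self) -> float:
        return float(self.stock_by_type.sum())

    def type_shares(self) -> np.ndarray:
        total = self.total_stock
        return self.stock_by_type / total if total > 0 else np.zeros(4)


def project_stock(
    sales: SalesSeries,
    survival: SurvivalCurve,
    schedule: PenetrationSchedule,
    years: Sequence[int],
    penetration_at: str = "sale",
) -> list[FleetState]:
    """Project the stock by automation type for each requested year.

    ``penetration_at="sale"`` (default) applies the AV sales shares of the
    cohort's sale year; ``"observation"`` applies the requested year's shares
    to every cohort.
    """
    if penetration_at not in ("sale", "observation"):
        raise ValueError("penetration_at must be 'sale' or 'observation'")
    years = sorted(years)
    needed = range(years[0] - survival.lifespan + 1, years[-1] + 1)
    missing = [j for j in needed if j not in sales.values]
    if missing:
        raise ValueError(
            "sales series does not cover the survival window; missing years: "
            f"{missing[0]}..{missing[-1]}"
        )

    states = []
    for y in years:
        stock = np.zeros(4)
        if penetration_at == "observation":
            obs_shares = _type_fractions(schedule, y)
        for age in range(survival.lifespan):
            j = y - age
            cohort = sales[j] * survival(age)
            if cohort == 0.0:
                continue
            fr = obs_shares if penetration_at == "observation" else _type_fractions(schedule, j)
            stock += cohort * fr
        states.append(FleetState(year=y, stock_by_type=stock))
    return states


def _type_fractions(schedule: PenetrationSchedule, year: int) -> np.ndarray:
    p1, p2, p3 = schedule.shares(year)
    return np.array([1.0 - p1 - p2 - p3, p1, p2, p3])


def fleet_v2v_share(fleet: FleetState, rule: EquipageRule, year: int | None = None) -> float:
    """Fraction of the stock that is V2V-equipped under ``rule`` (PVV)."""
    if year is None:
        year = fleet.year
    total = fleet.total_stock
    if total <= 0:
        warnings.warn("zero total stock; V2V share set to 0", stacklevel=2)
        return 0.0
    eligible = rule.eligible_at(year)
    if len(eligible) == len(VehicleType):
        return 1.0  # whole-fleet retrofit: exact by definition
    equipped = sum(fleet.stock_by_type[t] for t in eligible)
    return float(equipped / total)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_sales_csv(path: str | Path) -> SalesSeries:
    """Read a ``year,sales`` CSV (header row required)."""
    values: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values[int(row["year"])] = float(row["sales"])
    return SalesSeries(values)


def write_sales_csv(sales: SalesSeries, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "sales"])
        for y in sales.years:
            w.writerow([y, repr(float(sales[y]))])


def read_survival_csv(path: str | Path) -> SurvivalCurve:
    """Read an ``age,survival`` CSV (ages 0..l-1, header row required)."""
    rows: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows[int(row["age"])] = float(row["survival"])
    ages = sorted(rows)
    if ages != list(range(len(ages))):
        raise ValueError("survival CSV must list consecutive ages from 0")
    return SurvivalCurve(len(ages), np.array([rows[a] for a in ages]))


def write_survival_csv(curve: SurvivalCurve, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age", "survival"])
        for a in range(curve.lifespan):
            w.writerow([a, repr(float(curve.probabilities[a]))])


def write_fleet_csv(states: Iterable[FleetState], path: str | Path) -> None:
    """Per-year fleet table: ``year,traditional,primary,partially,fully,total,pvv``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "traditional", "primary", "partially", "fully", "total", "pvv"])
        for st in states:
            w.writerow(
                [st.year, *(f"{x:.3f}" for x in st.stock_by_type), f"{st.total_stock:.3f}",
                 "" if st.pvv is None else f"{st.pvv:.6f}"]
            )
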