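"""Baseline crash-risk models: Smeed / Brosos fatality laws and severities.

Both laws relate the per-vehicle fatality rate to the motorisation ratio
``m = stock / population``:

* Smeed:  fatalities / vehicle = exp(a) * m**(-b)   (power-law decline)
* Brosos: fatalities / vehicle = a * exp(-b * m)    (exponential decline)

Each is log-linear, so parameters are fitted by ordinary least squares on
the log per-vehicle rate.  Model choice is by mean absolute percentage
error on a held-out tail of the history.  The fitted rate is rendered as
FPT — fatalities per billion vehicle-kilometres — through the average
annual distance travelled per vehicle (AVKT); the fatality count itself,
``stock * rate``, does not depend on AVKT.

Injury and property-damage-only (PDO) crash counts scale off the fatality
count with fixed national multipliers (severe 4x, minor 42x, PDO 135x).
Crash counts and casualty counts are used interchangeably at each severity
(one fatal crash counted as one fatality).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_AVKT",
    "ModelForm",
    "RiskHistory",
    "RiskModel",
    "SeverityMultipliers",
    "Severity",
    "FittingError",
    "fit_fatality_model",
    "select_fatality_model",
    "baseline_annual",
    "expand_to_severities",
    "read_history_csv",
    "write_history_csv",
]

#: Default average annual vehicle-kilometres travelled per vehicle (km/year).
DEFAULT_AVKT = 15_000.0

MIN_FIT_YEARS = 5


class ModelForm(str, Enum):
    SMEED = "smeed"
    BROSOS = "brosos"


class Severity(str, Enum):
    PDO = "pdo"
    MINOR = "minor"
    SEVERE = "severe"
    FATAL = "fatal"


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class RiskHistory:
    """Observed (vehicle stock, population, fatalities) by year."""

    records: Mapping[int, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for year, (stock, pop, fat) in self.records.items():
            if stock <= 0 or pop <= 0 or fat <= 0:
                raise ValueError(f"non-positive history entry in {year}")

    @property
    def years(self) -> list[int]:
        return sorted(self.records)

    def subset(self, years) -> "RiskHistory":
        return RiskHistory({y: self.records[y] for y in years})

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ys = self.years
        stock = np.array([self.records[y][0] for y in ys])
        pop = np.array([self.records[y][1] for y in ys])
        fat = np.array([self.records[y][2] for y in ys])
        return stock, pop, fat


@dataclass(frozen=True)
class RiskModel:
    """Fitted fatality law with its distance normalisation."""

    form: ModelForm
    a: float
    b: float
    avkt: float = DEFAULT_AVKT

    def rate_per_vehicle(self, motorization) -> np.ndarray | float:
        """Annual fatalities per vehicle at motorisation ratio m = VS/Pop."""
        m = np.asarray(motorization, dtype=float)
        if np.any(m <= 0):
            raise ValueError("motorisation ratio must be positive")
        if self.form is ModelForm.SMEED:
            out = np.exp(self.a) * m ** (-self.b)
        else:
            out = self.a * np.exp(-self.b * m)
        return float(out) if out.ndim == 0 else out

    def fpt(self, motorization) -> np.ndarray | float:
        """Fatalities per billion vehicle-km travelled (FPT)."""
        r = self.rate_per_vehicle(motorization)
        return r / self.avkt * 1e9

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"form": self.form.value, "a": self.a, "b": self.b, "avkt": self.avkt})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(ModelForm(d["form"]), d["a"], d["b"], d["avkt"])


def fit_fatality_model(
    history: RiskHistory, form: ModelForm | str, avkt: float = DEFAULT_AVKT
) -> RiskModel:
    """Least-squares fit of one law on the log per-vehicle fatality rate."""
    form = ModelForm(form)
    stock, pop, fat = history.arrays()
    if len(stock) < MIN_FIT_YEARS:
        raise ValueError(f"need at least {MIN_FIT_YEARS} years of history")
    m = stock / pop
    log_rate = np.log(fat / stock)
    x = np.log(m) if form is ModelForm.SMEED else m
    if np.ptp(x) < 1e-12:
        raise FittingError("motorisation ratio is constant; fit is singular")
    slope, intercept = np.polyfit(x, log_rate, 1)
    if form is ModelForm.SMEED:
        return RiskModel(form, a=float(intercept), b=float(-slope), avkt=avkt)
    return RiskModel(form, a=float(np.exp(intercept)), b=float(-slope), avkt=avkt)


def select_fatality_model(
    history: RiskHistory, holdout_years: int = 3, avkt: float = DEFAULT_AVKT
) -> RiskModel:
    """Fit both laws on the earlier years and keep the one with the lower
    mean absolute percentage error on the held-out final years (tie: Smeed)."""
    years = history.years
    if not (1 <= holdout_years < len(years)):
        raise ValueError("holdout_years must be >= 1 and smaller than the history length")
    if len(years) - holdout_years < MIN_FIT_YEARS:
        raise ValueError("too few training years before the holdout window")
    train = history.subset(years[:-holdout_years])
    test = history.subset(years[-holdout_years:])
    stock, pop, fat = test.arrays()
    scores: dict[ModelForm, tuple[float, RiskModel]] = {}
    for form in (ModelForm.SMEED, ModelForm.BROSOS):
        model = fit_fatality_model(train, form, avkt=avkt)
        pred = stock * model.rate_per_vehicle(stock / pop)
        mape = float(np.mean(np.abs(pred - fat) / fat))
        scores[form] = (mape, model)
    smeed_mape, smeed_model = scores[ModelForm.SMEED]
    brosos_mape, brosos_model = scores[ModelForm.BROSOS]
    return brosos_model if brosos_mape < smeed_mape else smeed_model


def baseline_annual(
    model: RiskModel, year: int, stock: float, population: float
) -> tuple[float, float]:
    """(FPT in fatalities per billion km, baseline fatality count) for one year."""
    if population <= 0:
        raise ValueError("population must be positive")
    if stock < 0:
        raise ValueError("stock must be non-negative")
    if stock == 0:
        return 0.0, 0.0
    fpt = float(model.fpt(stock / population))
    fatalities = stock * model.avkt * fpt / 1e9
    return fpt, fatalities


@dataclass(frozen=True)
class SeverityMultipliers:
    """Crashes of each non-fatal severity per road fatality."""

    severe_per_fatality: float = 4.0
    minor_per_fatality: float = 42.0
    pdo_per_fatality: float = 135.0

    def __post_init__(self) -> None:
        if min(self.severe_per_fatality, self.minor_per_fatality, self.pdo_per_fatality) < 0:
            raise ValueError("multipliers must be non-negative")


def expand_to_severities(
    fatalities: float, multipliers: SeverityMultipliers = SeverityMultipliers()
) -> dict[Severity, float]:
    """Crash counts by severity implied by a fatality count."""
    if np.any(np.asarray(fatalities) < 0):
        raise ValueError("fatalities must be non-negative")
    return {
        Severity.PDO: multipliers.pdo_per_fatality * fatalities,
        Severity.MINOR: multipliers.minor_per_fatality * fatalities,
        Severity.SEVERE: multipliers.severe_per_fatality * fatalities,
        Severity.FATAL: fatalities,
    }


def read_history_csv(path: str | Path) -> RiskHistory:
    """Read a ``year,stock,population,fatalities`` CSV."""
    records = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records[int(row["year"])] = (
                float(row["stock"]),
                float(row["population"]),
                float(row["fatalities"]),
            )
    return RiskHistory(records)


def write_history_csv(history: RiskHistory, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "stock", "population", "fatalities"])
        for y in history.years:
            stock, pop, fat = history.records[y]
            w.writerow([y, repr(float(stock)), repr(float(pop)), repr(float(fat))])
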