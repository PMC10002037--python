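"""Scenario impact engine: blended crash-avoidance effectiveness.

For one scenario-year the fatality count blends, per vehicle type ``v``, the
exposure split between traditional and intelligent roads (``PTR``) and the
probability that a V2V interaction is available.  Because a V2V safety
function needs both the ego and the interacting vehicle equipped, the fleet
V2V share ``PVV`` enters squared::

    Fata[y, s] = sum_v VS[v, y] * AVKT * FPT[y] / 1e9
                 * sum_r PTR[r, y] * ( PVV^2  * (1 - Eff[v, r, on])
                                     + (1-PVV^2) * (1 - Eff[v, r, off]) )

``Eff`` is the comprehensive collision-avoidance effectiveness table: 16
values over vehicle type x road class x V2V state, estimated elsewhere from
sensing-technology / safety-function coverage of national crash types.  With
all effectiveness zero the expression collapses to the baseline fatality
count exactly.

Injury severities scale off fatalities; reductions are taken against the
no-deployment baseline; cumulative windows are plain sums of annual
reductions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fleet import FleetState
from .risk import Severity, SeverityMultipliers, expand_to_severities
from .scenarios import ScenarioSpec, VehicleType

__all__ = [
    "EffectivenessTable",
    "ImpactResult",
    "blended_survival_factor",
    "scenario_fatalities",
    "annual_series",
    "cumulative_reductions",
    "sdg_check",
    "read_effectiveness_csv",
    "write_effectiveness_csv",
]

# Comprehensive collision-avoidance effectiveness, [vehicle_type, road, v2v]:
# road 0 = traditional, 1 = intelligent; v2v 0 = off, 1 = working.
_DEFAULT_EFF = np.zeros((4, 2, 2))
_DEFAULT_EFF[:, 0, 0] = (0.000, 0.368, 0.556, 0.891)
_DEFAULT_EFF[:, 0, 1] = (0.267, 0.604, 0.747, 0.920)
_DEFAULT_EFF[:, 1, 0] = (0.267, 0.929, 0.946, 0.983)
_DEFAULT_EFF[:, 1, 1] = (0.463, 0.952, 0.967, 0.988)


@dataclass(frozen=True)
class EffectivenessTable:
    """Crash-avoidance effectiveness Eff[v, r, vv] in [0, 1)."""

    values: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = _DEFAULT_EFF.copy() if self.values is None else np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.shape != (4, 2, 2):
            raise ValueError("effectiveness table must be 4 x 2 x 2")
        if np.any(v < 0) or np.any(v >= 1):
            raise ValueError("effectiveness values must lie in [0, 1)")
        if v[0, 0, 0] != 0:
            raise ValueError("an unassisted traditional vehicle has zero effectiveness")
        if (
            np.any(np.diff(v, axis=0) < -1e-12)
            or np.any(np.diff(v, axis=1) < -1e-12)
            or np.any(np.diff(v, axis=2) < -1e-12)
        ):
            raise ValueError("effectiveness must be non-decreasing in v, r and vv")

    def __getitem__(self, key) -> float:
        return float(self.values[key])


def _v2v_weight(pvv: float, v2v_mixing: str) -> float:
    if v2v_mixing == "squared":
        return pvv * pvv
    if v2v_mixing == "linear":
        return pvv
    raise ValueError("v2v_mixing must be 'squared' or 'linear'")


def blended_survival_factor(
    v: VehicleType | int,
    ptr1: float,
    pvv: float,
    eff: EffectivenessTable | None = None,
    v2v_mixing: str = "squared",
) -> float:
    """Fraction of baseline crash risk that survives for vehicle type ``v``.

    Blends the four (road, V2V) branches of the effectiveness table by the
    travel split ``ptr1`` and the pairwise V2V availability ``pvv**2``.
    """
    if not (0.0 <= ptr1 <= 1.0 and 0.0 <= pvv <= 1.0):
        raise ValueError("ptr1 and pvv must lie in [0, 1]")
    eff = eff or EffectivenessTable()
    w = _v2v_weight(pvv, v2v_mixing)
    v = int(v)
    out = 0.0
    for r, ptr in ((0, 1.0 - ptr1), (1, ptr1)):
        out += ptr * (w * (1.0 - eff[v, r, 1]) + (1.0 - w) * (1.0 - eff[v, r, 0]))
    return out


def scenario_fatalities(
    fleet: FleetState,
    ptr1: float,
    pvv: float,
    fpt: float,
    avkt: float,
    eff: EffectivenessTable | None = None,
    v2v_mixing: str = "squared",
    v2v_eligible: frozenset[VehicleType] | None = None,
) -> float:
    """Scenario fatality count for one year (Fata), summed over vehicle types.

    By default the fleet-wide V2V share applies uniformly to every ego
    vehicle type, as the blend is written; passing ``v2v_eligible`` gates the
    V2V-working branch on the ego type being equippable at all.
    """
    eff = eff or EffectivenessTable()
    total = 0.0
    for v in VehicleType:
        stock = float(fleet.stock_by_type[v])
        if stock == 0.0:
            continue
        pvv_v = pvv if (v2v_eligible is None or v in v2v_eligible) else 0.0
        total += (
            stock * avkt * fpt / 1e9 * blended_survival_factor(v, ptr1, pvv_v, eff, v2v_mixing)
        )
    return total


@dataclass
class ImpactResult:
    """Per-scenario annual fatality/injury series and reductions vs baseline."""

    label: str
    table: pd.DataFrame  # index: year; columns: fatalities, severe, minor, pdo,
    #                      baseline_*, reduction_*

    @property
    def years(self) -> pd.Index:
        return self.table.index


_SEV_ORDER = (Severity.FATAL, Severity.SEVERE, Severity.MINOR, Severity.PDO)
_SEV_COL = {
    Severity.FATAL: "fatalities",
    Severity.SEVERE: "severe",
    Severity.MINOR: "minor",
    Severity.PDO: "pdo",
}


def annual_series(
    spec: ScenarioSpec,
    fleets: Sequence[FleetState],
    ptr1: Mapping[int, float],
    pvv: Mapping[int, float],
    fpt: Mapping[int, float],
    baseline_fatalities: Mapping[int, float],
    avkt: float,
    eff: EffectivenessTable | None = None,
    multipliers: SeverityMultipliers = SeverityMultipliers(),
    v2v_mixing: str = "squared",
    equipage_rule=None,
    type_aware_v2v: bool = False,
) -> ImpactResult:
    """Evaluate the blended fatality model for every year of a scenario.

    All per-year inputs must cover exactly the fleet years; severities are
    expanded from fatalities on both the scenario and baseline sides, and
    reductions are baseline minus scenario.
    """
    eff = eff or EffectivenessTable()
    years = [f.year for f in fleets]
    for name, series in (
        ("ptr1", ptr1), ("pvv", pvv), ("fpt", fpt), ("baseline", baseline_fatalities)
    ):
        missing = [y for y in years if y not in series]
        if missing:
            raise ValueError(f"{name} series missing years {missing}")

    if type_aware_v2v and equipage_rule is None:
        raise ValueError("type_aware_v2v requires the scenario's equipage rule")

    rows = []
    for f in fleets:
        y = f.year
        eligible = (
            frozenset(equipage_rule.eligible_at(y)) if type_aware_v2v else None
        )
        fat = scenario_fatalities(
            f, ptr1[y], pvv[y], fpt[y], avkt, eff, v2v_mixing, v2v_eligible=eligible
        )
        sev = expand_to_severities(fat, multipliers)
        base = expand_to_severities(baseline_fatalities[y], multipliers)
        row = {"year": y, "ptr1": ptr1[y], "pvv": pvv[y]}
        for s in _SEV_ORDER:
            col = _SEV_COL[s]
            row[col] = sev[s]
            row[f"baseline_{col}"] = base[s]
            row[f"reduction_{col}"] = base[s] - sev[s]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("year")
    return ImpactResult(label=spec.label, table=table)


def cumulative_reductions(
    result: ImpactResult, window: Sequence[int] | range = range(2015, 2051)
) -> dict[Severity, float]:
    """Summed annual reductions vs baseline over ``window``, by severity."""
    years = [y for y in window if y in result.table.index]
    if len(list(window)) == 0:
        raise ValueError("empty window")
    if not years:
        raise ValueError("window does not overlap the computed year range")
    sub = result.table.loc[years]
    return {s: float(sub[f"reduction_{_SEV_COL[s]}"].sum()) for s in _SEV_ORDER}


def sdg_check(
    result: ImpactResult,
    base_year: int = 2020,
    target_year: int = 2030,
    fraction: float = 0.5,
) -> tuple[bool, float]:
    """Does the scenario halve fatalities by ``target_year`` vs ``base_year``?

    The reference count is the baseline (historical) fatality level of the
    base year.  Returns (target met, fatality ratio).
    """
    for y in (base_year, target_year):
        if y not in result.table.index:
            raise ValueError(f"year {y} outside the computed range")
    ratio = float(
        result.table.loc[target_year, "fatalities"]
        / result.table.loc[base_year, "baseline_fatalities"]
    )
    return ratio <= fraction, ratio


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_effectiveness_csv(path: str | Path) -> EffectivenessTable:
    """Read a ``vehicle_type,road,v2v,effectiveness`` CSV (16 rows)."""
    values = np.full((4, 2, 2), np.nan)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values[int(row["vehicle_type"]), int(row["road"]), int(row["v2v"])] = float(
                row["effectiveness"]
            )
    if np.isnan(values).any():
        raise ValueError("effectiveness CSV must define all 16 cells")
    return EffectivenessTable(values)


def write_effectiveness_csv(eff: EffectivenessTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vehicle_type", "road", "v2v", "effectiveness"])
        for v in range(4):
            for r in range(2):
                for vv in range(2):
                    w.writerow([v, r, vv, repr(float(eff.values[v, r, vv]))])


def write_impact_csv(result: ImpactResult, path: str | Path) -> None:
    """Per-scenario annual output table."""
    result.table.to_csv(path, float_format="%.6f")
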