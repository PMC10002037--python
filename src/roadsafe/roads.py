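"""Road network inventory, intelligent-road coverage, and travel exposure.

Eight road types are tracked (mileage in thousand km): urban expressways,
urban ordinary roads, expressways, Class I-IV highways, and substandard
roads.  An intelligent-road (IR) deployment level prescribes, per road type,
a linear construction ramp ending in a full-coverage year.  The proportion
of vehicle travel that happens on intelligent roads is the travel-mix
weighted coverage::

    PTR1[y] = sum_t DDR[t] * RIR[t, y]

where ``DDR`` is the lifetime distribution of driving distance across road
types and ``RIR`` the IR coverage fraction of each type.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .scenarios import IRLevel

__all__ = [
    "ROAD_TYPES",
    "SELECTED_TYPES",
    "MILEAGE_2021",
    "RoadInventory",
    "TravelMix",
    "CoverageSchedule",
    "coverage_schedule",
    "ir_coverage_fraction",
    "proportion_travel_on_ir",
    "ir_mileage",
    "default_travel_mix",
    "read_inventory_csv",
    "write_inventory_csv",
    "read_mix_csv",
    "write_mix_csv",
]

ROAD_TYPES: tuple[str, ...] = (
    "urban_expressway",
    "urban_ordinary_road",
    "expressway",
    "class_i",
    "class_ii",
    "class_iii",
    "class_iv",
    "substandard",
)

#: The five road types selected for IR conversion in the planned scenarios.
SELECTED_TYPES: tuple[str, ...] = ROAD_TYPES[:5]

#: Reported 2021 mileages by type (thousand km).  These national statistics
#: are used as soft anchors for the synthetic inventory.
MILEAGE_2021: dict[str, float] = {
    "urban_expressway": 169.0,
    "urban_ordinary_road": 128.0,
    "expressway": 426.0,
    "class_i": 467.0,
    "class_ii": 3871.0,
    "class_iii": 2190.0,
    "class_iv": 24.0,
    "substandard": 493.0,
}

#: Share of lifetime driving distance carried by the five selected types.
SELECTED_TRAVEL_SHARE = 0.876


@dataclass(frozen=True)
class RoadInventory:
    """Mileage (thousand km) by year and road type."""

    mileage: Mapping[int, Mapping[str, float]]  # year -> type -> thousand km

    def __post_init__(self) -> None:
        for year, row in self.mileage.items():
            unknown = set(row) - set(ROAD_TYPES)
            if unknown:
                raise ValueError(f"unknown road types in {year}: {unknown}")
            if any(v < 0 for v in row.values()):
                raise ValueError(f"negative mileage in {year}")

    def row(self, year: int) -> dict[str, float]:
        try:
            return dict(self.mileage[year])
        except KeyError as exc:
            raise ValueError(f"inventory does not cover year {year}") from exc

    @property
    def years(self) -> list[int]:
        return sorted(self.mileage)


def interpolated_inventory(
    anchors: Mapping[int, Mapping[str, float]], years: range
) -> RoadInventory:
    """Inventory on ``years`` by per-type linear interpolation of anchor years
    (held flat outside the anchor span)."""
    ay = sorted(anchors)
    table = {}
    for y in years:
        table[y] = {
            t: float(np.interp(y, ay, [anchors[a][t] for a in ay]))
            for t in ROAD_TYPES
        }
    return RoadInventory(table)


@dataclass(frozen=True)
class TravelMix:
    """Distribution of lifetime vehicle-kilometres across road types (DDR)."""

    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.shares) != set(ROAD_TYPES):
            raise ValueError("mix must cover exactly the eight road types")
        if any(v < 0 for v in self.shares.values()):
            raise ValueError("negative travel share")
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"travel shares must sum to 1 (got {total})")


def default_travel_mix(
    selected_share: float = SELECTED_TRAVEL_SHARE,
    mileage: Mapping[str, float] | None = None,
) -> TravelMix:
    """Split the aggregate selected/other travel shares across road types in
    proportion to their 2021 mileages."""
    m = dict(MILEAGE_2021 if mileage is None else mileage)
    sel = sum(m[t] for t in SELECTED_TYPES)
    oth = sum(m[t] for t in ROAD_TYPES if t not in SELECTED_TYPES)
    shares = {}
    for t in ROAD_TYPES:
        if t in SELECTED_TYPES:
            shares[t] = selected_share * m[t] / sel
        else:
            shares[t] = (1.0 - selected_share) * m[t] / oth
    return TravelMix(shares)


@dataclass(frozen=True)
class CoverageSchedule:
    """Per-road-type IR construction schedule for one deployment level.

    ``full_year`` maps a road type to the year of full coverage (types not
    listed are never converted); construction ramps linearly from
    ``ramp_start``.
    """

    ir_level: IRLevel
    full_year: Mapping[str, int]
    ramp_start: int = 2023

    def __post_init__(self) -> None:
        unknown = set(self.full_year) - set(ROAD_TYPES)
        if unknown:
            raise ValueError(f"unknown road types: {unknown}")


#: Full-coverage years for the planned deployment of the five selected types.
_APIR_YEARS = {
    "urban_expressway": 2030,
    "urban_ordinary_road": 2035,
    "expressway": 2030,
    "class_i": 2035,
    "class_ii": 2040,
}
_RGIR_YEARS = {t: 2025 for t in SELECTED_TYPES}
_FIR_YEARS = {**_RGIR_YEARS, "class_iii": 2030, "class_iv": 2030, "substandard": 2030}


def coverage_schedule(ir_level: IRLevel, ramp_start: int = 2023) -> CoverageSchedule:
    level = IRLevel(ir_level)
    table = {
        IRLevel.NIR: {},
        IRLevel.APIR: _APIR_YEARS,
        IRLevel.RGIR: _RGIR_YEARS,
        IRLevel.FIR: _FIR_YEARS,
    }[level]
    return CoverageSchedule(level, table, ramp_start)


def ir_coverage_fraction(schedule: CoverageSchedule, road_type: str, year: float) -> float:
    """IR coverage fraction of ``road_type`` in ``year`` (RIR), in [0, 1]."""
    if road_type not in ROAD_TYPES:
        raise ValueError(f"unknown road type: {road_type!r}")
    full = schedule.full_year.get(road_type)
    if full is None:
        return 0.0
    if year >= full:
        return 1.0
    if year <= schedule.ramp_start:
        return 0.0
    return (year - schedule.ramp_start) / (full - schedule.ramp_start)


def proportion_travel_on_ir(mix: TravelMix, schedule: CoverageSchedule, year: float) -> float:
    """Travel-weighted IR coverage: PTR1 = sum_t DDR_t * RIR_t,y."""
    return float(
        sum(mix.shares[t] * ir_coverage_fraction(schedule, t, year) for t in ROAD_TYPES)
    )


def ir_mileage(inventory: RoadInventory, schedule: CoverageSchedule, year: int) -> float:
    """Thousand km of road covered by IR in ``year``."""
    row = inventory.row(year)
    return float(sum(row[t] * ir_coverage_fraction(schedule, t, year) for t in ROAD_TYPES))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_inventory_csv(path: str | Path) -> RoadInventory:
    """Read a ``year,road_type,mileage_thousand_km`` CSV."""
    table: dict[int, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(int(row["year"]), {})[row["road_type"]] = float(
                row["mileage_thousand_km"]
            )
    return RoadInventory(table)


def write_inventory_csv(inventory: RoadInventory, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "road_type", "mileage_thousand_km"])
        for y in inventory.years:
            for t in ROAD_TYPES:
                w.writerow([y, t, repr(float(inventory.mileage[y][t]))])


def read_mix_csv(path: str | Path) -> TravelMix:
    """Read a ``road_type,share`` CSV."""
    shares: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            shares[row["road_type"]] = float(row["share"])
    return TravelMix(shares)


def write_mix_csv(mix: TravelMix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["road_type", "share"])
        for t in ROAD_TYPES:
            w.writerow([t, repr(float(mix.shares[t]))])
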