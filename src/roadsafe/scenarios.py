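"""Deployment-scenario grid for autonomous vehicles, intelligent roads and V2V.

The study design crosses three technology axes:

* AV market-uptake level — ``NAV`` (none), ``SAV`` (slow: no fully-autonomous
  vehicles ever reach the market), ``RGAV`` (rapid growth: fully AVs become
  mainstream);
* intelligent-road construction level — ``NIR``, ``APIR`` (as planned),
  ``RGIR`` (rapid growth on the five selected road types), ``FIR`` (all eight
  road types);
* V2V equipage level — ``NV2V``, ``APV2V`` (partially/fully AVs only),
  ``HV2V`` (all AVs from 2025), ``FV2V`` (whole fleet from 2025).

The full factorial grid has 3 x 4 x 4 = 48 cells.  Cells that deploy road or
V2V infrastructure without any AVs, or intelligent roads without any V2V, have
no practical meaning and are filtered out, leaving 26 "synergetic" scenarios
plus the no-deployment baseline ``NAV-NIR-NV2V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from itertools import product
from typing import Mapping, Sequence


class AVLevel(str, Enum):
    NAV = "NAV"
    SAV = "SAV"
    RGAV = "RGAV"


class IRLevel(str, Enum):
    NIR = "NIR"
    APIR = "APIR"
    RGIR = "RGIR"
    FIR = "FIR"


class V2VLevel(str, Enum):
    NV2V = "NV2V"
    APV2V = "APV2V"
    HV2V = "HV2V"
    FV2V = "FV2V"


class VehicleType(IntEnum):
    """Automation level of a vehicle in the stock (index v = 0..3)."""

    TRADITIONAL = 0
    PRIMARY = 1
    PARTIALLY = 2
    FULLY = 3


#: Year from which fleet-wide V2V retrofit programmes take effect.
V2V_START_YEAR = 2025


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the AV x IR x V2V deployment grid."""

    av_level: AVLevel
    ir_level: IRLevel
    v2v_level: V2VLevel

    @property
    def label(self) -> str:
        return f"{self.av_level.value}-{self.ir_level.value}-{self.v2v_level.value}"

    @property
    def is_baseline(self) -> bool:
        return (
            self.av_level is AVLevel.NAV
            and self.ir_level is IRLevel.NIR
            and self.v2v_level is V2VLevel.NV2V
        )

    @property
    def is_valid_synergetic(self) -> bool:
        """A scenario is synergetic iff it deploys AVs, and never pairs
        intelligent roads with a fleet that has no V2V at all."""
        if self.av_level is AVLevel.NAV:
            return False
        if self.v2v_level is V2VLevel.NV2V and self.ir_level is not IRLevel.NIR:
            return False
        return True


def full_grid() -> list[ScenarioSpec]:
    """All 48 cells of the factorial grid, in lexicographic axis order."""
    return [
        ScenarioSpec(av, ir, vv)
        for av, ir, vv in product(AVLevel, IRLevel, V2VLevel)
    ]


def enumerate_valid_scenarios() -> list[ScenarioSpec]:
    """The 26 valid synergetic scenarios, lexicographic by (AV, IR, V2V)."""
    return [s for s in full_grid() if s.is_valid_synergetic]


def baseline_scenario() -> ScenarioSpec:
    """The no-deployment reference cell NAV-NIR-NV2V."""
    return ScenarioSpec(AVLevel.NAV, IRLevel.NIR, V2VLevel.NV2V)


def scenario_from_label(label: str) -> ScenarioSpec:
    av, ir, vv = label.split("-")
    return ScenarioSpec(AVLevel(av), IRLevel(ir), V2VLevel(vv))


# ---------------------------------------------------------------------------
# New-sales penetration schedules
# ---------------------------------------------------------------------------

ShareVector = tuple[float, float, float]  # (primary, partially, fully)

# Observed primary-AV sales shares: ~20% in 2021, 32.4% in 2022. Zero before.
_HISTORICAL: dict[int, ShareVector] = {
    2020: (0.0, 0.0, 0.0),
    2021: (0.20, 0.0, 0.0),
    2022: (0.324, 0.0, 0.0),
}


def _all_av_milestone(m2030: ShareVector, m2050: ShareVector) -> ShareVector:
    # Roadmap: every vehicle sold from 2035 on is an AV of some level. The
    # 2035 point is the straight-line interpolation of the 2030 and 2050
    # milestones, renormalised so the three AV shares sum to one.
    raw = tuple(a + (b - a) * (2035 - 2030) / (2050 - 2030) for a, b in zip(m2030, m2050))
    total = sum(raw)
    return tuple(x / total for x in raw)  # type: ignore[return-value]


@dataclass(frozen=True)
class PenetrationSchedule:
    """Piecewise-linear AV share of new-vehicle sales by milestone year.

    ``milestones`` maps a calendar year to the (primary, partially, fully)
    share vector; between milestones shares are interpolated linearly, before
    the first milestone they are zero, after the last they are held constant.
    """

    milestones: Mapping[int, ShareVector]

    def __post_init__(self) -> None:
        for year, shares in self.milestones.items():
            if any(s < -1e-12 or s > 1 + 1e-12 for s in shares):
                raise ValueError(f"share out of [0, 1] at {year}: {shares}")
            if sum(shares) > 1 + 1e-9:
                raise ValueError(f"shares sum past 1 at {year}: {shares}")

    def shares(self, year: float) -> ShareVector:
        years = sorted(self.milestones)
        if year <= years[0]:
            # zero before the first historical point
            return self.milestones[years[0]] if year == years[0] else (0.0, 0.0, 0.0)
        if year >= years[-1]:
            return self.milestones[years[-1]]
        import bisect

        i = bisect.bisect_right(years, year)
        y0, y1 = years[i - 1], years[i]
        w = (year - y0) / (y1 - y0)
        a, b = self.milestones[y0], self.milestones[y1]
        return tuple((1 - w) * x + w * y for x, y in zip(a, b))  # type: ignore[return-value]


_RGAV_2030: ShareVector = (0.35, 0.35, 0.20)
_RGAV_2050: ShareVector = (0.01, 0.09, 0.90)
_SAV_2030: ShareVector = (0.35, 0.55, 0.0)
_SAV_2050: ShareVector = (0.01, 0.99, 0.0)

DEFAULT_SCHEDULES: dict[AVLevel, PenetrationSchedule] = {
    AVLevel.NAV: PenetrationSchedule({2020: (0.0, 0.0, 0.0)}),
    AVLevel.SAV: PenetrationSchedule(
        {
            **_HISTORICAL,
            2025: (0.40, 0.10, 0.0),
            2030: _SAV_2030,
            2035: _all_av_milestone(_SAV_2030, _SAV_2050),
            2050: _SAV_2050,
        }
    ),
    AVLevel.RGAV: PenetrationSchedule(
        {
            **_HISTORICAL,
            2025: (0.40, 0.09, 0.01),
            2030: _RGAV_2030,
            2035: _all_av_milestone(_RGAV_2030, _RGAV_2050),
            2050: _RGAV_2050,
        }
    ),
}


def sales_penetration(
    av_level: AVLevel,
    year: float,
    schedules: Mapping[AVLevel, PenetrationSchedule] | None = None,
) -> ShareVector:
    """(primary, partially, fully) AV shares of new-vehicle sales in ``year``."""
    table = DEFAULT_SCHEDULES if schedules is None else schedules
    try:
        schedule = table[AVLevel(av_level)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown AV level: {av_level!r}") from exc
    return schedule.shares(year)


def schedules_from_yaml(block: Mapping) -> dict[AVLevel, PenetrationSchedule]:
    """Build penetration schedules from a ``scenarios:`` YAML mapping.

    Expected form::

        scenarios:
          RGAV:
            2025: [0.40, 0.09, 0.01]
            2030: [0.35, 0.35, 0.20]

    Levels not mentioned keep their defaults; listed levels are replaced
    wholesale (historical points must be restated if wanted).
    """
    out = dict(DEFAULT_SCHEDULES)
    for level_name, milestones in block.items():
        level = AVLevel(level_name)
        out[level] = PenetrationSchedule(
            {int(y): tuple(float(x) for x in v) for y, v in milestones.items()}
        )
    return out


# ---------------------------------------------------------------------------
# V2V equipage rules
# ---------------------------------------------------------------------------

_ALL_TYPES = frozenset(VehicleType)
_AV_TYPES = frozenset({VehicleType.PRIMARY, VehicleType.PARTIALLY, VehicleType.FULLY})
_CONNECTED_AV_TYPES = frozenset({VehicleType.PARTIALLY, VehicleType.FULLY})


@dataclass(frozen=True)
class EquipageRule:
    """Which vehicle types count as V2V-equipped, and from when.

    ``eligible_types`` applies at and after ``start_year`` (fleet-wide
    retrofit reading of "since 2025"); ``pre_start_eligible`` applies before
    it.  Partially and fully AVs carry V2V hardware from market entry, so the
    HV2V and FV2V programmes degenerate to the APV2V rule before their start
    year — this keeps equipage monotone across V2V levels at every year.
    """

    v2v_level: V2VLevel
    start_year: int
    eligible_types: frozenset[VehicleType]
    pre_start_eligible: frozenset[VehicleType] = field(default_factory=frozenset)

    def eligible_at(self, year: float) -> frozenset[VehicleType]:
        return self.eligible_types if year >= self.start_year else self.pre_start_eligible


_RULES: dict[V2VLevel, EquipageRule] = {
    V2VLevel.NV2V: EquipageRule(V2VLevel.NV2V, V2V_START_YEAR, frozenset()),
    V2VLevel.APV2V: EquipageRule(
        V2VLevel.APV2V, V2V_START_YEAR, _CONNECTED_AV_TYPES, _CONNECTED_AV_TYPES
    ),
    V2VLevel.HV2V: EquipageRule(
        V2VLevel.HV2V, V2V_START_YEAR, _AV_TYPES, _CONNECTED_AV_TYPES
    ),
    V2VLevel.FV2V: EquipageRule(
        V2VLevel.FV2V, V2V_START_YEAR, _ALL_TYPES, _CONNECTED_AV_TYPES
    ),
}


def v2v_equipage_rule(v2v_level: V2VLevel) -> EquipageRule:
    """Eligibility rule for a V2V deployment level."""
    try:
        return _RULES[V2VLevel(v2v_level)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown V2V level: {v2v_level!r}") from exc
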