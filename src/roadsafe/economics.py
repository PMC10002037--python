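"""Economic valuation of avoided crashes.

Annual savings are the avoided crashes at each injury severity times the
national unit economic cost of a crash of that severity (constant 2017 USD;
no inflation or discounting by default).  The unit costs aggregate medical
costs, lost productivity, travel delay, legal/court costs, insurance
administration and property damage.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .risk import Severity

__all__ = ["UnitCosts", "crash_cost_savings", "read_costs_csv", "write_costs_csv"]

_DEFAULT_COSTS: dict[Severity, float] = {
    Severity.PDO: 1_670.0,
    Severity.MINOR: 2_995.0,
    Severity.SEVERE: 128_195.0,
    Severity.FATAL: 471_192.0,
}


@dataclass(frozen=True)
class UnitCosts:
    """Economic cost per crash by severity (USD, 2017 price level)."""

    per_crash: Mapping[Severity, float] = field(
        default_factory=lambda: dict(_DEFAULT_COSTS)
    )

    def __post_init__(self) -> None:
        costs = {Severity(k): float(v) for k, v in self.per_crash.items()}
        object.__setattr__(self, "per_crash", costs)
        if set(costs) != set(Severity):
            raise ValueError("unit costs must cover all four severities")
        ordered = [costs[s] for s in (Severity.PDO, Severity.MINOR, Severity.SEVERE, Severity.FATAL)]
        if any(c <= 0 for c in ordered):
            raise ValueError("unit costs must be positive")
        if any(a >= b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("unit costs must increase strictly from PDO to fatal")

    def __getitem__(self, severity: Severity) -> float:
        return self.per_crash[Severity(severity)]


def crash_cost_savings(
    reductions: Mapping[int, Mapping[Severity, float]] | pd.DataFrame,
    costs: UnitCosts | None = None,
    discount_rate: float = 0.0,
    discount_base_year: int | None = None,
) -> pd.DataFrame:
    """Annual and cumulative savings (USD) from avoided crashes.

    ``reductions`` maps year -> severity -> avoided crash count (baseline
    minus scenario); a DataFrame with severity-named columns indexed by year
    is also accepted.  A non-zero ``discount_rate`` discounts each year to
    ``discount_base_year`` (defaults to the first year).
    Returns a DataFrame indexed by year with ``savings_usd`` and
    ``cumulative_usd`` columns.
    """
    costs = costs or UnitCosts()
    if isinstance(reductions, pd.DataFrame):
        reductions = {
            int(y): {Severity(c): float(row[c]) for c in reductions.columns}
            for y, row in reductions.iterrows()
        }
    years = sorted(reductions)
    if discount_base_year is None and years:
        discount_base_year = years[0]
    rows = []
    for y in years:
        by_sev = {Severity(s): float(v) for s, v in reductions[y].items()}
        if any(v < 0 for v in by_sev.values()):
            warnings.warn(
                f"negative crash reduction in {y}: scenario worse than baseline",
                stacklevel=2,
            )
        saving = sum(costs[s] * v for s, v in by_sev.items())
        if discount_rate:
            saving /= (1.0 + discount_rate) ** (y - discount_base_year)
        rows.append({"year": y, "savings_usd": saving})
    out = pd.DataFrame(rows).set_index("year")
    out["cumulative_usd"] = out["savings_usd"].cumsum()
    return out


def read_costs_csv(path: str | Path) -> UnitCosts:
    """Read a ``severity,usd`` CSV."""
    per_crash = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            per_crash[Severity(row["severity"])] = float(row["usd"])
    return UnitCosts(per_crash)


def write_costs_csv(costs: UnitCosts, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["severity", "usd"])
        for s in Severity:
            w.writerow([s.value, repr(costs[s])])
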