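#!/usr/bin/env python
"""Price the avoided crashes of every scenario: cumulative 2015-2050 savings
in crash-related economic costs at the national unit costs per severity
(2017 USD: PDO 1,670; minor 2,995; severe 128,195; fatal 471,192).

Writes results/economic_savings.csv.
"""

import csv
from pathlib import Path

from roadsafe.pipeline import RunConfig, run_pipeline

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    result = run_pipeline(RunConfig(seed=SEED))

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "economic_savings.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "cum_reduction_fatalities", "cum_reduction_severe",
                    "cum_reduction_minor", "cum_reduction_pdo", "cum_savings_billion_usd"])
        for row in result.summary:
            w.writerow([
                row["label"],
                f"{row['cum_reduction_fatalities']:.0f}",
                f"{row['cum_reduction_severe']:.0f}",
                f"{row['cum_reduction_minor']:.0f}",
                f"{row['cum_reduction_pdo']:.0f}",
                f"{row['cum_savings_usd'] / 1e9:.1f}",
            ])

    top = result.summary[0]
    print(f"largest saver: {top['label']} — "
          f"{top['cum_reduction_fatalities'] / 1e6:.2f} M fatalities, "
          f"{top['cum_reduction_severe'] / 1e6:.1f} M severe, "
          f"{top['cum_reduction_minor'] / 1e6:.1f} M minor, "
          f"{top['cum_reduction_pdo'] / 1e6:.1f} M PDO avoided; "
          f"${top['cum_savings_usd'] / 1e9:,.0f} B saved (2015-2050)")
    av_only = [r for r in result.summary if r["label"].endswith("NIR-NV2V")
               and not r["is_baseline"]]
    for row in av_only:
        print(f"AV-only {row['label']}: ${row['cum_savings_usd'] / 1e9:,.0f} B")


if __name__ == "__main__":
    main()
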