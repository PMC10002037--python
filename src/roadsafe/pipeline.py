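"""End-to-end scenario pipeline: inputs -> fleet -> exposure -> impacts.

``run_pipeline`` evaluates the baseline and all 26 synergetic deployment
scenarios over the reporting horizon (2015-2050 by default), writing one
annual CSV per scenario, a cross-scenario summary (2030 fatalities, SDG 3.6
status, cumulative reductions by severity, cumulative economic savings) and
a machine-readable JSON summary.  Output is deterministic for a fixed
configuration and seed; every table carries the configuration hash.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import economics, fleet, impact, risk, roads, scenarios, synthetic

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_bundle_from_csv"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    horizon: tuple[int, int] = (2015, 2050)
    inputs: str = "synthetic"  # "synthetic" or a directory of input CSVs
    seed: int = 0
    calibrate: bool = True
    scenario_labels: tuple[str, ...] | None = None  # None = all 26
    v2v_mixing: str = "squared"
    type_aware_v2v: bool = False
    penetration_at: str = "sale"
    ramp_start: int = 2023
    holdout_years: int = 3
    sdg_base_year: int = 2020
    sdg_target_year: int = 2030
    sdg_fraction: float = 0.5
    cumulative_window: tuple[int, int] = (2015, 2050)
    output_dir: str | None = None
    figures: bool = False

    def __post_init__(self) -> None:
        if self.horizon[0] >= self.horizon[1]:
            raise ValueError("horizon start must precede end")

    def digest(self) -> str:
        # hash the scientific configuration only, not where results land
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("output_dir", "figures")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("horizon", "cumulative_window", "scenario_labels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    bundle: synthetic.CountryInputBundle
    model: risk.RiskModel
    results: Mapping[str, impact.ImpactResult]  # label -> annual series
    summary: list[dict]  # one row per scenario, sorted by cumulative reduction
    written: list[Path] = field(default_factory=list)

    def result(self, label: str) -> impact.ImpactResult:
        return self.results[label]


def load_bundle_from_csv(directory: str | Path, seed: int = 0) -> synthetic.CountryInputBundle:
    """Assemble a bundle from the per-module CSV files in ``directory``
    (sales.csv, survival.csv, population.csv, history.csv, inventory.csv,
    mix.csv, manifest.yaml with ``avkt``)."""
    d = Path(directory)
    for name in ("sales", "survival", "population", "history", "inventory", "mix"):
        if not (d / f"{name}.csv").exists():
            raise FileNotFoundError(f"missing input file: {d / (name + '.csv')}")
    population = {}
    with open(d / "population.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            population[int(row["year"])] = float(row["population"])
    avkt = risk.DEFAULT_AVKT
    manifest = d / "manifest.yaml"
    if manifest.exists():
        import yaml

        avkt = float((yaml.safe_load(manifest.read_text()) or {}).get("avkt", avkt))
    return synthetic.CountryInputBundle(
        sales=fleet.read_sales_csv(d / "sales.csv"),
        survival=fleet.read_survival_csv(d / "survival.csv"),
        population=population,
        history=risk.read_history_csv(d / "history.csv"),
        inventory=roads.read_inventory_csv(d / "inventory.csv"),
        mix=roads.read_mix_csv(d / "mix.csv"),
        avkt=avkt,
        seed=seed,
        config=synthetic.GeneratorConfig(),
    )


def _stage(log: list[str], name: str, t0: float, detail: str = "") -> None:
    log.append(f"stage={name} elapsed={time.perf_counter() - t0:.3f}s {detail}".rstrip())


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    log: list[str] = [f"config_hash={config.digest()}"]
    t0 = time.perf_counter()

    # --- inputs -----------------------------------------------------------
    if config.inputs == "synthetic":
        bundle = synthetic.generate_inputs(config.seed)
        if config.calibrate:
            bundle = synthetic.calibrate_to_anchors(bundle)
    else:
        bundle = load_bundle_from_csv(config.inputs, config.seed)
    _stage(log, "inputs", t0, f"seed={config.seed} source={config.inputs}")

    # --- baseline risk ----------------------------------------------------
    selected = risk.select_fatality_model(bundle.history, config.holdout_years, avkt=bundle.avkt)
    model = risk.fit_fatality_model(bundle.history, selected.form, avkt=bundle.avkt)
    _stage(log, "risk_fit", t0, f"form={model.form.value} a={model.a:.4f} b={model.b:.4f}")

    years = list(range(config.horizon[0], config.horizon[1] + 1))

    # --- fleets per AV level ---------------------------------------------
    fleets_by_av = {
        level: fleet.project_stock(
            bundle.sales,
            bundle.survival,
            scenarios.DEFAULT_SCHEDULES[level],
            years,
            penetration_at=config.penetration_at,
        )
        for level in scenarios.AVLevel
    }
    _stage(log, "fleet", t0)

    # --- exposure ---------------------------------------------------------
    ptr1_by_ir = {
        level: {
            y: roads.proportion_travel_on_ir(
                bundle.mix, roads.coverage_schedule(level, config.ramp_start), y
            )
            for y in years
        }
        for level in scenarios.IRLevel
    }
    baseline_states = fleets_by_av[scenarios.AVLevel.NAV]
    fpt_series: dict[int, float] = {}
    baseline_fat: dict[int, float] = {}
    for st in baseline_states:
        fpt, fat = risk.baseline_annual(model, st.year, st.total_stock, bundle.population[st.year])
        fpt_series[st.year] = fpt
        baseline_fat[st.year] = fat
    _stage(log, "exposure", t0)

    # --- scenarios --------------------------------------------------------
    specs = [scenarios.baseline_scenario()] + scenarios.enumerate_valid_scenarios()
    if config.scenario_labels is not None:
        keep = set(config.scenario_labels) | {scenarios.baseline_scenario().label}
        specs = [s for s in specs if s.label in keep]

    results: dict[str, impact.ImpactResult] = {}
    summary_rows = []
    window = range(config.cumulative_window[0], config.cumulative_window[1] + 1)
    for spec in specs:
        av_fleets = fleets_by_av[spec.av_level]
        rule = scenarios.v2v_equipage_rule(spec.v2v_level)
        pvv = {st.year: fleet.fleet_v2v_share(st, rule) for st in av_fleets}
        res = impact.annual_series(
            spec,
            av_fleets,
            ptr1_by_ir[spec.ir_level],
            pvv,
            fpt_series,
            baseline_fat,
            bundle.avkt,
            v2v_mixing=config.v2v_mixing,
            equipage_rule=rule,
            type_aware_v2v=config.type_aware_v2v,
        )
        results[spec.label] = res
        cum = impact.cumulative_reductions(res, window)
        reductions = res.table[
            ["reduction_pdo", "reduction_minor", "reduction_severe", "reduction_fatalities"]
        ].rename(
            columns=lambda c: c.replace("reduction_", "").replace("fatalities", "fatal")
        )
        savings = economics.crash_cost_savings(reductions.loc[list(window)])
        met, ratio = impact.sdg_check(
            res, config.sdg_base_year, config.sdg_target_year, config.sdg_fraction
        )
        summary_rows.append(
            {
                "label": spec.label,
                "is_baseline": spec.is_baseline,
                "fatalities_2030": float(res.table.loc[2030, "fatalities"])
                if 2030 in res.table.index
                else None,
                "sdg_ratio": ratio,
                "sdg_met": bool(met),
                "cum_reduction_fatalities": cum[risk.Severity.FATAL],
                "cum_reduction_severe": cum[risk.Severity.SEVERE],
                "cum_reduction_minor": cum[risk.Severity.MINOR],
                "cum_reduction_pdo": cum[risk.Severity.PDO],
                "cum_savings_usd": float(savings["cumulative_usd"].iloc[-1]),
            }
        )
    summary_rows.sort(key=lambda r: (-r["cum_reduction_fatalities"], r["label"]))
    _stage(log, "scenarios", t0, f"n={len(specs)}")

    out = PipelineResult(config, bundle, model, results, summary_rows)
    if config.output_dir is not None:
        _write_outputs(out, log)
    return out


def _write_outputs(out: PipelineResult, log: list[str]) -> None:
    d = Path(out.config.output_dir)
    d.mkdir(parents=True, exist_ok=True)
    digest = out.config.digest()
    for label, res in sorted(out.results.items()):
        path = d / f"annual_{label}.csv"
        with open(path, "w", newline="") as fh:
            fh.write(f"# config_hash={digest}\n")
            res.table.to_csv(fh, float_format="%.6f", lineterminator="\n")
        out.written.append(path)

    summary_path = d / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        fh.write(f"# config_hash={digest}\n")
        writer = csv.DictWriter(fh, fieldnames=list(out.summary[0]), lineterminator="\n")
        writer.writeheader()
        for row in out.summary:
            writer.writerow(
                {k: (f"{v:.6f}" if isinstance(v, float) else v) for k, v in row.items()}
            )
    out.written.append(summary_path)

    sdg_path = d / "sdg_achievement.csv"
    with open(sdg_path, "w", newline="") as fh:
        fh.write(f"# config_hash={digest}\n")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["label", "sdg_ratio", "sdg_met"])
        for row in sorted(out.summary, key=lambda r: r["label"]):
            w.writerow([row["label"], f"{row['sdg_ratio']:.6f}", row["sdg_met"]])
    out.written.append(sdg_path)

    json_path = d / "summary.json"
    json_path.write_text(
        json.dumps(
            {
                "config_hash": digest,
                "model": {"form": out.model.form.value, "a": out.model.a, "b": out.model.b,
                          "avkt": out.model.avkt},
                "scenarios": out.summary,
            },
            indent=2,
            sort_keys=True,
        )
    )
    out.written.append(json_path)

    log_path = d / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")
    out.written.append(log_path)

    if out.config.figures:
        _write_figures(out, d)


def _write_figures(out: PipelineResult, d: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for label, res in sorted(out.results.items()):
        ax.plot(res.table.index, res.table["fatalities"], lw=1, label=label)
    ax.set_xlabel("year")
    ax.set_ylabel("annual road fatalities")
    ax.legend(fontsize=4, ncol=2)
    fig.savefig(d / "annual_fatalities.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 5))
    rows = [r for r in out.summary if r["fatalities_2030"] is not None]
    rows.sort(key=lambda r: r["fatalities_2030"])
    ax.barh([r["label"] for r in rows], [r["fatalities_2030"] for r in rows])
    ax.set_xlabel("road fatalities in 2030")
    fig.tight_layout()
    fig.savefig(d / "fatalities_2030.png", dpi=150)
    plt.close(fig)
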