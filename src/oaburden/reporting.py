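"""End-to-end orchestration and paper-shaped report tables.

``run`` drives the full analysis: read the three CSV inputs, select the
cohort, link deaths, compute per-person burdens on the (method x weight)
grid, and write three report tables plus a JSON run summary:

* ``table_incidence.csv`` — new cases, column %, insured and incidence per
  1000 by sex, age band, osteoarthritis type, care setting and network;
* ``table_daly_grid.csv`` — DALY totals and DALYs per 1000 for every
  (method, disability weight) cell, same strata;
* ``table_knee_hip.csv`` — the knee and hip subgroup detail by sex and age;
* ``summary.json`` — exclusion counts per selection rule, totals per cell,
  and the configuration used.

``compare_methods`` reduces a finished run to the headline ratios: total
DALYs GBD-2015 / Harvard-1994 at each weight, and MINSA / WHO weight ratio
under each method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import pipeline
from .engine import DW_MINSA, DW_WHO, DisabilityWeight, MethodSpec, method_preset
from .life_tables import default_life_tables, load_life_table
from .pipeline import (aggregate, compute_burden, link_deaths, round_half_up,
                       select_cohort)

__all__ = ["RunConfig", "ReportBundle", "run", "compare_methods", "load_run_config"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; serialisable to/from YAML."""

    records: str | Path
    deaths: str | Path
    denominators: str | Path
    out_dir: str | Path
    year: int = 2016
    methods: tuple[str, ...] = ("harvard1994", "gbd2015")
    weights: tuple[float, ...] = (0.165, 0.28)
    life_tables: str = "bundled"  # or a directory of <ref>.csv files
    contributory_deaths: bool = False
    age_weight_on_yld: bool = True
    min_age: int = 15

    def __post_init__(self) -> None:
        if not self.methods or not self.weights:
            raise ValueError("at least one method and one disability weight required")


_WEIGHT_LABELS = {0.165: "who", 0.28: "minsa"}


def _resolve_weights(values) -> list[DisabilityWeight]:
    out = []
    for v in values:
        if isinstance(v, DisabilityWeight):
            out.append(v)
        else:
            label = _WEIGHT_LABELS.get(float(v), f"dw{float(v):g}")
            out.append(DisabilityWeight(float(v), label))
    return out


def _resolve_specs(config: RunConfig) -> list[MethodSpec]:
    return [
        method_preset(name, age_weight_on_yld=config.age_weight_on_yld)
        for name in config.methods
    ]


def _resolve_tables(config: RunConfig):
    if config.life_tables == "bundled":
        return default_life_tables()
    root = Path(config.life_tables)
    refs = {s.life_table_ref for s in _resolve_specs(config)}
    tables = {}
    for ref in refs:
        path = root / f"{ref}.csv"
        if not path.exists():
            raise FileNotFoundError(f"life table file {path} not found")
        tables[ref] = load_life_table(path)
    return tables


@dataclass
class ReportBundle:
    """In-memory results of one run plus the paths written."""

    strata: pd.DataFrame
    knee_hip: pd.DataFrame
    summary: dict
    paths: dict[str, Path] = field(default_factory=dict)


def run(config: RunConfig) -> ReportBundle:
    """Execute the pipeline end to end and write the report bundle."""
    for name in ("records", "deaths", "denominators"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} file {p} not found")

    records = pd.read_csv(config.records, parse_dates=["visit_date"])
    deaths = pd.read_csv(config.deaths, parse_dates=["death_date"])
    denominators = pd.read_csv(config.denominators)

    selection = select_cohort(records, year=config.year, min_age=config.min_age)
    cohort = link_deaths(
        selection.cohort, deaths, include_contributory=config.contributory_deaths
    )
    specs = _resolve_specs(config)
    weights = _resolve_weights(config.weights)
    tables = _resolve_tables(config)
    burdens = compute_burden(cohort, specs, weights, tables)

    strata = aggregate(
        burdens, cohort, denominators,
        dimensions=("sex", "age_band", "oa_type", "setting", "network"),
    )
    knee_hip = _knee_hip_detail(burdens, cohort, denominators)

    totals = {
        f"{m}_{w}": float(
            burdens.loc[(burdens["method"] == m) & (burdens["dw"] == w), "daly"].sum()
        )
        for m in (s.name for s in specs)
        for w in (wt.label for wt in weights)
    }
    summary = {
        "year": config.year,
        "input_rows": int(len(records)),
        "selected_patients": int(selection.n_selected),
        "exclusions": selection.exclusions,
        "oa_deaths_linked": int(cohort["died_of_oa"].sum()),
        "methods": [s.name for s in specs],
        "weights": {w.label: w.value for w in weights},
        "total_dalys": totals,
        "total_insured": int(
            denominators.set_index(["dimension", "level"])
            .loc[("total", "total"), "insured_count"]
        ),
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incidence_cols = ["dimension", "level", "new_cases", "pct_col", "insured",
                      "incidence_per_1000"]
    paths = {
        "table_incidence": out / "table_incidence.csv",
        "table_daly_grid": out / "table_daly_grid.csv",
        "table_knee_hip": out / "table_knee_hip.csv",
        "summary": out / "summary.json",
    }
    strata[incidence_cols].to_csv(paths["table_incidence"], index=False)
    grid = strata.drop(columns=["insured", "incidence_per_1000"]).copy()
    for col in grid.columns:
        if col.startswith("dalys_") and not col.startswith("dalys_per_1000"):
            grid[col] = grid[col].round().astype("Int64")
    grid.to_csv(paths["table_daly_grid"], index=False)
    knee_hip.to_csv(paths["table_knee_hip"], index=False)
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return ReportBundle(strata=strata, knee_hip=knee_hip, summary=summary, paths=paths)


def _knee_hip_detail(burdens, cohort, denominators) -> pd.DataFrame:
    frames = []
    for oa_type in ("knee", "hip"):
        sub = cohort[cohort["oa_type"] == oa_type]
        ids = set(sub["patient_id"])
        sub_burdens = burdens[burdens["patient_id"].isin(ids)]
        if len(sub) == 0:
            continue
        tbl = aggregate(sub_burdens, sub, denominators, dimensions=("sex", "age_band"))
        tbl.insert(0, "oa_type", oa_type)
        frames.append(tbl)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def compare_methods(bundle_or_summary) -> dict:
    """Headline ratios from a finished run.

    Returns ``{"gbd_over_harvard": {weight_label: ratio},
    "minsa_over_who": {method_name: ratio}}``.  Requires both methods (for
    the first) and both weights (for the second) to be present.
    """
    summary = (
        bundle_or_summary.summary
        if isinstance(bundle_or_summary, ReportBundle)
        else bundle_or_summary
    )
    totals = summary["total_dalys"]
    methods = summary["methods"]
    weights = list(summary["weights"])

    def cell(m, w):
        key = f"{m}_{w}"
        if key not in totals:
            raise KeyError(f"missing (method, weight) cell {key!r} in totals")
        return totals[key]

    out: dict = {"gbd_over_harvard": {}, "minsa_over_who": {}}
    if "gbd2015" in methods and "harvard1994" in methods:
        for w in weights:
            out["gbd_over_harvard"][w] = cell("gbd2015", w) / cell("harvard1994", w)
    elif len(methods) < 2:
        raise ValueError("method comparison requires both methodologies in the run")
    if "minsa" in weights and "who" in weights:
        for m in methods:
            out["minsa_over_who"][m] = cell(m, "minsa") / cell(m, "who")
    return out


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    for key in ("methods", "weights"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def dalys_per_1000(total_dalys: float, insured: int) -> float:
    """Convenience re-export of the rounded per-1000 rate."""
    return pipeline.daly_rate(total_dalys, insured)


def percent_increase(base: float, new: float) -> float:
    """100 * (new/base - 1), rounded half-up to the nearest integer."""
    return round_half_up(100.0 * (new / base - 1.0), 0)
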