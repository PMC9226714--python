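"""File formats, run configuration, and the end-to-end pipeline.

Patient records travel as a YAML document holding a list of per-patient
mappings (dynamic specs are variable-length, so a nested structure beats a
wide table). All tabular outputs are UTF-8 comma-delimited files with a
header row and decimal points. Every run writes a machine-readable manifest
(config, seed, package version) and no timestamps, so a rerun from the same
config is bit-identical.
"""

from __future__ import annotations


import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ValidationError

from . import __version__
from .cohort import (
    AGGREGATE_NAMES,
    SCENARIOS,
    ParameterRegistry,
    PatientRecord,
    RegistryError,
    _reported_series,
    apply_scenario,
    build_patient_model,
    load_registry,
)
from .engine import SimulationConfig, SimulationResult, simulate_patient
from .patterns import FitResult, cohort_fit, fit_percentage
from .stats import (
    ContributionTable,
    ScenarioComparison,
    compare_scenarios,
    contribution_table,
)
from .synthetic import GeneratorConfig, attach_reports, sample_cohort

log = logging.getLogger(__name__)

__all__ = [
    "PatientFileError",
    "read_patients",
    "write_patients",
    "RunConfig",
    "run_pipeline",
    "write_summary_report",
    "load_reference_sums",
]


class PatientFileError(ValueError):
    """Itemized validation failure for a patient record file."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("\n".join(errors))


def read_patients(path: str | Path, registry: Optional[ParameterRegistry] = None) -> list[PatientRecord]:
    """Read and validate a patient record file (YAML list of records).

    Every record is validated against the schema and, when a registry is
    given, against the parameter catalogue; all failures are collected into
    one itemized report identifying the record and field.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not doc:
        raise PatientFileError([f"{path}: no patients in file"])
    if not isinstance(doc, list):
        raise PatientFileError([f"{path}: expected a list of patient records"])
    records: list[PatientRecord] = []
    errors: list[str] = []
    for i, entry in enumerate(doc):
        label = entry.get("patient_id", f"record #{i + 1}") if isinstance(entry, dict) else f"record #{i + 1}"
        try:
            rec = PatientRecord.model_validate(entry)
        except ValidationError as exc:
            for e in exc.errors():
                loc = ".".join(str(x) for x in e["loc"])
                errors.append(f"{label}: {loc}: {e['msg']}")
            continue
        if registry is not None:
            unknown = set(rec.parameters) - set(registry.parameters)
            if unknown:
                errors.append(f"{label}: unknown parameters {sorted(unknown)}")
                continue
        records.append(rec)
    if errors:
        raise PatientFileError(errors)
    return records


def write_patients(records: Sequence[PatientRecord], path: str | Path) -> None:
    data = [r.model_dump(exclude_none=True, exclude_defaults=True) for r in records]
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=True, allow_unicode=True), encoding="utf-8"
    )


class RunConfig(BaseModel):
    """Everything one pipeline run needs, serializable into the manifest."""

    registry_path: Optional[str] = None
    patients_path: Optional[str] = None
    synthetic: Optional[GeneratorConfig] = None
    scenarios: list[str] = ["baseline", "last5", "medicated_only"]
    rate_cap_mode: str = "symmetric"
    experience_delay: float = 1.0
    fit_tolerance: Optional[float] = None  # None -> 1% of range
    out_dir: str = "ihsim_run"
    seed: int = 0
    log_level: str = "INFO"


def _tidy_trajectories(results: Sequence[SimulationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for name, series in list(res.aggregates.items()) + [("experience", res.experience)]:
            for year, value in zip(res.years, series):
                rows.append((res.patient_id, int(year), name, float(value)))
    return pd.DataFrame(rows, columns=["patient_id", "year", "variable", "value"])


def write_summary_report(
    tables: dict[str, ContributionTable],
    comparison: ScenarioComparison,
    path: str | Path,
) -> pd.DataFrame:
    """Write the three-scenario summary: 12 rows of (SUM, %) per scenario
    plus the Mann–Whitney p column for last5 vs medicated_only."""
    needed = ("baseline", "last5", "medicated_only")
    missing = [s for s in needed if s not in tables]
    if missing:
        raise ValueError(f"missing scenarios for the summary report: {missing}")
    rows = []
    for name in AGGREGATE_NAMES:
        row = {"aggregate": name}
        for scen in needed:
            t = tables[scen]
            row[f"{scen}_sum"] = round(t.signed_sums[name], 2)
            row[f"{scen}_contribution_pct"] = t.contribution_percents[name]
        row["p_last5_vs_medicated"] = round(comparison.p_values[name], 3)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def load_reference_sums() -> pd.DataFrame:
    """Published per-scenario signed sums (inputs to the contribution
    arithmetic), shipped as package data."""
    from importlib import resources

    with (resources.files("ihsim") / "data" / "reference_scenario_sums.csv").open("rb") as fh:
        return pd.read_csv(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the artifact bundle.

    Stages: load registry → load or generate patients → dynamize → simulate
    → attach/parse reported courses → pattern fit → scenario windows →
    contribution tables → scenario comparison → report + manifest.
    Returns the bundle as a dict (results, fits, tables, paths).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "registry"
    try:
        registry = load_registry(config.registry_path)

        stage = "patients"
        if config.synthetic is not None:
            records = sample_cohort(config=config.synthetic)
        elif config.patients_path:
            records = read_patients(config.patients_path, registry)
        else:
            raise ValueError("config must give patients_path or synthetic")

        stage = "simulate"
        models = [build_patient_model(r, registry) for r in records]
        results = []
        for m in models:
            sim_cfg = SimulationConfig(
                start_year=m.onset_year,
                end_year=m.interview_year,
                rate_cap_mode=config.rate_cap_mode,
                experience_delay=config.experience_delay,
            )
            results.append(simulate_patient(m, sim_cfg))

        stage = "reports"
        if config.synthetic is not None:
            records = attach_reports(records, results, config.synthetic)
        courses = {
            r.patient_id: _reported_series(r.reported_course, r)
            for r in records
            if r.reported_course is not None
        }

        stage = "fit"
        fits: list[FitResult] = []
        for res in results:
            course = courses.get(res.patient_id)
            if course is None or len(res.experience) < 2:
                continue
            fits.append(
                fit_percentage(
                    res.experience, course.series,
                    tolerance=config.fit_tolerance, patient_id=res.patient_id,
                )
            )
        pooled = cohort_fit(fits) if fits else None

        stage = "scenarios"
        tables: dict[str, ContributionTable] = {}
        windowed: dict[str, list[SimulationResult]] = {}
        for scen_name in config.scenarios:
            scen = SCENARIOS[scen_name]
            windowed[scen_name] = apply_scenario(results, models, scen)
            tables[scen_name] = contribution_table(windowed[scen_name], scen_name)

        stage = "comparison"
        comparison = None
        if "last5" in windowed and "medicated_only" in windowed:
            comparison = compare_scenarios(
                windowed["last5"], windowed["medicated_only"]
            )

        stage = "write"
        _tidy_trajectories(results).to_csv(out / "trajectories.csv", index=False)
        pd.DataFrame(
            [
                {
                    "patient_id": f.patient_id,
                    "n_segments": f.n_segments,
                    "n_matches": f.n_matches,
                    "fit_percent": f.fit_percent,
                }
                for f in fits
            ]
        ).to_csv(out / "fit_results.csv", index=False)
        for scen_name, table in tables.items():
            pd.DataFrame(
                {
                    "aggregate": list(table.signed_sums),
                    "signed_sum": [round(v, 2) for v in table.signed_sums.values()],
                    "contribution_pct": list(table.contribution_percents.values()),
                }
            ).to_csv(out / f"contribution_{scen_name}.csv", index=False)
        if comparison is not None:
            pd.DataFrame(
                {
                    "aggregate": list(comparison.u_statistics),
                    "U": list(comparison.u_statistics.values()),
                    "p": list(comparison.p_values.values()),
                }
            ).to_csv(out / "comparison.csv", index=False)
            if all(s in tables for s in ("baseline", "last5", "medicated_only")):
                write_summary_report(tables, comparison, out / "summary_report.csv")
        manifest = {
            "package": "ihsim",
            "version": __version__,
            "seed": config.seed,
            "config": json.loads(config.model_dump_json()),
            "cohort_fit_percent": pooled,
            "n_patients": len(records),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
    return {
        "records": records,
        "models": models,
        "results": results,
        "fits": fits,
        "cohort_fit_percent": pooled,
        "tables": tables,
        "comparison": comparison,
        "out_dir": str(out),
    }
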