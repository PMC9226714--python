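"""Parameter registry, patient-model assembly, and analysis scenarios.

The structured interview yields 71 model input parameters. Each belongs to
exactly one of twelve clinical aggregates — the named state variables whose
levels the engine integrates (anxiety, depression, sleep inertia, work and
social impairment, sleepiness, fatigue, naps, nocturnal sleep, other
psychiatric disorders, somatic pathologies, and the two stimulant effects).
The registry is editable data, not code: parameter kinds, instrument scales,
polarity rules and aggregate membership live in ``data/registry.yaml``.

Scenarios select which patients and which years enter the summary
statistics: the full disease duration for everyone (baseline), the final
five years (last5), or the final five years of patients exposed to
methylphenidate or modafinil in that window (medicated_only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, model_validator

from .dynamization import (
    ChangeEvent,
    DynamicParameterSpec,
    MedicationEpisode,
    ParameterKind,
    PolarityRule,
    RawParameter,
    TargetSchedule,
    build_medication_schedule,
    build_target_schedule,
)
from .engine import DelaySpec, SimulationConfig, SimulationResult, simulate_patient
from .patterns import ReportedCourse, interpolate_anchors, render_template

__all__ = [
    "AggregateDefinition",
    "ParameterRegistry",
    "load_registry",
    "PatientRecord",
    "RecordParameter",
    "MedicationRecord",
    "ReportedCourseRecord",
    "PatientModel",
    "ScenarioSpec",
    "SCENARIOS",
    "aggregate_schedule",
    "build_patient_model",
    "apply_scenario",
    "AGGREGATE_NAMES",
]

#: The twelve output state variables, in reporting order.
AGGREGATE_NAMES: tuple[str, ...] = (
    "Anxiety",
    "Depression",
    "Sleep inertia",
    "Work and social impairment",
    "Sleepiness",
    "Fatigue",
    "Naps",
    "Nocturnal sleep",
    "Other psychiatric disorders",
    "Somatic pathologies",
    "Methylphenidate effect",
    "Modafinil effect",
)

#: Stimulant drug name → its effect parameter in the registry.
DRUG_PARAMETERS = {
    "methylphenidate": "methylphenidate_effect",
    "modafinil": "modafinil_effect",
}


@dataclass
class AggregateDefinition:
    name: str
    members: list[str]
    delay: float = 2.0
    combine_rule: str = "mean"


class RegistryError(ValueError):
    pass


@dataclass
class ParameterRegistry:
    """The editable parameter catalogue: kinds, scales, polarities, membership."""

    parameters: dict[str, RawParameter]
    aggregates: dict[str, AggregateDefinition]

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for agg in self.aggregates.values():
            if not agg.members:
                raise RegistryError(f"aggregate {agg.name!r} has no members")
            if agg.combine_rule not in ("mean", "sum"):
                raise RegistryError(f"aggregate {agg.name!r}: bad combine_rule")
            for m in agg.members:
                if m not in self.parameters:
                    raise RegistryError(
                        f"aggregate {agg.name!r} lists unknown parameter {m!r}"
                    )
                if m in seen:
                    raise RegistryError(
                        f"parameter {m!r} assigned to both {seen[m]!r} and {agg.name!r}"
                    )
                seen[m] = agg.name
        orphans = set(self.parameters) - set(seen)
        if orphans:
            raise RegistryError(
                f"parameters not assigned to any aggregate: {sorted(orphans)}"
            )
        missing = set(AGGREGATE_NAMES) - set(self.aggregates)
        if missing:
            raise RegistryError(f"missing aggregates: {sorted(missing)}")

    def aggregate_of(self, parameter_name: str) -> str:
        for agg in self.aggregates.values():
            if parameter_name in agg.members:
                return agg.name
        raise KeyError(parameter_name)


def load_registry(path: Optional[str] = None) -> ParameterRegistry:
    """Load and validate a registry file (the packaged default when ``path``
    is None)."""
    if path is None:
        text = (resources.files("ihsim") / "data" / "registry.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    params: dict[str, RawParameter] = {}
    for entry in doc["parameters"]:
        scale = entry.get("scale")
        try:
            # registry rows carry no values; placeholder static 0 satisfies
            # the one-of invariant until a record supplies real data
            params[entry["name"]] = RawParameter(
                name=entry["name"],
                kind=ParameterKind(entry.get("kind", "continuous")),
                scale_min=None if scale is None else float(scale[0]),
                scale_max=None if scale is None else float(scale[1]),
                static_value=0.0,
                polarity_rule=PolarityRule(entry.get("polarity", "always_negative")),
            )
        except Exception as exc:  # re-raise with the offending entry named
            raise RegistryError(f"registry entry {entry.get('name')!r}: {exc}") from exc
    aggs = {
        a["name"]: AggregateDefinition(
            name=a["name"],
            members=[p["name"] for p in doc["parameters"] if p["aggregate"] == a["name"]],
            delay=float(a.get("delay", 2.0)),
            combine_rule=a.get("combine_rule", "mean"),
        )
        for a in doc["aggregates"]
    }
    reg = ParameterRegistry(parameters=params, aggregates=aggs)
    reg.validate()
    return reg


# ---------------------------------------------------------------------------
# patient records


class RecordParameter(BaseModel):
    """Per-patient data for one registry parameter: static or dynamic."""

    static_value: Optional[float] = None
    first_occurrence_year: Optional[int] = None
    last_occurrence_year: Optional[int] = None
    max_value: Optional[float] = None
    min_value: float = 0.0
    change_events: list[ChangeEvent] = []
    perception: Optional[str] = None  # for data_dependent polarity

    @model_validator(mode="after")
    def _check(self) -> "RecordParameter":
        dynamic = self.first_occurrence_year is not None
        if dynamic == (self.static_value is not None):
            raise ValueError(
                "give either static_value or a dynamic spec (first_occurrence_year"
                " + max_value), not both"
            )
        if dynamic and self.max_value is None:
            raise ValueError("dynamic parameter needs max_value")
        return self


class MedicationRecord(BaseModel):
    drug: str
    start_year: int
    stop_year: int
    perceived_effect: float  # native 0-100; sign comes from perception
    perception: str = "positive"

    @model_validator(mode="after")
    def _check(self) -> "MedicationRecord":
        if self.drug not in DRUG_PARAMETERS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.start_year > self.stop_year:
            raise ValueError("medication start_year must not exceed stop_year")
        return self


class ReportedCourseRecord(BaseModel):
    source: str = "template"  # "template" | "custom_drawn"
    template_id: Optional[int] = None
    anchors: Optional[list[tuple[float, float]]] = None
    amplitude: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "ReportedCourseRecord":
        if self.source == "template" and self.template_id is None:
            raise ValueError("template report needs template_id")
        if self.source == "custom_drawn" and not self.anchors:
            raise ValueError("custom_drawn report needs anchors")
        return self


class PatientRecord(BaseModel):
    """One interview record: descriptors, parameter data, medication, report."""

    patient_id: str
    onset_year: int
    interview_year: int
    sex: Optional[str] = None
    age_at_interview: Optional[float] = None
    parameters: dict[str, RecordParameter] = {}
    medication: list[MedicationRecord] = []
    reported_course: Optional[ReportedCourseRecord] = None

    @model_validator(mode="after")
    def _check(self) -> "PatientRecord":
        if self.interview_year < self.onset_year:
            raise ValueError("interview_year must be >= onset_year")
        return self

    @property
    def duration(self) -> int:
        return self.interview_year - self.onset_year


@dataclass
class PatientModel:
    """A fully dynamized patient, ready for simulation."""

    patient_id: str
    onset_year: int
    interview_year: int
    schedules: dict[str, TargetSchedule]
    aggregate_delays: dict[str, DelaySpec]
    membership: dict[str, list[str]]  # aggregate -> member parameters present
    reported_course: Optional[ReportedCourse] = None
    medication_years: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    combine_rule: str = "mean"
    initial_values: dict[str, float] = field(default_factory=dict)

    aggregate_order: tuple[str, ...] = AGGREGATE_NAMES

    def member_schedules(self, aggregate: str) -> list[TargetSchedule]:
        return [self.schedules[m] for m in self.membership.get(aggregate, [])]

    @property
    def duration(self) -> int:
        return self.interview_year - self.onset_year

    def medicated_in(self, start_year: int, end_year: int) -> bool:
        """Any stimulant exposure overlapping [start_year, end_year]."""
        return any(
            a <= end_year and b >= start_year
            for spans in self.medication_years.values()
            for (a, b) in spans
        )


def aggregate_schedule(
    member_schedules: Sequence[TargetSchedule], rule: str = "mean"
) -> TargetSchedule:
    """Combine member target schedules into one aggregate schedule.

    The per-year aggregate target is the mean (default) or the sum of the
    member targets, clamped to [-100, 100].
    """
    if not member_schedules:
        raise ValueError("aggregate_schedule needs at least one member")
    years0 = member_schedules[0].years
    for s in member_schedules[1:]:
        if not np.array_equal(s.years, years0):
            raise ValueError("member schedules are on mismatched year axes")
    stack = np.vstack([s.targets for s in member_schedules])
    if rule == "mean":
        g = stack.mean(axis=0)
    elif rule == "sum":
        g = stack.sum(axis=0)
    else:
        raise ValueError(f"unknown combine rule {rule!r}")
    return TargetSchedule("aggregate", years0, np.clip(g, -100.0, 100.0))


def _reported_series(rec: ReportedCourseRecord, record: PatientRecord) -> ReportedCourse:
    years = np.arange(record.onset_year, record.interview_year + 1)
    if rec.source == "template":
        series = render_template(rec.template_id, record.duration or 1, rec.amplitude)
        # duration 0 patients get a single repeated value
        if record.duration == 0:
            series = series[:1]
        return ReportedCourse(record.patient_id, "template", series, rec.template_id)
    series = interpolate_anchors(rec.anchors, years)
    return ReportedCourse(record.patient_id, "custom_drawn", series)


def build_patient_model(record: PatientRecord, registry: ParameterRegistry) -> PatientModel:
    """Dynamize one interview record against the registry.

    Every parameter the record mentions must exist in the registry; absent
    phenomena simply contribute nothing (their aggregates fall back to zero
    schedules). Medication episodes feed the stimulant-effect parameters.
    """
    onset, horizon = record.onset_year, record.interview_year
    schedules: dict[str, TargetSchedule] = {}
    membership: dict[str, list[str]] = {name: [] for name in AGGREGATE_NAMES}

    for pname, pdata in record.parameters.items():
        if pname not in registry.parameters:
            raise RegistryError(
                f"patient {record.patient_id!r}: unknown parameter {pname!r}"
            )
        if pname in DRUG_PARAMETERS.values():
            raise RegistryError(
                f"patient {record.patient_id!r}: drug effects are given via "
                "medication episodes, not parameter entries"
            )
        template = registry.parameters[pname]
        dyn = None
        if pdata.first_occurrence_year is not None:
            dyn = DynamicParameterSpec(
                first_occurrence_year=pdata.first_occurrence_year,
                last_occurrence_year=pdata.last_occurrence_year,
                max_value=pdata.max_value,
                min_value=pdata.min_value,
                change_events=pdata.change_events,
            )
        raw = template.model_copy(
            update={
                "static_value": pdata.static_value,
                "dynamic_spec": dyn,
                "perception": pdata.perception,
            }
        )
        schedules[pname] = build_target_schedule(raw, onset, horizon)
        membership[registry.aggregate_of(pname)].append(pname)

    medication_years: dict[str, list[tuple[int, int]]] = {}
    for drug, param_name in DRUG_PARAMETERS.items():
        episodes = [
            MedicationEpisode(
                start_year=m.start_year,
                stop_year=m.stop_year,
                perceived_effect=m.perceived_effect,
            )
            for m in record.medication
            if m.drug == drug
        ]
        if episodes:
            template = registry.parameters[param_name]
            perception = next(
                m.perception for m in record.medication if m.drug == drug
            )
            raw = template.model_copy(update={"perception": perception})
            schedules[param_name] = build_medication_schedule(
                episodes, raw, onset, horizon
            )
            membership[registry.aggregate_of(param_name)].append(param_name)
            medication_years[drug] = [(e.start_year, e.stop_year) for e in episodes]

    delays = {
        name: DelaySpec(adjustment_time=registry.aggregates[name].delay)
        for name in AGGREGATE_NAMES
    }
    reported = (
        _reported_series(record.reported_course, record)
        if record.reported_course is not None
        else None
    )
    return PatientModel(
        patient_id=record.patient_id,
        onset_year=onset,
        interview_year=horizon,
        schedules=schedules,
        aggregate_delays=delays,
        membership=membership,
        reported_course=reported,
        medication_years=medication_years,
    )


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class ScenarioSpec:
    """Which patients and which years enter a summary scenario."""

    name: str
    window_rule: str = "full"  # "full" | "last5"
    min_duration: int = 0
    require_medication: bool = False
    window_years: int = 5


SCENARIOS: dict[str, ScenarioSpec] = {
    "baseline": ScenarioSpec(name="baseline"),
    "last5": ScenarioSpec(name="last5", window_rule="last5", min_duration=5),
    "medicated_only": ScenarioSpec(
        name="medicated_only", window_rule="last5", min_duration=5,
        require_medication=True,
    ),
}


def apply_scenario(
    results: Sequence[SimulationResult],
    models: Sequence[PatientModel],
    scenario: ScenarioSpec,
) -> list[SimulationResult]:
    """Clip trajectories to the scenario window and drop excluded patients.

    Values are never altered — only patients and years are selected. The
    last5 window keeps the final five yearly samples of each trajectory;
    patients whose disease lasted under ``min_duration`` years are excluded,
    and medicated_only additionally requires stimulant exposure overlapping
    the window.
    """
    by_id = {m.patient_id: m for m in models}
    out: list[SimulationResult] = []
    for res in results:
        model = by_id[res.patient_id]
        if model.duration < scenario.min_duration:
            continue
        if scenario.window_rule == "full":
            sel = slice(None)
            w0, w1 = int(res.years[0]), int(res.years[-1])
        elif scenario.window_rule == "last5":
            sel = slice(-scenario.window_years, None)
            w0, w1 = int(res.years[-scenario.window_years]), int(res.years[-1])
        else:
            raise ValueError(f"unknown window rule {scenario.window_rule!r}")
        if scenario.require_medication and not model.medicated_in(w0, w1):
            continue
        out.append(
            SimulationResult(
                patient_id=res.patient_id,
                years=res.years[sel],
                aggregates={k: v[sel] for k, v in res.aggregates.items()},
                experience=res.experience[sel],
            )
        )
    if not out:
        raise ValueError(f"scenario {scenario.name!r} selected no patients")
    return out
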