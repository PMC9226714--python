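"""Dynamization: turn raw interview answers into per-year target schedules.

Every model input parameter — a questionnaire score, a comorbidity, a
medication episode — is recorded in its native units. Before it can drive a
stock-and-flow level it is (i) normalized to a common 0–100 magnitude scale,
(ii) given a sign by its polarity rule (phenomena like depression only ever
push the experience down; naps may push either way depending on whether the
patient found them refreshing), and (iii) unrolled onto the yearly simulation
grid as a *target schedule*: the goal value g_t in [-100, 100] that the
corresponding level chases at each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

log = logging.getLogger(__name__)

__all__ = [
    "ParameterKind",
    "PolarityRule",
    "ChangeEvent",
    "DynamicParameterSpec",
    "RawParameter",
    "TargetSchedule",
    "normalize_value",
    "polarity_sign",
    "build_target_schedule",
    "build_static_schedule",
    "build_medication_schedule",
    "MedicationEpisode",
    "zero_schedule",
]


class ParameterKind(str, Enum):
    continuous = "continuous"
    ordinal = "ordinal"
    nominal = "nominal"
    binary = "binary"


class PolarityRule(str, Enum):
    always_negative = "always_negative"
    always_positive = "always_positive"
    data_dependent = "data_dependent"


class ChangeEvent(BaseModel):
    """A reported change of a phenomenon's intensity: year, new value, pace."""

    year: int
    value: float  # new target value, native units
    rate: str = "step"  # "step" (jump at the event year) or "linear" (ramp)


class DynamicParameterSpec(BaseModel):
    """Temporal extent and extremes of a phenomenon, as elicited in interview."""

    first_occurrence_year: int
    last_occurrence_year: Optional[int] = None
    max_value: float
    min_value: float = 0.0
    change_events: list[ChangeEvent] = []

    @model_validator(mode="after")
    def _check(self) -> "DynamicParameterSpec":
        if (
            self.last_occurrence_year is not None
            and self.first_occurrence_year > self.last_occurrence_year
        ):
            raise ValueError(
                "first_occurrence_year must not exceed last_occurrence_year"
            )
        if self.min_value > self.max_value:
            raise ValueError("min_value must not exceed max_value")
        years = [e.year for e in self.change_events]
        if years != sorted(years):
            raise ValueError("change_events must be sorted by year")
        return self


class RawParameter(BaseModel):
    """One of the model input parameters in native units.

    Exactly one of ``static_value`` / ``dynamic_spec`` is present; static
    parameters hold one value for the whole simulated period.
    """

    name: str
    kind: ParameterKind = ParameterKind.continuous
    scale_min: Optional[float] = None
    scale_max: Optional[float] = None
    static_value: Optional[float] = None
    dynamic_spec: Optional[DynamicParameterSpec] = None
    polarity_rule: PolarityRule = PolarityRule.always_negative
    perception: Optional[str] = None  # "positive"/"negative", data_dependent only

    @model_validator(mode="after")
    def _check(self) -> "RawParameter":
        if (self.static_value is None) == (self.dynamic_spec is None):
            raise ValueError(
                f"parameter {self.name!r}: exactly one of static_value / "
                "dynamic_spec must be given"
            )
        if self.scale_min is not None and self.scale_max is not None:
            if self.scale_min >= self.scale_max:
                raise ValueError(
                    f"parameter {self.name!r}: degenerate scale "
                    f"[{self.scale_min}, {self.scale_max}]"
                )
        return self


@dataclass
class TargetSchedule:
    """Per-year goal values g_t in [-100, 100] for one input parameter.

    The signed target splits into a non-negative increasing component (the
    inflow side) and a non-negative decreasing component (the outflow side)
    with g_t = IF_t - DF_t exactly.
    """

    parameter_name: str
    years: np.ndarray  # ordered simulation years (calendar)
    targets: np.ndarray  # g_t, same length as years

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.years.shape != self.targets.shape:
            raise ValueError("years and targets must have equal length")
        if np.any(np.abs(self.targets) > 100 + 1e-9):
            raise ValueError(
                f"schedule for {self.parameter_name!r} leaves [-100, 100]"
            )

    @property
    def increasing_component(self) -> np.ndarray:
        """IF_t: the non-negative part of the target."""
        return np.where(self.targets > 0, self.targets, 0.0)

    @property
    def decreasing_component(self) -> np.ndarray:
        """DF_t: magnitude of the negative part, so g = IF - DF exactly."""
        return np.where(self.targets > 0, 0.0, -self.targets)


def normalize_value(raw: float, parameter: RawParameter) -> float:
    """Map a native-units value onto the common [0, 100] magnitude scale.

    Continuous and ordinal values are placed linearly between the declared
    scale endpoints (ordinal categories therefore come out evenly spaced);
    binary and nominal presence/absence map to {0, 100}. Values outside the
    declared scale are clamped with a warning — interview data plausibly
    contains mild out-of-range entries.
    """
    if parameter.kind in (ParameterKind.binary, ParameterKind.nominal):
        return 100.0 if raw else 0.0
    lo, hi = parameter.scale_min, parameter.scale_max
    if lo is None or hi is None:
        raise ValueError(
            f"parameter {parameter.name!r}: no scale declared and no "
            "cohort-range fallback supplied"
        )
    if lo >= hi:
        raise ValueError(f"parameter {parameter.name!r}: degenerate scale")
    if raw < lo or raw > hi:
        log.warning(
            "parameter %r: raw value %s outside scale [%s, %s]; clamped",
            parameter.name, raw, lo, hi,
        )
        raw = min(max(raw, lo), hi)
    return 100.0 * (raw - lo) / (hi - lo)


def polarity_sign(parameter: RawParameter) -> float:
    """Resolve the sign a parameter's normalized magnitude carries."""
    if parameter.polarity_rule is PolarityRule.always_negative:
        return -1.0
    if parameter.polarity_rule is PolarityRule.always_positive:
        return 1.0
    if parameter.perception == "positive":
        return 1.0
    if parameter.perception == "negative":
        return -1.0
    raise ValueError(
        f"parameter {parameter.name!r}: polarity is data_dependent but no "
        "perception ('positive'/'negative') was recorded"
    )


def _year_axis(onset_year: int, horizon_year: int) -> np.ndarray:
    if horizon_year < onset_year:
        raise ValueError("horizon_year must be >= onset_year")
    return np.arange(onset_year, horizon_year + 1)


def zero_schedule(name: str, onset_year: int, horizon_year: int) -> TargetSchedule:
    years = _year_axis(onset_year, horizon_year)
    return TargetSchedule(name, years, np.zeros(len(years)))


def build_static_schedule(
    parameter: RawParameter, onset_year: int, horizon_year: int
) -> TargetSchedule:
    """Constant schedule for a static parameter."""
    if parameter.static_value is None:
        raise ValueError(f"parameter {parameter.name!r} is not static")
    g = polarity_sign(parameter) * normalize_value(parameter.static_value, parameter)
    years = _year_axis(onset_year, horizon_year)
    return TargetSchedule(parameter.name, years, np.full(len(years), g))


def build_target_schedule(
    parameter: RawParameter,
    onset_year: int,
    horizon_year: int,
    *,
    interpolation: str = "step",
) -> TargetSchedule:
    """Unroll a parameter onto the yearly grid from onset to horizon.

    Dynamic parameters are zero before their first occurrence, start at the
    normalized extreme value, move through their change events (piecewise
    constant by default, ramped when the event's rate qualifier or
    ``interpolation`` is "linear"), and return to zero after the last
    occurrence year. Static parameters yield a constant schedule.
    """
    if parameter.static_value is not None:
        return build_static_schedule(parameter, onset_year, horizon_year)
    spec = parameter.dynamic_spec
    assert spec is not None
    years = _year_axis(onset_year, horizon_year)
    sign = polarity_sign(parameter)

    first = spec.first_occurrence_year
    last = spec.last_occurrence_year if spec.last_occurrence_year is not None else horizon_year
    for ev in spec.change_events:
        if ev.year < first or ev.year > last:
            raise ValueError(
                f"parameter {parameter.name!r}: change event in year {ev.year} "
                f"outside the active window [{first}, {last}]"
            )
        if ev.year > horizon_year:
            raise ValueError(
                f"parameter {parameter.name!r}: change event in year {ev.year} "
                "outside the simulated window"
            )

    # magnitude trajectory over the active window, then signed and masked
    g = np.zeros(len(years), dtype=float)
    level = normalize_value(spec.max_value, parameter)
    prev_year = first
    events = list(spec.change_events)
    for i, year in enumerate(years):
        if year < first or year > last:
            continue
        # apply events up to this year
        while events and events[0].year <= year:
            ev = events.pop(0)
            new_level = normalize_value(ev.value, parameter)
            mode = ev.rate if ev.rate in ("step", "linear") else interpolation
            if mode == "linear" and ev.year > prev_year:
                # ramp from the previous plateau across the preceding gap
                span = ev.year - prev_year
                start_idx = np.searchsorted(years, prev_year)
                end_idx = np.searchsorted(years, ev.year)
                for k in range(start_idx, min(end_idx + 1, len(years))):
                    frac = (years[k] - prev_year) / span
                    g[k] = level + frac * (new_level - level)
            level = new_level
            prev_year = ev.year
        if g[i] == 0.0:
            g[i] = level
    return TargetSchedule(parameter.name, years, sign * g)


class MedicationEpisode(BaseModel):
    """One continuous course of a drug with its perceived effect (native 0-100)."""

    start_year: int
    stop_year: int
    perceived_effect: float

    @model_validator(mode="after")
    def _check(self) -> "MedicationEpisode":
        if self.start_year > self.stop_year:
            raise ValueError("episode start_year must not exceed stop_year")
        return self


def build_medication_schedule(
    episodes: Sequence[MedicationEpisode],
    parameter: RawParameter,
    onset_year: int,
    horizon_year: int,
    *,
    persistence_years: int = 1,
    persistence_decay: float = 0.5,
) -> TargetSchedule:
    """Target schedule for a drug-effect parameter.

    The target equals the normalized perceived effect while the drug is
    administered; after discontinuation it decays linearly to zero over the
    persistence window (default one simulation year at half strength), and is
    zero outside episodes.
    """
    eps = sorted(episodes, key=lambda e: e.start_year)
    for a, b in zip(eps, eps[1:]):
        if b.start_year <= a.stop_year:
            raise ValueError(
                f"parameter {parameter.name!r}: overlapping medication episodes"
            )
    years = _year_axis(onset_year, horizon_year)
    g = np.zeros(len(years))
    sign = polarity_sign(parameter) if eps else 1.0
    for ep in eps:
        effect = normalize_value(ep.perceived_effect, parameter)
        for i, year in enumerate(years):
            if ep.start_year <= year <= ep.stop_year:
                g[i] = sign * effect
            elif ep.stop_year < year <= ep.stop_year + persistence_years:
                k = year - ep.stop_year
                g[i] = sign * effect * persistence_decay**k
    return TargetSchedule(parameter.name, years, g)
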