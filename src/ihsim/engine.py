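"""Target-seeking stock-and-flow integration on a yearly grid.

Each clinical aggregate is a level (stock) pulled toward a time-varying goal
g_t by a balancing feedback loop: the net rate is the goal gap divided by an
adjustment time d (the delay), optionally capped by the goal magnitude. The
level accumulates the rate by explicit Euler steps of one year — the model's
native clock — from disease onset to the re-evaluation interview. The
patient's overall experience is itself a level whose goal at each step is the
sum of the twelve aggregate levels.

Two rate laws are provided. ``literal`` applies the cap as
MIN(gap/d, g), which makes a negative goal repel the level (the cap then
*lowers* the rate below the gap-closing rate). ``symmetric`` caps the rate
magnitude by the goal magnitude while keeping the gap-closing sign,
sign(gap/d) * MIN(|gap/d|, |g|), so levels gradually approach the goal from
either side; it is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from pydantic import BaseModel, model_validator

from .dynamization import TargetSchedule

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import PatientModel

__all__ = [
    "DelaySpec",
    "SimulationConfig",
    "RateComponents",
    "StateLevel",
    "SimulationResult",
    "step_rate",
    "integrate_level",
    "simulate_patient",
]


class DelaySpec(BaseModel):
    """Adjustment time of a balancing loop, in years."""

    adjustment_time: float

    @model_validator(mode="after")
    def _check(self) -> "DelaySpec":
        if not (self.adjustment_time > 0):
            raise ValueError("adjustment_time must be positive")
        return self


class SimulationConfig(BaseModel):
    """Clock and rate-law options shared by all levels of a run."""

    start_year: int
    end_year: int
    step_years: int = 1
    rate_cap_mode: str = "symmetric"  # "symmetric" | "literal"
    experience_delay: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if self.step_years != 1:
            raise ValueError("the simulation step is fixed at one year")
        if self.rate_cap_mode not in ("symmetric", "literal"):
            raise ValueError("rate_cap_mode must be 'symmetric' or 'literal'")
        return self

    @property
    def n_steps(self) -> int:
        return self.end_year - self.start_year


@dataclass
class RateComponents:
    inflow: float  # net rate applied to the level, per year
    target: float
    gap: float  # target - level


@dataclass
class StateLevel:
    """A named stock with its initial value and simulated trajectory."""

    name: str
    initial_value: float = 0.0
    trajectory: np.ndarray | None = None

    @property
    def value(self) -> float:
        if self.trajectory is None:
            return self.initial_value
        return float(self.trajectory[-1])


@dataclass
class SimulationResult:
    """Yearly trajectories of the twelve aggregates plus overall experience."""

    patient_id: str
    years: np.ndarray
    aggregates: dict[str, np.ndarray]
    experience: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.years)
        for name, series in self.aggregates.items():
            if len(series) != n:
                raise ValueError(f"aggregate {name!r} off the common year axis")
        if len(self.experience) != n:
            raise ValueError("experience series off the common year axis")


def step_rate(
    level_value: float,
    target: float,
    delay: DelaySpec,
    mode: str = "symmetric",
) -> RateComponents:
    """Net per-year rate pulling a level toward its target.

    The raw gap-closing rate is (target - level)/adjustment_time; the cap by
    the target value is applied literally or symmetrically (see module notes).
    """
    if not (math.isfinite(level_value) and math.isfinite(target)):
        raise ValueError("non-finite level or target")
    gap = target - level_value
    raw = gap / delay.adjustment_time
    if mode == "literal":
        inflow = min(raw, target)
    elif mode == "symmetric":
        if target == 0.0:
            inflow = raw
        else:
            inflow = math.copysign(min(abs(raw), abs(target)), raw) if raw != 0 else 0.0
    else:
        raise ValueError(f"unknown rate_cap_mode {mode!r}")
    return RateComponents(inflow=inflow, target=target, gap=gap)


def integrate_level(
    level: StateLevel,
    schedule: TargetSchedule,
    delay: DelaySpec,
    config: SimulationConfig,
) -> StateLevel:
    """Euler-integrate one level over the configured window (dt = 1 year).

    The returned trajectory has one entry per year from start to end
    inclusive; entry 0 is the initial value.
    """
    years = np.arange(config.start_year, config.end_year + 1)
    sched_years = schedule.years
    if sched_years[0] > years[0] or sched_years[-1] < years[-1]:
        raise ValueError(
            f"schedule for {schedule.parameter_name!r} does not cover the "
            f"simulated window {years[0]}..{years[-1]}"
        )
    offset = int(years[0] - sched_years[0])
    traj = np.empty(len(years))
    traj[0] = level.initial_value
    for t in range(len(years) - 1):
        g = float(schedule.targets[offset + t])
        rate = step_rate(traj[t], g, delay, config.rate_cap_mode)
        traj[t + 1] = traj[t] + rate.inflow  # dt = 1 year
    return StateLevel(name=level.name, initial_value=level.initial_value, trajectory=traj)


def simulate_patient(model: "PatientModel", config: SimulationConfig | None = None) -> SimulationResult:
    """Run one patient: integrate the twelve aggregate levels, then the
    overall-experience level whose per-step goal is their sum.
    """
    from .cohort import aggregate_schedule  # local import to avoid a cycle

    if config is None:
        config = SimulationConfig(
            start_year=model.onset_year, end_year=model.interview_year
        )
    years = np.arange(config.start_year, config.end_year + 1)

    aggregates: dict[str, np.ndarray] = {}
    for agg_name in model.aggregate_order:
        members = model.member_schedules(agg_name)
        if members:
            sched = aggregate_schedule(members, rule=model.combine_rule)
            sched = TargetSchedule(agg_name, sched.years, sched.targets)
        else:
            sched = TargetSchedule(agg_name, years, np.zeros(len(years)))
        delay = model.aggregate_delays[agg_name]
        lv = integrate_level(
            StateLevel(agg_name, model.initial_values.get(agg_name, 0.0)),
            sched, delay, config,
        )
        aggregates[agg_name] = lv.trajectory

    # overall experience: target at step t is the sum of aggregate levels at t
    total = np.sum(np.vstack(list(aggregates.values())), axis=0)
    exp_delay = DelaySpec(adjustment_time=config.experience_delay)
    exp = np.empty(len(years))
    exp[0] = model.initial_values.get("experience", 0.0)
    for t in range(len(years) - 1):
        rate = step_rate(exp[t], float(total[t]), exp_delay, config.rate_cap_mode)
        exp[t + 1] = exp[t] + rate.inflow
    return SimulationResult(
        patient_id=model.patient_id, years=years, aggregates=aggregates, experience=exp
    )
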