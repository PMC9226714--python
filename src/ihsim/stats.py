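"""Scenario contribution tables and Mann–Whitney scenario comparisons.

For each scenario the signed sum of every aggregate level over all selected
patients and window years summarizes that aggregate's push on the overall
experience (negative: it depressed the experience). The *absolute
contribution* of aggregate i is 100·|s_i| / Σ_j |s_j| — its share of the
total dynamics regardless of direction. Scenarios are compared per aggregate
with a two-sided Mann–Whitney test on per-patient windowed sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .cohort import AGGREGATE_NAMES
from .engine import SimulationResult

__all__ = [
    "ContributionTable",
    "ScenarioComparison",
    "sum_outputs",
    "patient_sums",
    "contribution_percent",
    "contribution_table",
    "mann_whitney_u",
    "compare_scenarios",
]


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class ContributionTable:
    scenario: str
    signed_sums: dict[str, float]
    contribution_percents: dict[str, float]
    n_patients: int


@dataclass
class ScenarioComparison:
    group_a: str
    group_b: str
    u_statistics: dict[str, float]
    p_values: dict[str, float]
    alpha: float = 0.05


def sum_outputs(windowed: Sequence[SimulationResult], aggregate: str) -> float:
    """Signed sum of one aggregate's level over all patients and window years."""
    if not windowed:
        raise ValueError("no windowed results supplied")
    try:
        return float(sum(res.aggregates[aggregate].sum() for res in windowed))
    except KeyError:
        raise KeyError(f"unknown aggregate {aggregate!r}") from None


def patient_sums(windowed: Sequence[SimulationResult], aggregate: str, *, mean: bool = False) -> np.ndarray:
    """Per-patient windowed sum (or mean) of one aggregate — the Mann–Whitney
    sampling unit."""
    if not windowed:
        raise ValueError("no windowed results supplied")
    op = np.mean if mean else np.sum
    return np.array([float(op(res.aggregates[aggregate])) for res in windowed])


def contribution_percent(signed_sums: Sequence[float]) -> list[float]:
    """Absolute contribution percentages, half-up rounded to one decimal.

    p_i = 100·|s_i| / Σ_j |s_j|; the unrounded values sum to exactly 100.
    """
    s = np.asarray(signed_sums, dtype=float)
    total = np.abs(s).sum()
    if total == 0:
        raise ValueError("all signed sums are zero; contributions undefined")
    return [_round1(100.0 * abs(x) / total) for x in s]


def contribution_table(
    windowed: Sequence[SimulationResult], scenario: str
) -> ContributionTable:
    """Full per-scenario summary over the twelve aggregates."""
    sums = {name: sum_outputs(windowed, name) for name in AGGREGATE_NAMES}
    pcts = contribution_percent(list(sums.values()))
    return ContributionTable(
        scenario=scenario,
        signed_sums=sums,
        contribution_percents=dict(zip(sums, pcts)),
        n_patients=len(windowed),
    )


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with midrank ties.

    The p-value is exact (full enumeration of the U null distribution) when
    the groups are tie-free and n1·n2 ≤ 400, otherwise a normal approximation
    with tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and a.size * b.size <= 400:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_scenarios(
    results_a: Sequence[SimulationResult],
    results_b: Sequence[SimulationResult],
    *,
    name_a: str = "last5",
    name_b: str = "medicated_only",
    per_patient_mean: bool = False,
) -> ScenarioComparison:
    """Per-aggregate Mann–Whitney comparison of two scenarios.

    The samples are the per-patient windowed sums (optionally means) of each
    aggregate. The groups may share patients — the medicated subset is, by
    design, drawn from the same cohort as the full window scenario.
    """
    if not results_a or not results_b:
        raise ValueError("both scenario result sets must be non-empty")
    u: dict[str, float] = {}
    p: dict[str, float] = {}
    for name in AGGREGATE_NAMES:
        sa = patient_sums(results_a, name, mean=per_patient_mean)
        sb = patient_sums(results_b, name, mean=per_patient_mean)
        u[name], p[name] = mann_whitney_u(sa, sb)
    return ScenarioComparison(group_a=name_a, group_b=name_b, u_statistics=u, p_values=p)
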