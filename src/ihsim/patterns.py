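"""Reported-course reconstruction and derivative-sign waveform matching.

At interview each patient chose the one of nine plotted course patterns that
best matched their experience of the disease, or drew their own on a blank
graph. The match between that report and the simulated overall-experience
level is scored by comparing first differences on the yearly grid: each
year-to-year segment of either waveform is classified as decreasing, constant
or increasing (a small tolerance separates "analytically rising" from
"visually flat"), and the fit is the percentage of segments whose classes
agree. Amplitude never enters the score — only the direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SegmentClass",
    "ReportedCourse",
    "FitResult",
    "TEMPLATE_NAMES",
    "classify_segments",
    "fit_percentage",
    "cohort_fit",
    "render_template",
    "interpolate_anchors",
    "default_tolerance",
]


class SegmentClass(IntEnum):
    decreasing = -1
    constant = 0
    increasing = 1


#: The nine predefined course patterns offered at interview, by template id.
TEMPLATE_NAMES: dict[int, str] = {
    1: "monotone worsening",
    2: "monotone improvement",
    3: "constant",
    4: "slight oscillation",
    5: "strong oscillation",
    6: "worsening-then-plateau",
    7: "improvement-then-plateau",
    8: "worsening-then-improvement",
    9: "improvement-then-worsening",
}


@dataclass
class ReportedCourse:
    """A patient's own account of the disease course on the yearly grid."""

    patient_id: str
    source: str  # "template" | "custom_drawn"
    series: np.ndarray
    template_id: int | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)


@dataclass
class FitResult:
    """Per-patient derivative-sign agreement between report and simulation."""

    patient_id: str
    n_segments: int
    n_matches: int

    @property
    def fit_percent(self) -> float:
        return _round1(100.0 * self.n_matches / self.n_segments)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def default_tolerance(*series: Sequence[float]) -> float:
    """Constancy tolerance: 1% of the largest value range among the series."""
    rng = max((float(np.ptp(np.asarray(s, dtype=float))) for s in series), default=0.0)
    return 0.01 * rng


def classify_segments(series: Sequence[float], tolerance: float = 0.0) -> list[SegmentClass]:
    """Classify each year-to-year segment by the sign of its first difference.

    |Δ| ≤ tolerance → constant; Δ > tolerance → increasing; else decreasing.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("series must contain at least two yearly values")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    out = []
    for d in np.diff(y):
        if abs(d) <= tolerance:
            out.append(SegmentClass.constant)
        elif d > tolerance:
            out.append(SegmentClass.increasing)
        else:
            out.append(SegmentClass.decreasing)
    return out


def fit_percentage(
    simulated: Sequence[float],
    reported: Sequence[float],
    tolerance: float | None = None,
    patient_id: str = "",
) -> FitResult:
    """Derivative-sign match between two waveforms on a common yearly grid.

    With ``tolerance=None`` the default 1%-of-range rule is applied to both
    series jointly, keeping the statistic symmetric in its arguments.
    """
    a = np.asarray(simulated, dtype=float)
    b = np.asarray(reported, dtype=float)
    if a.shape != b.shape:
        raise ValueError("simulated and reported series differ in length")
    if tolerance is None:
        tolerance = default_tolerance(a, b)
    ca = classify_segments(a, tolerance)
    cb = classify_segments(b, tolerance)
    matches = sum(1 for x, y in zip(ca, cb) if x == y)
    return FitResult(patient_id=patient_id, n_segments=len(ca), n_matches=matches)


def cohort_fit(fits: Iterable[FitResult], mode: str = "pooled") -> float:
    """Cohort-level fit percentage.

    ``pooled`` (default) concatenates all segments before computing the
    match fraction — many-segment patients weigh more; ``mean`` averages the
    per-patient percentages unweighted.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fit results supplied")
    if mode == "pooled":
        total = sum(f.n_segments for f in fits)
        matched = sum(f.n_matches for f in fits)
        return _round1(100.0 * matched / total)
    if mode == "mean":
        return _round1(float(np.mean([f.fit_percent for f in fits])))
    raise ValueError(f"unknown cohort fit mode {mode!r}")


def render_template(
    template_id: int, duration: int, amplitude: float = 100.0
) -> np.ndarray:
    """Canonical per-year values of one of the nine course patterns.

    Worsening runs from 0 down to -amplitude, improvement from -amplitude up
    to 0; oscillating patterns have a fixed 4-year period (slight ±10, strong
    ±40, scaled by amplitude/100); "then-plateau" and reversal shapes place
    the break point at mid-course. The series has ``duration + 1`` values,
    all within [-100, 100].
    """
    if duration < 1:
        raise ValueError("duration must be at least one year")
    if template_id not in TEMPLATE_NAMES:
        raise ValueError(f"unknown template_id {template_id}")
    a = float(np.clip(amplitude, 0.0, 100.0))
    t = np.arange(duration + 1, dtype=float)
    mid = duration / 2.0
    if template_id == 1:  # monotone worsening
        y = -a * t / duration
    elif template_id == 2:  # monotone improvement
        y = -a + a * t / duration
    elif template_id == 3:  # constant
        y = np.zeros_like(t)
    elif template_id in (4, 5):  # oscillations, period 4 years
        swing = (10.0 if template_id == 4 else 40.0) * a / 100.0
        y = swing * np.sin(2.0 * np.pi * t / 4.0)
    elif template_id == 6:  # worsening-then-plateau
        y = np.where(t <= mid, -a * t / max(mid, 1e-9), -a)
    elif template_id == 7:  # improvement-then-plateau
        y = np.where(t <= mid, -a + a * t / max(mid, 1e-9), 0.0)
    elif template_id == 8:  # worsening-then-improvement (V shape)
        y = np.where(t <= mid, -a * t / max(mid, 1e-9), -a + a * (t - mid) / max(duration - mid, 1e-9))
    else:  # 9: improvement-then-worsening (inverted V)
        y = np.where(t <= mid, -a + a * t / max(mid, 1e-9), -a * (t - mid) / max(duration - mid, 1e-9))
    return np.clip(y, -100.0, 100.0)


def interpolate_anchors(anchors: Sequence[tuple[float, float]], years: Sequence[int]) -> np.ndarray:
    """Linearly interpolate a custom-drawn course from (year, value) anchors."""
    if len(anchors) < 1:
        raise ValueError("at least one anchor required")
    pts = sorted(anchors)
    ax = np.array([p[0] for p in pts], dtype=float)
    ay = np.array([p[1] for p in pts], dtype=float)
    return np.interp(np.asarray(years, dtype=float), ax, ay)
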