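"""Dosimetric-leaf-gap tuning.

Two estimators are provided:

* the classic sweeping-gap extrapolation — transmission-corrected readings
  of a uniform synchronous gap are linear in the gap width, and the line's
  x-intercept magnitude is the DLG;
* the asynchronous-oscillating-sweeping-gap (aOSG) tune — the model DLG is
  swept over a grid and the value minimizing the mean absolute relative
  difference between calculated and measured doses over a battery of
  (gap, tongue-and-groove fraction) plans is kept.  Because the aOSG plans
  expose tongue-and-groove losses that synchronous sweeps cannot see, the
  aOSG optimum absorbs any TG modelling mismatch and typically exceeds the
  sweeping-gap value.

Transmission is measured directly (closed/open ratio) and is an input to
DLG tuning, never co-fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence

import numpy as np

#: The default aOSG battery: three gaps x five TG fractions = fifteen plans.
DEFAULT_GAPS = (10.0, 20.0, 30.0)
DEFAULT_TG_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Default DLG grid (mm): 0 to 3.4 in 0.1 mm steps.
DEFAULT_DLG_GRID = tuple(np.round(np.arange(0.0, 3.4 + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class AOSGPlan:
    """One asynchronous oscillating sweeping-gap delivery.

    ``shift`` is the stagger between adjacent leaf pairs; the TG fraction is
    shift / gap by definition.
    """

    gap: float
    tg_fraction: float
    shift: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be > 0")
        if not 0.0 <= self.tg_fraction <= 1.0:
            raise ValueError("tg_fraction must be in [0, 1]")
        if abs(self.shift - self.tg_fraction * self.gap) > 1e-9:
            raise ValueError(
                f"shift {self.shift} != tg_fraction*gap = {self.tg_fraction * self.gap}"
            )


@dataclass
class AOSGReadingSet:
    """Measured doses for a plan battery plus a calculated-dose provider.

    ``calculated_provider(plan, dlg)`` returns the TPS dose for the plan at
    a candidate model DLG.
    """

    plans: List[AOSGPlan]
    measured: List[float]
    calculated_provider: Callable[[AOSGPlan, float], float]

    def __post_init__(self) -> None:
        if len(self.plans) != len(self.measured):
            raise ValueError("one measured value per plan required")
        if any(m <= 0 for m in self.measured):
            raise ValueError("measured doses must be > 0")


@dataclass
class DLGCurve:
    """The aOSG cost curve over the DLG grid and its minimizer."""

    dlg_grid: np.ndarray
    mean_abs_diff: np.ndarray  # fraction of measured dose
    per_plan_sd: np.ndarray
    optimum: float
    value_at_optimum: float
    tie: bool = False
    refined: bool = False


@dataclass
class SweepingGapSeries:
    """Readings of synchronous sweeping gaps plus open/closed references."""

    gaps: List[float]
    readings: List[float]
    open_reading: float
    closed_reading: float
    sweep_length: float = 100.0

    def __post_init__(self) -> None:
        gaps = np.asarray(self.gaps, dtype=float)
        if not np.all(np.diff(gaps) > 0):
            raise ValueError("gaps must be strictly increasing")
        if np.any(gaps >= self.sweep_length):
            raise ValueError("all gaps must be < sweep_length")
        if len(self.gaps) != len(self.readings):
            raise ValueError("gaps and readings must have equal length")
        if not 0 < self.closed_reading < self.open_reading:
            raise ValueError("need 0 < closed_reading < open_reading")


def build_aosg_plans(
    gaps: Sequence[float] = DEFAULT_GAPS,
    tg_fractions: Sequence[float] = DEFAULT_TG_FRACTIONS,
) -> List[AOSGPlan]:
    """Full (gap x TG fraction) cross product; defaults give fifteen plans."""
    if len(gaps) == 0 or len(tg_fractions) == 0:
        raise ValueError("gaps and tg_fractions must be non-empty")
    plans = []
    for g in gaps:
        for tau in tg_fractions:
            plans.append(
                AOSGPlan(
                    gap=float(g),
                    tg_fraction=float(tau),
                    shift=float(tau) * float(g),
                    label=f"g{g:g}_tg{tau:g}",
                )
            )
    return plans


def tune_dlg(
    readings: AOSGReadingSet,
    dlg_grid: Sequence[float] = DEFAULT_DLG_GRID,
    parabolic_refine: bool = False,
) -> DLGCurve:
    """Sweep the model DLG and minimize the mean absolute dose difference.

    Per grid value d, relative differences (calc(plan, d) - meas) / meas are
    computed over all plans; the cost is their mean absolute value and the
    spread their standard deviation.  The optimum is the grid argmin
    (smallest d on ties, flagged), optionally refined by a three-point
    parabola through the argmin's neighbours.
    """
    grid = np.asarray(sorted(dlg_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("dlg_grid is empty")
    meas = np.asarray(readings.measured, dtype=float)
    cost = np.empty(grid.size)
    sds = np.empty(grid.size)
    for k, d in enumerate(grid):
        calc = np.array(
            [readings.calculated_provider(p, float(d)) for p in readings.plans]
        )
        diffs = (calc - meas) / meas
        cost[k] = np.mean(np.abs(diffs))
        sds[k] = np.std(diffs, ddof=1) if diffs.size > 1 else 0.0

    i = int(np.argmin(cost))  # argmin returns the first (smallest d) on ties
    tie = bool(np.sum(np.isclose(cost, cost[i], rtol=0, atol=1e-15)) > 1)
    optimum, value, refined = float(grid[i]), float(cost[i]), False
    if parabolic_refine and 0 < i < grid.size - 1:
        x0, x1, x2 = grid[i - 1 : i + 2]
        y0, y1, y2 = cost[i - 1 : i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        if denom != 0:
            a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
            if a > 0:
                xv = -b / (2 * a)
                if x0 <= xv <= x2:
                    optimum, refined = float(xv), True
    return DLGCurve(
        dlg_grid=grid,
        mean_abs_diff=cost,
        per_plan_sd=sds,
        optimum=optimum,
        value_at_optimum=value,
        tie=tie,
        refined=refined,
    )


def estimate_transmission(open_reading: float, closed_reading: float) -> float:
    """MLC transmission as the closed-leaves / open-field dose ratio."""
    if open_reading <= 0:
        raise ValueError("open_reading must be > 0")
    if closed_reading < 0:
        raise ValueError("closed_reading must be >= 0")
    if closed_reading >= open_reading:
        raise ValueError("closed reading must be smaller than the open reading")
    return closed_reading / open_reading


def estimate_dlg_sweeping(series: SweepingGapSeries, transmission: float) -> float:
    """Classic sweeping-gap DLG extrapolation.

    Readings are first corrected for the leaf transmission accumulated while
    the point is shielded, R'(g) = R(g) - T * R_open * (1 - g / L); the
    corrected readings are linear in the gap, R' = m g + b, and the DLG is
    the x-intercept magnitude b / m.
    """
    gaps = np.asarray(series.gaps, dtype=float)
    if gaps.size < 2:
        raise ValueError("at least two gap readings are required")
    readings = np.asarray(series.readings, dtype=float)
    corrected = readings - transmission * series.open_reading * (
        1.0 - gaps / series.sweep_length
    )
    m, b = np.polyfit(gaps, corrected, 1)
    if m <= 0:
        raise ValueError(f"non-positive fitted slope {m}")
    return float(b / m)
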