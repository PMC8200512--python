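"""Penumbra extraction and effective-spot-size tuning.

The effective target spot size broadens the calculated penumbra; it is tuned
per axis by scanning a sigma grid and finding where the mean signed deviation
between calculated and measured 20–80% penumbras (five field sizes, both
sides) crosses zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .params import Axis

#: Field sizes (mm) scanned for penumbra tuning: 0.5x0.5 cm and 1–4 cm in 1 cm steps.
PENUMBRA_FIELD_SIZES = (5.0, 10.0, 20.0, 30.0, 40.0)

#: Default sigma grid (mm): 0 to 2 in 0.2 mm steps.
DEFAULT_SIGMA_GRID = tuple(np.round(np.arange(0.0, 2.0 + 1e-9, 0.2), 10))


@dataclass
class Profile:
    """A 1D dose profile scan.

    Positions are mm at the isocenter plane, strictly increasing and spanning
    the central axis (x = 0).  Readings are arbitrary dose units until
    :func:`normalize_profile` rescales them to 100% at the central axis.
    """

    axis: Axis
    field_size: float
    positions: np.ndarray
    readings: np.ndarray
    depth_mm: float = 100.0
    ssd_mm: float = 900.0
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.readings.shape:
            raise ValueError("positions and readings must be equal-length 1D arrays")
        if self.positions.size < 2:
            raise ValueError("profile needs at least two samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not (self.positions[0] <= 0.0 <= self.positions[-1]):
            raise ValueError("central axis position 0 must lie within the scan range")

    def central_reading(self) -> float:
        """Reading at x = 0, linearly interpolated if not sampled exactly."""
        return float(np.interp(0.0, self.positions, self.readings))


@dataclass(frozen=True)
class PenumbraPair:
    """Left and right 20–80% penumbra widths (mm) of one profile."""

    left: float
    right: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.left) and np.isfinite(self.right)):
            raise ValueError("penumbras must be finite")
        if self.left <= 0 or self.right <= 0:
            raise ValueError("penumbras must be > 0")


@dataclass
class SpotTuneResult:
    """Outcome of a spot-size grid scan on one axis."""

    grid: np.ndarray
    mean_deviation: np.ndarray  # signed, calc - meas, mm
    optimum: float
    method: str  # "zero_crossing" or "argmin"
    crossings: list = field(default_factory=list)
    ambiguous: bool = False


def normalize_profile(p: Profile) -> Profile:
    """Rescale readings so the central-axis value is 100%.

    The 100% level is the central-axis reading (interpolated if needed), not
    the profile maximum — relevant for FFF beams, where the unflattened cone
    peaks off-axis at large fields.
    """
    central = p.central_reading()
    if central <= 0:
        raise ValueError(f"central-axis reading {central} is not positive")
    return Profile(
        axis=p.axis,
        field_size=p.field_size,
        positions=p.positions.copy(),
        readings=p.readings * (100.0 / central),
        depth_mm=p.depth_mm,
        ssd_mm=p.ssd_mm,
        label=p.label,
    )


def _edge_crossing(x: np.ndarray, y: np.ndarray, level: float, side: str) -> float:
    """Position where the profile crosses `level` on one edge, by linear interpolation.

    The searched region is the monotone edge: for the right side, samples at
    x >= 0 (decreasing dose); for the left, x <= 0.  Exactly one bracketing
    interval is required.
    """
    if side == "right":
        mask = x >= 0
        xs, ys = x[mask], y[mask]
    else:
        mask = x <= 0
        xs, ys = x[mask][::-1], y[mask][::-1]  # walk outward from the axis
    d = ys - level
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    exact = np.nonzero(d == 0)[0]
    candidates = []
    for i in sign_change:
        t = d[i] / (d[i] - d[i + 1])
        candidates.append(float(xs[i] + t * (xs[i + 1] - xs[i])))
    for i in exact:
        candidates.append(float(xs[i]))
    candidates = sorted(set(np.round(candidates, 12)))
    if not candidates:
        raise ValueError(f"no {level}% crossing found on the {side} side")
    if len(candidates) > 1:
        raise ValueError(
            f"multiple {level}% crossings on the {side} side: {candidates}"
        )
    return candidates[0]


def extract_penumbra(p: Profile) -> PenumbraPair:
    """20–80% penumbra widths of a normalized profile.

    Per side, the 20% and 80% crossing positions are found by linear
    interpolation between bracketing samples; the penumbra is |x20 - x80|.
    Raises if either level is not crossed exactly once in the edge region.
    """
    x, y = p.positions, p.readings
    right = abs(
        _edge_crossing(x, y, 20.0, "right") - _edge_crossing(x, y, 80.0, "right")
    )
    left = abs(
        _edge_crossing(x, y, 20.0, "left") - _edge_crossing(x, y, 80.0, "left")
    )
    return PenumbraPair(left=left, right=right)


def mean_penumbra_deviation(
    calc: Iterable[Profile], meas: Iterable[Profile]
) -> float:
    """Mean signed (calculated - measured) penumbra deviation in mm.

    Profiles are matched on (axis, field_size); the mean runs over all
    matched pairs x {left, right} with equal weight.  Profiles are normalized
    before extraction.
    """
    calc_map = {(p.axis, p.field_size): p for p in calc}
    meas_map = {(p.axis, p.field_size): p for p in meas}
    keys = sorted(set(calc_map) & set(meas_map))
    if not keys:
        raise ValueError("no matched (axis, field_size) pairs")
    if set(calc_map) != set(meas_map):
        raise ValueError(
            "calculated and measured profile sets do not match: "
            f"{sorted(set(calc_map) ^ set(meas_map))}"
        )
    devs = []
    for k in keys:
        pc = extract_penumbra(normalize_profile(calc_map[k]))
        pm = extract_penumbra(normalize_profile(meas_map[k]))
        devs.append(pc.left - pm.left)
        devs.append(pc.right - pm.right)
    return float(np.mean(devs))


def tune_spot_size(
    meas: Sequence[Profile],
    calc_provider: Callable[[float], Sequence[Profile]],
    grid: Sequence[float] = DEFAULT_SIGMA_GRID,
) -> SpotTuneResult:
    """Scan a sigma grid and locate the zero of the mean penumbra deviation.

    ``calc_provider(sigma)`` returns the calculated profile set for a
    candidate spot size.  The optimum is the linearly interpolated zero
    crossing of the (monotone, approximately linear) deviation curve; when
    the curve never changes sign the grid argmin of |deviation| is returned
    instead (``method="argmin"``) — e.g. a beam whose measured penumbra is
    narrower than the sharpest calculation, where the best fit is sigma = 0.
    Multiple sign changes are reported and flagged ambiguous.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sigma grid is empty")
    dev = np.array([mean_penumbra_deviation(calc_provider(s), meas) for s in grid])

    crossings = []
    for i in range(len(grid) - 1):
        if dev[i] == 0.0:
            crossings.append(float(grid[i]))
        elif dev[i] * dev[i + 1] < 0:
            t = dev[i] / (dev[i] - dev[i + 1])
            crossings.append(float(grid[i] + t * (grid[i + 1] - grid[i])))
    if dev[-1] == 0.0:
        crossings.append(float(grid[-1]))
    crossings = sorted(set(crossings))

    if len(crossings) >= 1:
        return SpotTuneResult(
            grid=grid,
            mean_deviation=dev,
            optimum=crossings[0],
            method="zero_crossing",
            crossings=crossings,
            ambiguous=len(crossings) > 1,
        )
    return SpotTuneResult(
        grid=grid,
        mean_deviation=dev,
        optimum=float(grid[int(np.argmin(np.abs(dev)))]),
        method="argmin",
        crossings=[],
        ambiguous=False,
    )
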