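"""Closed-form synthetic dose engine.

Stands in for both the linac ("measured" role) and the TPS ("calculated"
role) so that every tuning stage of the commissioning workflow has a known
ground truth to recover.  The model laws are the simplest ones that
reproduce the qualitative behaviour of a rounded-leaf MLC beam model:

* profiles are double-erf edges of a DLG-widened aperture blurred by the
  effective spot (plus detector blurring in quadrature for measurements),
  sitting on a transmission floor;
* a sweeping-gap delivery deposits dose linearly in (gap + DLG), minus a
  tongue-and-groove loss proportional to the inter-leaf shift, plus leaf
  transmission during the fraction of the sweep the point is shielded;
* small-field output factors are products of one erf edge per axis;
* QA planes are sums of erf-edged rectangular apertures.

The laws are synthetic: they are not a transport calculation and make no
claim to emulate any commercial algorithm quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .gamma import DoseGrid
from .params import BeamModelParams, FieldGeometry, Role, SyntheticTruth
from .profiles import Profile

#: Calibration constant: the open-field (gap = sweep length) reading.
CALIBRATION = 1.0

_ROLE_CODE = {"measured": 0, "calculated": 1}
_AXIS_CODE = {"crossline": 0, "inline": 1}


def _rng(truth: SyntheticTruth, *tags: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed & 0x7FFFFFFF, *(t & 0x7FFFFFFF for t in tags)])


def _double_erf_edge(x: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Fluence of a slit aperture [-w, w] blurred by a Gaussian of width sigma."""
    if sigma > 0:
        s = math.sqrt(2.0) * sigma
        return 0.5 * (erf((half_width - x) / s) + erf((half_width + x) / s))
    return (np.abs(x) < half_width).astype(float) + 0.5 * (np.abs(x) == half_width)


def effective_sigma(geom: FieldGeometry, truth: SyntheticTruth, role: Role) -> float:
    sigma = truth.params.sigma_x if geom.axis == "crossline" else truth.params.sigma_y
    if role == "measured":
        return math.hypot(sigma, truth.detector_sigma)
    return sigma


def simulate_profile(
    geom: FieldGeometry,
    truth: SyntheticTruth,
    role: Role,
    positions: Sequence[float],
) -> Profile:
    """Synthesize a 1D profile for one field size and scan axis.

    The MLC-defined edges along the leaf-travel (crossline) axis are widened
    by DLG/2 each; inline edges are not.  The reading is

        (1 - T) * [double-erf edge] + T,

    normalized to 100% at the central axis.  Measured profiles add detector
    blurring in quadrature and, when ``noise_cv > 0``, multiplicative
    Gaussian noise.
    """
    positions = np.asarray(positions, dtype=float)
    if not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")
    p = truth.params
    half_width = geom.field_size / 2.0
    if geom.axis == "crossline":
        half_width += p.dlg / 2.0
    sigma_eff = effective_sigma(geom, truth, role)
    t = p.transmission
    y = (1.0 - t) * _double_erf_edge(positions, half_width, sigma_eff) + t
    central = float(np.interp(0.0, positions, y))
    if central <= 0:
        raise ValueError("degenerate geometry: zero central-axis reading")
    y = y * (100.0 / central)

    # the scan must resolve both penumbras: 20% and 80% of the (noise-free)
    # central-axis level must be bracketed on each side
    left, right = y[positions <= 0], y[positions >= 0]
    for side, arr in (("left", left), ("right", right)):
        if arr.min() > 20.0 or arr.max() < 80.0:
            raise ValueError(
                f"positions do not cover the 20-80% levels on the {side} side "
                f"(range {arr.min():.1f}-{arr.max():.1f}%)"
            )

    if role == "measured" and truth.noise_cv > 0:
        rng = _rng(
            truth,
            int(round(geom.field_size * 10)),
            _AXIS_CODE[geom.axis],
            _ROLE_CODE[role],
        )
        y = y * (1.0 + truth.noise_cv * rng.standard_normal(y.shape))

    return Profile(
        axis=geom.axis,
        field_size=geom.field_size,
        positions=positions,
        readings=y,
        label=f"{geom.axis}-{geom.field_size:g}mm-{role}",
    )


def default_positions(
    geom: FieldGeometry, truth: SyntheticTruth, step: float = 0.1
) -> np.ndarray:
    """Scan positions covering both field edges with margin for the penumbra tails."""
    sigma_max = math.hypot(
        max(truth.params.sigma_x, truth.params.sigma_y), truth.detector_sigma
    )
    half = geom.field_size / 2.0 + abs(truth.params.dlg) / 2.0
    margin = max(5.0, 8.0 * sigma_max)
    extent = half + margin
    n = int(math.ceil(extent / step))
    return step * np.arange(-n, n + 1)


def sweeping_gap_reading(
    gap: float,
    truth: SyntheticTruth,
    role: Role,
    tg_fraction: float = 0.0,
    sweep_length: float = 100.0,
    model_dlg: Optional[float] = None,
    noise: bool = True,
) -> float:
    """Point dose of a (possibly asynchronous) sweeping-gap delivery.

    A uniform gap ``g`` sweeps across ``sweep_length`` L; adjacent leaf pairs
    are shifted by ``s = tg_fraction * g``, exposing tongue-and-groove losses.
    The dose law is

        D = C * (g + DLG - lambda * s) / L + T * (1 - g / L)

    with lambda the TG loss coefficient of the role (the "linac" and the
    "TPS" may disagree — sweeping-gap tests with s = 0 cannot see that
    mismatch, asynchronous ones can).  For the calculated role ``model_dlg``
    overrides the physical DLG, which is what a DLG sweep varies.
    """
    if not 0.0 < gap < sweep_length:
        raise ValueError(f"gap must be in (0, {sweep_length}) mm, got {gap}")
    if not 0.0 <= tg_fraction <= 1.0:
        raise ValueError("tg_fraction must be in [0, 1]")
    p = truth.params
    if role == "calculated":
        dlg = p.dlg if model_dlg is None else model_dlg
        lam = truth.tg_loss_calculated
    else:
        dlg = p.dlg
        lam = truth.tg_loss_measured
    shift = tg_fraction * gap
    dose = (
        CALIBRATION * (gap + dlg - lam * shift) / sweep_length
        + p.transmission * (1.0 - gap / sweep_length)
    )
    if role == "measured" and truth.noise_cv > 0 and noise:
        rng = _rng(truth, int(round(gap * 1000)), int(round(tg_fraction * 1000)), 7)
        dose *= 1.0 + truth.noise_cv * float(rng.standard_normal())
    return float(dose)


def open_field_reading(truth: SyntheticTruth, role: Role = "measured") -> float:
    """Open-field reference reading (the calibration constant)."""
    dose = CALIBRATION
    if role == "measured" and truth.noise_cv > 0:
        rng = _rng(truth, 11)
        dose *= 1.0 + truth.noise_cv * float(rng.standard_normal())
    return float(dose)


def closed_field_reading(truth: SyntheticTruth, role: Role = "measured") -> float:
    """Reading with all leaves closed behind the jaws: pure leaf transmission."""
    dose = CALIBRATION * truth.params.transmission
    if role == "measured" and truth.noise_cv > 0:
        rng = _rng(truth, 13)
        dose *= 1.0 + truth.noise_cv * float(rng.standard_normal())
    return float(dose)


def output_factor(
    field_size: float, params: BeamModelParams, role: Role = "calculated"
) -> float:
    """Small-field output factor of a square MLC-defined field.

    Product of one erf source-occlusion edge per axis on a transmission
    floor:

        OF = (1 - T) * E(a + DLG/2, sigma_x) * E(a, sigma_y) + T,
        E(w, s) = erf(w / (sqrt(2) s)),  E = 1 when s = 0,

    with a the half field size.  Strictly increasing in DLG and T, strictly
    decreasing in sigma_x and sigma_y while the field is small enough for the
    source to be partially occluded; tends to 1 for large fields.  The same
    law serves both roles — measured and calculated differ only through the
    parameters supplied.
    """
    if field_size <= 0:
        raise ValueError("field_size must be > 0")
    a = field_size / 2.0

    def edge(w: float, sigma: float) -> float:
        if sigma <= 0:
            return 1.0
        return float(erf(w / (math.sqrt(2.0) * sigma)))

    t = params.transmission
    return (1.0 - t) * edge(a + params.dlg / 2.0, params.sigma_x) * edge(
        a, params.sigma_y
    ) + t


@dataclass(frozen=True)
class Aperture:
    """One rectangular erf-edged beam segment of a modulated plane."""

    cx: float
    cy: float
    width: float
    height: float
    weight: float = 1.0


@dataclass(frozen=True)
class ModulationPattern:
    """A modulated delivery as a weighted sum of rectangular apertures."""

    apertures: Tuple[Aperture, ...]

    @classmethod
    def random(
        cls, seed: int, n_apertures: int = 5, extent: float = 60.0
    ) -> "ModulationPattern":
        """Reproducible pseudo-clinical pattern: overlapping offset apertures."""
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        aps = []
        for _ in range(n_apertures):
            aps.append(
                Aperture(
                    cx=float(rng.uniform(-0.2, 0.2) * extent),
                    cy=float(rng.uniform(-0.2, 0.2) * extent),
                    width=float(rng.uniform(0.3, 0.7) * extent),
                    height=float(rng.uniform(0.3, 0.7) * extent),
                    weight=float(rng.uniform(0.5, 1.5)),
                )
            )
        return cls(apertures=tuple(aps))


def simulate_dose_plane(
    params: BeamModelParams,
    pattern: ModulationPattern,
    extent: float = 60.0,
    spacing: float = 2.0,
) -> DoseGrid:
    """Evaluate a modulated dose plane on a square grid of side ``extent`` mm.

    Each aperture contributes weight * edge_x * edge_y, with the x edges
    DLG-widened and sigma_x-blurred and the y edges sigma_y-blurred; the
    whole plane sits on a transmission floor scaled by the total weight.
    Deterministic: randomness only ever enters through the pattern seed.
    """
    n = int(round(extent / spacing)) + 1
    coords = spacing * np.arange(n) - extent / 2.0
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    t = params.transmission
    total_weight = sum(a.weight for a in pattern.apertures)
    dose = np.zeros_like(xx)
    for a in pattern.apertures:
        ex = _double_erf_edge(xx - a.cx, a.width / 2.0 + params.dlg / 2.0, params.sigma_x)
        ey = _double_erf_edge(yy - a.cy, a.height / 2.0, params.sigma_y)
        dose += a.weight * ((1.0 - t) * ex * ey + t)
    if total_weight > 0:
        dose /= total_weight
    return DoseGrid(
        dose=dose, spacing=(spacing, spacing), origin=(-extent / 2.0, -extent / 2.0)
    )


def simulate_profiles(
    truth: SyntheticTruth,
    role: Role,
    field_sizes: Sequence[float],
    axis: str,
    step: float = 0.1,
) -> List[Profile]:
    """Profiles for a set of field sizes on one axis (convenience wrapper)."""
    out = []
    for fs in field_sizes:
        geom = FieldGeometry(field_size=fs, axis=axis)  # type: ignore[arg-type]
        out.append(simulate_profile(geom, truth, role, default_positions(geom, truth, step)))
    return out
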