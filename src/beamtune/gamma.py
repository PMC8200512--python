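"""Global 2D gamma-index comparison of dose planes.

Implements the gamma test in the global-normalization convention of AAPM
TG-218: the dose-difference denominator is a fixed percentage of the
reference-plane maximum, points below a low-dose threshold are excluded, and
a point passes when

    gamma(r) = min_{r'} sqrt( |r' - r|^2 / dta^2 + (De(r') - Dr(r))^2 / dD^2 ) <= 1

where the minimum runs over the evaluated plane, dta is the
distance-to-agreement criterion and dD the absolute dose criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator


@dataclass
class DoseGrid:
    """Dose values on a regular 2D grid.

    ``dose[j, i]`` is the dose at ``(y0 + j*dy, x0 + i*dx)``; spacings are mm.
    """

    dose: np.ndarray
    spacing: Tuple[float, float]  # (dy, dx) mm
    origin: Tuple[float, float] = (0.0, 0.0)  # (y0, x0) mm
    units: str = "normalized"

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 2:
            raise ValueError("dose must be a 2D array")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be > 0")
        if np.any(self.dose < 0):
            raise ValueError("doses must be >= 0")

    @property
    def y(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.dose.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.dose.shape[1])


@dataclass
class GammaResult:
    """Gamma map on the reference grid, with the below-threshold mask.

    ``gamma`` is NaN at masked (excluded) points; ``pass_rate`` is the
    percentage of evaluated points with gamma <= 1.
    """

    gamma: np.ndarray
    mask: np.ndarray  # True where the point was evaluated
    pass_rate: float
    dose_pct: float
    dta_mm: float
    threshold_pct: float
    normalization: str = "global"
    search_step_mm: float = 0.0
    search_radius_mm: float = 0.0


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    dose_pct: float = 3.0,
    dta_mm: float = 2.0,
    threshold_pct: float = 10.0,
) -> GammaResult:
    """Compute the global gamma map of ``evaluated`` against ``reference``.

    The evaluated plane is bilinearly upsampled so the search step is at
    most ``dta_mm / 10``; the search radius is ``3 * dta_mm``.  Reference
    points below ``threshold_pct`` % of the reference maximum are excluded
    from the gamma map and from the pass-rate denominator.
    """
    ref_max = float(reference.dose.max())
    if ref_max <= 0:
        raise ValueError("reference maximum must be > 0")
    if dose_pct <= 0 or dta_mm <= 0:
        raise ValueError("criteria must be > 0")
    dd_abs = dose_pct / 100.0 * ref_max
    mask = reference.dose >= threshold_pct / 100.0 * ref_max
    if not mask.any():
        raise ValueError("all reference points fall below the dose threshold")

    ry, rx = reference.y, reference.x
    ey, ex = evaluated.y, evaluated.x
    if rx[-1] < ex[0] or ex[-1] < rx[0] or ry[-1] < ey[0] or ey[-1] < ry[0]:
        raise ValueError("reference and evaluated grids do not overlap")

    interp = RegularGridInterpolator(
        (ey, ex), evaluated.dose, method="linear", bounds_error=False, fill_value=np.nan
    )

    step = dta_mm / 10.0
    radius = 3.0 * dta_mm
    n = int(math.ceil(radius / step))
    offsets_1d = step * np.arange(-n, n + 1)
    oy, ox = np.meshgrid(offsets_1d, offsets_1d, indexing="ij")
    r2 = oy**2 + ox**2
    keep = r2 <= radius**2 + 1e-12
    oy, ox, r2 = oy[keep], ox[keep], r2[keep]
    order = np.argsort(r2)  # nearest offsets first: enables early exit
    oy, ox, r2 = oy[order], ox[order], r2[order]

    yy, xx = np.meshgrid(ry, rx, indexing="ij")
    pts_y = yy[mask]
    pts_x = xx[mask]
    ref_d = reference.dose[mask]

    gamma_sq = np.full(pts_y.shape, np.inf)
    for dy, dx, rr in zip(oy, ox, r2):
        dist_term = rr / dta_mm**2
        # offsets are distance-sorted: once the pure-distance term exceeds
        # every current minimum the search cannot improve
        if dist_term >= gamma_sq.max():
            break
        ed = interp(np.column_stack([pts_y + dy, pts_x + dx]))
        valid = np.isfinite(ed)
        if not valid.any():
            continue
        cand = np.full_like(gamma_sq, np.inf)
        cand[valid] = dist_term + (ed[valid] - ref_d[valid]) ** 2 / dd_abs**2
        np.minimum(gamma_sq, cand, out=gamma_sq)

    gmap = np.full(reference.dose.shape, np.nan)
    gmap[mask] = np.sqrt(gamma_sq)
    evaluated_vals = gmap[mask]
    pass_rate = 100.0 * float(np.mean(evaluated_vals <= 1.0))
    return GammaResult(
        gamma=gmap,
        mask=mask,
        pass_rate=pass_rate,
        dose_pct=dose_pct,
        dta_mm=dta_mm,
        threshold_pct=threshold_pct,
        normalization="global",
        search_step_mm=step,
        search_radius_mm=radius,
    )


def qa_verdict(pass_rate: float) -> str:
    """QA decision per the universal tolerance (95%) and action (90%) limits.

    >= 95% -> "pass"; 90–95% -> "investigate"; < 90% -> "fail".
    """
    if not 0.0 <= pass_rate <= 100.0:
        raise ValueError("pass_rate must be in [0, 100]")
    if pass_rate >= 95.0:
        return "pass"
    if pass_rate >= 90.0:
        return "investigate"
    return "fail"
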