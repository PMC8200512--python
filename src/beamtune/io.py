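"""Readers and writers for the toolkit's plain-text formats.

All tabular data are CSV with ``# key=value`` header lines where per-file
metadata is needed; floats are serialized with 12 significant digits so
write/read round-trips are lossless at that precision.  Dose planes are
either the package's own text-grid format or single-frame DICOM RT Dose
files (read through pydicom).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dlg import AOSGPlan, SweepingGapSeries
from .gamma import DoseGrid
from .profiles import Profile

_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FMT % float(x)


def _read_headers(path: Path) -> Tuple[Dict[str, str], str]:
    """Split ``# key=value`` header lines from the CSV body."""
    meta: Dict[str, str] = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body_lines.append(line)
    return meta, "\n".join(body_lines)


# ---------------------------------------------------------------- profiles

def write_profile(p: Profile, path: Path) -> None:
    lines = [
        f"# axis={p.axis}",
        f"# field_size_mm={_fmt(p.field_size)}",
        f"# depth_mm={_fmt(p.depth_mm)}",
        f"# ssd_mm={_fmt(p.ssd_mm)}",
        "position_mm,reading",
    ]
    for x, y in zip(p.positions, p.readings):
        lines.append(f"{_fmt(x)},{_fmt(y)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: Path) -> Profile:
    meta, body = _read_headers(Path(path))
    df = pd.read_csv(_io.StringIO(body))
    return Profile(
        axis=meta["axis"],  # type: ignore[arg-type]
        field_size=float(meta["field_size_mm"]),
        positions=df["position_mm"].to_numpy(),
        readings=df["reading"].to_numpy(),
        depth_mm=float(meta.get("depth_mm", 100.0)),
        ssd_mm=float(meta.get("ssd_mm", 900.0)),
        label=Path(path).stem,
    )


# ------------------------------------------------------------- aOSG plans

def write_aosg_plans(plans: Sequence[AOSGPlan], path: Path) -> None:
    lines = ["label,gap_mm,tg_fraction,shift_mm"]
    for p in plans:
        lines.append(
            f"{p.label},{_fmt(p.gap)},{_fmt(p.tg_fraction)},{_fmt(p.shift)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_aosg_plans(path: Path) -> List[AOSGPlan]:
    df = pd.read_csv(path)
    return [
        AOSGPlan(
            gap=float(r.gap_mm),
            tg_fraction=float(r.tg_fraction),
            shift=float(r.shift_mm),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def write_aosg_readings(
    plans: Sequence[AOSGPlan], doses: Sequence[float], path: Path
) -> None:
    lines = ["label,measured_dose"]
    for p, d in zip(plans, doses):
        lines.append(f"{p.label},{_fmt(d)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_aosg_readings(path: Path) -> Dict[str, float]:
    df = pd.read_csv(path)
    return {str(r.label): float(r.measured_dose) for r in df.itertuples()}


# --------------------------------------------------------- sweeping series

def write_sweeping_series(series: SweepingGapSeries, path: Path) -> None:
    lines = [
        f"# open_reading={_fmt(series.open_reading)}",
        f"# closed_reading={_fmt(series.closed_reading)}",
        f"# sweep_length_mm={_fmt(series.sweep_length)}",
        "gap_mm,reading",
    ]
    for g, r in zip(series.gaps, series.readings):
        lines.append(f"{_fmt(g)},{_fmt(r)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sweeping_series(path: Path) -> SweepingGapSeries:
    meta, body = _read_headers(Path(path))
    df = pd.read_csv(_io.StringIO(body))
    return SweepingGapSeries(
        gaps=df["gap_mm"].tolist(),
        readings=df["reading"].tolist(),
        open_reading=float(meta["open_reading"]),
        closed_reading=float(meta["closed_reading"]),
        sweep_length=float(meta.get("sweep_length_mm", 100.0)),
    )


# ----------------------------------------------------------- output factors

def write_of_table(df: pd.DataFrame, path: Path) -> None:
    """Columns: field_size_mm, detector, raw_ratio, correction_factor, measured_of."""
    cols = ["field_size_mm", "detector", "raw_ratio", "correction_factor", "measured_of"]
    df[cols].to_csv(path, index=False, float_format=_FMT)


def read_of_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------- dose planes

def write_dose_plane(grid: DoseGrid, path: Path) -> None:
    lines = [
        f"# spacing_mm={_fmt(grid.spacing[0])},{_fmt(grid.spacing[1])}",
        f"# origin_mm={_fmt(grid.origin[0])},{_fmt(grid.origin[1])}",
        f"# units={grid.units}",
    ]
    for row in grid.dose:
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dose_plane_text(path: Path) -> DoseGrid:
    meta, body = _read_headers(Path(path))
    dose = np.loadtxt(_io.StringIO(body), delimiter=",", ndmin=2)
    dy, dx = (float(v) for v in meta["spacing_mm"].split(","))
    y0, x0 = (float(v) for v in meta.get("origin_mm", "0,0").split(","))
    return DoseGrid(
        dose=dose, spacing=(dy, dx), origin=(y0, x0),
        units=meta.get("units", "normalized"),
    )


def read_dose_plane_dicom(path: Path) -> DoseGrid:
    """Single-frame DICOM RT Dose plane."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    dose = ds.pixel_array.astype(float) * float(getattr(ds, "DoseGridScaling", 1.0))
    if dose.ndim == 3:
        if dose.shape[0] != 1:
            raise ValueError("only single-frame RT Dose planes are supported")
        dose = dose[0]
    dy, dx = (float(v) for v in ds.PixelSpacing)
    pos = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return DoseGrid(dose=dose, spacing=(dy, dx), origin=(float(pos[1]), float(pos[0])),
                    units="Gy")


def read_dose_plane(path: Path) -> DoseGrid:
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return read_dose_plane_dicom(path)
    return read_dose_plane_text(path)


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """Structured configuration of a commissioning run (YAML on disk)."""

    beam: str = "synthetic"
    seed: int = 0
    # engine (TPS stand-in) section
    tg_loss_measured: float = 0.0
    tg_loss_calculated: float = 0.0
    detector_sigma: float = 0.0
    noise_cv: float = 0.0
    truth_params: Optional[dict] = None  # only used by fixture generation
    # tuning grids (None -> package default; an explicit empty list is invalid)
    sigma_grid: Optional[List[float]] = None
    dlg_grid: Optional[List[float]] = None
    # DOE
    doe_levels: Optional[dict] = None
    alpha: float = 0.01
    # gamma criteria
    gamma_dose_pct: float = 3.0
    gamma_dta_mm: float = 2.0
    gamma_threshold_pct: float = 10.0
    # input files
    profiles: List[str] = field(default_factory=list)
    aosg_plans: Optional[str] = None
    aosg_readings: Optional[str] = None
    sweeping: Optional[str] = None
    output_factors: Optional[str] = None
    dose_planes: List[dict] = field(default_factory=list)  # {reference, evaluated, label}

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for name in ("sigma_grid", "dlg_grid"):
            g = getattr(self, name)
            if g is None:
                continue
            if len(g) == 0:
                raise ValueError(f"{name} must be non-empty")
            if sorted(g) != list(g):
                raise ValueError(f"{name} must be sorted")


def load_config(path: Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: Path) -> None:
    data = {k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
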