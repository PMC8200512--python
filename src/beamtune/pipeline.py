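"""End-to-end commissioning pipeline and synthetic fixture generation.

``run_commission`` executes the full workflow on the inputs named in a
:class:`~beamtune.io.RunConfig`:

    transmission -> spot-size tuning (both axes) -> DLG (aOSG + sweeping)
    -> DOE sensitivity -> gamma QA

The transmission ratio is read first (a single division) because the
calculated profiles and sweeping doses need a transmission value; the
report presents the stages in the tuning order spot -> transmission -> DLG.
Missing input families are skipped with a logged warning and the report is
partial.  The "TPS" side of every comparison is the synthetic closed-form
engine, configured from the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .dlg import (
    DEFAULT_DLG_GRID,
    DEFAULT_GAPS,
    DEFAULT_TG_FRACTIONS,
    AOSGPlan,
    AOSGReadingSet,
    DLGCurve,
    SweepingGapSeries,
    build_aosg_plans,
    estimate_dlg_sweeping,
    estimate_transmission,
    tune_dlg,
)
from .doe import (
    OF_FIELD_SIZES,
    AnovaTable,
    EffectTable,
    FactorLevels,
    build_l27,
    compute_responses,
    design_to_settings,
    effects_and_anova,
)
from .engine import (
    ModulationPattern,
    closed_field_reading,
    open_field_reading,
    output_factor,
    simulate_dose_plane,
    simulate_profile,
    simulate_profiles,
    sweeping_gap_reading,
)
from .gamma import gamma_map, qa_verdict
from .io import (
    RunConfig,
    read_aosg_plans,
    read_aosg_readings,
    read_dose_plane,
    read_of_table,
    read_profile,
    read_sweeping_series,
    save_config,
    write_aosg_plans,
    write_aosg_readings,
    write_dose_plane,
    write_of_table,
    write_profile,
    write_sweeping_series,
)
from .params import BeamModelParams, FieldGeometry, SyntheticTruth
from .profiles import (
    DEFAULT_SIGMA_GRID,
    PENUMBRA_FIELD_SIZES,
    Profile,
    SpotTuneResult,
    tune_spot_size,
)

logger = logging.getLogger("beamtune")

DEFAULT_SWEEPING_GAPS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: Small-field detector correction factors applied to raw reading ratios
#: (synthetic stand-ins shaped like published small-field corrections:
#: > 1 for the smallest fields, -> 1 at 30-40 mm).
DEFAULT_CORRECTIONS: Dict[str, Dict[float, float]] = {
    "diamond": {5.0: 1.021, 10.0: 1.008, 15.0: 1.004, 20.0: 1.002, 30.0: 1.0, 40.0: 1.0},
    "diode": {5.0: 1.035, 10.0: 1.013, 15.0: 1.006, 20.0: 1.003, 30.0: 1.001, 40.0: 1.0},
}


@dataclass
class GammaSummary:
    label: str
    pass_rate: float
    verdict: str


@dataclass
class CommissionReport:
    """Everything the commissioning run produced, JSON-serializable."""

    beam: str
    seed: int
    params: Optional[BeamModelParams] = None
    spot_x: Optional[SpotTuneResult] = None
    spot_y: Optional[SpotTuneResult] = None
    dlg_curve: Optional[DLGCurve] = None
    dlg_sweeping: Optional[float] = None
    transmission: Optional[float] = None
    effects: Optional[EffectTable] = None
    anova: Optional[AnovaTable] = None
    gamma: List[GammaSummary] = field(default_factory=list)
    config_hash: str = ""
    version: str = __version__
    warnings: List[str] = field(default_factory=list)

    def parameter_table(self) -> Dict[str, Optional[float]]:
        """The headline table: four tuned parameters plus both DLG estimates."""
        return {
            "sigma_x_mm": None if self.spot_x is None else self.spot_x.optimum,
            "sigma_y_mm": None if self.spot_y is None else self.spot_y.optimum,
            "dlg_aosg_mm": None if self.dlg_curve is None else self.dlg_curve.optimum,
            "dlg_sweeping_mm": self.dlg_sweeping,
            "transmission": self.transmission,
        }

    def to_dict(self) -> dict:
        def spot(s: Optional[SpotTuneResult]):
            if s is None:
                return None
            return {
                "grid_mm": [float(v) for v in s.grid],
                "mean_deviation_mm": [float(v) for v in s.mean_deviation],
                "optimum_mm": float(s.optimum),
                "method": s.method,
                "crossings_mm": [float(v) for v in s.crossings],
                "ambiguous": s.ambiguous,
            }

        d: dict = {
            "beam": self.beam,
            "seed": self.seed,
            "version": self.version,
            "config_hash": self.config_hash,
            "parameters": self.parameter_table(),
            "spot_tuning": {"crossline": spot(self.spot_x), "inline": spot(self.spot_y)},
            "warnings": list(self.warnings),
        }
        if self.dlg_curve is not None:
            c = self.dlg_curve
            d["dlg_tuning"] = {
                "grid_mm": [float(v) for v in c.dlg_grid],
                "mean_abs_diff": [float(v) for v in c.mean_abs_diff],
                "per_plan_sd": [float(v) for v in c.per_plan_sd],
                "optimum_mm": float(c.optimum),
                "value_at_optimum": float(c.value_at_optimum),
            }
        if self.effects is not None:
            d["doe"] = {
                "amplitudes_pct": {
                    src: {f"{fs:g}mm": float(v) for fs, v in row.items()}
                    for src, row in self.effects.amplitudes.iterrows()
                },
            }
        if self.anova is not None:
            d.setdefault("doe", {})["significant"] = {
                f"{fs:g}mm": self.anova.significant_sources(fs)
                for fs in self.anova.tables
            }
            d["doe"]["degenerate_error"] = {
                f"{fs:g}mm": bool(v) for fs, v in self.anova.degenerate.items()
            }
        d["gamma"] = [
            {"label": g.label, "pass_rate_pct": float(g.pass_rate), "verdict": g.verdict}
            for g in self.gamma
        ]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _engine_truth(cfg: RunConfig, params: BeamModelParams) -> SyntheticTruth:
    return SyntheticTruth(
        params=params,
        tg_loss_measured=cfg.tg_loss_measured,
        tg_loss_calculated=cfg.tg_loss_calculated,
        detector_sigma=cfg.detector_sigma,
        noise_cv=0.0,
        seed=cfg.seed,
    )


def run_commission(cfg: RunConfig, base_dir: Path = Path(".")) -> CommissionReport:
    """Run every commissioning stage the config provides inputs for."""
    base_dir = Path(base_dir)
    # validate everything cheap before any tuning computation
    if cfg.profiles and cfg.sigma_grid is not None and len(cfg.sigma_grid) == 0:
        raise ValueError("sigma_grid is empty")
    if cfg.aosg_readings and cfg.dlg_grid is not None and len(cfg.dlg_grid) == 0:
        raise ValueError("dlg_grid is empty")
    sigma_grid = list(cfg.sigma_grid) if cfg.sigma_grid else list(DEFAULT_SIGMA_GRID)
    dlg_grid = list(cfg.dlg_grid) if cfg.dlg_grid else list(DEFAULT_DLG_GRID)

    report = CommissionReport(beam=cfg.beam, seed=cfg.seed)

    def warn(msg: str) -> None:
        logger.warning(msg)
        report.warnings.append(msg)

    # -- transmission (needed by every calculated quantity downstream)
    transmission = 0.0
    series: Optional[SweepingGapSeries] = None
    if cfg.sweeping:
        series = read_sweeping_series(base_dir / cfg.sweeping)
        transmission = estimate_transmission(series.open_reading, series.closed_reading)
        report.transmission = transmission
    else:
        warn("no sweeping-gap input: transmission and sweeping DLG skipped")

    # -- spot-size tuning, one axis at a time
    sigma_x = sigma_y = 0.0
    if cfg.profiles:
        profiles = [read_profile(base_dir / p) for p in cfg.profiles]
        for axis, attr in (("crossline", "spot_x"), ("inline", "spot_y")):
            meas = [p for p in profiles if p.axis == axis]
            if not meas:
                warn(f"no {axis} profiles: sigma tuning on this axis skipped")
                continue

            def provider(sigma: float, _meas=meas, _axis=axis) -> List[Profile]:
                params = BeamModelParams(
                    sigma_x=sigma if _axis == "crossline" else 0.0,
                    sigma_y=sigma if _axis == "inline" else 0.0,
                    dlg=0.0,
                    transmission=transmission,
                )
                truth = _engine_truth(cfg, params).with_(detector_sigma=0.0)
                return [
                    simulate_profile(
                        FieldGeometry(field_size=m.field_size, axis=_axis),
                        truth,
                        "calculated",
                        m.positions,
                    )
                    for m in _meas
                ]

            result = tune_spot_size(meas, provider, sigma_grid)
            logger.info(
                "%s spot tuning: optimum %.3f mm (%s); deviations %s",
                axis, result.optimum, result.method,
                np.array2string(result.mean_deviation, precision=4),
            )
            setattr(report, attr, result)
        if report.spot_x is not None:
            sigma_x = report.spot_x.optimum
        if report.spot_y is not None:
            sigma_y = report.spot_y.optimum
    else:
        warn("no profile inputs: spot-size tuning skipped")

    # -- DLG: aOSG tune plus classic sweeping-gap estimate
    if cfg.aosg_plans and cfg.aosg_readings:
        plans = read_aosg_plans(base_dir / cfg.aosg_plans)
        doses = read_aosg_readings(base_dir / cfg.aosg_readings)
        measured = [doses[p.label] for p in plans]

        def calc_provider(plan: AOSGPlan, d: float) -> float:
            params = BeamModelParams(
                sigma_x=sigma_x, sigma_y=sigma_y, dlg=0.0, transmission=transmission
            )
            truth = _engine_truth(cfg, params)
            return sweeping_gap_reading(
                plan.gap, truth, "calculated", plan.tg_fraction, model_dlg=d
            )

        curve = tune_dlg(
            AOSGReadingSet(plans=plans, measured=measured, calculated_provider=calc_provider),
            dlg_grid,
        )
        report.dlg_curve = curve
        logger.info(
            "aOSG DLG tuning: optimum %.2f mm, mean |diff| %.4f",
            curve.optimum, curve.value_at_optimum,
        )
    else:
        warn("no aOSG inputs: aOSG DLG tuning skipped")
    if series is not None:
        report.dlg_sweeping = estimate_dlg_sweeping(series, transmission)

    # -- DOE sensitivity of small-field output factors
    if cfg.output_factors and cfg.doe_levels:
        of = read_of_table(base_dir / cfg.output_factors)
        measured_of: Dict[str, Dict[float, float]] = {}
        corrections: Dict[str, Dict[float, float]] = {}
        for det, sub in of.groupby("detector"):
            measured_of[str(det)] = dict(
                zip(sub["field_size_mm"].astype(float), sub["raw_ratio"].astype(float))
            )
            corrections[str(det)] = dict(
                zip(sub["field_size_mm"].astype(float), sub["correction_factor"].astype(float))
            )
        levels = FactorLevels(**{k: tuple(v) for k, v in cfg.doe_levels.items()})
        design = build_l27()
        settings = design_to_settings(design, levels)
        responses = compute_responses(
            settings,
            measured_of,
            lambda params, fs: output_factor(fs, params, "calculated"),
            corrections,
        )
        report.effects, report.anova = effects_and_anova(design, responses, cfg.alpha)
    elif cfg.output_factors or cfg.doe_levels:
        warn("DOE stage needs both output_factors and doe_levels: skipped")

    # -- gamma QA of dose planes
    for entry in cfg.dose_planes:
        ref = read_dose_plane(base_dir / entry["reference"])
        ev = read_dose_plane(base_dir / entry["evaluated"])
        res = gamma_map(
            ref, ev, cfg.gamma_dose_pct, cfg.gamma_dta_mm, cfg.gamma_threshold_pct
        )
        report.gamma.append(
            GammaSummary(
                label=str(entry.get("label", entry["reference"])),
                pass_rate=res.pass_rate,
                verdict=qa_verdict(res.pass_rate),
            )
        )

    # final tuned parameter set
    if report.dlg_curve is not None or report.spot_x is not None:
        report.params = BeamModelParams(
            sigma_x=sigma_x,
            sigma_y=sigma_y,
            dlg=report.dlg_curve.optimum if report.dlg_curve else 0.0,
            transmission=transmission,
        )
    return report


def run_commission_file(config_path: Path) -> CommissionReport:
    """Load a YAML config and run the pipeline relative to its directory."""
    from .io import load_config

    config_path = Path(config_path)
    cfg = load_config(config_path)
    report = run_commission(cfg, base_dir=config_path.parent)
    report.config_hash = hashlib.sha256(config_path.read_bytes()).hexdigest()[:16]
    return report


def generate_fixtures(
    truth: SyntheticTruth,
    out_dir: Path,
    doe_levels: Optional[FactorLevels] = None,
    evaluated_params: Optional[BeamModelParams] = None,
    plane_extent: float = 60.0,
    plane_spacing: float = 2.0,
) -> Path:
    """Write every input family of a commissioning run from the dose engine.

    Produces 10 measured profile CSVs (five field sizes x two axes), the
    fifteen-plan aOSG battery with measured doses, a sweeping-gap series
    with open/closed references, the two-detector output-factor table over
    the 27 DOE settings' field sizes, a measured/evaluated dose-plane pair,
    and a ready-to-run YAML config.  Deterministic given ``truth.seed``.

    Returns the config path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(
        beam="synthetic",
        seed=truth.seed,
        tg_loss_measured=truth.tg_loss_measured,
        tg_loss_calculated=truth.tg_loss_calculated,
        detector_sigma=truth.detector_sigma,
        noise_cv=truth.noise_cv,
        truth_params={
            "sigma_x": truth.params.sigma_x,
            "sigma_y": truth.params.sigma_y,
            "dlg": truth.params.dlg,
            "transmission": truth.params.transmission,
        },
    )

    # profiles
    profile_paths = []
    for axis in ("crossline", "inline"):
        for p in simulate_profiles(truth, "measured", PENUMBRA_FIELD_SIZES, axis):
            name = f"profile_{axis}_{p.field_size:g}mm.csv"
            write_profile(p, out_dir / name)
            profile_paths.append(name)
    cfg.profiles = profile_paths

    # aOSG battery
    plans = build_aosg_plans(DEFAULT_GAPS, DEFAULT_TG_FRACTIONS)
    doses = [
        sweeping_gap_reading(p.gap, truth, "measured", p.tg_fraction) for p in plans
    ]
    write_aosg_plans(plans, out_dir / "aosg_plans.csv")
    write_aosg_readings(plans, doses, out_dir / "aosg_readings.csv")
    cfg.aosg_plans = "aosg_plans.csv"
    cfg.aosg_readings = "aosg_readings.csv"

    # sweeping-gap series (synchronous: tg_fraction = 0)
    series = SweepingGapSeries(
        gaps=list(DEFAULT_SWEEPING_GAPS),
        readings=[
            sweeping_gap_reading(g, truth, "measured", 0.0)
            for g in DEFAULT_SWEEPING_GAPS
        ],
        open_reading=open_field_reading(truth),
        closed_reading=closed_field_reading(truth),
    )
    write_sweeping_series(series, out_dir / "sweeping.csv")
    cfg.sweeping = "sweeping.csv"

    # output factors: raw ratios such that correction x raw = true OF (+ noise)
    rng = np.random.default_rng([truth.seed & 0x7FFFFFFF, 17])
    rows = []
    for det, corr in DEFAULT_CORRECTIONS.items():
        for fs in OF_FIELD_SIZES:
            of_true = output_factor(fs, truth.params, "measured")
            noise = (
                1.0 + truth.noise_cv * float(rng.standard_normal())
                if truth.noise_cv > 0
                else 1.0
            )
            raw = of_true * noise / corr[fs]
            rows.append(
                {
                    "field_size_mm": fs,
                    "detector": det,
                    "raw_ratio": raw,
                    "correction_factor": corr[fs],
                    "measured_of": raw * corr[fs],
                }
            )
    write_of_table(pd.DataFrame(rows), out_dir / "output_factors.csv")
    cfg.output_factors = "output_factors.csv"
    if doe_levels is not None:
        cfg.doe_levels = {
            name: list(getattr(doe_levels, name))
            for name in ("sigma_x", "sigma_y", "dlg", "transmission")
        }

    # dose planes: reference from the truth, evaluated from the model params
    pattern = ModulationPattern.random(truth.seed, n_apertures=5, extent=plane_extent)
    ref = simulate_dose_plane(truth.params, pattern, plane_extent, plane_spacing)
    ev_params = truth.params if evaluated_params is None else evaluated_params
    ev = simulate_dose_plane(ev_params, pattern, plane_extent, plane_spacing)
    write_dose_plane(ref, out_dir / "plane_measured.csv")
    write_dose_plane(ev, out_dir / "plane_calculated.csv")
    cfg.dose_planes = [
        {
            "reference": "plane_measured.csv",
            "evaluated": "plane_calculated.csv",
            "label": "synthetic-plan",
        }
    ]

    config_path = out_dir / "config.yaml"
    save_config(cfg, config_path)
    return config_path
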