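"""Taguchi L27 sensitivity analysis of small-field output factors.

The four beam-model parameters are varied over three levels each on the
L27(3^13) orthogonal array.  Main effects occupy columns 1, 2, 5 and 9 of
the standard array; each requested two-factor interaction occupies the two
columns algebraically confounded with the product of its factors' columns.
Unassigned columns estimate the error term (no replication is assumed).

The array is generated from its GF(3) representation: runs are the 27
triples (a, b, c) in {0,1,2}^3 and column k with coefficient vector
(u, v, w) holds level 1 + (u a + v b + w c) mod 3.  Any two distinct
columns then automatically satisfy the orthogonality property (each of the
nine level pairs occurs exactly three times).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .params import BeamModelParams

FACTOR_NAMES = ("sigma_x", "sigma_y", "dlg", "transmission")

#: Column coefficient vectors of the standard L27(3^13) array, columns 1..13.
_COLUMN_VECTORS: Tuple[Tuple[int, int, int], ...] = (
    (1, 0, 0),  # 1
    (0, 1, 0),  # 2
    (1, 1, 0),  # 3
    (1, 2, 0),  # 4
    (0, 0, 1),  # 5
    (1, 0, 1),  # 6
    (1, 0, 2),  # 7
    (0, 1, 1),  # 8
    (1, 1, 1),  # 9
    (1, 2, 1),  # 10
    (0, 1, 2),  # 11
    (1, 1, 2),  # 12
    (1, 2, 2),  # 13
)

#: Linear-graph factor columns: up to four factors on columns 1, 2, 5, 10.
#: These four columns are level-consistent on the diagonal runs, so trials
#: 1, 14 and 27 set every factor to level 1, 2 and 3 respectively.
_FACTOR_COLUMN_SLOTS = (1, 2, 5, 10)

#: Default interactions: DLG x sigma_x and DLG x sigma_y.
DEFAULT_INTERACTIONS = (("dlg", "sigma_x"), ("dlg", "sigma_y"))

#: Field sizes (mm) of the output-factor responses: 0.5-2 cm in 0.5 cm
#: steps plus 3 and 4 cm.
OF_FIELD_SIZES = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0)


def _normalize_vector(v: Tuple[int, int, int]) -> Tuple[int, int, int]:
    """Scale a GF(3) vector so its first nonzero coefficient is 1."""
    for c in v:
        if c % 3 != 0:
            inv = 1 if c % 3 == 1 else 2  # 2*2 = 4 = 1 mod 3
            return tuple((inv * x) % 3 for x in v)  # type: ignore[return-value]
    raise ValueError("zero vector has no column")


_VECTOR_TO_COLUMN = {v: i + 1 for i, v in enumerate(_COLUMN_VECTORS)}


def _interaction_columns(col_a: int, col_b: int) -> Tuple[int, int]:
    """The two columns confounded with the interaction of two factor columns."""
    u = np.array(_COLUMN_VECTORS[col_a - 1])
    v = np.array(_COLUMN_VECTORS[col_b - 1])
    c1 = _normalize_vector(tuple((u + v) % 3))
    c2 = _normalize_vector(tuple((u + 2 * v) % 3))
    return _VECTOR_TO_COLUMN[c1], _VECTOR_TO_COLUMN[c2]


@dataclass
class TaguchiDesign:
    """The 27 x 13 level matrix with its column bookkeeping.

    ``array[i, k]`` is the level (1-3) of column k+1 in trial i+1.
    """

    array: np.ndarray
    factor_columns: Dict[str, int]
    interaction_columns: Dict[Tuple[str, str], Tuple[int, int]]
    error_columns: Tuple[int, ...]

    @property
    def n_trials(self) -> int:
        return self.array.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.array,
            index=pd.RangeIndex(1, 28, name="trial"),
            columns=[f"col{k}" for k in range(1, 14)],
        )
        return df


@dataclass(frozen=True)
class FactorLevels:
    """Three numeric levels per factor (strictly increasing).

    Spot sizes and DLG in mm, transmission as a fraction.
    """

    sigma_x: Tuple[float, float, float]
    sigma_y: Tuple[float, float, float]
    dlg: Tuple[float, float, float]
    transmission: Tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in FACTOR_NAMES:
            lv = getattr(self, name)
            if len(lv) != 3:
                raise ValueError(f"{name}: exactly 3 levels required")
            if not (lv[0] < lv[1] < lv[2]):
                raise ValueError(f"{name}: levels must be strictly increasing: {lv}")

    def value(self, factor: str, level: int) -> float:
        if level not in (1, 2, 3):
            raise ValueError(f"level index must be 1, 2 or 3, got {level}")
        return getattr(self, factor)[level - 1]


# Published level sets for the three beam models studied (T converted from %).
MILLENNIUM_LEVELS = FactorLevels(
    sigma_x=(0.7, 1.3, 1.8),
    sigma_y=(0.0, 1.1, 1.4),
    dlg=(0.75, 2.3, 3.0),
    transmission=(0.01, 0.018, 0.02),
)
HD_LEVELS = FactorLevels(
    sigma_x=(0.0, 0.6, 1.2),
    sigma_y=(0.0, 0.6, 1.2),
    dlg=(0.2, 1.5, 2.5),
    transmission=(0.008, 0.012, 0.018),
)
HD_FFF_LEVELS = FactorLevels(
    sigma_x=(0.0, 0.6, 1.2),
    sigma_y=(0.0, 0.6, 1.2),
    dlg=(0.0, 0.8, 1.6),
    transmission=(0.008, 0.012, 0.018),
)


def build_l27(
    factors: Sequence[str] = FACTOR_NAMES,
    interactions: Sequence[Tuple[str, str]] = DEFAULT_INTERACTIONS,
) -> TaguchiDesign:
    """Construct the L27 array and assign factor/interaction/error columns."""
    factors = list(factors)
    if len(set(factors)) != len(factors):
        raise ValueError("duplicate factor names")
    if len(factors) > len(_FACTOR_COLUMN_SLOTS):
        raise ValueError(
            f"at most {len(_FACTOR_COLUMN_SLOTS)} factors fit the L27 linear graph "
            f"({len(factors)} requested: the column budget of 13 is exceeded)"
        )
    factor_columns = {f: _FACTOR_COLUMN_SLOTS[i] for i, f in enumerate(factors)}

    used = set(factor_columns.values())
    interaction_columns: Dict[Tuple[str, str], Tuple[int, int]] = {}
    for pair in interactions:
        fa, fb = pair
        if fa not in factor_columns or fb not in factor_columns:
            raise ValueError(f"interaction {pair} names an unassigned factor")
        cols = _interaction_columns(factor_columns[fa], factor_columns[fb])
        clash = [c for c in cols if c in used]
        if clash:
            raise ValueError(
                f"interaction {pair} needs columns {cols}, already occupied: {clash}"
            )
        interaction_columns[(fa, fb)] = cols
        used.update(cols)

    error_columns = tuple(k for k in range(1, 14) if k not in used)

    runs = np.array(list(product(range(3), repeat=3)))  # (a, b, c), a slowest
    vecs = np.array(_COLUMN_VECTORS)
    array = (runs @ vecs.T) % 3 + 1
    return TaguchiDesign(
        array=array,
        factor_columns=factor_columns,
        interaction_columns=interaction_columns,
        error_columns=error_columns,
    )


def design_to_settings(
    design: TaguchiDesign, levels: FactorLevels
) -> List[BeamModelParams]:
    """Map each trial's level indices to a concrete beam-parameter set."""
    settings = []
    for row in design.array:
        values = {
            factor: levels.value(factor, int(row[col - 1]))
            for factor, col in design.factor_columns.items()
        }
        settings.append(BeamModelParams(**values))
    return settings


CorrectionSpec = Union[float, Mapping[float, float]]


def compute_responses(
    settings: Sequence[BeamModelParams],
    measured_of: Mapping[str, Mapping[float, float]],
    calc_provider,
    corrections: Mapping[str, CorrectionSpec],
) -> pd.DataFrame:
    """Per-trial, per-field-size response in percent.

    ``measured_of[detector][field_size]`` is the uncorrected reading ratio;
    the detector's small-field correction factor (scalar or per field size)
    multiplies it.  ``calc_provider(params, field_size)`` returns the
    calculated output factor.  The response is the mean over detectors of
    (calculated - corrected measured) x 100.
    """
    detectors = sorted(measured_of)
    if not detectors:
        raise ValueError("at least one detector required")
    field_sizes = sorted(measured_of[detectors[0]])
    corrected: Dict[str, Dict[float, float]] = {}
    for det in detectors:
        if sorted(measured_of[det]) != field_sizes:
            raise ValueError("detectors must report the same field sizes")
        corr = corrections.get(det, 1.0)
        corrected[det] = {
            fs: measured_of[det][fs]
            * (corr if isinstance(corr, (int, float)) else corr[fs])
            for fs in field_sizes
        }
    rows = []
    for params in settings:
        row = {}
        for fs in field_sizes:
            calc = calc_provider(params, fs)
            meas = np.mean([corrected[det][fs] for det in detectors])
            row[fs] = 100.0 * (calc - meas)
        rows.append(row)
    return pd.DataFrame(
        rows, index=pd.RangeIndex(1, len(settings) + 1, name="trial")
    )


def _column_level_means(col_levels: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.array([y[col_levels == lv].mean() for lv in (1, 2, 3)])


def _column_ss(col_levels: np.ndarray, y: np.ndarray) -> float:
    grand = y.mean()
    means = _column_level_means(col_levels, y)
    return float(9.0 * np.sum((means - grand) ** 2))


@dataclass
class EffectTable:
    """Level means and amplitudes per source and field size.

    ``level_means[(source, field_size)]`` is a length-3 array for main
    effects and a 3x3 cell-mean matrix for interactions; the amplitude is
    the max-minus-min spread of those means, in percent.
    """

    amplitudes: pd.DataFrame  # index: source, columns: field size
    level_means: Dict[Tuple[str, float], np.ndarray]


@dataclass
class AnovaTable:
    """One ANOVA per field size, sources sorted by increasing p.

    When the error sum of squares vanishes (noise-free synthetic responses)
    no F test exists; the table is flagged degenerate and sorted by source
    sum of squares instead.
    """

    tables: Dict[float, pd.DataFrame]
    alpha: float
    degenerate: Dict[float, bool]

    def significant_sources(self, field_size: float) -> List[str]:
        t = self.tables[field_size]
        return list(t.index[t["significant"]])


def _source_name(key) -> str:
    if isinstance(key, tuple):
        return f"{key[0]}*{key[1]}"
    return key


def effects_and_anova(
    design: TaguchiDesign,
    responses: pd.DataFrame,
    alpha: float = 0.01,
) -> Tuple[EffectTable, AnovaTable]:
    """Taguchi column-sum ANOVA and effect amplitudes, one per field size.

    Main-effect sums of squares are 9 * sum of squared level-mean deviations
    (2 df); an interaction's SS is the sum over its two confounded columns
    (4 df); the error SS pools the unassigned columns.  The decomposition is
    exact: source SS + error SS = total SS.
    """
    if responses.shape[0] != design.n_trials:
        raise ValueError("responses must have one row per trial")
    arr = design.array
    level_means: Dict[Tuple[str, float], np.ndarray] = {}
    amp_rows: Dict[str, Dict[float, float]] = {}
    tables: Dict[float, pd.DataFrame] = {}
    degenerate: Dict[float, bool] = {}

    err_df = 2 * len(design.error_columns)
    for fs in responses.columns:
        y = responses[fs].to_numpy(dtype=float)
        total_ss = float(np.sum((y - y.mean()) ** 2))
        records = []
        for factor, col in design.factor_columns.items():
            lv = arr[:, col - 1]
            ss = _column_ss(lv, y)
            means = _column_level_means(lv, y)
            level_means[(factor, fs)] = means
            amp_rows.setdefault(factor, {})[fs] = float(means.max() - means.min())
            records.append((factor, ss, 2))
        for pair, cols in design.interaction_columns.items():
            ss = sum(_column_ss(arr[:, c - 1], y) for c in cols)
            cell = interaction_surface(design, y, pair)
            name = _source_name(pair)
            level_means[(name, fs)] = cell
            amp_rows.setdefault(name, {})[fs] = float(cell.max() - cell.min())
            records.append((name, ss, 4))
        error_ss = sum(_column_ss(arr[:, c - 1], y) for c in design.error_columns)

        deg = error_ss <= 1e-12 * max(total_ss, 1.0)
        degenerate[fs] = bool(deg)
        ms_err = error_ss / err_df if err_df > 0 else np.nan
        out = []
        for name, ss, df in records:
            if deg or err_df == 0:
                fstat, p = np.nan, np.nan
                sig = False
            else:
                fstat = (ss / df) / ms_err
                p = float(f_dist.sf(fstat, df, err_df))
                sig = p < alpha
            out.append(
                {"source": name, "ss": ss, "df": df, "F": fstat, "p": p,
                 "significant": sig}
            )
        out.append(
            {"source": "error", "ss": error_ss, "df": err_df, "F": np.nan,
             "p": np.nan, "significant": False}
        )
        table = pd.DataFrame(out).set_index("source")
        body = table.drop(index="error")
        body = (
            body.sort_values("p")
            if not deg
            else body.sort_values("ss", ascending=False)
        )
        tables[fs] = pd.concat([body, table.loc[["error"]]])

    amplitudes = pd.DataFrame(amp_rows).T
    amplitudes = amplitudes[sorted(amplitudes.columns)]
    return (
        EffectTable(amplitudes=amplitudes, level_means=level_means),
        AnovaTable(tables=tables, alpha=alpha, degenerate=degenerate),
    )


def interaction_surface(
    design: TaguchiDesign,
    responses: Union[np.ndarray, Sequence[float], pd.Series],
    pair: Tuple[str, str],
) -> np.ndarray:
    """3x3 cell-mean surface of one factor pair (three observations per cell)."""
    y = np.asarray(responses, dtype=float)
    if y.shape != (design.n_trials,):
        raise ValueError("responses must be one value per trial")
    fa, fb = pair
    la = design.array[:, design.factor_columns[fa] - 1]
    lb = design.array[:, design.factor_columns[fb] - 1]
    cell = np.empty((3, 3))
    for i in (1, 2, 3):
        for j in (1, 2, 3):
            sel = (la == i) & (lb == j)
            cell[i - 1, j - 1] = y[sel].mean()
    return cell
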