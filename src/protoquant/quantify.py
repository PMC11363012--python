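"""Absolute in-cell quantification via external calibration and cell geometry.

The chain: peak area → extract concentration (inverse calibration line) →
amount in the 12 μL extract (which is the entire cell content) → in-cell
molar concentration via the sphere volume computed from the imaged
diameter.  Values below the calibration LOQ are censored — reported as a
status flag, never as a number — and treated as zero in population
summaries.

Units: amounts in pmol, calibration levels (extract concentrations) in nM,
extract volumes in μL, cell volumes in pL, in-cell concentrations in mM.
The identity 1 pmol / 1 pL = 1 M keeps the arithmetic transparent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CompoundRecord, FeatureTable
from .library import INTERNAL_STANDARD

__all__ = [
    "FLAG_QUANTIFIED",
    "FLAG_BELOW_LOQ",
    "FLAG_ABOVE_RANGE",
    "FLAG_ABSENT",
    "CalibrationCurve",
    "QuantMatrix",
    "fit_calibration",
    "fit_calibration_table",
    "normalize_internal_standard",
    "cell_volume_from_diameter",
    "area_to_cell_amount",
    "cell_concentration",
    "quantify_cells",
    "max_base_solubility",
    "flag_above_solubility",
]

logger = logging.getLogger(__name__)

FLAG_QUANTIFIED = "quantified"
FLAG_BELOW_LOQ = "below_loq"
FLAG_ABOVE_RANGE = "above_range"
FLAG_ABSENT = "absent"

#: nM extract concentration × μL extract volume -> pmol
_NM_UL_TO_PMOL = 1e-3

#: relative tolerance used when comparing an amount against range edges, so
#: that a value sitting exactly on the LOQ is "quantified"
_EDGE_RTOL = 1e-9

BACK_CALC_TOLERANCE = 0.20  # 20% accuracy filter on back-calculated levels


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted external calibration line for one compound.

    ``slope`` and ``intercept`` map extract concentration (nM) to peak
    area; ``linear_range`` and ``loq`` are in level units (nM) and are
    converted to amounts with the extract volume at quantification time.
    """

    compound: str
    slope: float  # area per nM
    intercept: float  # area
    weighting: str  # none | 1/x | 1/x^2
    linear_range: tuple[float, float]  # nM, retained levels
    loq: float  # nM, lowest retained level
    r_squared: float
    levels_retained: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.compound}: slope must be positive")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"{self.compound}: empty linear range")
        if self.loq > hi:
            raise ValueError(f"{self.compound}: LOQ above linear range")


_WEIGHTS = {
    "none": lambda x: np.ones_like(x),
    "1/x": lambda x: 1.0 / x,
    "1/x^2": lambda x: 1.0 / x**2,
    "1/x²": lambda x: 1.0 / x**2,
}


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares slope/intercept minimizing Σ w (y - a x - b)²."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("calibration failed: degenerate level design")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(slope), float(ym - slope * xm)


def fit_calibration(
    levels: Sequence[float],
    areas: Sequence[float],
    weighting: str = "1/x^2",
    compound: str = "",
) -> CalibrationCurve:
    """Fit a weighted calibration line with a back-calculation accuracy filter.

    Levels failing the filter (mean back-calculated concentration deviating
    more than 20% from nominal, averaged over replicate injections when the
    level appears more than once) are dropped and the line refitted until
    stable.
    The linear range is the span of retained levels and the LOQ is the
    lowest retained level.  Fewer than three retained levels is a failed
    calibration.

    Parameters
    ----------
    levels : nominal extract concentrations, nM, ascending.
    areas : measured peak areas, one per level, >= 0.
    weighting : ``none``, ``1/x`` or ``1/x^2`` (default; with levels
        spanning six decades, equal-relative weighting is the only choice
        that keeps back-calculation accurate at the low end).
    """
    x_all = np.asarray(levels, dtype=float)
    y_all = np.asarray(areas, dtype=float)
    if x_all.shape != y_all.shape or x_all.ndim != 1:
        raise ValueError("levels and areas must be 1-D and of equal length")
    if len(x_all) < 3:
        raise ValueError("calibration failed: need at least 3 levels")
    if (x_all <= 0).any():
        raise ValueError("calibration levels must be positive")
    if (y_all < 0).any():
        raise ValueError("calibration areas must be nonnegative")
    if weighting not in _WEIGHTS:
        raise ValueError(f"unknown weighting {weighting!r}")

    unique_levels = np.unique(x_all)
    level_kept = {lvl: True for lvl in unique_levels}
    for _ in range(len(unique_levels)):
        keep = np.array([level_kept[v] for v in x_all])
        x, y = x_all[keep], y_all[keep]
        if len(np.unique(x)) < 3:
            raise ValueError(
                f"calibration failed for {compound or 'compound'}: "
                f"fewer than 3 levels pass the back-calculation filter"
            )
        w = _WEIGHTS[weighting](x)
        slope, intercept = _wls_line(x, y, w)
        if slope <= 0:
            raise ValueError(
                f"calibration failed for {compound or 'compound'}: nonpositive slope"
            )
        # accuracy filter on the mean back-calculated level (replicate-aware);
        # drop only the worst offender per pass — a single aberrant level
        # (e.g. detector saturation) skews the fit and would otherwise take
        # accurate levels down with it
        back = (y_all - intercept) / slope
        worst_level, worst_dev = None, BACK_CALC_TOLERANCE * (1 + 1e-12)
        for lvl in unique_levels:
            if not level_kept[lvl]:
                continue
            rel_dev = abs(back[x_all == lvl].mean() - lvl) / lvl
            if rel_dev > worst_dev:
                worst_level, worst_dev = lvl, rel_dev
        if worst_level is None:
            break
        level_kept[worst_level] = False

    keep = np.array([level_kept[v] for v in x_all])
    x, y = x_all[keep], y_all[keep]
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        compound=compound,
        slope=slope,
        intercept=intercept,
        weighting=weighting,
        linear_range=(float(x.min()), float(x.max())),
        loq=float(x.min()),
        r_squared=r2,
        levels_retained=tuple(float(v) for v in x),
    )


def fit_calibration_table(
    long_table: pd.DataFrame, weighting: str = "1/x^2"
) -> dict[str, CalibrationCurve]:
    """Fit one curve per compound from a long (compound, level, area) frame."""
    needed = {"compound", "level", "area"}
    if not needed <= set(long_table.columns):
        raise ValueError(f"calibration table needs columns {sorted(needed)}")
    curves = {}
    for compound, group in long_table.groupby("compound", sort=True):
        group = group.sort_values("level")
        curves[str(compound)] = fit_calibration(
            group["level"].to_numpy(), group["area"].to_numpy(), weighting, str(compound)
        )
    return curves


def normalize_internal_standard(
    table: FeatureTable, is_feature_id: str
) -> tuple[FeatureTable, list[str]]:
    """Scale each sample so its internal-standard area equals the median.

    Returns the corrected table and the list of samples excluded because
    their IS area was zero or missing (these are flagged and dropped with a
    logged warning rather than silently rescaled by infinity).
    """
    if is_feature_id not in list(table.areas.index):
        raise ValueError(f"internal-standard feature {is_feature_id!r} not in table")
    is_areas = table.areas.loc[is_feature_id]
    good = is_areas > 0
    excluded = [s for s, ok in good.items() if not ok]
    if excluded:
        logger.warning(
            "excluding %d sample(s) with zero/missing internal standard: %s",
            len(excluded), excluded,
        )
    kept = table.areas.loc[:, good]
    median = float(is_areas[good].median()) if good.any() else float("nan")
    scale = median / kept.loc[is_feature_id]
    corrected = kept.mul(scale, axis=1)
    return FeatureTable(table.features.copy(), corrected), excluded


def cell_volume_from_diameter(diameter: float) -> float:
    """Sphere volume from an imaged protoplast diameter: (π/6) d³, in pL."""
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return math.pi / 6.0 * diameter**3 / 1000.0  # μm³ -> pL


def area_to_cell_amount(
    area: float,
    curve: CalibrationCurve,
    extract_volume: float = 12.0,
) -> tuple[float, str]:
    """Invert the calibration line and scale to the whole-extract amount.

    The QC aliquot taken before injection removes volume, not
    concentration, so the intensive extract concentration — and hence the
    back-computed cell amount — is unaffected by it.

    Returns (amount in pmol, flag).  Below-LOQ amounts return NaN with the
    ``below_loq`` flag; amounts above the validated linear range keep their
    numeric value but are flagged ``above_range``.
    """
    if extract_volume <= 0:
        raise ValueError("extract volume must be positive")
    loq_amount = curve.loq * _NM_UL_TO_PMOL * extract_volume
    high_amount = curve.linear_range[1] * _NM_UL_TO_PMOL * extract_volume
    if area <= curve.intercept:
        return (float("nan"), FLAG_BELOW_LOQ)
    amount = (area - curve.intercept) / curve.slope * _NM_UL_TO_PMOL * extract_volume
    if amount < loq_amount * (1 - _EDGE_RTOL):
        return (float("nan"), FLAG_BELOW_LOQ)
    if amount > high_amount * (1 + _EDGE_RTOL):
        return (amount, FLAG_ABOVE_RANGE)
    return (amount, FLAG_QUANTIFIED)


def cell_concentration(amount: float, volume: float) -> float:
    """In-cell concentration in mM from amount (pmol) and cell volume (pL)."""
    if volume <= 0:
        raise ValueError("cell volume must be positive")
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    return amount / volume * 1000.0  # pmol/pL = M -> mM


@dataclass
class QuantMatrix:
    """Cells × compounds in-cell concentrations (mM) with status flags.

    ``concentrations`` holds NaN wherever the flag is ``below_loq`` or
    ``absent``; ``above_range`` entries keep their (extrapolated) value.
    """

    concentrations: pd.DataFrame  # index: cell_id, columns: compounds
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.concentrations.index.equals(self.flags.index) or not (
            self.concentrations.columns.equals(self.flags.columns)
        ):
            raise ValueError("concentration and flag frames must be aligned")
        censored = self.flags.isin([FLAG_BELOW_LOQ, FLAG_ABSENT])
        if self.concentrations.to_numpy()[censored.to_numpy()].size and not np.isnan(
            self.concentrations.to_numpy()[censored.to_numpy()]
        ).all():
            raise ValueError("censored entries must carry no numeric concentration")
        quantified = self.flags == FLAG_QUANTIFIED
        values = self.concentrations.to_numpy()[quantified.to_numpy()]
        if values.size and not (values > 0).all():
            raise ValueError("quantified entries must be positive")

    @property
    def cells(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.concentrations.columns)

    def values_filled(self, fill: float = 0.0) -> pd.DataFrame:
        """Concentrations with censored entries replaced by ``fill``."""
        return self.concentrations.fillna(fill)

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.concentrations.index)
        for compound in self.compounds:
            out[compound] = self.concentrations[compound]
            out[f"{compound}__flag"] = self.flags[compound]
        out.index.name = "cell_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "QuantMatrix":
        frame = pd.read_csv(path, index_col="cell_id")
        compounds = [c for c in frame.columns if not c.endswith("__flag")]
        conc = frame[compounds].astype(float)
        flags = frame[[f"{c}__flag" for c in compounds]].copy()
        flags.columns = compounds
        return cls(conc, flags)


def quantify_cells(
    table: FeatureTable,
    metadata: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    assignments: Mapping[str, str],
    library: Sequence[CompoundRecord] | None = None,
    extract_volume: float = 12.0,
    normalize_is: bool = True,
    is_feature_id: str | None = None,
) -> QuantMatrix:
    """Full area → in-cell concentration pipeline for a single-cell table.

    ``assignments`` maps feature_id -> compound name (from
    :func:`protoquant.formula.match_known_compounds`).  Every assigned
    quantifiable compound must have a calibration curve.  A compound with
    no detected feature — or zero area in a given cell — is ``absent``.
    """
    by_name = {c.name: c for c in library} if library is not None else {}

    if is_feature_id is None:
        for fid, name in assignments.items():
            if name == INTERNAL_STANDARD:
                is_feature_id = fid
                break
    excluded: list[str] = []
    if normalize_is and is_feature_id is not None:
        table, excluded = normalize_internal_standard(table, is_feature_id)

    compound_features: dict[str, str] = {}
    for fid, name in assignments.items():
        if name == INTERNAL_STANDARD:
            continue
        if by_name and name in by_name and not by_name[name].quantifiable:
            continue
        if name not in curves:
            raise ValueError(f"missing calibration curve for compound {name!r}")
        compound_features[name] = fid
    compounds = sorted(compound_features)

    meta = metadata.set_index("cell_id")
    cells = [c for c in meta.index if c in table.samples and c not in excluded]
    conc = pd.DataFrame(np.nan, index=cells, columns=compounds, dtype=float)
    flags = pd.DataFrame(FLAG_ABSENT, index=cells, columns=compounds)
    for cell in cells:
        diameter = float(meta.loc[cell, "diameter"])
        volume = cell_volume_from_diameter(diameter)
        for compound in compounds:
            area = float(table.areas.loc[compound_features[compound], cell])
            if area <= 0:
                continue  # stays absent: no detected signal
            amount, flag = area_to_cell_amount(area, curves[compound], extract_volume)
            flags.loc[cell, compound] = flag
            if flag in (FLAG_QUANTIFIED, FLAG_ABOVE_RANGE):
                conc.loc[cell, compound] = cell_concentration(amount, volume)
    conc.index.name = "cell_id"
    flags.index.name = "cell_id"
    return QuantMatrix(conc, flags)


def max_base_solubility(intrinsic_solubility: float, pka: float, ph: float) -> float:
    """Henderson–Hasselbalch solubility cap for a monoprotic base.

    Total solubility S = S0 · (1 + 10^(pKa − pH)): at vacuolar pH well
    below the pKa almost all of the base is protonated and soluble, but
    the cap is finite — quantified in-cell concentrations above it imply
    storage beyond simple aqueous solution.
    """
    if intrinsic_solubility < 0:
        raise ValueError("intrinsic solubility must be nonnegative")
    return intrinsic_solubility * (1.0 + 10.0 ** (pka - ph))


def flag_above_solubility(
    quant: QuantMatrix, solubility_m: Mapping[str, float]
) -> pd.DataFrame:
    """Boolean mask of quantified entries exceeding a compound's solubility (M)."""
    mask = pd.DataFrame(False, index=quant.cells, columns=quant.compounds)
    for compound, cap_m in solubility_m.items():
        if compound not in mask.columns:
            continue
        values = quant.concentrations[compound]
        mask[compound] = (quant.flags[compound] == FLAG_QUANTIFIED) & (
            values > cap_m * 1000.0
        )
    return mask
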