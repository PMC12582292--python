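"""Targeted absolute quantification from split single-cell lysates.

Per analyte, an external calibration curve (ordinary least squares of mean
replicate peak area on nominal standard concentration) converts a peak area to
a concentration in the analysis solution. The limit of quantification is the
lowest calibration standard whose back-calculated accuracy is within a
tolerance (default ±20 %) and whose replicate CV is at or below a tolerance
(default 20 %) — the common bioanalytical acceptance rule.

Because the lysate of each picked protoplast is split in half (one half for
MS, one for RNA-seq), the measured amount is doubled to obtain the whole-cell
amount, which is then divided by the cell volume estimated from the measured
diameter under a spherical assumption, V = (π/6)·d³ (µm³ ≡ fL).

Unit chain: analysis concentration (µM) x aliquot volume (µL) gives pmol;
x1000 gives fmol; fmol / (pL x 1e-3) = fmol/nL = µM intracellular.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import (
    MetaboliteMatrix,
    ValidationError,
    WellRecord,
    WellStatus,
    log,
)


@dataclass
class CalibrationStandardSeries:
    """Dilution ladder of one analyte: nominal analysis-solution
    concentrations (µM) with replicate peak areas (triplicate expected)."""

    analyte: str
    points: list[tuple[float, list[float]]]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if len(set(concs)) < 2:
            raise ValidationError(f"{self.analyte}: need >= 2 distinct standard concentrations")
        for c, areas in self.points:
            if len(areas) < 1:
                raise ValidationError(f"{self.analyte}: standard at {c} µM has no replicates")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> dict[str, "CalibrationStandardSeries"]:
        """Build one series per analyte from a long standards table with
        columns analyte, nominal_conc_uM, area (replicate column optional)."""
        out = {}
        for analyte, sub in df.groupby("analyte", sort=False):
            points = [
                (float(c), list(map(float, grp["area"])))
                for c, grp in sub.groupby("nominal_conc_uM", sort=True)
            ]
            out[str(analyte)] = cls(analyte=str(analyte), points=points)
        return out


@dataclass
class CalibrationCurve:
    """Per-analyte linear response: area = slope * conc + intercept."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    loq_uM: float = math.nan
    range_uM: tuple[float, float] = (math.nan, math.nan)

    @property
    def usable(self) -> bool:
        return self.slope > 0


@dataclass
class QuantResult:
    analyte: str
    well_id: str
    area: float
    analysis_conc_uM: float
    amount_fmol: float
    cell_volume_pL: float
    conc_uM: float
    below_loq: bool


def fit_calibration(series: CalibrationStandardSeries) -> CalibrationCurve:
    """Ordinary least squares of mean replicate area on nominal concentration.

    A negative fitted slope yields a curve flagged unusable (with a warning);
    identical concentrations raise before this point (series invariant).
    """
    concs = np.array([c for c, _ in series.points], dtype=float)
    mean_areas = np.array([float(np.mean(a)) for _, a in series.points])
    res = scipy.stats.linregress(concs, mean_areas)
    curve = CalibrationCurve(
        analyte=series.analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        range_uM=(float(concs.min()), float(concs.max())),
    )
    if curve.slope <= 0:
        warnings.warn(f"{series.analyte}: non-positive calibration slope; curve unusable")
    return curve


def determine_loq(
    series: CalibrationStandardSeries,
    curve: CalibrationCurve,
    accuracy_tol: float = 0.2,
    cv_tol: float = 0.2,
) -> float:
    """Lowest standard with back-calculated accuracy within ±accuracy_tol and
    replicate CV <= cv_tol; +inf when no standard qualifies."""
    if not curve.usable:
        return math.inf
    for conc, areas in sorted(series.points):
        back = (np.asarray(areas, dtype=float) - curve.intercept) / curve.slope
        mean_back = float(np.mean(back))
        accuracy_ok = abs(mean_back - conc) <= accuracy_tol * conc
        mean_area = float(np.mean(areas))
        cv = float(np.std(areas, ddof=1) / mean_area) if len(areas) > 1 and mean_area > 0 else 0.0
        if accuracy_ok and cv <= cv_tol:
            return float(conc)
    return math.inf


def fit_all_calibrations(
    standards: pd.DataFrame,
    accuracy_tol: float = 0.2,
    cv_tol: float = 0.2,
) -> dict[str, CalibrationCurve]:
    """Fit curve + LOQ for every analyte in a long standards table."""
    curves = {}
    for name, series in CalibrationStandardSeries.from_frame(standards).items():
        curve = fit_calibration(series)
        curve.loq_uM = determine_loq(series, curve, accuracy_tol, cv_tol)
        curves[name] = curve
    log.info("fitted %d calibration curves", len(curves))
    return curves


def calibration_table(curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte": list(curves),
            "slope": [c.slope for c in curves.values()],
            "intercept": [c.intercept for c in curves.values()],
            "r2": [c.r2 for c in curves.values()],
            "loq_uM": [c.loq_uM for c in curves.values()],
            "range_low_uM": [c.range_uM[0] for c in curves.values()],
            "range_high_uM": [c.range_uM[1] for c in curves.values()],
        }
    ).set_index("analyte")


def cell_volume_pL(diameter_um: float) -> float:
    """Spherical protoplast volume from diameter; µm³ = fL, /1000 = pL."""
    return math.pi / 6.0 * diameter_um**3 * 1e-3


def quantify_cell(
    area: float,
    curve: CalibrationCurve,
    well: WellRecord,
    aliquot_volume_uL: float = 4.0,
    split_factor: float = 2.0,
) -> QuantResult:
    """Convert one peak area to an intracellular concentration for a single
    picked cell. Negative analysis concentrations (area below the intercept)
    are clamped to 0 and flagged below LOQ; concentrations below the
    analyte's LOQ are censored to 0."""
    if well.status is not WellStatus.SINGLE:
        raise ValidationError(f"well {well.well_id} is {well.status.value}; quantification needs a single cell")
    if well.diameter_um is None:
        raise ValidationError(f"well {well.well_id} lacks a diameter")
    if not curve.usable:
        raise ValidationError(f"{curve.analyte}: calibration curve is unusable (slope <= 0)")
    analysis_conc = (area - curve.intercept) / curve.slope
    analysis_conc = max(analysis_conc, 0.0)
    v_pL = cell_volume_pL(well.diameter_um)
    below = analysis_conc < curve.loq_uM
    if below:
        amount_fmol = 0.0
        conc = 0.0
    else:
        amount_fmol = split_factor * analysis_conc * aliquot_volume_uL * 1e3
        conc = amount_fmol / (v_pL * 1e-3)  # fmol / nL = µM
    return QuantResult(
        analyte=curve.analyte,
        well_id=well.well_id,
        area=float(area),
        analysis_conc_uM=float(analysis_conc),
        amount_fmol=float(amount_fmol),
        cell_volume_pL=float(v_pL),
        conc_uM=float(conc),
        below_loq=bool(below),
    )


def quantify_plate(
    peak_areas: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    wells: list[WellRecord],
    aliquot_volume_uL: float = 4.0,
    split_factor: float = 2.0,
) -> list[QuantResult]:
    """Quantify every (analyte, single well) pair of a peak-area table."""
    by_id = {w.well_id: w for w in wells}
    results = []
    for well_id in peak_areas.columns:
        well = by_id.get(str(well_id))
        if well is None:
            raise ValidationError(f"peak-area column {well_id} has no well record")
        if well.status is not WellStatus.SINGLE:
            continue
        for analyte in peak_areas.index:
            results.append(
                quantify_cell(
                    float(peak_areas.at[analyte, well_id]),
                    curves[str(analyte)],
                    well,
                    aliquot_volume_uL=aliquot_volume_uL,
                    split_factor=split_factor,
                )
            )
    log.info("quantified %d (analyte, cell) pairs", len(results))
    return results


def assemble_metabolite_matrix(
    results: list[QuantResult], wells: list[WellRecord]
) -> MetaboliteMatrix:
    """Arrange quantification results into an analyte x single-cell matrix."""
    by_id = {w.well_id: w for w in wells}
    singles = [w.well_id for w in wells if w.status is WellStatus.SINGLE]
    analytes: list[str] = []
    for r in results:
        if r.analyte not in analytes:
            analytes.append(r.analyte)
        if r.well_id not in by_id:
            raise ValidationError(f"result references unknown well {r.well_id}")
    conc = np.zeros((len(analytes), len(singles)))
    mask = np.ones_like(conc, dtype=bool)
    seen = set()
    a_idx = {a: i for i, a in enumerate(analytes)}
    c_idx = {c: j for j, c in enumerate(singles)}
    for r in results:
        key = (r.analyte, r.well_id)
        if key in seen:
            raise ValidationError(f"duplicate quantification for {key}")
        seen.add(key)
        i, j = a_idx[r.analyte], c_idx[r.well_id]
        conc[i, j] = r.conc_uM
        mask[i, j] = r.below_loq
    return MetaboliteMatrix(
        analytes=analytes,
        cells=singles,
        conc_uM=conc,
        below_loq=mask,
        batch_of_cell=[by_id[c].batch for c in singles],
    )


def background_report(
    peak_areas: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    wells: list[WellRecord],
) -> pd.DataFrame:
    """Empty-well background: per analyte, how many empty wells show signal
    above the LOQ equivalent, and the median back-calculated analysis
    concentration among the detected ones."""
    empty_ids = [w.well_id for w in wells if w.status is WellStatus.EMPTY]
    if not empty_ids:
        warnings.warn("no empty wells present; background report is empty")
        return pd.DataFrame(columns=["n_empty", "n_detected", "median_analysis_conc_uM"])
    rows = {}
    present = [c for c in empty_ids if c in peak_areas.columns]
    for analyte in peak_areas.index:
        curve = curves[str(analyte)]
        areas = peak_areas.loc[analyte, present].to_numpy(dtype=float)
        back = np.clip((areas - curve.intercept) / curve.slope, 0.0, None) if curve.usable else np.zeros_like(areas)
        detected = back >= curve.loq_uM
        rows[str(analyte)] = {
            "n_empty": len(present),
            "n_detected": int(detected.sum()),
            "median_analysis_conc_uM": float(np.median(back[detected])) if detected.any() else np.nan,
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "analyte"
    return report
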