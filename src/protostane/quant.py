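"""MRM internal-standard quantification.

The triple-quadrupole assay quantifies 14 triterpenoids against a
glycyrrhetinic-acid internal standard (IS).  For each analyte the response
is the ratio of the analyte peak area to the IS area in the same injection;
calibration is an unweighted straight line Y = aX + b of that ratio against
the analyte concentration X (μg/mL) in the injected (post IS-mix) solution.
Back-calculated concentrations convert to dry-matrix content (mg/g) through
the preparation constants: 0.20 g powder extracted into 25 mL, then diluted
1:1 with the IS working solution, so 1 μg/mL injected corresponds to
0.25 mg/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRMTransition",
    "CalibrationCurve",
    "AreaMeasurement",
    "PrepConstants",
    "DilutionSeries",
    "ContentMatrix",
    "ND",
    "fit_calibration",
    "invert_calibration",
    "content_mg_per_g",
    "estimate_lod_loq",
    "quantify_batch",
]

ND = "ND"  # sentinel for contents below the limit of detection


@dataclass(frozen=True)
class MRMTransition:
    """One precursor → product transition monitored on the QqQ."""

    analyte: str
    precursor_mz: float
    product_mz: float
    cone_voltage: float
    collision_energy: float
    is_internal_standard: bool = False


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear area-ratio response Y = slope·X + intercept for one analyte.

    X is μg/mL in the injected solution; ``linear_range`` bounds the
    validated interval.
    """

    analyte: str
    slope: float
    intercept: float
    r: float | None = None
    linear_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if self.linear_range is not None and not self.linear_range[0] < self.linear_range[1]:
            raise ValueError("linear range must satisfy low < high")


@dataclass(frozen=True)
class AreaMeasurement:
    """Analyte and IS peak areas from one injection."""

    sample_id: str
    analyte: str
    peak_area: float
    is_area: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise ValueError("peak area must be non-negative")
        if self.is_area <= 0:  # NaN (missing IS) passes; handled downstream
            raise ValueError("IS area must be positive")


@dataclass(frozen=True)
class PrepConstants:
    """Sample-preparation constants for the content conversion.

    sample_mass 0.20 g of powder, extraction_volume 25 mL of acetonitrile,
    and a 1:1 dilution of extract with IS working solution
    (``is_mix_dilution`` = 2).
    """

    sample_mass_g: float = 0.20
    extraction_volume_ml: float = 25.0
    is_mix_dilution: float = 2.0

    def __post_init__(self) -> None:
        if min(self.sample_mass_g, self.extraction_volume_ml, self.is_mix_dilution) <= 0:
            raise ValueError("preparation constants must be strictly positive")


def fit_calibration(points: list[tuple[float, float]], analyte: str = "") -> CalibrationCurve:
    """Unweighted ordinary least squares of area ratio against concentration.

    ``r`` is the Pearson correlation of (X, Y).  At least three distinct
    concentrations are required; an all-constant X or Y is a degenerate
    design.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("calibration needs >= 3 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate design: responses are constant, r undefined")
    res = stats.linregress(x, y)
    lo, hi = float(x.min()), float(x.max())
    return CalibrationCurve(
        analyte, float(res.slope), float(res.intercept), float(res.rvalue), (lo, hi)
    )


def invert_calibration(curve: CalibrationCurve, y: float) -> tuple[float, str]:
    """Back-calculate concentration X = (y − b)/a and flag it against range.

    Returns ``(concentration, flag)`` with flag one of ``below-range``,
    ``in-range``, ``above-range`` (``in-range`` when the curve carries no
    validated range).
    """
    x = (y - curve.intercept) / curve.slope
    flag = "in-range"
    if curve.linear_range is not None:
        lo, hi = curve.linear_range
        if x < lo:
            flag = "below-range"
        elif x > hi:
            flag = "above-range"
    return x, flag


def content_mg_per_g(x_ug_per_ml: float, prep: PrepConstants = PrepConstants()) -> float:
    """Convert injected concentration (μg/mL) to dry-matrix content (mg/g)."""
    if x_ug_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return (
        x_ug_per_ml
        * prep.is_mix_dilution
        * prep.extraction_volume_ml
        / (prep.sample_mass_g * 1000.0)
    )


@dataclass(frozen=True)
class DilutionSeries:
    """(concentration, signal, noise) triples at strictly decreasing levels."""

    analyte: str
    points: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        concs = [p[0] for p in self.points]
        if any(b >= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        if any(p[2] <= 0 for p in self.points):
            raise ValueError("noise must be positive")


def estimate_lod_loq(series: DilutionSeries) -> tuple[float, float]:
    """LOD and LOQ as the concentrations where S/N crosses 3 and 10.

    The crossing is located by log-linear interpolation of log(S/N) against
    log(concentration) between the bracketing dilution steps; the series
    must span both thresholds.
    """
    conc = np.array([p[0] for p in series.points])
    sn = np.array([p[1] / p[2] for p in series.points])
    lod = _crossing(conc, sn, 3.0)
    loq = _crossing(conc, sn, 10.0)
    return lod, loq


def _crossing(conc: np.ndarray, sn: np.ndarray, threshold: float) -> float:
    for i in range(len(conc) - 1):
        hi_sn, lo_sn = sn[i], sn[i + 1]
        if hi_sn >= threshold >= lo_sn:
            if hi_sn == lo_sn:
                return float(conc[i + 1])
            t = (math.log(threshold) - math.log(lo_sn)) / (math.log(hi_sn) - math.log(lo_sn))
            return float(
                math.exp(math.log(conc[i + 1]) + t * (math.log(conc[i]) - math.log(conc[i + 1])))
            )
    raise ValueError(
        f"series does not bracket S/N = {threshold}; extend the dilution ladder"
    )


@dataclass
class ContentMatrix:
    """Samples × analytes content table (mg/g) with an ND mask.

    ``values`` holds NaN where the content is below the LOD; ``nd_mask`` is
    True there.  ``origins`` labels each sample with its geographic source.
    """

    values: pd.DataFrame
    nd_mask: pd.DataFrame
    origins: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.nd_mask.index) or not self.values.columns.equals(
            self.nd_mask.columns
        ):
            raise ValueError("values and nd_mask must share index and columns")
        if not self.values.index.equals(self.origins.index):
            raise ValueError("origins must be indexed by sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def to_frame(self) -> pd.DataFrame:
        """Wide table with the literal ``"ND"`` sentinel, origin first."""
        out = self.values.copy().astype(object)
        out[self.nd_mask] = ND
        out.insert(0, "origin", self.origins)
        return out

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ContentMatrix":
        origins = df["origin"].astype(str)
        body = df.drop(columns=["origin"])
        nd_mask = body.astype(str).eq(ND)
        values = body.mask(nd_mask).apply(pd.to_numeric)
        return ContentMatrix(values, nd_mask, origins)


def quantify_batch(
    areas: list[AreaMeasurement],
    curves: dict[str, CalibrationCurve],
    prep: PrepConstants = PrepConstants(),
    lods_ng_per_ml: dict[str, float] | None = None,
    origins: dict[str, str] | None = None,
) -> tuple[ContentMatrix, pd.DataFrame]:
    """Back-calculate a ContentMatrix from replicate MRM area measurements.

    Replicate injections of a sample/analyte pair are averaged on the
    back-calculated concentration scale; a mean concentration below the
    analyte's LOD is recorded as ND.  Returns the matrix plus a long-format
    diagnostics table (mean concentration, range flag, replicate RSD).

    Output is invariant to the order of ``areas``.
    """
    by_cell: dict[tuple[str, str], list[float]] = {}
    samples: list[str] = []
    analytes: list[str] = []
    skipped = []
    for m in sorted(areas, key=lambda m: (m.sample_id, m.analyte, m.replicate)):
        if m.analyte not in curves:
            raise KeyError(f"no calibration curve for analyte {m.analyte!r}")
        if math.isnan(m.is_area):
            skipped.append(
                {
                    "sample_id": m.sample_id,
                    "analyte": m.analyte,
                    "mean_conc_ug_ml": np.nan,
                    "range_flag": "missing-IS",
                    "replicate_rsd_pct": np.nan,
                    "n_replicates": 0,
                    "nd": False,
                }
            )
            continue
        x, _ = invert_calibration(curves[m.analyte], m.peak_area / m.is_area)
        by_cell.setdefault((m.sample_id, m.analyte), []).append(x)
        if m.sample_id not in samples:
            samples.append(m.sample_id)
        if m.analyte not in analytes:
            analytes.append(m.analyte)
    values = pd.DataFrame(np.nan, index=samples, columns=analytes)
    nd_mask = pd.DataFrame(False, index=samples, columns=analytes)
    diag_rows = []
    for (sid, analyte), concs in by_cell.items():
        mean_x = float(np.mean(concs))
        rsd = (
            float(np.std(concs, ddof=1) / mean_x * 100.0)
            if len(concs) > 1 and mean_x != 0
            else np.nan
        )
        _, flag = invert_calibration(
            curves[analyte],
            curves[analyte].slope * mean_x + curves[analyte].intercept,
        )
        lod = (lods_ng_per_ml or {}).get(analyte)
        is_nd = lod is not None and mean_x * 1000.0 < lod  # μg/mL → ng/mL
        if is_nd:
            nd_mask.loc[sid, analyte] = True
        else:
            values.loc[sid, analyte] = content_mg_per_g(max(mean_x, 0.0), prep)
        diag_rows.append(
            {
                "sample_id": sid,
                "analyte": analyte,
                "mean_conc_ug_ml": mean_x,
                "range_flag": flag,
                "replicate_rsd_pct": rsd,
                "n_replicates": len(concs),
                "nd": is_nd,
            }
        )
    origin_series = pd.Series(
        [(origins or {}).get(s, "unknown") for s in samples], index=samples, name="origin"
    )
    diagnostics = pd.DataFrame(diag_rows + skipped)
    return ContentMatrix(values, nd_mask, origin_series), diagnostics
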