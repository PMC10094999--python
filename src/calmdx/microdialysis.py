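"""Serotonin quantification from HPLC-ECD detector responses.

A calibration line (response = slope * concentration + intercept) is fitted by
ordinary least squares on the standard injections — 0.50, 1.0 and 10.0 pg/uL
serotonin by default — and dialysate responses are inverted through it.
Concentrations are physical, so responses below the intercept clip to zero
with a below-LOD flag.  Dialysate is collected on a 15-min grid at 1 uL/min
(10 uL injected per sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from calmdx.errors import AssayError, ValidationError
from calmdx.io_formats import DialysisSample
from calmdx.trace_analysis import BinnedSeries

#: standard serotonin concentrations (pg/uL) injected for calibration
STANDARD_CONCENTRATIONS_PG_UL = (0.50, 1.0, 10.0)

FLOW_RATE_UL_MIN = 1.0
INJECTION_VOLUME_UL = 10.0
WINDOW_MIN = 15.0


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    standards: list  # (concentration pg/uL, response)
    r_squared: float


@dataclass
class DialysisSeries:
    """Quantified serotonin samples plus assay provenance."""

    samples: list
    curve: CalibrationCurve | None = None
    flow_rate_ul_min: float = FLOW_RATE_UL_MIN
    injection_volume_ul: float = INJECTION_VOLUME_UL


def fit_calibration(standards, force_origin: bool = False) -> CalibrationCurve:
    """OLS calibration line from (concentration, response) pairs.

    With force_origin the intercept is pinned at zero (slope = <xy>/<x^2>).
    """
    standards = [(float(c), float(r)) for c, r in standards]
    conc = np.array([c for c, _ in standards])
    resp = np.array([r for _, r in standards])
    if conc.size < 2 or np.unique(conc).size < 2:
        raise AssayError("calibration needs >= 2 distinct standard concentrations")
    if force_origin:
        slope = float(conc @ resp / (conc @ conc))
        intercept = 0.0
        fitted = slope * conc
    else:
        res = sps.linregress(conc, resp)
        slope, intercept = float(res.slope), float(res.intercept)
        fitted = slope * conc + intercept
    ss_res = float(((resp - fitted) ** 2).sum())
    ss_tot = float(((resp - resp.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(slope=slope, intercept=intercept, standards=standards,
                            r_squared=r2)


def quantify(response, curve: CalibrationCurve):
    """Invert the calibration line: concentration = (response - intercept)/slope.

    Returns (concentration, below_lod).  Negative inversions clip to 0 pg/uL
    with below_lod True.  Array input returns arrays.
    """
    if curve.slope <= 0:
        raise AssayError(f"non-positive calibration slope {curve.slope}")
    response = np.asarray(response, dtype=float)
    conc = (response - curve.intercept) / curve.slope
    below = conc < 0
    conc = np.where(below, 0.0, conc)
    if conc.ndim == 0:
        return float(conc), bool(below)
    return conc, below


def quantify_series(samples: list, curve: CalibrationCurve | None = None) -> DialysisSeries:
    """Quantify every response-bearing sample in place of its response.

    Samples already carrying a concentration pass through unchanged; a curve
    is only required when at least one sample still holds a raw response.
    """
    out = []
    for s in samples:
        if s.concentration is not None:
            out.append(s)
            continue
        if curve is None:
            raise ValidationError("response-bearing samples need a calibration curve")
        conc, below = quantify(s.response, curve)
        out.append(DialysisSample(s.window_start_min, s.window_end_min,
                                  concentration=conc, below_lod=below))
    return DialysisSeries(samples=out, curve=curve)


def align_to_bins(series, bin_width_min: float = WINDOW_MIN) -> tuple[BinnedSeries, int | None]:
    """Place quantified samples on the [k*15, (k+1)*15) min grid.

    Sample windows must coincide with grid bins.  Returns the serotonin
    BinnedSeries and the index of the pre-stimulation baseline bin
    ([-15, 0) min), or None if absent.
    """
    samples = series.samples if isinstance(series, DialysisSeries) else list(series)
    if not samples:
        return BinnedSeries(bin_edges_min=np.array([0.0, bin_width_min]),
                            values=np.array([np.nan]), kind="serotonin"), None
    for s in samples:
        k = s.window_start_min / bin_width_min
        if not (np.isclose(k, round(k), atol=1e-6)
                and np.isclose(s.width_min, bin_width_min, atol=1e-6)):
            raise ValidationError(
                f"sample window [{s.window_start_min}, {s.window_end_min}) min "
                f"not aligned to the {bin_width_min}-min grid"
            )
        if s.concentration is None:
            raise ValidationError("samples must be quantified before alignment")
    samples = sorted(samples, key=lambda s: s.window_start_min)
    k_lo = int(round(samples[0].window_start_min / bin_width_min))
    k_hi = int(round(samples[-1].window_end_min / bin_width_min))
    edges = np.arange(k_lo, k_hi + 1) * bin_width_min
    values = np.full(k_hi - k_lo, np.nan)
    for s in samples:
        values[int(round(s.window_start_min / bin_width_min)) - k_lo] = s.concentration
    starts = edges[:-1]
    baseline = np.flatnonzero(np.isclose(starts, -bin_width_min))
    baseline_idx = int(baseline[0]) if baseline.size else None
    return BinnedSeries(bin_edges_min=edges, values=values, kind="serotonin"), baseline_idx


def series_table(series: DialysisSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_start_min": [s.window_start_min for s in series.samples],
            "window_end_min": [s.window_end_min for s in series.samples],
            "concentration_pg_ul": [s.concentration for s in series.samples],
            "below_lod": [s.below_lod for s in series.samples],
        }
    )
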