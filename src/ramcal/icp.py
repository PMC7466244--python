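"""Reference-method (ICP-AES) arithmetic.

The optical emission reference method quantifies each element against a
straight-line standard curve (blank + multi-element standards), with two
acceptance gates on the curve: the coefficient of determination must
exceed 0.995 and every non-blank standard must back-predict within 10%
of its nominal concentration.  Samples digested at high analyte levels
are diluted (e.g. 1:10 v/v) before measurement, so quantification
multiplies back by the dilution factor.  Repeatability of replicate
measurements is summarized as the pooled within-sample standard
deviation, and accuracy against a certified reference material as
percent recovery, %R = 100 * measured / certified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CalibrationCurve", "RecoveryReport", "CurveQualityError",
           "fit_calibration_curve", "predict_response", "quantify_sample",
           "summarize_measurements", "percent_recovery"]


class CurveQualityError(ValueError):
    """Standard curve failed an acceptance gate (names the gate)."""


@dataclass
class CalibrationCurve:
    standards: np.ndarray     # nominal concentrations, ppm (includes a blank)
    responses: np.ndarray     # instrument signal
    slope: float
    intercept: float
    r2: float
    element: str = ""
    wavelength: float | None = None   # monitored emission line, nm


@dataclass
class RecoveryReport:
    element: str
    measured: float
    certified: float
    recovery: float           # percent
    units: str = "mg/kg"


def fit_calibration_curve(standards, responses, element: str = "",
                          wavelength: float | None = None,
                          r2_min: float = 0.995,
                          max_back_error: float = 0.10) -> CalibrationCurve:
    """Ordinary least-squares standard curve with quality gates.

    Requires >= 3 points including a blank (0 ppm).  Rejects the curve
    when r^2 <= ``r2_min`` or when any non-blank standard back-predicts
    more than ``max_back_error`` (relative) from its nominal value.
    """
    c = np.asarray(standards, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size or c.size < 3:
        raise ValueError("need >= 3 (standard, response) pairs")
    if np.any(c < 0):
        raise ValueError("standard concentrations must be non-negative")
    if not np.any(c == 0):
        raise ValueError("standards must include a blank (0 ppm)")
    res = stats.linregress(c, r)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    curve = CalibrationCurve(c, r, slope, intercept, r2, element, wavelength)
    if r2 <= r2_min:
        raise CurveQualityError(
            f"linearity gate: r^2 = {r2:.4f} <= {r2_min} for {element or 'curve'}")
    if slope == 0:
        raise CurveQualityError("zero-slope curve cannot quantify")
    nonblank = c > 0
    back = (r[nonblank] - intercept) / slope
    rel = np.abs(back - c[nonblank]) / c[nonblank]
    if np.any(rel > max_back_error):
        worst = float(rel.max())
        raise CurveQualityError(
            f"back-prediction gate: max relative error {worst:.1%} "
            f"> {max_back_error:.0%} for {element or 'curve'}")
    return curve


def predict_response(curve: CalibrationCurve, concentration: float) -> float:
    """Instrument response the curve predicts for a concentration."""
    return curve.intercept + curve.slope * float(concentration)


def quantify_sample(curve: CalibrationCurve, response: float,
                    dilution_factor: float = 1.0) -> float:
    """Concentration (ppm) in the undiluted digest: d * (r - b0)/b1."""
    if curve.slope == 0:
        raise ZeroDivisionError("zero-slope curve")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return dilution_factor * (float(response) - curve.intercept) / curve.slope


def summarize_measurements(table: pd.DataFrame, iso_r: bool = False) -> pd.DataFrame:
    """Per-element summary of replicate measurements.

    ``table`` has columns sample_id, element, ppm with one row per
    replicate.  Returns min/max/mean/median of the per-sample means and
    the repeatability = pooled within-sample replicate standard
    deviation (sqrt of the df-weighted mean of within-sample variances);
    with ``iso_r`` the 2.8*SD repeatability limit is reported instead.
    """
    required = {"sample_id", "element", "ppm"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    out = []
    for element, sub in table.groupby("element", sort=False):
        g = sub.groupby("sample_id")["ppm"]
        means = g.mean()
        counts = g.count()
        # pooled within-sample SD; samples with a single replicate add no df
        ss = ((sub["ppm"] - sub["sample_id"].map(means)) ** 2).sum()
        df = int((counts - 1).sum())
        rep = float(np.sqrt(ss / df)) if df > 0 else 0.0
        if iso_r:
            rep *= 2.8
        out.append({
            "element": element,
            "min_ppm": float(means.min()),
            "max_ppm": float(means.max()),
            "mean_ppm": float(means.mean()),
            "median_ppm": float(means.median()),
            "repeatability_ppm": rep,
        })
    return pd.DataFrame(out)


def percent_recovery(measured: float, certified: float) -> float:
    """%R = 100 * measured / certified against a certified material."""
    if certified == 0:
        raise ZeroDivisionError("certified value must be nonzero")
    return 100.0 * float(measured) / float(certified)
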