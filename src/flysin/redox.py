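"""Glutathione (Ellman/DTNB) and DHE-based hydrogen peroxide computations.

Glutathione concentrations come from inverting an A415 calibration line
fitted on known GSH standards.  The free read measures reduced GSH; the
total read, taken after borohydride reduction, measures GSH + 2·GSSG, so
GSSG = (total − free) / 2.  DHE fluorescence (ex 480 / em 625 nm) is an
indirect, relative readout of H₂O₂: results are blank-corrected values and
fold-changes against the control group, never absolute concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "GlutathioneResult",
    "fit_calibration",
    "gsh_concentrations",
    "h2o2_relative",
    "analyze_assay_table",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line A415 = slope · concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    n_points: int

    def concentration(self, absorbance: float) -> float:
        """Invert the line; negative back-calculations are clipped to 0."""
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive to invert")
        c = (absorbance - self.intercept) / self.slope
        if c < 0:
            warnings.warn(f"back-calculated concentration {c:.4g} < 0 clipped to 0")
            return 0.0
        return float(c)

    def absorbance(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class GlutathioneResult:
    """Free (reduced) GSH, total glutathione, and derived GSSG, same units."""

    free_gsh: float
    total_gsh: float
    gssg: float
    total_below_free: bool = False


def fit_calibration(concentrations, absorbances) -> CalibrationCurve:
    """Ordinary least squares calibration line on ≥ 3 distinct standards."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 calibration points")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        warnings.warn("constant absorbance readings: R^2 undefined, assay flagged")
        r2 = np.nan
    else:
        r2 = float(res.rvalue**2)
    return CalibrationCurve(float(res.slope), float(res.intercept), r2,
                            float(res.stderr), len(x))


def gsh_concentrations(free_read: float, total_read: float,
                       curve: CalibrationCurve) -> GlutathioneResult:
    """Back-calculate GSH/total/GSSG from the two absorbance reads.

    GSSG = (total − free)/2, since each GSSG yields two GSH on reduction.
    If the total read falls below the free read (plate noise), GSSG is
    clipped at 0 and the record flagged.
    """
    free = curve.concentration(free_read)
    total = curve.concentration(total_read)
    below = total < free
    if below:
        warnings.warn("total glutathione below free GSH; GSSG clipped to 0")
    gssg = max(0.0, (total - free) / 2.0)
    return GlutathioneResult(free, total, gssg, total_below_free=below)


def h2o2_relative(readings: pd.DataFrame, blank: float,
                  control_group: str | None = None) -> pd.DataFrame:
    """Blank-corrected DHE fluorescence and fold-change vs the control group.

    ``readings`` needs columns ``group`` and ``value``.  Adds
    ``corrected`` (= value − blank) and ``ratio_to_control`` (corrected /
    control-group mean corrected).  The control is ``control_group`` or, if
    None, the first group in sorted order.
    """
    out = readings.copy()
    out["corrected"] = out["value"] - blank
    groups = sorted(out["group"].unique())
    ctrl = control_group if control_group is not None else groups[0]
    if ctrl not in groups:
        raise ValueError(f"control group {ctrl!r} not present")
    ctrl_mean = float(out.loc[out["group"] == ctrl, "corrected"].mean())
    out["ratio_to_control"] = out["corrected"] / ctrl_mean if ctrl_mean != 0 else np.nan
    return out


def analyze_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample glutathione results from the assay CSV dialect.

    Expects columns sample_id, reading_type (free|total|calib),
    concentration (calibration rows), value.  One shared calibration per
    table.
    """
    calib = df[df["reading_type"] == "calib"]
    curve = fit_calibration(calib["concentration"], calib["value"])
    rows = []
    for sid, sub in df[df["reading_type"] != "calib"].groupby("sample_id", sort=True):
        free = float(sub.loc[sub["reading_type"] == "free", "value"].iloc[0])
        total = float(sub.loc[sub["reading_type"] == "total", "value"].iloc[0])
        res = gsh_concentrations(free, total, curve)
        rows.append({"sample_id": sid, "free_gsh": res.free_gsh,
                     "total_gsh": res.total_gsh, "gssg": res.gssg,
                     "flagged": res.total_below_free})
    return pd.DataFrame(rows, columns=["sample_id", "free_gsh", "total_gsh", "gssg", "flagged"])
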