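"""Isotope-dilution responses, matrix-matched calibration and ICH LOD/LOQ.

The measured quantity is the response: the analyte 12C peak area divided by
the area of its 13C internal-standard channel (own 13C isotopologue, or the
13C channel of the panel-assigned surrogate). Ratioing against a co-analyzed
labeled standard cancels matrix ionization effects and injection variability.

Matrix-matched calibration prepares external standards in pooled biological
matrix; the endogenous background response (measured on matrix-only blanks)
is subtracted from the standard responses before ordinary least-squares
regression, so the fitted slope reflects added concentration only.

Sensitivity follows the ICH slope method on a dedicated low-concentration
series: LOD = 3.3 sigma / S and LOQ = 10 sigma / S, with S the regression
slope and sigma the residual standard deviation of the low-range fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import AnalytePanel, PeakTable, channel_id

__all__ = [
    "LOD_FACTOR",
    "LOQ_FACTOR",
    "LOQ_LOD_RATIO",
    "CalibrationCurve",
    "CalibrationError",
    "compute_responses",
    "subtract_matrix_background",
    "fit_calibration",
    "estimate_lod_loq",
    "loq_from_lod",
    "back_calculate",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0
#: LOQ/LOD is 10/3.3 by construction of the slope method.
LOQ_LOD_RATIO = LOQ_FACTOR / LOD_FACTOR


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float  # response per nM
    intercept: float  # response units
    r_squared: float
    residual_sd: float  # response units, n-2 denominator
    n_points: int
    lod: float | None = None  # nM
    loq: float | None = None  # nM
    matrix_matched: bool = False
    rejected: bool = False

    def with_sensitivity(self, lod: float, loq: float) -> "CalibrationCurve":
        return replace(self, lod=lod, loq=loq)


def compute_responses(peaks: PeakTable, panel: AnalytePanel) -> pd.DataFrame:
    """Per-(sample, analyte) isotope-dilution response ratios.

    Returns a frame with columns ``sample_id``, ``analyte``, ``response``,
    ``istd_channel``, ``no_istd`` plus the sample-level descriptors carried
    through from the peak table (role, level, replicate indices, timepoint).
    Records whose ISTD area is zero or missing are flagged ``no_istd`` with a
    NaN response; they are excluded downstream.
    """
    df = peaks.data
    areas = df.set_index(["sample_id", "channel_id"])["area"]
    carry_cols = ["role", "level_nM", "tech_rep", "bio_rep", "timepoint"]
    sample_info = df.drop_duplicates("sample_id").set_index("sample_id")[carry_cols]

    rows = []
    n_no_istd = 0
    for analyte in panel.names:
        chan12 = channel_id(analyte, "12C")
        istd_chan = panel.istd_channel(analyte)
        a12 = areas.xs(chan12, level="channel_id", drop_level=True) \
            if chan12 in df["channel_id"].values else pd.Series(dtype=float)
        a13 = areas.xs(istd_chan, level="channel_id", drop_level=True) \
            if istd_chan in df["channel_id"].values else pd.Series(dtype=float)
        joined = pd.DataFrame({"a12": a12, "a13": a13}).dropna(subset=["a12"])
        if joined.empty:
            continue
        no_istd = joined["a13"].isna() | (joined["a13"] == 0)
        n_no_istd += int(no_istd.sum())
        resp = joined["a12"] / joined["a13"].where(~no_istd)
        block = pd.DataFrame({
            "sample_id": joined.index,
            "analyte": analyte,
            "response": resp.values,
            "istd_channel": istd_chan,
            "no_istd": no_istd.values,
        })
        rows.append(block)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "analyte", "response", "istd_channel", "no_istd"]
    )
    out = out.join(sample_info, on="sample_id")
    if n_no_istd:
        import logging
        logging.getLogger(__name__).warning(
            "%d response(s) flagged no-ISTD (zero/missing 13C area)", n_no_istd
        )
    return out


def subtract_matrix_background(
    standards: pd.DataFrame, blanks: pd.DataFrame
) -> pd.DataFrame:
    """Subtract the mean matrix-blank response per analyte from standard responses.

    Negative corrected responses are clipped to zero and flagged
    (``clipped`` column). Requires at least one blank response per analyte
    present in ``standards``.
    """
    if blanks.empty:
        raise CalibrationError("matrix-matched calibration requested but no blanks given")
    bg = blanks.groupby("analyte")["response"].mean()
    missing = set(standards["analyte"]) - set(bg.index)
    if missing:
        raise CalibrationError(f"no matrix blanks for analytes: {sorted(missing)}")
    out = standards.copy()
    corrected = out["response"] - out["analyte"].map(bg)
    out["clipped"] = corrected < 0
    out["response"] = corrected.clip(lower=0.0)
    return out


def fit_calibration(
    points: pd.DataFrame | list[tuple[float, float]],
    analyte: str = "",
    matrix_matched: bool = False,
    weighting: str = "1/x",
) -> CalibrationCurve:
    """Least-squares calibration fit on (nominal nM, response) points.

    MRM peak-area noise is close to a constant relative CV, so residual
    variance grows with concentration; over a 200-fold calibration range an
    unweighted fit lets the top standards dominate and leaves the intercept
    poorly determined at the scale of low-abundance analytes. The default is
    therefore 1/x-weighted least squares (the standard choice for wide-range
    chromatographic calibration); pass ``weighting="none"`` for ordinary
    least squares.

    Replicate injections at a level are retained as individual points.
    Requires >= 3 distinct concentration levels. A negative fitted slope
    marks the curve rejected (it is returned, but cannot be used for
    back-calculation). R^2 and the residual SD are reported unweighted.
    """
    if isinstance(points, pd.DataFrame):
        x = np.asarray(points["level_nM"], dtype=float)
        y = np.asarray(points["response"], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 3:
        raise CalibrationError(
            f"{analyte or 'calibration'}: need >= 3 distinct levels, got {len(np.unique(x))}"
        )
    if weighting == "none":
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif weighting == "1/x":
        if (x <= 0).any():
            raise CalibrationError(
                f"{analyte or 'calibration'}: 1/x weighting requires positive levels"
            )
        w = 1.0 / x
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve((X.T * w) @ X, (X.T * w) @ y)
        intercept, slope = float(beta[0]), float(beta[1])
    else:
        raise CalibrationError(f"unknown weighting {weighting!r}")
    resid = y - (intercept + slope * x)
    n = len(x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        residual_sd=residual_sd,
        n_points=n,
        matrix_matched=matrix_matched,
        rejected=slope <= 0,
    )


def estimate_lod_loq(
    low_series: pd.DataFrame | list[tuple[float, float]],
    analyte: str = "",
    min_levels: int = 5,
) -> tuple[float, float]:
    """ICH slope-method LOD/LOQ from a low-concentration regression series.

    LOD = 3.3 sigma / S, LOQ = 10 sigma / S, with sigma the residual SD and S
    the slope of the low-range fit. The series should span the expected
    detection region (sub-nM to ~100 nM).
    """
    if isinstance(low_series, pd.DataFrame):
        n_levels = low_series["level_nM"].nunique()
    else:
        n_levels = len({p[0] for p in low_series})
    if n_levels < min_levels:
        raise CalibrationError(
            f"{analyte or 'LOD series'}: need >= {min_levels} levels, got {n_levels}"
        )
    # ICH slope method: ordinary (unweighted) regression on the low range,
    # where the response variance is near-constant
    curve = fit_calibration(low_series, analyte=analyte, weighting="none")
    if curve.slope <= 0:
        raise CalibrationError(f"{analyte or 'LOD series'}: non-positive slope")
    lod = LOD_FACTOR * curve.residual_sd / curve.slope
    loq = LOQ_FACTOR * curve.residual_sd / curve.slope
    return lod, loq


def loq_from_lod(lod: float) -> float:
    """LOQ implied by an LOD under the slope method (ratio 10/3.3)."""
    return lod * LOQ_LOD_RATIO


def back_calculate(response, curve: CalibrationCurve):
    """Invert the calibration: concentration (nM) = (response - intercept) / S.

    Negative back-calculated concentrations are reported as 0. Accepts a
    scalar or array; returns the same shape.
    """
    if curve.rejected:
        raise CalibrationError(f"{curve.analyte}: curve rejected, cannot back-calculate")
    x = (np.asarray(response, dtype=float) - curve.intercept) / curve.slope
    x = np.clip(x, 0.0, None)
    if np.ndim(response) == 0:
        return float(x)
    return x
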