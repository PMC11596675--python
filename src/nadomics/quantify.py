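"""Extract concentrations to absolute intracellular pools.

Back-calculated extract concentrations (nM) are first censored against the
analyte's LOQ (an instrument-domain quantity, so censoring happens before
any biology-domain conversion), then converted to intracellular pools in
nmol per gram cell dry weight:

    amount (nmol)  = conc_nM * dilution_factor * extract_volume (L)
    biomass (g)    = CDW (g/L) * sampled broth volume (L)
    pool           = amount / biomass          [nmol / g CDW]

Replicate groups are screened for a single outlier with a two-tailed Dixon's
Q test at 95% confidence; outliers are retained in the matrix but flagged and
excluded from summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve

__all__ = [
    "DIXON_Q_TWO_TAILED_95",
    "normalize_to_cdw",
    "censor_below_loq",
    "dixon_q_filter",
    "apply_dixon_by_group",
]

#: Two-tailed critical values for Dixon's r10 ("Q") statistic at the 95%
#: confidence level, n = 3..30 (standard published table, Rorabacher 1991).
DIXON_Q_TWO_TAILED_95: dict[int, float] = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


def normalize_to_cdw(
    extract_conc_nM,
    dilution_factor: float,
    extract_volume_l: float,
    broth_volume_l: float,
    cdw_g_per_l: float,
):
    """Convert an extract concentration (nM) to nmol per g CDW.

    Linear in the concentration and in the dilution factor; inversely
    proportional to biomass (CDW x sampled volume).
    """
    if extract_volume_l <= 0 or broth_volume_l <= 0:
        raise ValueError("volumes must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    biomass_g = cdw_g_per_l * broth_volume_l
    if biomass_g <= 0:
        raise ValueError("biomass (CDW x broth volume) must be positive")
    conc = np.asarray(extract_conc_nM, dtype=float)
    if (conc < 0).any():
        raise ValueError("extract concentration must be >= 0")
    amount_nmol = conc * dilution_factor * extract_volume_l
    out = amount_nmol / biomass_g
    return float(out) if np.ndim(extract_conc_nM) == 0 else out


def censor_below_loq(values_nM, curve: CalibrationCurve) -> pd.DataFrame:
    """Flag extract-level concentrations below the curve's LOQ.

    Returns a frame with ``value_nM`` and boolean ``censored``; values equal
    to the LOQ are quantifiable (strict < comparison). Censored values should
    be excluded from means and tests and reported as "<LOQ".
    """
    if curve.loq is None:
        raise ValueError(f"{curve.analyte}: curve has no LOQ")
    vals = np.atleast_1d(np.asarray(values_nM, dtype=float))
    return pd.DataFrame({"value_nM": vals, "censored": vals < curve.loq})


def dixon_q_filter(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass two-tailed Dixon's Q outlier test on one replicate group.

    Q = gap / range for the more extreme of the two end values, compared to
    the tabulated two-tailed critical value. At most one value is removed.
    Returns (kept, removed) arrays; groups of n < 3 (with a warning) or zero
    range are returned unchanged.
    """
    if alpha != 0.05:
        raise ValueError("critical values are tabulated for alpha = 0.05 only")
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 3:
        warnings.warn(f"Dixon's Q needs n >= 3 (got {n}); no test applied", stacklevel=2)
        return vals, np.array([])
    if n > 30:
        raise ValueError("Dixon's Q critical values tabulated for n <= 30")
    s = np.sort(vals)
    rng = s[-1] - s[0]
    if rng == 0:
        return vals, np.array([])
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    if q_high >= q_low:
        q, suspect = q_high, s[-1]
    else:
        q, suspect = q_low, s[0]
    if q > DIXON_Q_TWO_TAILED_95[n]:
        # remove exactly one occurrence of the suspect value
        idx = int(np.where(vals == suspect)[0][0])
        keep = np.delete(vals, idx)
        return keep, np.array([suspect])
    return vals, np.array([])


def apply_dixon_by_group(
    quant: pd.DataFrame,
    value_col: str = "conc_nmol_per_gcdw",
    group_cols: tuple[str, ...] = ("analyte", "timepoint", "bio_rep"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag at most one Dixon outlier per technical-replicate group.

    Censored records are not tested. Outliers stay in the frame with
    ``outlier=True`` so summaries can exclude them while the record remains
    auditable.
    """
    out = quant.copy()
    out["outlier"] = False
    testable = ~out.get("censored", pd.Series(False, index=out.index)).astype(bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small groups are expected, not reportable
        for _, idx in out[testable].groupby(list(group_cols)).groups.items():
            vals = out.loc[idx, value_col].to_numpy(dtype=float)
            if len(vals) < 3 or len(vals) > 30:
                continue
            _, removed = dixon_q_filter(vals, alpha=alpha)
            if len(removed):
                pos = idx[np.where(vals == removed[0])[0][0]]
                out.loc[pos, "outlier"] = True
    return out
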