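"""Method-validation metrics: precision, accuracy and stability recovery.

Precision is the coefficient of variation (%CV) of replicate back-calculated
QC concentrations; accuracy is the relative bias (%) against the nominal QC
level. Both are computed intraday (per day) and interday (pooled across
days), with an acceptance band of +-20%.

Stability is expressed as percentage recovery (after / before incubation or
treatment), with condition-specific acceptance bands: the freeze-thaw default
is 75-120%; autosampler reports additionally annotate the narrower 75-115%
band observed for 24 h at 6 degC.

Matrix caveat: when the pooled matrix carries more endogenous analyte than
the low QC level itself (true for NAD+ and NADH vs 250 nM), the bias at that
level is meaningless and is skipped rather than reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCResult",
    "RecoveryResult",
    "precision_accuracy",
    "recovery",
    "skip_rule_below_matrix",
    "ACCEPTANCE_CV_PERCENT",
    "ACCEPTANCE_BIAS_PERCENT",
    "RECOVERY_BANDS",
]

ACCEPTANCE_CV_PERCENT = 20.0
ACCEPTANCE_BIAS_PERCENT = 20.0

#: Acceptance bands (%) by stability condition.
RECOVERY_BANDS = {
    "autosampler_24h": (75.0, 120.0),
    "freeze_thaw": (75.0, 120.0),
}
#: The band observed for 24 h autosampler storage, annotated on reports.
AUTOSAMPLER_OBSERVED_BAND = (75.0, 115.0)


@dataclass(frozen=True)
class QCResult:
    analyte: str
    qc_level: float  # nominal nM
    scope: str  # "intraday" or "interday"
    day: object | None
    n: int
    mean_measured: float
    cv_percent: float | None
    bias_percent: float | None
    cv_pass: bool | None
    bias_pass: bool | None
    bias_skipped: bool = False


@dataclass(frozen=True)
class RecoveryResult:
    analyte: str
    condition: str
    cycle: int | None
    level: object
    recovery_percent: float | None
    acceptance: str  # "pass" | "fail" | "undefined"


def _cell_result(analyte, level, scope, day, values, skip_bias: bool) -> QCResult:
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(np.mean(values)) if n else float("nan")
    if n < 3:
        warnings.warn(
            f"{analyte} @ {level} nM ({scope}): only {n} replicate(s); "
            "CV/bias computed with reduced confidence",
            stacklevel=3,
        )
    if mean == 0 or n < 2:
        cv = None
        cv_pass = None
    else:
        cv = 100.0 * float(np.std(values, ddof=1)) / mean
        cv_pass = abs(cv) <= ACCEPTANCE_CV_PERCENT
    if skip_bias or n == 0:
        bias, bias_pass = None, None
    else:
        bias = 100.0 * (mean - level) / level
        bias_pass = abs(bias) <= ACCEPTANCE_BIAS_PERCENT
    return QCResult(
        analyte=analyte, qc_level=float(level), scope=scope, day=day, n=n,
        mean_measured=mean, cv_percent=cv, bias_percent=bias,
        cv_pass=cv_pass, bias_pass=bias_pass, bias_skipped=skip_bias,
    )


def precision_accuracy(
    qc: pd.DataFrame,
    matrix_endogenous: dict[str, float] | None = None,
    interday: str = "pooled",
) -> list[QCResult]:
    """Intraday and interday %CV and bias% from back-calculated QC injections.

    Parameters
    ----------
    qc : frame with columns ``analyte``, ``level_nM``, ``day``, ``measured_nM``
    matrix_endogenous : optional mapping analyte -> endogenous concentration
        (nM) in the calibration matrix; bias is skipped for cells whose QC
        level lies below it (see :func:`skip_rule_below_matrix`).
    interday : "pooled" pools replicates across days (default); "mean_of_days"
        computes CV/bias on daily means instead.
    """
    matrix_endogenous = matrix_endogenous or {}
    results: list[QCResult] = []
    for (analyte, level), grp in qc.groupby(["analyte", "level_nM"], sort=False):
        skip = skip_rule_below_matrix(level, matrix_endogenous.get(analyte, 0.0))
        for day, day_grp in grp.groupby("day", sort=False):
            results.append(
                _cell_result(analyte, level, "intraday", day,
                             day_grp["measured_nM"], skip)
            )
        if interday == "pooled":
            vals = grp["measured_nM"]
        elif interday == "mean_of_days":
            vals = grp.groupby("day")["measured_nM"].mean()
        else:
            raise ValueError(f"unknown interday mode {interday!r}")
        results.append(_cell_result(analyte, level, "interday", None, vals, skip))
    return results


def recovery(
    before: pd.DataFrame,
    after: pd.DataFrame,
    condition: str,
    cycle: int | None = None,
    band: tuple[float, float] | None = None,
) -> list[RecoveryResult]:
    """Percentage recovery = 100 * mean(after) / mean(before), per analyte x level.

    Frames need columns ``analyte``, ``level``, ``measured_nM``; pairs are
    matched on (analyte, level). A zero before-mean yields an undefined
    (flagged) recovery.
    """
    if band is None:
        key = "freeze_thaw" if condition.startswith("freeze_thaw") else condition
        band = RECOVERY_BANDS.get(key, (75.0, 120.0))
    b = before.groupby(["analyte", "level"])["measured_nM"].mean()
    a = after.groupby(["analyte", "level"])["measured_nM"].mean()
    results = []
    for key in b.index:
        if key not in a.index:
            continue
        analyte, level = key
        if b[key] == 0:
            results.append(RecoveryResult(analyte, condition, cycle, level, None, "undefined"))
            continue
        rec = 100.0 * a[key] / b[key]
        ok = band[0] <= rec <= band[1]
        results.append(
            RecoveryResult(analyte, condition, cycle, level, float(rec),
                           "pass" if ok else "fail")
        )
    return results


def skip_rule_below_matrix(qc_level: float, matrix_endogenous: float) -> bool:
    """True when bias at this QC level should be skipped.

    The endogenous pool in the calibration matrix dominates the spiked
    amount when it exceeds the QC level (strict inequality), making relative
    bias against the nominal level uninterpretable.
    """
    return matrix_endogenous > qc_level
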