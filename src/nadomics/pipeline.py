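"""End-to-end orchestration: peak areas -> validated intracellular pools.

Stages: isotope-dilution responses, matrix-background subtraction,
matrix-matched OLS calibration with ICH LOD/LOQ from the low-concentration
series, back-calculation of unknowns, LOQ censoring at extract level, CDW
normalization, and Dixon's-Q outlier flagging per technical-replicate group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal
from .panel_io import AnalytePanel, PeakTable
from .quantify import apply_dixon_by_group, normalize_to_cdw

__all__ = ["PipelineResult", "fit_panel_curves", "quantify_unknowns", "run_pipeline"]


@dataclass
class PipelineResult:
    curves: dict[str, cal.CalibrationCurve]
    quant: pd.DataFrame  # long-format quantification matrix
    responses: pd.DataFrame
    qc_measured: pd.DataFrame  # back-calculated QC concentrations (nM)


def fit_panel_curves(
    peaks: PeakTable,
    panel: AnalytePanel,
    matrix_matched: bool = True,
) -> tuple[dict[str, cal.CalibrationCurve], pd.DataFrame]:
    """Fit one calibration curve per quantified analyte from a calibration batch.

    Standards (role ``standard``) are blank-subtracted against the matrix
    blanks before regression; sensitivity (role ``lod_standard``, prepared in
    solvent) feeds the LOD/LOQ regression. Returns (curves, responses).
    """
    responses = cal.compute_responses(peaks, panel)
    responses = responses[~responses["no_istd"]]
    std = responses[responses["role"] == "standard"]
    blanks = responses[responses["role"] == "blank"]
    low = responses[responses["role"] == "lod_standard"]
    if matrix_matched:
        std = cal.subtract_matrix_background(std, blanks)
    curves: dict[str, cal.CalibrationCurve] = {}
    for analyte, grp in std.groupby("analyte"):
        curve = cal.fit_calibration(grp, analyte=analyte, matrix_matched=matrix_matched)
        low_grp = low[low["analyte"] == analyte]
        if len(low_grp):
            lod, loq = cal.estimate_lod_loq(low_grp, analyte=analyte)
            curve = curve.with_sensitivity(lod, loq)
        curves[analyte] = curve
    return curves, responses


def quantify_unknowns(
    peaks: PeakTable,
    meta: pd.DataFrame,
    panel: AnalytePanel,
    curves: dict[str, cal.CalibrationCurve],
    dixon: bool = True,
) -> pd.DataFrame:
    """Back-calculate, censor, normalize and outlier-screen unknown samples."""
    responses = cal.compute_responses(peaks, panel)
    responses = responses[~responses["no_istd"]]
    unknowns = responses[responses["role"] == "unknown"].copy()
    meta_idx = meta.set_index("sample_id")

    rows = []
    for analyte, grp in unknowns.groupby("analyte"):
        curve = curves.get(analyte)
        if curve is None or curve.rejected:
            continue
        conc_nM = cal.back_calculate(grp["response"].to_numpy(), curve)
        censored = (
            conc_nM < curve.loq if curve.loq is not None
            else np.zeros(len(conc_nM), dtype=bool)
        )
        for (_, rec), c, cen in zip(grp.iterrows(), conc_nM, censored):
            m = meta_idx.loc[rec["sample_id"]]
            pool = normalize_to_cdw(
                c,
                dilution_factor=float(m["dilution_factor"]),
                extract_volume_l=float(m["extract_volume_l"]),
                broth_volume_l=float(m["broth_volume_l"]),
                cdw_g_per_l=float(m["cdw_g_per_l"]),
            )
            rows.append({
                "analyte": analyte,
                "sample_id": rec["sample_id"],
                "timepoint": rec["timepoint"],
                "bio_rep": rec["bio_rep"],
                "tech_rep": rec["tech_rep"],
                "extract_nM": c,
                "conc_nmol_per_gcdw": pool,
                "censored": bool(cen),
            })
    quant = pd.DataFrame(rows)
    if dixon and len(quant):
        quant = apply_dixon_by_group(quant)
    elif len(quant):
        quant["outlier"] = False
    return quant


def run_pipeline(
    cal_peaks: PeakTable,
    sample_peaks: PeakTable,
    meta: pd.DataFrame,
    panel: AnalytePanel,
    matrix_matched: bool = True,
    dixon: bool = True,
) -> PipelineResult:
    """Full chain from a calibration batch plus biological samples."""
    curves, responses = fit_panel_curves(cal_peaks, panel, matrix_matched=matrix_matched)

    # back-calculate the QC injections for precision/accuracy reporting
    qc = responses[responses["role"] == "qc"]
    qc_rows = []
    for analyte, grp in qc.groupby("analyte"):
        curve = curves.get(analyte)
        if curve is None or curve.rejected:
            continue
        measured = cal.back_calculate(grp["response"].to_numpy(), curve)
        for (_, rec), m in zip(grp.iterrows(), measured):
            qc_rows.append({
                "analyte": analyte, "sample_id": rec["sample_id"],
                "level_nM": rec["level_nM"], "measured_nM": m,
            })
    quant = quantify_unknowns(sample_peaks, meta, panel, curves, dixon=dixon)
    return PipelineResult(
        curves=curves,
        quant=quant,
        responses=responses,
        qc_measured=pd.DataFrame(qc_rows),
    )
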